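"""Worked example on PDB entry 1UBY (requires network access once).

1UBY deposits two REMARK 350 biomolecules: biomolecule 1 is the dimer
recommended by the entry's authors; biomolecule 2 is a dimer proposed by
a computational tool.  The biomolecule-2 interface buries substantial
area (dASA about 1767 A^2) yet sits on a *flexible* patch — its
avg_sigma_b is large and positive (about +15) — so the B-factor score
flags it as a likely packing artifact even though its size looks
biological.
"""

import math

from betaface import ContactParams, delta_asa
from betaface.beta_contacts import beta_contacts, interfacial_atoms
from betaface.bfactor_features import compute_features, pair_normalized_bfactors
from betaface.fetch import fetch_pdb
from betaface.structure_io import ComplexPair, assemble_biounit, load_structure

text = fetch_pdb("1UBY")
st = load_structure(text, entry_id="1UBY")

bvals = [a.bfactor_raw for atoms in st.chains.values() for a in atoms]
print(f"raw B-factor range: [{min(bvals):.2f}, {max(bvals):.2f}]")

for asm in st.assemblies:
    if len(asm.transforms) < 2:
        continue
    unit_a = assemble_biounit(st, asm.chain_ids, [asm.transforms[0]], "A")
    unit_b = assemble_biounit(st, asm.chain_ids, asm.transforms[1:], "B")
    pair = ComplexPair("1UBY", unit_a, unit_b)
    contacts = beta_contacts(pair, ContactParams())
    interf = interfacial_atoms(pair, contacts)
    feats = compute_features(pair, interf, pair_normalized_bfactors(pair),
                             log_base=math.e)
    dasa, _ = delta_asa(pair)
    print(f"biomolecule {asm.name}: avg_sigma_b = {feats.avg_sigma_b:7.2f}  "
          f"dASA = {dasa:8.2f} A^2  ({feats.n_interfacial} interfacial atoms)")

print("\nA large positive avg_sigma_b on a large interface is the "
      "signature of a mis-annotated crystal contact.")
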