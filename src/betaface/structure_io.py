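"""Read PDB structures, assemble biological units, infer covalent bonds.

The quantities downstream (β contacts, normalized B factors, ΔASA) are all
defined on *biological units* — groups of chains, possibly including
symmetry copies generated from REMARK 350 BIOMT operators. This module
turns PDB text into plain atom tables, applies assembly transforms, infers
the covalent-bond graph needed for the local-contact rule, and applies the
entry-level quality filters used when compiling benchmark datasets from
crystallographic entries.

Parsing is delegated to :mod:`gemmi`; a light fixed-column validation pass
runs first so that malformed coordinate or B-factor fields produce errors
that name the offending line.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "BioUnit",
    "ComplexPair",
    "EntryQC",
    "Structure",
    "Assembly",
    "IOConfig",
    "load_structure",
    "assemble_biounit",
    "infer_covalent_bonds",
    "covalent_nearby",
    "filter_complex_entry",
    "to_pdb_text",
    "load_config",
]

#: van der Waals radii (Å) used for the contact distance criterion and SASA.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
}
DEFAULT_VDW_RADIUS = 1.70

#: single-bond covalent radii (Å) for bond inference.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "S": 1.05,
    "P": 1.07,
    "SE": 1.20,
    "F": 0.57,
    "CL": 1.02,
    "BR": 1.20,
    "I": 1.39,
}
DEFAULT_COVALENT_RADIUS = 0.77

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class PDBParseError(ValueError):
    """Raised for malformed PDB records; message names the line number."""


@dataclass
class IOConfig:
    """Structure-reading policy.

    Parameters
    ----------
    vdw_radii : element symbol → radius (Å); missing elements fall back to
        ``default_vdw_radius``.
    covalent_tolerance : slack (Å) added to summed covalent radii when
        inferring bonds.
    drop_hydrogens : exclude H/D atoms entirely (most X-ray depositions
        lack them; including them would make features deposition-dependent).
    keep_hetero : retain non-water HETATM atoms.  They never become
        interfacial-atom candidates but may block β contacts.
    """

    vdw_radii: dict[str, float] = field(default_factory=lambda: dict(VDW_RADII))
    default_vdw_radius: float = DEFAULT_VDW_RADIUS
    covalent_tolerance: float = 0.4
    disulfide_cutoff: float = 2.3
    drop_hydrogens: bool = True
    keep_hetero: bool = True


DEFAULT_CONFIG = IOConfig()


def load_config(path: str) -> IOConfig:
    """Read a ``key = value`` config file into an :class:`IOConfig`.

    Recognised keys: ``covalent_tolerance``, ``disulfide_cutoff``,
    ``drop_hydrogens``, ``keep_hetero``, ``default_vdw_radius`` and
    ``vdw.<ELEMENT>`` entries overriding single radii.
    """
    cfg = IOConfig()
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key.startswith("vdw."):
                cfg.vdw_radii[key[4:].upper()] = float(value)
            elif key in ("covalent_tolerance", "disulfide_cutoff", "default_vdw_radius"):
                setattr(cfg, key, float(value))
            elif key in ("drop_hydrogens", "keep_hetero"):
                setattr(cfg, key, value.lower() in ("1", "true", "yes"))
            else:
                raise ValueError(f"unknown config key: {key!r}")
    return cfg


@dataclass
class Atom:
    """One coordinate record.

    ``bfactor_raw`` is the PDB B column in Å²; ``vdw_radius`` is assigned
    from the element at load time.  ``residue_id`` is
    (chain id, residue sequence number, insertion code).
    """

    serial: int
    element: str
    name: str
    residue_id: tuple[str, int, str]
    residue_name: str
    coord: np.ndarray
    bfactor_raw: float
    occupancy: float = 1.0
    altloc: str = ""
    is_standard_residue: bool = True
    is_hetero: bool = False
    vdw_radius: float = DEFAULT_VDW_RADIUS

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.serial}: non-finite coordinates")
        if self.bfactor_raw < 0:
            raise ValueError(f"atom {self.serial}: negative B factor")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.serial}: non-positive vdW radius")

    @property
    def chain_id(self) -> str:
        return self.residue_id[0]


@dataclass
class Assembly:
    """One REMARK 350 biomolecule: chain selection plus BIOMT operators."""

    name: str
    chain_ids: list[str]
    transforms: list[tuple[np.ndarray, np.ndarray]]  # (3x3 rotation, translation)


@dataclass
class Structure:
    """Parsed entry: atoms grouped by chain, plus entry-level metadata."""

    entry_id: str
    chains: dict[str, list[Atom]]
    assemblies: list[Assembly]
    resolution: float | None = None
    experimental_method: str | None = None

    def chain_ids(self) -> list[str]:
        return list(self.chains)


class BioUnit:
    """One binding partner: a set of chains with atoms and a bond graph.

    Atom ids inside a unit are positional indices ``0..n_atoms-1``.  The
    covalent bond graph (symmetric adjacency, same ids) is inferred lazily.
    """

    def __init__(self, unit_id: str, atoms: Sequence[Atom],
                 config: IOConfig = DEFAULT_CONFIG):
        if not atoms:
            raise ValueError(f"biological unit {unit_id!r} has no atoms")
        self.unit_id = unit_id
        self.atoms: list[Atom] = list(atoms)
        self.config = config
        self.chains: list[str] = sorted({a.chain_id for a in self.atoms})
        self._bond_graph: dict[int, set[int]] | None = None
        counts: dict[str, set[tuple[int, str]]] = defaultdict(set)
        for a in self.atoms:
            if a.is_standard_residue and not a.is_hetero:
                counts[a.chain_id].add(a.residue_id[1:])
        # hetero-only chains (e.g. a symmetry copy of ligands) count 0 residues
        self.n_residues_per_chain: dict[str, int] = {
            c: len(counts.get(c, ())) for c in self.chains
        }

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    @property
    def bfactors(self) -> np.ndarray:
        return np.array([a.bfactor_raw for a in self.atoms], dtype=float)

    @property
    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    @property
    def bond_graph(self) -> dict[int, set[int]]:
        if self._bond_graph is None:
            self._bond_graph = infer_covalent_bonds(self)
        return self._bond_graph

    def n_residues(self) -> int:
        return sum(self.n_residues_per_chain.values())

    def mean_residues_per_chain(self) -> float:
        counts = [c for c in self.n_residues_per_chain.values() if c > 0]
        if not counts:
            raise ValueError(f"unit {self.unit_id!r} has no polymer residues")
        return float(np.mean(counts))


@dataclass
class ComplexPair:
    """Two biological units from one entry, with an optional class label.

    Atom ids at the pair level are global: unit A keeps its local ids,
    unit B's are offset by ``len(unit_a)``, so the two id sets are disjoint.
    """

    entry_id: str
    unit_a: BioUnit
    unit_b: BioUnit
    label: str = "unknown"
    resolution: float | None = None

    def __post_init__(self) -> None:
        if self.label not in ("biological", "packing", "unknown"):
            raise ValueError(f"bad label {self.label!r}")

    @property
    def n_a(self) -> int:
        return len(self.unit_a)

    @property
    def n_b(self) -> int:
        return len(self.unit_b)

    def coords(self) -> np.ndarray:
        return np.vstack([self.unit_a.coords, self.unit_b.coords])

    def vdw_radii(self) -> np.ndarray:
        return np.concatenate([self.unit_a.vdw_radii, self.unit_b.vdw_radii])

    def unit_of(self, gid: int) -> str:
        return "A" if gid < self.n_a else "B"

    def atom(self, gid: int) -> Atom:
        if gid < self.n_a:
            return self.unit_a.atoms[gid]
        return self.unit_b.atoms[gid - self.n_a]

    def bond_graph(self) -> dict[int, set[int]]:
        """Union of both units' covalent graphs under global atom ids."""
        graph = {i: set(nb) for i, nb in self.unit_a.bond_graph.items()}
        off = self.n_a
        for i, nbrs in self.unit_b.bond_graph.items():
            graph[i + off] = {j + off for j in nbrs}
        return graph

    def candidate_mask(self) -> np.ndarray:
        """Interfacial-atom candidacy: standard-residue, non-hetero atoms."""
        flags = [a.is_standard_residue and not a.is_hetero
                 for a in self.unit_a.atoms + self.unit_b.atoms]
        return np.array(flags, dtype=bool)


@dataclass
class EntryQC:
    """Entry-level quality facts checked by :func:`filter_complex_entry`."""

    method: str
    resolution: float
    n_atoms: int
    n_residues: int
    partner_residue_counts: tuple[int, int]
    nonstandard_contact_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.nonstandard_contact_fraction <= 1.0:
            raise ValueError("nonstandard_contact_fraction outside [0, 1]")


# ---------------------------------------------------------------------------
# parsing

def _validate_pdb_lines(pdb_text: str) -> None:
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        padded = line.ljust(80)
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z"),
                             (54, 60, "occupancy"), (60, 66, "B factor")):
            fld = padded[lo:hi].strip()
            if fld == "" and what in ("occupancy", "B factor"):
                continue
            try:
                float(fld)
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: malformed {what} field {fld!r}"
                ) from None


def _dedup_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per (residue, atom name): highest occupancy,
    ties broken by alphabetically first altloc."""
    best: dict[tuple, Atom] = {}
    order: list[tuple] = []
    for a in atoms:
        key = (a.residue_id, a.name)
        if key not in best:
            best[key] = a
            order.append(key)
        else:
            b = best[key]
            if (a.occupancy, _altloc_rank(a.altloc)) > (b.occupancy, _altloc_rank(b.altloc)):
                best[key] = a
    return [replace(best[k], altloc="") for k in order]


def _altloc_rank(altloc: str) -> float:
    # higher is better; 'A' preferred over 'B' etc. on occupancy ties
    return -ord(altloc) if altloc else 0.0


def load_structure(pdb_text: str, entry_id: str = "",
                   config: IOConfig = DEFAULT_CONFIG) -> Structure:
    """Parse PDB-format text into chains of :class:`Atom`.

    Waters are always dropped; hydrogens and hetero atoms follow
    ``config``.  Alternate locations are reduced to a single conformer.
    REMARK 350 biomolecule definitions are returned as
    :class:`Assembly` objects with explicit rotation/translation pairs.
    """
    _validate_pdb_lines(pdb_text)
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise ValueError("empty structure: no models")
    st.setup_entities()
    model = st[0]

    chains: dict[str, list[Atom]] = {}
    raw: dict[str, list[Atom]] = defaultdict(list)
    n_kept = 0
    for chain in model:
        for res in chain:
            resname = res.name.strip()
            if resname in WATER_NAMES:
                continue
            is_std = resname in STANDARD_RESIDUES
            is_het = res.het_flag == "H" and not is_std
            if is_het and not config.keep_hetero:
                continue
            for at in res:
                elem = at.element.name.upper()
                if config.drop_hydrogens and elem in ("H", "D"):
                    continue
                altloc = at.altloc if at.altloc != "\x00" else ""
                raw[chain.name].append(Atom(
                    serial=at.serial,
                    element=elem,
                    name=at.name,
                    residue_id=(chain.name, res.seqid.num, res.seqid.icode.strip()),
                    residue_name=resname,
                    coord=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    bfactor_raw=float(at.b_iso),
                    occupancy=float(at.occ),
                    altloc=altloc,
                    is_standard_residue=is_std,
                    is_hetero=is_het,
                    vdw_radius=config.vdw_radii.get(
                        elem, config.default_vdw_radius),
                ))
                n_kept += 1
    if n_kept == 0:
        raise ValueError("empty structure: no atoms after filtering")
    for cid, atoms in raw.items():
        chains[cid] = _dedup_altlocs(atoms)

    assemblies = []
    for asm in st.assemblies:
        for gi, gen in enumerate(asm.generators):
            transforms = []
            for op in gen.operators:
                mat = np.array(op.transform.mat.tolist(), dtype=float)
                vec = np.array(op.transform.vec.tolist(), dtype=float)
                transforms.append((mat, vec))
            name = asm.name if len(asm.generators) == 1 else f"{asm.name}.{gi + 1}"
            assemblies.append(Assembly(
                name=name,
                chain_ids=[c for c in gen.chains if c in chains],
                transforms=transforms,
            ))

    resolution = float(st.resolution) if st.resolution > 0 else None
    method = None
    try:
        info = st.get_info("_exptl.method")
        method = info if info else None
    except Exception:
        pass
    return Structure(entry_id=entry_id or st.name, chains=chains,
                     assemblies=assemblies, resolution=resolution,
                     experimental_method=method)


# ---------------------------------------------------------------------------
# biological-unit assembly

def _is_identity(rot: np.ndarray, trans: np.ndarray, tol: float = 1e-8) -> bool:
    return np.allclose(rot, np.eye(3), atol=tol) and np.allclose(trans, 0, atol=tol)


def assemble_biounit(chains: Mapping[str, list[Atom]] | Structure,
                     selection: Sequence[str],
                     transforms: Iterable[tuple[np.ndarray, np.ndarray]] | None = None,
                     unit_id: str = "",
                     config: IOConfig = DEFAULT_CONFIG) -> BioUnit:
    """Build a :class:`BioUnit` from selected chains, applying transforms.

    ``transforms`` is a list of (rotation, translation) pairs; each one
    produces a copy of the selected chains (the identity yields the
    deposited coordinates).  Symmetry copies get chain ids suffixed with
    the copy index so residue bookkeeping stays per physical chain.
    """
    if isinstance(chains, Structure):
        chains = chains.chains
    if not selection:
        raise ValueError("empty chain selection")
    for cid in selection:
        if cid not in chains:
            raise KeyError(f"unknown chain id {cid!r}")
    tlist = list(transforms) if transforms is not None else [(np.eye(3), np.zeros(3))]
    if not tlist:
        raise ValueError("empty transform list")
    atoms: list[Atom] = []
    serial = 0
    for copy_idx, (rot, trans) in enumerate(tlist):
        rot = np.asarray(rot, dtype=float)
        trans = np.asarray(trans, dtype=float)
        if rot.shape != (3, 3) or trans.shape != (3,):
            raise ValueError("transform must be a 3x3 rotation and 3-vector")
        if abs(np.linalg.det(rot)) < 1e-6:
            raise ValueError("singular transform matrix")
        suffix = "" if copy_idx == 0 else f"-{copy_idx + 1}"
        for cid in selection:
            for a in chains[cid]:
                atoms.append(replace(
                    a,
                    serial=serial,
                    coord=rot @ a.coord + trans,
                    residue_id=(cid + suffix,) + a.residue_id[1:],
                ))
                serial += 1
    return BioUnit(unit_id or "+".join(selection), atoms, config=config)


def build_pair(structure: Structure,
               selection_a: Sequence[str], selection_b: Sequence[str],
               label: str = "unknown",
               config: IOConfig = DEFAULT_CONFIG) -> ComplexPair:
    """Convenience: a ComplexPair from two chain-group selections."""
    return ComplexPair(
        entry_id=structure.entry_id,
        unit_a=assemble_biounit(structure, selection_a, unit_id="A", config=config),
        unit_b=assemble_biounit(structure, selection_b, unit_id="B", config=config),
        label=label,
        resolution=structure.resolution,
    )


# ---------------------------------------------------------------------------
# covalent bonds

def infer_covalent_bonds(unit: BioUnit) -> dict[int, set[int]]:
    """Distance-based covalent bond graph.

    Edges require interatomic distance ≤ sum of covalent radii + tolerance
    AND chemically plausible topology: both atoms in the same residue, or a
    peptide link (C of residue *k* to N of the next residue in the same
    chain), or a disulfide (S–S ≤ 2.3 Å).  Isolated atoms are allowed.
    """
    tol = unit.config.covalent_tolerance
    graph: dict[int, set[int]] = {i: set() for i in range(len(unit.atoms))}

    by_residue: dict[tuple, list[int]] = defaultdict(list)
    for i, a in enumerate(unit.atoms):
        by_residue[a.residue_id].append(i)

    def radius(a: Atom) -> float:
        return COVALENT_RADII.get(a.element, DEFAULT_COVALENT_RADIUS)

    def try_bond(i: int, j: int) -> None:
        ai, aj = unit.atoms[i], unit.atoms[j]
        cutoff = radius(ai) + radius(aj) + tol
        if np.linalg.norm(ai.coord - aj.coord) <= cutoff:
            graph[i].add(j)
            graph[j].add(i)

    for members in by_residue.values():
        for x in range(len(members)):
            for y in range(x + 1, len(members)):
                try_bond(members[x], members[y])

    # peptide bonds: C(i) - N(i+1) along each chain's residue order
    by_chain: dict[str, list[tuple]] = defaultdict(list)
    for rid in by_residue:
        by_chain[rid[0]].append(rid)
    for rids in by_chain.values():
        rids.sort(key=lambda r: (r[1], r[2]))
        for prev, nxt in zip(rids, rids[1:]):
            c_atoms = [i for i in by_residue[prev] if unit.atoms[i].name == "C"]
            n_atoms = [i for i in by_residue[nxt] if unit.atoms[i].name == "N"]
            for i in c_atoms:
                for j in n_atoms:
                    try_bond(i, j)

    # disulfides
    sulfurs = [i for i, a in enumerate(unit.atoms) if a.element == "S"]
    for x in range(len(sulfurs)):
        for y in range(x + 1, len(sulfurs)):
            i, j = sulfurs[x], sulfurs[y]
            if unit.atoms[i].residue_id == unit.atoms[j].residue_id:
                continue
            d = np.linalg.norm(unit.atoms[i].coord - unit.atoms[j].coord)
            if d <= unit.config.disulfide_cutoff:
                graph[i].add(j)
                graph[j].add(i)
    return graph


def covalent_nearby(atom_id: int, bond_graph: Mapping[int, set[int]],
                    depth: int = 2) -> set[int]:
    """Atoms within ``depth`` covalent-bond steps of ``atom_id`` (inclusive).

    With the default depth 2 this is the "covalently-bonded nearby" set
    used by the local-contact rule: in a chain i−j−k−l−m queried at i it
    returns {i, j, k}.
    """
    if atom_id not in bond_graph:
        raise KeyError(f"unknown atom id {atom_id}")
    frontier = {atom_id}
    seen = {atom_id}
    for _ in range(depth):
        frontier = {j for i in frontier for j in bond_graph[i]} - seen
        seen |= frontier
    return seen


# ---------------------------------------------------------------------------
# entry quality filter

RULE_DESCRIPTIONS = {
    "i": "experimental method is X-ray crystallography",
    "ii": "resolution better than 2.5 A",
    "iii": "atom count at least 3x residue count",
    "iv": "both partners have more than 5 residues",
    "v": "non-standard-residue contact fraction below 20%",
}


def filter_complex_entry(qc: EntryQC) -> tuple[bool, list[str]]:
    """Entry quality rules used when compiling complexes from the PDB.

    Returns ``(passed, failed_rule_ids)`` where rule ids are the roman
    numerals of :data:`RULE_DESCRIPTIONS`.
    """
    for fieldname in ("method", "resolution", "n_atoms", "n_residues",
                      "partner_residue_counts", "nonstandard_contact_fraction"):
        if getattr(qc, fieldname, None) is None:
            raise ValueError(f"missing QC field: {fieldname}")
    failed = []
    method = qc.method.upper().replace("-", " ")
    if "X RAY" not in method and "XRAY" not in method:
        failed.append("i")
    if not qc.resolution < 2.5:
        failed.append("ii")
    if not qc.n_atoms >= 3 * qc.n_residues:
        failed.append("iii")
    if not all(n > 5 for n in qc.partner_residue_counts):
        failed.append("iv")
    if not qc.nonstandard_contact_fraction < 0.20:
        failed.append("v")
    return (not failed, failed)


# ---------------------------------------------------------------------------
# writing

def to_pdb_text(unit_or_atoms: BioUnit | Sequence[Atom]) -> str:
    """Serialize atoms as fixed-column ATOM/HETATM records.

    Coordinates are written to 3 decimals and B factors to 2, the PDB
    column precision; round-tripping through :func:`load_structure`
    reproduces them at that precision.
    """
    atoms = unit_or_atoms.atoms if isinstance(unit_or_atoms, BioUnit) else list(unit_or_atoms)
    # PDB has one-character chain ids; longer internal ids (symmetry copies
    # like "A-2") are relabelled to fresh letters so residues stay distinct.
    pool = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
    chain_map: dict[str, str] = {}
    for a in atoms:
        cid = a.residue_id[0]
        if cid not in chain_map:
            if len(cid) == 1 and cid not in chain_map.values():
                chain_map[cid] = cid
            else:
                chain_map[cid] = next(c for c in pool if c not in chain_map.values())
    lines = []
    for idx, a in enumerate(atoms, start=1):
        record = "HETATM" if a.is_hetero else "ATOM  "
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        chain = chain_map[a.residue_id[0]]
        icode = (a.residue_id[2] or " ")[:1]
        lines.append(
            f"{record}{idx % 100000:5d} {name:<4s}{'':1s}{a.residue_name:<3s} "
            f"{chain}{a.residue_id[1] % 10000:4d}{icode}   "
            f"{a.coord[0]:8.3f}{a.coord[1]:8.3f}{a.coord[2]:8.3f}"
            f"{a.occupancy:6.2f}{a.bfactor_raw:6.2f}          "
            f"{a.element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
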