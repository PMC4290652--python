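"""Normalized B factors and the B-factor interface features.

Crystallographic B factors measure atomic positional disorder
(B = 8π²⟨u²⟩); their absolute scale varies between depositions, so each
binding unit's B factors are standardized and clipped:

    b_norm = clip((B - mean) / (1.645 · std), -1, 1)

The 1.645 factor maps the two-sided 90% interval of a normal distribution
onto [-1, 1]; values outside are saturated.  Normalization is always done
within one binding unit, never across the complex.

Interfaces are then summarized by:

* ΣB — sum of b_norm over all interfacial atoms of both units;
* No.B — count of interfacial atoms with b_norm < 0 (rigid side);
* avgΣB, avgNo.B — the same divided by log(min_r + 1), where min_r is
  the smaller of the two units' average residues-per-chain — a size
  normalization so that small peptide partners and huge oligomers are
  comparable;
* avgΣB*avgNo.B — the product avgNo.B · avgΣB / 100, amplifying the
  agreement of the two signals.

Biological interfaces tend to be locally rigid (negative ΣB); crystal
packing contacts sit on flexible surface patches (ΣB around or above 0).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .structure_io import BioUnit, ComplexPair

__all__ = [
    "NormalizedB",
    "InterfaceFeatures",
    "normalize_bfactors",
    "pair_normalized_bfactors",
    "min_r",
    "compute_features",
    "FEATURE_NAMES",
]

#: one-sided 5% quantile of the standard normal: scales the 90% interval to [-1, 1]
NORMAL_90 = 1.645

FEATURE_NAMES = ("sigma_b", "no_b", "avg_sigma_b", "avg_no_b",
                 "product", "delta_asa", "avg_delta_asa")


@dataclass
class NormalizedB:
    atom_id: int
    b_norm_raw: float
    b_norm: float


@dataclass
class InterfaceFeatures:
    """The per-interface scores; ``delta_asa`` fields are filled by the
    interface-area module and default to NaN here."""

    sigma_b: float
    no_b: int
    min_r: float
    avg_sigma_b: float
    avg_no_b: float
    product: float
    delta_asa: float = float("nan")
    avg_delta_asa: float = float("nan")
    n_interfacial: int = 0
    empty_interface: bool = False

    def as_dict(self) -> dict[str, float]:
        return {
            "sigma_b": self.sigma_b, "no_b": self.no_b, "min_r": self.min_r,
            "avg_sigma_b": self.avg_sigma_b, "avg_no_b": self.avg_no_b,
            "product": self.product, "delta_asa": self.delta_asa,
            "avg_delta_asa": self.avg_delta_asa,
            "n_interfacial": self.n_interfacial,
        }


def normalize_bfactors(unit: BioUnit, ddof: int = 0) -> dict[int, NormalizedB]:
    """Per-unit standardized, clipped B factors keyed by local atom id.

    Uses the population standard deviation (``ddof=0``) over all the
    unit's (non-water, non-hydrogen) atoms.  If every B factor is equal
    the normalized values are all zero and a warning is emitted.
    """
    b = unit.bfactors
    if len(b) < 2:
        raise ValueError("need at least 2 atoms to normalize B factors")
    mean = float(b.mean())
    std = float(b.std(ddof=ddof))
    if std == 0.0:
        warnings.warn(
            f"unit {unit.unit_id!r}: all B factors equal; normalized B set to 0",
            stacklevel=2)
        raw = np.zeros_like(b)
    else:
        raw = (b - mean) / (std * NORMAL_90)
    clipped = np.clip(raw, -1.0, 1.0)
    return {i: NormalizedB(atom_id=i, b_norm_raw=float(raw[i]),
                           b_norm=float(clipped[i]))
            for i in range(len(b))}


def pair_normalized_bfactors(pair: ComplexPair) -> dict[int, NormalizedB]:
    """Both units' normalized B factors under global (pair-level) atom ids.

    Normalization is performed individually on each contact partner.
    """
    merged: dict[int, NormalizedB] = {}
    for i, nb in normalize_bfactors(pair.unit_a).items():
        merged[i] = NormalizedB(i, nb.b_norm_raw, nb.b_norm)
    off = pair.n_a
    for i, nb in normalize_bfactors(pair.unit_b).items():
        merged[i + off] = NormalizedB(i + off, nb.b_norm_raw, nb.b_norm)
    return merged


def min_r(pair: ComplexPair) -> float:
    """Smaller of the two units' average residues-per-chain."""
    return min(pair.unit_a.mean_residues_per_chain(),
               pair.unit_b.mean_residues_per_chain())


def compute_features(pair: ComplexPair,
                     interfacial: Mapping[str, set[int]],
                     normalized: Mapping[int, NormalizedB] | None = None,
                     log_base: float = math.e) -> InterfaceFeatures:
    """ΣB, No.B and their size-normalized variants for one interface.

    ``interfacial`` holds global atom ids per unit (the output of
    :func:`betaface.beta_contacts.interfacial_atoms`); ΣB sums over the
    union of both sides.  An interface with zero interfacial atoms yields
    all-zero features flagged ``empty_interface`` — tiny crystal contacts
    are a legitimate outcome, not an error.
    """
    if normalized is None:
        normalized = pair_normalized_bfactors(pair)
    atoms = sorted(set(interfacial.get("A", set())) | set(interfacial.get("B", set())))
    mr = min_r(pair)
    denom = math.log(mr + 1.0, log_base)
    if denom <= 0:
        raise ValueError("log(min_r + 1) must be positive")
    if not atoms:
        return InterfaceFeatures(sigma_b=0.0, no_b=0, min_r=mr,
                                 avg_sigma_b=0.0, avg_no_b=0.0, product=0.0,
                                 n_interfacial=0, empty_interface=True)
    vals = np.array([normalized[a].b_norm for a in atoms])
    sigma_b = float(vals.sum())
    no_b = int((vals < 0.0).sum())
    avg_sigma_b = sigma_b / denom
    avg_no_b = no_b / denom
    return InterfaceFeatures(
        sigma_b=sigma_b, no_b=no_b, min_r=mr,
        avg_sigma_b=avg_sigma_b, avg_no_b=avg_no_b,
        product=avg_no_b * avg_sigma_b / 100.0,
        n_interfacial=len(atoms),
    )
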