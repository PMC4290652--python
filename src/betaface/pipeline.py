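"""End-to-end convenience: complex → interfacial atoms → feature vector."""

from __future__ import annotations

import math

from .beta_contacts import ContactParams, beta_contacts, interfacial_atoms
from .bfactor_features import InterfaceFeatures, compute_features, pair_normalized_bfactors
from .interface_area import DEFAULT_N_POINTS, DEFAULT_PROBE, delta_asa
from .structure_io import ComplexPair

__all__ = ["interface_features"]


def interface_features(pair: ComplexPair,
                       params: ContactParams | None = None,
                       with_delta_asa: bool = False,
                       probe_radius: float = DEFAULT_PROBE,
                       n_sphere_points: int = DEFAULT_N_POINTS,
                       log_base: float = math.e) -> InterfaceFeatures:
    """Full feature vector for one complex.

    Runs β-contact detection, the local-contact interfacial-atom rule,
    per-unit B-factor normalization and the ΣB-family features; ΔASA and
    avgΔASA are appended when ``with_delta_asa`` (SASA is the costly
    step, so it is opt-in).
    """
    params = params or ContactParams()
    contacts = beta_contacts(pair, params)
    interfacial = interfacial_atoms(pair, contacts)
    feats = compute_features(pair, interfacial,
                             pair_normalized_bfactors(pair),
                             log_base=log_base)
    if with_delta_asa:
        feats.delta_asa, feats.avg_delta_asa = delta_asa(
            pair, probe_radius, n_sphere_points, log_base=log_base)
    return feats
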