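import numpy as np
import pytest

from betaface import SyntheticConfig, generate_complex


TINY_PDB = """\
REMARK 350 BIOMOLECULE: 1
REMARK 350 APPLY THE FOLLOWING TO CHAINS: A
REMARK 350   BIOMT1   1  1.000000  0.000000  0.000000        0.00000
REMARK 350   BIOMT2   1  0.000000  1.000000  0.000000        0.00000
REMARK 350   BIOMT3   1  0.000000  0.000000  1.000000        0.00000
REMARK 350   BIOMT1   2 -1.000000  0.000000  0.000000       20.00000
REMARK 350   BIOMT2   2  0.000000 -1.000000  0.000000        0.00000
REMARK 350   BIOMT3   2  0.000000  0.000000  1.000000        0.00000
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 12.00           C
ATOM      3  C   ALA A   1      12.759   7.092  -4.974  1.00 14.00           C
ATOM      4  O   ALA A   1      13.164   7.762  -5.923  1.00 16.00           O
ATOM      5  N   GLY A   2      13.255   7.215  -3.745  1.00 11.00           N
ATOM      6  CA  GLY A   2      14.321   8.162  -3.442  1.00 13.00           C
ATOM      7  C   GLY A   2      15.654   7.702  -4.021  1.00 15.00           C
ATOM      8  O   GLY A   2      15.937   6.504  -4.029  1.00 17.00           O
ATOM      9  CA ASER A   3      16.500   8.700  -4.500  0.70 18.00           C
ATOM     10  CA BSER A   3      16.600   8.800  -4.600  0.30 19.00           C
HETATM   11  O   HOH A 101      20.000   9.000  -5.000  1.00 30.00           O
HETATM   12 ZN    ZN A 102      18.000   9.500  -5.500  1.00 22.00          ZN
END
"""


@pytest.fixture(scope="session")
def tiny_pdb_text():
    return TINY_PDB


@pytest.fixture(scope="session")
def rigid_pair():
    """One interface-rigid synthetic complex (biological-like)."""
    return generate_complex(SyntheticConfig(seed=11,
                                            bfactor_model="interface-rigid"),
                            label="biological")


@pytest.fixture(scope="session")
def uniform_pair():
    """One uniform-B synthetic complex (packing-like null)."""
    return generate_complex(SyntheticConfig(seed=12, bfactor_model="uniform"),
                            label="packing")


# ---------------------------------------------------------------------------
# independent geometry oracles (brute force; never call the implementation)

def gabriel_graph_bruteforce(coords: np.ndarray) -> set[tuple[int, int]]:
    """Edge iff the sphere with the segment as diameter is empty."""
    n = len(coords)
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            mid = (coords[i] + coords[j]) / 2.0
            r2 = ((coords[i] - coords[j]) ** 2).sum() / 4.0
            d2 = ((coords - mid) ** 2).sum(axis=1)
            d2[i] = d2[j] = np.inf
            if d2.min() > r2:
                edges.add((i, j))
    return edges


def delaunay_adjacency_bruteforce(coords: np.ndarray) -> set[tuple[int, int]]:
    """Pairs belonging to some empty-circumsphere tetrahedron (O(n^5))."""
    from itertools import combinations
    n = len(coords)
    edges = set()
    for quad in combinations(range(n), 4):
        p = coords[list(quad)]
        # circumcenter: solve 2(p_k - p_0) . c = |p_k|^2 - |p_0|^2
        a = 2.0 * (p[1:] - p[0])
        b = (p[1:] ** 2).sum(axis=1) - (p[0] ** 2).sum()
        try:
            c = np.linalg.solve(a, b)
        except np.linalg.LinAlgError:
            continue
        r2 = ((p[0] - c) ** 2).sum()
        d2 = ((coords - c) ** 2).sum(axis=1)
        d2[list(quad)] = np.inf
        if d2.min() > r2 * (1.0 - 1e-9):
            for x, y in combinations(quad, 2):
                edges.add((x, y))
    return edges


def angle_scan_bruteforce(i: int, j: int, coords: np.ndarray,
                          beta_angle_deg: float) -> bool:
    """Direct all-k angle enumeration for the forbidden-region test."""
    theta = np.radians(beta_angle_deg)
    for k in range(len(coords)):
        if k in (i, j):
            continue
        u = coords[i] - coords[k]
        v = coords[j] - coords[k]
        cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        if np.arccos(np.clip(cosang, -1, 1)) >= theta:
            return False
    return True
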