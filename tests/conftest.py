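"""Shared fixtures and independent oracle helpers.

Oracles here deliberately avoid the library's own code paths: brute-force
all-pairs minimum-image clustering, a four-point torsion formula, and a
characteristic-polynomial eigensolve.
"""

from __future__ import annotations

import numpy as np
import pytest

from fibriltwist import Box, Frame, PeptideTopology
from fibriltwist import synthetic as syn


@pytest.fixture(scope="session")
def gnn_topology_one() -> PeptideTopology:
    return PeptideTopology(n_peptides=1, sequence=syn.GNN_SEQUENCE)


@pytest.fixture(scope="session")
def sheet_frame() -> Frame:
    """Five extended peptides stacked in a sheet."""
    return syn.build_parallel_sheet(5, spacing=0.48)


@pytest.fixture(scope="session")
def fibril_three_ribbon():
    """Ideal three-ribbon fibril, 8 degree twist, with its ground truth."""
    return syn.build_helical_fibril(
        syn.FibrilSpec(n_ribbons=3, peptides_per_ribbon=10, twist_deg=8.0)
    )


def make_bead_frame(
    peptide_beads: list[np.ndarray], edge: float = 20.0, sequence: str = "G"
) -> Frame:
    """Frame built from explicit per-peptide bead arrays; sequence 'G' gives
    3 beads per peptide so coordinates can be placed by hand."""
    topo = PeptideTopology(n_peptides=len(peptide_beads), sequence=sequence)
    coords = np.concatenate([np.asarray(b, dtype=float) for b in peptide_beads])
    return Frame(0.0, coords, Box.cubic(edge), topo)


def triplet(origin, direction=(1.0, 0.0, 0.0), spacing=0.15) -> np.ndarray:
    """Three collinear beads — a minimal single-residue glycine peptide."""
    o = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    return np.stack([o + k * spacing * d for k in range(3)])


# ---------------------------------------------------------------------------
# oracles


def brute_force_clusters(frame: Frame, cutoff: float) -> list[set[int]]:
    """O(N^2) all-pairs minimum-image single-linkage clustering."""
    top = frame.topology
    L = frame.box.lengths
    n = top.n_peptides
    adj = np.zeros((n, n), dtype=bool)
    beads = [frame.peptide_coordinates(p) for p in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d = beads[i][:, None, :] - beads[j][None, :, :]
            d -= L * np.round(d / L)
            if np.min(np.linalg.norm(d, axis=-1)) < cutoff:
                adj[i, j] = adj[j, i] = True
    seen, comps = set(), []
    for start in range(n):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(int(v) for v in np.nonzero(adj[u])[0] if v not in comp)
        seen |= comp
        comps.append(comp)
    return comps


def torsion_deg(p0, p1, p2, p3) -> float:
    """Independent four-point dihedral (IUPAC sign convention), degrees."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1 /= np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def charpoly_eigenvalues(tensor: np.ndarray) -> np.ndarray:
    """Eigenvalues of a symmetric 3x3 via its characteristic polynomial."""
    s = np.asarray(tensor, dtype=float)
    tr = s[0, 0] + s[1, 1] + s[2, 2]
    minors = (
        s[0, 0] * s[1, 1] - s[0, 1] * s[1, 0]
        + s[0, 0] * s[2, 2] - s[0, 2] * s[2, 0]
        + s[1, 1] * s[2, 2] - s[1, 2] * s[2, 1]
    )
    det = (
        s[0, 0] * (s[1, 1] * s[2, 2] - s[1, 2] * s[2, 1])
        - s[0, 1] * (s[1, 0] * s[2, 2] - s[1, 2] * s[2, 0])
        + s[0, 2] * (s[1, 0] * s[2, 1] - s[1, 1] * s[2, 0])
    )
    roots = np.roots([1.0, -tr, minors, -det])
    return np.sort(roots.real)


def random_rotation(seed: int) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
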