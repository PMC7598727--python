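"""Cluster detection under periodic boundary conditions.

Two peptides are linked when any bead of one lies within a cutoff distance
(default 0.5 nm) of any bead of the other, measured with the minimum-image
convention; clusters are the connected components of that link graph, and a
component of size one is a free monomer.  Clusters split across a periodic
boundary are reassembled by a breadth-first unwrap before descriptors are
computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .io_core import Frame, Trajectory

__all__ = [
    "ClusterSet",
    "UnwrappedCluster",
    "KineticCurves",
    "find_clusters",
    "unwrap_cluster",
    "kinetic_counts",
    "track_largest",
]


@dataclass
class ClusterSet:
    """Partition of the peptides of one frame into clusters and monomers."""

    time: float
    clusters: list[frozenset[int]]
    monomers: frozenset[int]
    #: one linking bead pair (global indices) per linked peptide pair
    link_beads: dict[tuple[int, int], tuple[int, int]] = field(default_factory=dict)

    @property
    def n_monomers(self) -> int:
        return len(self.monomers)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def largest(self) -> frozenset[int]:
        """Largest cluster; ties broken by the lowest smallest-member index."""
        if not self.clusters:
            return frozenset()
        return max(self.clusters, key=lambda c: (len(c), -min(c)))

    @property
    def largest_size(self) -> int:
        return len(self.largest) if self.clusters else 0


@dataclass
class UnwrappedCluster:
    """A cluster with its beads shifted by integer box vectors so that it is
    spatially contiguous (no member pair separated by a boundary)."""

    members: tuple[int, ...]
    coordinates: dict[int, np.ndarray]  # peptide -> bead coords (nm)

    def all_coordinates(self) -> np.ndarray:
        return np.concatenate([self.coordinates[p] for p in self.members])

    def mass_centers(self) -> np.ndarray:
        return np.stack([self.coordinates[p].mean(axis=0) for p in self.members])


def _link_graph(frame: Frame, cutoff: float) -> nx.Graph:
    """Peptide link graph under the bead–bead minimum-image cutoff."""
    box = frame.box
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if cutoff >= box.min_edge / 2:
        raise ValueError(
            f"cutoff {cutoff} nm >= half the smallest box edge "
            f"({box.min_edge / 2} nm): minimum image is ambiguous"
        )
    top = frame.topology
    L = box.lengths
    wrapped = np.mod(frame.coordinates, L)
    tree = cKDTree(wrapped, boxsize=L)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    pep = top.bead_peptide_index()

    g = nx.Graph()
    g.add_nodes_from(range(top.n_peptides))
    if len(pairs) == 0:
        return g
    # strict "< cutoff" semantics; the tree query is inclusive at r
    delta = wrapped[pairs[:, 0]] - wrapped[pairs[:, 1]]
    delta -= L * np.round(delta / L)
    dist = np.linalg.norm(delta, axis=1)
    keep = dist < cutoff
    for (i, j) in pairs[keep]:
        pi, pj = int(pep[i]), int(pep[j])
        if pi == pj:
            continue
        key = (pi, pj) if pi < pj else (pj, pi)
        if not g.has_edge(*key):
            g.add_edge(*key, beads=(int(i), int(j)) if pi < pj else (int(j), int(i)))
    return g


def find_clusters(frame: Frame, cutoff: float = 0.5) -> ClusterSet:
    """Partition a frame's peptides into clusters (size >= 2) and monomers.

    Parameters
    ----------
    frame : Frame
    cutoff : float
        Bead–bead linkage distance in nm; must be below half the smallest
        box edge so the minimum image is unique.
    """
    g = _link_graph(frame, cutoff)
    clusters: list[frozenset[int]] = []
    monomers: set[int] = set()
    for comp in nx.connected_components(g):
        if len(comp) >= 2:
            clusters.append(frozenset(comp))
        else:
            monomers.update(comp)
    clusters.sort(key=lambda c: (-len(c), min(c)))
    links = {
        (u, v) if u < v else (v, u): data["beads"]
        for u, v, data in g.edges(data=True)
    }
    return ClusterSet(frame.time, clusters, frozenset(monomers), links)


def unwrap_cluster(
    cluster: frozenset[int] | set[int],
    frame: Frame,
    cutoff: float = 0.5,
    cluster_set: ClusterSet | None = None,
) -> UnwrappedCluster:
    """Reassemble a boundary-split cluster into contiguous coordinates.

    Breadth-first traversal of the cluster's link graph from its lowest
    member; each newly reached peptide is rigidly shifted by the integer box
    vector that minimises the distance of the bead pair that links it to the
    already-unwrapped part.  Descriptors computed on the result do not depend
    on how the cluster was wrapped.
    """
    members = sorted(cluster)
    if cluster_set is None:
        cluster_set = find_clusters(frame, cutoff)
    g = nx.Graph()
    g.add_nodes_from(members)
    mset = set(members)
    for (u, v), beads in cluster_set.link_beads.items():
        if u in mset and v in mset:
            g.add_edge(u, v, beads=beads)
    if len(members) > 1 and not nx.is_connected(g):
        raise ValueError("input peptide set is not connected at this cutoff")

    L = frame.box.lengths
    pep_of_bead = frame.topology.bead_peptide_index()
    bpp = frame.topology.beads_per_peptide

    def rebuilt(p: int) -> np.ndarray:
        # make the peptide itself whole: min-image walk along the bonded
        # bead chain (consecutive beads are far closer than half a box edge)
        raw = frame.peptide_coordinates(p)
        out = raw.copy()
        for k in range(1, len(out)):
            d = raw[k] - out[k - 1]
            out[k] = raw[k] - L * np.round(d / L)
        return out

    seed = members[0]
    coords = {seed: rebuilt(seed)}
    for u, v in nx.bfs_edges(g, seed):
        bu, bv = g.edges[u, v]["beads"]
        if pep_of_bead[bu] != u:
            bu, bv = bv, bu
        rv = rebuilt(v)
        anchor = coords[u][bu - u * bpp]
        d = rv[bv - v * bpp] - anchor
        coords[v] = rv - L * np.round(d / L)
    return UnwrappedCluster(tuple(members), coords)


@dataclass
class KineticCurves:
    """Per-frame cluster bookkeeping: monomer count Nm, cluster count Nc, and
    the size M of the largest cluster (0 when no cluster exists)."""

    times: np.ndarray
    n_monomers: np.ndarray
    n_clusters: np.ndarray
    largest_size: np.ndarray
    n_peptides: int

    @property
    def m_rel(self) -> np.ndarray:
        return self.largest_size / self.n_peptides


def kinetic_counts(trajectory: Trajectory, cutoff: float = 0.5) -> KineticCurves:
    """Nm(t), Nc(t) and largest-cluster size M(t) for a whole trajectory."""
    if len(trajectory) < 1:
        raise ValueError("trajectory has no frames")
    nm, nc, mm = [], [], []
    for frame in trajectory:
        cs = find_clusters(frame, cutoff)
        nm.append(cs.n_monomers)
        nc.append(cs.n_clusters)
        mm.append(cs.largest_size)
    return KineticCurves(
        trajectory.times,
        np.asarray(nm),
        np.asarray(nc),
        np.asarray(mm),
        trajectory.topology.n_peptides,
    )


def track_largest(
    trajectory: Trajectory, cutoff: float = 0.5
) -> list[frozenset[int]]:
    """Identity-linked largest cluster per frame.

    At each frame the largest cluster is selected; among equally large
    candidates the one sharing the most members with the previously tracked
    set wins, then the lowest smallest-member index.  Returns the tracked
    member set per frame (empty set when the frame has no cluster).
    """
    if len(trajectory) < 2:
        raise ValueError("tracking needs at least two frames")
    tracked: list[frozenset[int]] = []
    prev: frozenset[int] = frozenset()
    for frame in trajectory:
        cs = find_clusters(frame, cutoff)
        if not cs.clusters:
            tracked.append(frozenset())
            continue
        mmax = max(len(c) for c in cs.clusters)
        candidates = [c for c in cs.clusters if len(c) == mmax]
        best = max(candidates, key=lambda c: (len(c & prev), -min(c)))
        tracked.append(best)
        prev = best
    return tracked
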