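"""Generators for structures and kinetics with analytically known answers.

These stand in for molecular-dynamics data in every test: ideal helical
fibrils whose helicity is -sin(dphi) by construction, parallel/antiparallel
sheet stacks with end-to-end correlation exactly 1, amorphous near-spherical
clusters, dilute monomer gases, deliberately boundary-split copies of any of
those, and a Gillespie simulator of Smoluchowski-type coalescence kinetics.

Every generator is seeded and bit-reproducible, and returns the ground truth
alongside the structure.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .clustering import KineticCurves
from .io_core import Box, Frame, PeptideTopology

__all__ = [
    "GNN_SEQUENCE",
    "Y7A_SEQUENCE",
    "build_backbone",
    "build_peptide",
    "FibrilSpec",
    "FibrilGroundTruth",
    "build_helical_fibril",
    "build_parallel_sheet",
    "build_amorphous_cluster",
    "build_monomer_gas",
    "split_across_boundary",
    "CoalescenceSpec",
    "constant_kernel",
    "sum_kernel",
    "simulate_coalescence",
    "entity_count_at",
]

GNN_SEQUENCE = "GNNQQNY"
Y7A_SEQUENCE = "GNNQQNA"

# idealised coarse-grained backbone geometry (nm / degrees)
_BOND_N_CA = 0.1458
_BOND_CA_C = 0.1525
_BOND_C_N = 0.1329
_ANGLE_N_CA_C = 111.0
_ANGLE_CA_C_N = 116.6
_ANGLE_C_N_CA = 121.9
_OMEGA = 180.0
_SIDECHAIN_BOND = 0.25

_NO_SIDECHAIN = frozenset("G")


def _place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """Natural-extension placement: position d with |cd| = bond, angle
    b-c-d = angle and dihedral a-b-c-d = torsion."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    d_local = np.array(
        [-bond * np.cos(ang), bond * np.sin(ang) * np.cos(tor),
         bond * np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Backbone bead positions (N, CA, C per residue) realising the given
    dihedrals.

    phi[0] and psi[-1] are undefined for a chain and ignored; pass arrays of
    length n_residues for convenience.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    n_res = len(phi)
    if len(psi) != n_res or n_res < 2:
        raise ValueError("phi and psi must have equal length >= 2")
    coords = np.zeros((3 * n_res, 3))
    # first residue placed explicitly in the xy-plane
    coords[0] = (0.0, 0.0, 0.0)  # N1
    coords[1] = (_BOND_N_CA, 0.0, 0.0)  # CA1
    ang = np.radians(180.0 - _ANGLE_N_CA_C)
    coords[2] = coords[1] + _BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n_res):
        n_prev, ca_prev, c_prev = coords[3 * i - 3], coords[3 * i - 2], coords[3 * i - 1]
        n_i = _place_atom(n_prev, ca_prev, c_prev, _BOND_C_N, _ANGLE_CA_C_N, psi[i - 1])
        ca_i = _place_atom(ca_prev, c_prev, n_i, _BOND_N_CA, _ANGLE_C_N_CA, _OMEGA)
        c_i = _place_atom(c_prev, n_i, ca_i, _BOND_CA_C, _ANGLE_N_CA_C, phi[i])
        coords[3 * i: 3 * i + 3] = [n_i, ca_i, c_i]
    return coords


def build_peptide(
    sequence: str = GNN_SEQUENCE,
    phi: float | np.ndarray = -135.0,
    psi: float | np.ndarray = 135.0,
) -> np.ndarray:
    """Full bead set of one peptide (backbone + side chains), centered at its
    mass center.

    Defaults give an ideal extended chain.  Side-chain beads sit on the
    in-plane bisector pointing away from the backbone at each non-glycine CA.
    """
    n_res = len(sequence)
    phi = np.full(n_res, phi) if np.isscalar(phi) else np.asarray(phi, float)
    psi = np.full(n_res, psi) if np.isscalar(psi) else np.asarray(psi, float)
    bb = build_backbone(phi, psi)
    beads: list[np.ndarray] = []
    for i, aa in enumerate(sequence):
        n_i, ca_i, c_i = bb[3 * i], bb[3 * i + 1], bb[3 * i + 2]
        beads.extend([n_i, ca_i, c_i])
        if aa not in _NO_SIDECHAIN:
            u = (ca_i - n_i) / np.linalg.norm(ca_i - n_i) + (
                ca_i - c_i
            ) / np.linalg.norm(ca_i - c_i)
            u /= np.linalg.norm(u)
            beads.append(ca_i + _SIDECHAIN_BOND * u)
    arr = np.asarray(beads)
    return arr - arr.mean(axis=0)


def _template_frame(template: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal frame of a centered template: columns are
    its first two principal directions and their cross product."""
    cov = template.T @ template
    _, evecs = np.linalg.eigh(cov)
    t1, t2 = evecs[:, -1], evecs[:, -2]
    # deterministic sign: t1 toward the last bead, t2 toward the first
    if np.dot(t1, template[-1] - template[0]) < 0:
        t1 = -t1
    if np.dot(t2, template[0]) < 0:
        t2 = -t2
    return np.column_stack([t1, t2, np.cross(t1, t2)])


def _place_rigid(
    template: np.ndarray, center: np.ndarray, long_dir: np.ndarray, up_dir: np.ndarray
) -> np.ndarray:
    """Rigidly place a centered template: its long axis along long_dir, its
    second axis along the component of up_dir orthogonal to long_dir."""
    u1 = long_dir / np.linalg.norm(long_dir)
    u2 = up_dir - np.dot(up_dir, u1) * u1
    u2 /= np.linalg.norm(u2)
    target = np.column_stack([u1, u2, np.cross(u1, u2)])
    rot = target @ _template_frame(template).T
    return template @ rot.T + center


@dataclass(frozen=True)
class FibrilSpec:
    """Geometry of an ideal multi-ribbon helical fibril.

    Peptide mass centers of ribbon k, step m sit at cylindrical coordinates
    (radius, 2*pi*k/n_ribbons + m*twist, m*rise); peptides lie radially
    (long axis pointing outward), so the structure is n_ribbons ribbons
    twisted about a common core.  Helicity of the noise-free structure is
    exactly -sin(twist) for any rise, radius, and ribbon count.
    """

    n_ribbons: int = 3
    peptides_per_ribbon: int = 12
    rise: float = 0.48  # nm per step along the axis
    twist_deg: float = 8.0  # azimuthal advance per step
    radius: float = 1.0  # core radius, nm
    noise: float = 0.0  # Gaussian amplitude, nm
    seed: int = 0
    sequence: str = GNN_SEQUENCE

    def __post_init__(self) -> None:
        if self.n_ribbons < 1 or self.peptides_per_ribbon < 1:
            raise ValueError("need at least one ribbon and one peptide per ribbon")
        if self.rise <= 0 or self.radius <= 0 or self.noise < 0:
            raise ValueError("rise and radius must be positive, noise >= 0")


@dataclass
class FibrilGroundTruth:
    """Known answers for a generated fibril."""

    axis_anchor: list[float]
    axis_direction: list[float]
    ribbons: list[list[int]]
    helicity: float  # -sin(twist)
    twist_deg: float
    rise: float
    radius: float
    centers: list[list[float]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "FibrilGroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def build_helical_fibril(spec: FibrilSpec) -> tuple[Frame, FibrilGroundTruth]:
    """Construct an ideal helical fibril frame plus its ground truth."""
    template = build_peptide(spec.sequence)
    rng = np.random.default_rng(spec.seed)
    centers, coords, membership = [], [], []
    idx = 0
    for k in range(spec.n_ribbons):
        ribbon = []
        for m in range(spec.peptides_per_ribbon):
            phi = 2 * np.pi * k / spec.n_ribbons + m * np.radians(spec.twist_deg)
            c = np.array(
                [spec.radius * np.cos(phi), spec.radius * np.sin(phi), m * spec.rise]
            )
            r_hat = np.array([np.cos(phi), np.sin(phi), 0.0])
            coords.append(_place_rigid(template, c, r_hat, np.array([0.0, 0.0, 1.0])))
            centers.append(c)
            ribbon.append(idx)
            idx += 1
        membership.append(ribbon)
    centers = np.asarray(centers)
    d = centers[:, None, :] - centers[None, :, :]
    dmin = np.min(
        np.linalg.norm(d, axis=-1)[np.triu_indices(len(centers), k=1)]
    ) if len(centers) > 1 else np.inf
    if dmin < 0.05:
        raise ValueError(
            f"inter-center spacing {dmin:.3f} nm below bead clash distance"
        )
    all_coords = np.concatenate(coords)
    if spec.noise > 0:
        all_coords = all_coords + rng.normal(0.0, spec.noise, all_coords.shape)
    extent = np.ptp(all_coords, axis=0).max()
    edge = max(4.0, 2.5 * extent)
    shift = edge / 2 - all_coords.mean(axis=0)
    all_coords += shift
    topology = PeptideTopology(
        n_peptides=spec.n_ribbons * spec.peptides_per_ribbon, sequence=spec.sequence
    )
    frame = Frame(0.0, all_coords, Box.cubic(edge), topology)
    truth = FibrilGroundTruth(
        axis_anchor=list(centers.mean(axis=0) + shift),
        axis_direction=[0.0, 0.0, 1.0],
        ribbons=membership,
        helicity=float(-np.sin(np.radians(spec.twist_deg))),
        twist_deg=spec.twist_deg,
        rise=spec.rise,
        radius=spec.radius,
        centers=(centers + shift).tolist(),
    )
    return frame, truth


def build_parallel_sheet(
    m: int,
    spacing: float = 0.48,
    orientation: str = "parallel",
    sequence: str = GNN_SEQUENCE,
) -> Frame:
    """Stack of identical extended peptides at the given spacing (nm).

    Antiparallel stacks flip every second peptide head-to-tail; the squared
    dot product makes the end-to-end correlation 1 either way.
    """
    if m < 2:
        raise ValueError("a sheet needs at least two peptides")
    topology = PeptideTopology(n_peptides=m, sequence=sequence)
    template = build_peptide(sequence)
    # Head-to-tail flip: a 180-degree rotation about an axis perpendicular to
    # the end-to-end vector maps that vector exactly onto its negative.
    i0 = int(topology.role_offsets("N", residue=1)[0])
    i1 = int(topology.role_offsets("C", residue=len(sequence))[0])
    v = template[i1] - template[i0]
    v /= np.linalg.norm(v)
    w = np.cross(v, [0.0, 0.0, 1.0])
    if np.linalg.norm(w) < 1e-8:
        w = np.cross(v, [1.0, 0.0, 0.0])
    w /= np.linalg.norm(w)
    rot_pi = 2.0 * np.outer(w, w) - np.eye(3)
    centroid = template.mean(axis=0)
    flipped = (template - centroid) @ rot_pi.T + centroid
    coords = []
    for i in range(m):
        pep = template if (orientation == "parallel" or i % 2 == 0) else flipped
        coords.append(pep + np.array([0.0, i * spacing, 0.0]))
    all_coords = np.concatenate(coords)
    extent = np.ptp(all_coords, axis=0).max()
    edge = max(4.0, 2.5 * extent)
    all_coords += edge / 2 - all_coords.mean(axis=0)
    return Frame(0.0, all_coords, Box.cubic(edge), topology)


def build_amorphous_cluster(
    m: int,
    radius: float = 2.5,
    seed: int = 0,
    min_separation: float = 0.6,
    sequence: str = GNN_SEQUENCE,
) -> Frame:
    """Near-spherical disordered cluster: centers uniform in a ball with a
    minimum-separation constraint, orientations isotropic."""
    from scipy.spatial.transform import Rotation

    if m < 2:
        raise ValueError("need at least two peptides")
    rng = np.random.default_rng(seed)
    template = build_peptide(sequence)
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < m:
        attempts += 1
        if attempts > 200_000:
            raise RuntimeError("rejection sampling failed; lower min_separation")
        p = rng.uniform(-radius, radius, 3)
        if np.linalg.norm(p) > radius:
            continue
        if centers and np.min(
            np.linalg.norm(np.asarray(centers) - p, axis=1)
        ) < min_separation:
            continue
        centers.append(p)
    coords = []
    for c in centers:
        rot = Rotation.random(rng=rng).as_matrix()
        coords.append(template @ rot.T + c)
    all_coords = np.concatenate(coords)
    extent = np.ptp(all_coords, axis=0).max()
    edge = max(4.0, 2.5 * extent)
    all_coords += edge / 2 - all_coords.mean(axis=0)
    topology = PeptideTopology(n_peptides=m, sequence=sequence)
    return Frame(0.0, all_coords, Box.cubic(edge), topology)


def build_monomer_gas(
    n: int,
    edge: float,
    seed: int = 0,
    min_separation: float | None = None,
    sequence: str = GNN_SEQUENCE,
) -> Frame:
    """Dilute gas of isolated monomers in a periodic cubic box.

    The default minimum center separation guarantees no bead pair of
    different peptides comes within the 0.5 nm clustering cutoff, including
    across periodic boundaries.
    """
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    template = build_peptide(sequence)
    r_max = float(np.linalg.norm(template, axis=1).max())
    if min_separation is None:
        min_separation = 2 * r_max + 0.6
    centers: list[np.ndarray] = []
    attempts = 0
    L = np.full(3, float(edge))
    while len(centers) < n:
        attempts += 1
        if attempts > 500_000:
            raise RuntimeError("box too crowded for the requested separation")
        p = rng.uniform(0.0, edge, 3)
        if centers:
            d = np.asarray(centers) - p
            d -= L * np.round(d / L)
            if np.min(np.linalg.norm(d, axis=1)) < min_separation:
                continue
        centers.append(p)
    coords = []
    for c in centers:
        rot = Rotation.random(rng=rng).as_matrix()
        coords.append(template @ rot.T + c)
    topology = PeptideTopology(n_peptides=n, sequence=sequence)
    return Frame(0.0, np.concatenate(coords), Box.cubic(edge), topology)


def split_across_boundary(frame: Frame, shift: np.ndarray) -> Frame:
    """Translate all coordinates by `shift` and wrap into the box; a shift
    that pushes a structure over a face splits it into periodic images."""
    L = frame.box.lengths
    coords = np.mod(frame.coordinates + np.asarray(shift, dtype=float), L)
    return Frame(frame.time, coords, frame.box, frame.topology)


# ---------------------------------------------------------------------------
# stochastic coalescence kinetics


def constant_kernel(k0: float = 1.0):
    """Size-independent coalescence kernel K(i, j) = k0."""
    return lambda i, j: k0


def sum_kernel(k0: float = 1.0):
    """Additive kernel K(i, j) = k0 * (i + j)."""
    return lambda i, j: k0 * (i + j)


@dataclass(frozen=True)
class CoalescenceSpec:
    """Well-mixed stochastic aggregation model.

    Entities (monomers and clusters) coalesce pairwise with rate
    kernel(size_i, size_j); clusters of size >= 2 may shed a monomer with
    rate `detachment` each.  Mimics the qualitative three-stage kinetics of
    peptide aggregation: rapid dimerisation, cluster coalescence, and (with
    detachment) a monomer steady state.
    """

    n_peptides: int = 72
    kernel: object = None  # callable (i, j) -> rate; default constant 1
    detachment: float = 0.0
    duration: float = np.inf
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_peptides < 2:
            raise ValueError("need at least two peptides")
        if self.detachment < 0:
            raise ValueError("detachment rate must be >= 0")


def simulate_coalescence(spec: CoalescenceSpec) -> tuple[KineticCurves, list[dict]]:
    """Exact (Gillespie) simulation of the coalescence model.

    Returns the event-resolved kinetic curves (Nm, Nc, largest size M after
    every event) and an event log.  The total peptide count is conserved at
    every step.
    """
    kernel = spec.kernel or constant_kernel(1.0)
    rng = np.random.default_rng(spec.seed)
    sizes = [1] * spec.n_peptides
    t = 0.0
    times, nm, nc, mm = [0.0], [spec.n_peptides], [0], [0]
    events: list[dict] = []
    while True:
        n = len(sizes)
        pair_rates = []
        pairs = []
        for i in range(n):
            for j in range(i + 1, n):
                pairs.append((i, j))
                pair_rates.append(kernel(sizes[i], sizes[j]))
        det_idx = [i for i, s in enumerate(sizes) if s >= 2]
        det_rates = [spec.detachment] * len(det_idx)
        total = float(np.sum(pair_rates) + np.sum(det_rates))
        if total <= 0:
            if n > 1 and spec.detachment == 0 and not pairs:
                raise RuntimeError("all rates zero before reaching an absorbing state")
            break
        t += rng.exponential(1.0 / total)
        if t > spec.duration:
            break
        u = rng.uniform(0.0, total)
        cum = np.cumsum(pair_rates + det_rates)
        k = int(np.searchsorted(cum, u, side="right"))
        if k < len(pairs):
            i, j = pairs[k]
            merged = sizes[i] + sizes[j]
            sizes = [s for idx, s in enumerate(sizes) if idx not in (i, j)]
            sizes.append(merged)
            events.append({"t": t, "type": "coalescence", "size": merged})
        else:
            i = det_idx[k - len(pairs)]
            sizes[i] -= 1
            if sizes[i] == 1:
                pass  # a dimer split into two monomers: one stays as size-1
            sizes.append(1)
            events.append({"t": t, "type": "detachment", "size": sizes[i]})
        clusters = [s for s in sizes if s >= 2]
        times.append(t)
        nm.append(sum(1 for s in sizes if s == 1))
        nc.append(len(clusters))
        mm.append(max(clusters) if clusters else 0)
        if len(sizes) == 1 and spec.detachment == 0:
            break
    curves = KineticCurves(
        np.asarray(times), np.asarray(nm), np.asarray(nc), np.asarray(mm),
        spec.n_peptides,
    )
    return curves, events


def entity_count_at(curves: KineticCurves, t_grid: np.ndarray) -> np.ndarray:
    """Piecewise-constant number of entities (monomers + clusters) evaluated
    at the given times; the final state persists beyond the last event."""
    entities = curves.n_monomers + curves.n_clusters
    idx = np.searchsorted(curves.times, np.asarray(t_grid, float), side="right") - 1
    idx = np.clip(idx, 0, len(entities) - 1)
    return entities[idx]
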