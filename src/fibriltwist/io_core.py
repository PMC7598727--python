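"""Trajectory I/O and the internal frame representation.

All coordinates are stored internally in nanometres.  Angstroms appear only
at the PDB boundary (PDB files are written/read in Å per the format), and the
unit of a plain XYZ file is declared by the caller.

A coarse-grained peptide is three backbone beads per residue (N, CA, C) plus
one side-chain bead for every non-glycine residue.  The topology maps each
bead of a frame to a (peptide, residue, role) triple; all beads carry the
same mass, so mass centers are plain centroids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "BACKBONE_ROLES",
    "PeptideTopology",
    "Box",
    "Frame",
    "Trajectory",
    "TopologyError",
    "FormatError",
    "read_trajectory",
    "write_trajectory",
    "peptide_mass_centers",
]

BACKBONE_ROLES = ("N", "CA", "C")
SIDECHAIN_ROLE = "SC"

#: one-letter residues with no side-chain bead
_NO_SIDECHAIN = frozenset("G")


class TopologyError(ValueError):
    """Bead bookkeeping does not match the declared topology."""


class FormatError(ValueError):
    """A trajectory file record could not be parsed."""


@dataclass(frozen=True)
class PeptideTopology:
    """Bead layout of a system of identical coarse-grained peptides.

    Parameters
    ----------
    n_peptides : int
        Number of peptide chains (N0).
    sequence : str
        One-letter residue sequence, e.g. ``"GNNQQNY"``; glycine residues
        carry no side-chain bead, all others carry one.
    side_chain_residue_index : int, optional
        1-based residue whose side-chain bead represents the peptide when a
        single-bead representation is requested (the tyrosine for GNNQQNY).
        Defaults to the last residue.
    bead_mass : float
        Mass of every bead (identical for all beads); only the ratio matters
        so the default of 1.0 is fine for geometry.
    """

    n_peptides: int
    sequence: str
    side_chain_residue_index: int | None = None
    bead_mass: float = 1.0

    def __post_init__(self) -> None:
        if self.n_peptides < 1:
            raise TopologyError("n_peptides must be >= 1")
        if not self.sequence:
            raise TopologyError("empty sequence")
        idx = self.side_chain_residue_index
        if idx is None:
            object.__setattr__(self, "side_chain_residue_index", self.n_residues)
        elif not (1 <= idx <= self.n_residues):
            raise TopologyError(f"side_chain_residue_index {idx} out of range")

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def beads_per_peptide(self) -> int:
        # 3 backbone beads per residue + one side-chain bead per non-Gly
        n_sc = sum(1 for aa in self.sequence if aa not in _NO_SIDECHAIN)
        return 3 * self.n_residues + n_sc

    @property
    def n_beads(self) -> int:
        return self.n_peptides * self.beads_per_peptide

    def bead_roles(self) -> list[tuple[int, str]]:
        """Per-bead (1-based residue index, role) for a single peptide.

        Bead order within a residue is N, CA, C, then SC when present.
        """
        roles: list[tuple[int, str]] = []
        for i, aa in enumerate(self.sequence, start=1):
            for r in BACKBONE_ROLES:
                roles.append((i, r))
            if aa not in _NO_SIDECHAIN:
                roles.append((i, SIDECHAIN_ROLE))
        return roles

    def bead_peptide_index(self) -> np.ndarray:
        """Peptide index (0-based) of every bead in the frame."""
        return np.repeat(np.arange(self.n_peptides), self.beads_per_peptide)

    def bead_slice(self, peptide: int) -> slice:
        bpp = self.beads_per_peptide
        return slice(peptide * bpp, (peptide + 1) * bpp)

    def role_offsets(self, role: str, residue: int | None = None) -> np.ndarray:
        """Offsets (within one peptide) of beads with `role`, optionally of
        one 1-based residue."""
        out = [
            k
            for k, (res, r) in enumerate(self.bead_roles())
            if r == role and (residue is None or res == residue)
        ]
        return np.asarray(out, dtype=int)

    def has_side_chain(self, residue: int) -> bool:
        return self.sequence[residue - 1] not in _NO_SIDECHAIN

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PeptideTopology":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            n_peptides=int(data["n_peptides"]),
            sequence=str(data["sequence"]),
            side_chain_residue_index=data.get("side_chain_residue_index"),
            bead_mass=float(data.get("bead_mass", 1.0)),
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "n_peptides": self.n_peptides,
                    "sequence": self.sequence,
                    "side_chain_residue_index": self.side_chain_residue_index,
                    "bead_mass": self.bead_mass,
                },
                fh,
            )


@dataclass(frozen=True)
class Box:
    """Orthorhombic periodic box; edge lengths in nm."""

    edge_lengths: tuple[float, float, float]
    periodic: tuple[bool, bool, bool] = (True, True, True)

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.edge_lengths):
            raise ValueError("box edge lengths must be positive")

    @classmethod
    def cubic(cls, edge: float) -> "Box":
        return cls((float(edge),) * 3)

    @property
    def lengths(self) -> np.ndarray:
        return np.asarray(self.edge_lengths, dtype=float)

    @property
    def min_edge(self) -> float:
        return float(min(self.edge_lengths))


@dataclass
class Frame:
    """One time point: bead coordinates (nm) bound to a topology and a box."""

    time: float
    coordinates: np.ndarray
    box: Box
    topology: PeptideTopology

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (self.topology.n_beads, 3):
            raise TopologyError(
                f"frame has {self.coordinates.shape[0]} beads, topology "
                f"declares {self.topology.n_beads}"
            )

    def peptide_coordinates(self, peptide: int) -> np.ndarray:
        return self.coordinates[self.topology.bead_slice(peptide)]


@dataclass
class Trajectory:
    """Time-ordered frames sharing one topology."""

    frames: list[Frame] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [f.time for f in self.frames]
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i) -> Frame:
        return self.frames[i]

    @property
    def topology(self) -> PeptideTopology:
        return self.frames[0].topology

    @property
    def times(self) -> np.ndarray:
        return np.asarray([f.time for f in self.frames])


# ---------------------------------------------------------------------------
# XYZ dialect: the comment line carries "time=<t> box=<Lx,Ly,Lz>", lengths in
# the declared unit (nm by default).


def _read_xyz(path: Path, topology: PeptideTopology, unit_scale: float) -> Trajectory:
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        frame_no += 1
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise FormatError(f"line {i + 1}: expected bead count") from exc
        if n != topology.n_beads:
            raise TopologyError(
                f"frame {frame_no} has {n} beads, topology declares "
                f"{topology.n_beads}"
            )
        comment = lines[i + 1]
        time, box = _parse_xyz_comment(comment, frame_no, unit_scale)
        coords = np.empty((n, 3))
        for k in range(n):
            parts = lines[i + 2 + k].split()
            if len(parts) < 4:
                raise FormatError(f"line {i + 3 + k}: short XYZ record")
            try:
                coords[k] = [float(p) for p in parts[1:4]]
            except ValueError as exc:
                raise FormatError(f"line {i + 3 + k}: bad coordinate") from exc
        coords *= unit_scale
        if time is None:
            time = float(frame_no - 1)
        frames.append(Frame(time, coords, box, topology))
        i += 2 + n
    if not frames:
        raise FormatError(f"{path}: no frames found")
    return Trajectory(frames)


def _parse_xyz_comment(
    comment: str, frame_no: int, unit_scale: float
) -> tuple[float | None, Box]:
    time = None
    box = None
    for token in comment.split():
        if token.startswith("time="):
            time = float(token[5:])
        elif token.startswith("box="):
            edges = tuple(float(x) * unit_scale for x in token[4:].split(","))
            if len(edges) == 1:
                edges = edges * 3
            box = Box(edges)  # type: ignore[arg-type]
    if box is None:
        raise FormatError(f"frame {frame_no}: XYZ comment line lacks box=")
    return time, box


def _write_xyz(path: Path, traj: Trajectory) -> None:
    names = [r for _, r in traj.topology.bead_roles()] * traj.topology.n_peptides
    with open(path, "w") as fh:
        for frame in traj:
            L = frame.box.edge_lengths
            fh.write(f"{traj.topology.n_beads}\n")
            fh.write(f"time={frame.time:.10g} box={L[0]:.10g},{L[1]:.10g},{L[2]:.10g}\n")
            for name, xyz in zip(names, frame.coordinates):
                fh.write(f"{name} {xyz[0]:.8f} {xyz[1]:.8f} {xyz[2]:.8f}\n")


# ---------------------------------------------------------------------------
# PDB / GRO via MDAnalysis (coordinates converted Å -> nm on the way in).


def _read_mda(path: Path, topology: PeptideTopology, fmt: str) -> Trajectory:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path), format=fmt)
        frames: list[Frame] = []
        for frame_no, ts in enumerate(u.trajectory, start=1):
            if ts.n_atoms != topology.n_beads:
                raise TopologyError(
                    f"frame {frame_no} has {ts.n_atoms} beads, topology "
                    f"declares {topology.n_beads}"
                )
            if ts.dimensions is None or not np.all(ts.dimensions[:3] > 0):
                raise FormatError(f"frame {frame_no}: no box information")
            coords = ts.positions.astype(float) / 10.0  # Å -> nm
            box = Box(tuple(float(d) / 10.0 for d in ts.dimensions[:3]))
            t = float(ts.time) if ts.time is not None else float(frame_no - 1)
            frames.append(Frame(t, coords, box, topology))
    # MDAnalysis reports time 0 for every model of a multi-MODEL PDB; fall
    # back to the frame index so Trajectory's ordering invariant holds.
    times = [f.time for f in frames]
    if len(frames) > 1 and len(set(times)) != len(times):
        for k, f in enumerate(frames):
            f.time = float(k)
    return Trajectory(frames)


def _write_pdb(path: Path, traj: Trajectory) -> None:
    import MDAnalysis as mda

    top = traj.topology
    roles = top.bead_roles() * top.n_peptides
    resids = np.concatenate(
        [np.asarray([res for res, _ in top.bead_roles()]) + p * top.n_residues
         for p in range(top.n_peptides)]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            top.n_beads,
            n_residues=top.n_peptides * top.n_residues,
            atom_resindex=resids - 1,
            trajectory=True,
        )
        u.add_TopologyAttr("names", [r for _, r in roles])
        u.add_TopologyAttr("resids", np.arange(1, top.n_peptides * top.n_residues + 1))
        u.add_TopologyAttr(
            "resnames", ["PEP"] * (top.n_peptides * top.n_residues)
        )
        with mda.Writer(str(path), n_atoms=top.n_beads, multiframe=True) as w:
            for frame in traj:
                u.atoms.positions = frame.coordinates * 10.0  # nm -> Å
                u.dimensions = [*(frame.box.lengths * 10.0), 90.0, 90.0, 90.0]
                w.write(u.atoms)


_FORMATS = {"xyz", "pdb", "gro"}


def read_trajectory(
    path: str | Path,
    topology: PeptideTopology,
    format: str | None = None,
    xyz_unit: str = "nm",
) -> Trajectory:
    """Read a trajectory file into the internal nm representation.

    Parameters
    ----------
    path : str or Path
    topology : PeptideTopology
        Bead bookkeeping; the per-frame bead count must match.
    format : {"xyz", "pdb", "gro"}, optional
        Inferred from the file suffix when omitted.
    xyz_unit : {"nm", "angstrom"}
        Length unit of a plain XYZ file (the format itself declares none).
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported trajectory format: {fmt!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "xyz":
        scale = {"nm": 1.0, "angstrom": 0.1, "a": 0.1}[xyz_unit.lower()]
        return _read_xyz(path, topology, scale)
    return _read_mda(path, topology, fmt.upper())


def write_trajectory(path: str | Path, traj: Trajectory, format: str | None = None) -> None:
    """Write a trajectory as XYZ (nm, with time/box metadata) or PDB (Å)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "xyz":
        _write_xyz(path, traj)
    elif fmt == "pdb":
        _write_pdb(path, traj)
    else:
        raise ValueError(f"unsupported output format: {fmt!r}")


def peptide_mass_centers(
    frame: Frame, selection: str = "all", residue: int | None = None
) -> np.ndarray:
    """Per-peptide mass centers (equal bead masses -> centroids).

    selection="all" averages every bead of the peptide; "side_chain" uses the
    side-chain bead of the topology's designated residue (e.g. the tyrosine of
    GNNQQNY), the representation that stabilises cluster-axis fits.
    """
    top = frame.topology
    if selection == "all":
        coords = frame.coordinates.reshape(top.n_peptides, top.beads_per_peptide, 3)
        return coords.mean(axis=1)
    if selection == "side_chain":
        res = residue if residue is not None else top.side_chain_residue_index
        if not top.has_side_chain(res):
            raise TopologyError(
                f"residue {res} ({top.sequence[res - 1]}) has no side-chain bead"
            )
        offsets = top.role_offsets(SIDECHAIN_ROLE, residue=res)
        idx = (
            np.arange(top.n_peptides)[:, None] * top.beads_per_peptide + offsets
        ).ravel()
        pts = frame.coordinates[idx].reshape(top.n_peptides, len(offsets), 3)
        return pts.mean(axis=1)
    raise ValueError(f"unknown selection {selection!r}")
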