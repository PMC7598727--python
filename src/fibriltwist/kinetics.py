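"""Kinetic-curve reductions, power-law scaling fits, and unit utilities.

Aggregation kinetics are summarised by the monomer half-time t1/2, the time
tmax at which the cluster count peaks, and master curves obtained by scaling
counts by the initial peptide number N0 and time by t1/2 (monomers) or tmax
(clusters).  The size dependence of the mean radius of gyration is fitted by
two power laws: Rg ~ M^alpha for small amorphous clusters and
Rg - Rg* ~ (M - M*)^beta above the critical fibril size M*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.constants import Avogadro, Boltzmann, calorie
from scipy.stats import linregress

from .clustering import KineticCurves
from .io_core import Box

__all__ = [
    "ScalingFit",
    "half_time",
    "cluster_peak_time",
    "scale_curves",
    "collapse_gap",
    "descriptor_vs_size",
    "fit_power_small",
    "fit_power_shifted",
    "concentration_from_box",
    "box_for_concentration",
    "equilibrium_concentration",
    "convert_unit",
    "CRITICAL_SIZE_DEFAULT",
    "CRITICAL_RG_NM_DEFAULT",
]

#: critical aggregate size separating amorphous from fibril-like morphology
CRITICAL_SIZE_DEFAULT = 25
#: mean radius of gyration at the critical size (13.32 Å)
CRITICAL_RG_NM_DEFAULT = 1.332


def half_time(curves: KineticCurves) -> float:
    """First time at which Nm crosses N0/2, linearly interpolated."""
    nm = np.asarray(curves.n_monomers, dtype=float)
    t = np.asarray(curves.times, dtype=float)
    target = curves.n_peptides / 2.0
    if nm[0] < target:
        raise ValueError("monomer count already below N0/2 at the first frame")
    below = np.nonzero(nm <= target)[0]
    if len(below) == 0:
        raise ValueError("monomer count never reaches N0/2")
    k = int(below[0])
    if nm[k] == target or k == 0:
        return float(t[k])
    # linear interpolation between the bracketing frames
    f = (nm[k - 1] - target) / (nm[k - 1] - nm[k])
    return float(t[k - 1] + f * (t[k] - t[k - 1]))


def cluster_peak_time(curves: KineticCurves, smooth_window: int = 5) -> float:
    """Time of the (smoothed) maximum of the cluster count; earliest on ties.

    A centered moving average of `smooth_window` frames guards against noise;
    the window is clipped to the series length.
    """
    nc = np.asarray(curves.n_clusters, dtype=float)
    if len(nc) < 3:
        raise ValueError("need at least three frames")
    w = max(1, min(smooth_window, len(nc)))
    if w % 2 == 0:
        w -= 1
    if w > 1:
        kernel = np.ones(w) / w
        padded = np.pad(nc, w // 2, mode="edge")
        smooth = np.convolve(padded, kernel, mode="valid")
    else:
        smooth = nc
    return float(curves.times[int(np.argmax(smooth))])


def scale_curves(
    curves: KineticCurves, smooth_window: int = 5
) -> pd.DataFrame:
    """Dimensionless master-curve series.

    Returns a frame with columns t_over_thalf, nm_scaled (Nm/N0),
    t_over_tmax, nc_scaled (Nc/N0).
    """
    t_half = half_time(curves)
    t_max = cluster_peak_time(curves, smooth_window)
    if t_half <= 0 or t_max <= 0:
        raise ValueError("scaling times must be positive")
    return pd.DataFrame(
        {
            "time": curves.times,
            "t_over_thalf": curves.times / t_half,
            "nm_scaled": curves.n_monomers / curves.n_peptides,
            "t_over_tmax": curves.times / t_max,
            "nc_scaled": curves.n_clusters / curves.n_peptides,
        }
    )


def collapse_gap(
    scaled_a: pd.DataFrame,
    scaled_b: pd.DataFrame,
    which: str = "monomers",
    n_grid: int = 200,
) -> float:
    """Maximum vertical gap between two scaled curves on a common log-time
    grid — a collapse-quality measure (0 for a perfect collapse)."""
    xcol, ycol = (
        ("t_over_thalf", "nm_scaled")
        if which == "monomers"
        else ("t_over_tmax", "nc_scaled")
    )
    xa, ya = scaled_a[xcol].to_numpy(), scaled_a[ycol].to_numpy()
    xb, yb = scaled_b[xcol].to_numpy(), scaled_b[ycol].to_numpy()
    lo = max(xa[xa > 0].min(), xb[xb > 0].min())
    hi = min(xa.max(), xb.max())
    if hi <= lo:
        raise ValueError("scaled time ranges do not overlap")
    grid = np.logspace(np.log10(lo), np.log10(hi), n_grid)
    fa = np.interp(grid, xa, ya)
    fb = np.interp(grid, xb, yb)
    return float(np.max(np.abs(fa - fb)))


def descriptor_vs_size(observations: list[tuple[int, float]]) -> pd.DataFrame:
    """Mean, SD and standard error of a descriptor pooled per cluster size.

    `observations` are (M, value) pairs pooled over frames and runs; sizes
    with one observation report NaN spread.
    """
    df = pd.DataFrame(observations, columns=["M", "value"])
    out = (
        df.groupby("M")["value"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out


@dataclass(frozen=True)
class ScalingFit:
    """Log-log power-law fit result."""

    exponent: float
    intercept: float
    stderr: float
    m_range: tuple[float, float]
    variant: str  # "small" or "shifted"
    m_star: float | None = None
    rg_star: float | None = None


def fit_power_small(
    m: np.ndarray, rg_mean: np.ndarray, m_max: float = CRITICAL_SIZE_DEFAULT
) -> ScalingFit:
    """Fit Rg ~ M^alpha on sizes below m_max (unweighted log-log LS)."""
    m = np.asarray(m, dtype=float)
    rg = np.asarray(rg_mean, dtype=float)
    mask = m < m_max
    if mask.sum() < 3:
        raise ValueError("need at least three sizes below the cut")
    if np.any(m[mask] <= 0) or np.any(rg[mask] <= 0):
        raise ValueError("sizes and radii must be positive for a log-log fit")
    res = linregress(np.log(m[mask]), np.log(rg[mask]))
    return ScalingFit(
        exponent=float(res.slope),
        intercept=float(res.intercept),
        stderr=float(res.stderr) if res.stderr is not None else float("nan"),
        m_range=(float(m[mask].min()), float(m[mask].max())),
        variant="small",
    )


def fit_power_shifted(
    m: np.ndarray,
    rg_mean: np.ndarray,
    m_star: float = CRITICAL_SIZE_DEFAULT,
    rg_star: float = CRITICAL_RG_NM_DEFAULT,
) -> ScalingFit:
    """Fit Rg - Rg* ~ (M - M*)^beta on sizes above the critical size M*."""
    m = np.asarray(m, dtype=float)
    rg = np.asarray(rg_mean, dtype=float)
    mask = m > m_star
    if mask.sum() < 3:
        raise ValueError("need at least three sizes above M*")
    dm = m[mask] - m_star
    drg = rg[mask] - rg_star
    if np.any(drg <= 0):
        raise ValueError("Rg must exceed Rg* over the fit domain")
    res = linregress(np.log(dm), np.log(drg))
    return ScalingFit(
        exponent=float(res.slope),
        intercept=float(res.intercept),
        stderr=float(res.stderr) if res.stderr is not None else float("nan"),
        m_range=(float(m[mask].min()), float(m[mask].max())),
        variant="shifted",
        m_star=float(m_star),
        rg_star=float(rg_star),
    )


# ---------------------------------------------------------------------------
# concentrations and units


def concentration_from_box(n_peptides: int, edge_nm: float) -> float:
    """Molar concentration (mM) of n peptides in a cubic box of edge L nm."""
    if n_peptides < 1 or edge_nm <= 0:
        raise ValueError("need n_peptides >= 1 and a positive box edge")
    volume_litre = (edge_nm * 1e-9) ** 3 * 1e3  # m^3 -> L
    return n_peptides / Avogadro / volume_litre * 1e3  # mol/L -> mM


def box_for_concentration(n_peptides: int, c0_mM: float) -> float:
    """Cubic box edge (nm) realising a target concentration (mM)."""
    if c0_mM <= 0:
        raise ValueError("concentration must be positive")
    volume_litre = n_peptides / Avogadro / (c0_mM / 1e3)
    return (volume_litre / 1e3) ** (1.0 / 3.0) * 1e9


def equilibrium_concentration(
    curves: KineticCurves, box: Box, tracked_sizes: np.ndarray | None = None
) -> float:
    """Equilibrium free-monomer concentration (mM) from the trajectory tail.

    The tail starts at the first frame where the largest cluster attains its
    final size (supply the identity-tracked sizes when available; the raw
    per-frame largest size is the fallback); ceq is the tail-mean Nm divided
    by the box volume.
    """
    sizes = np.asarray(
        tracked_sizes if tracked_sizes is not None else curves.largest_size
    )
    final = sizes[-1]
    start = int(np.nonzero(sizes == final)[0][0])
    tail = np.asarray(curves.n_monomers, dtype=float)[start:]
    if len(tail) == 0:
        raise ValueError("empty trajectory tail")
    edge = box.edge_lengths
    volume_litre = float(edge[0] * edge[1] * edge[2]) * 1e-27 * 1e3
    return float(tail.mean() / Avogadro / volume_litre * 1e3)


_LENGTH = {("angstrom", "nm"): 0.1, ("nm", "angstrom"): 10.0}


def convert_unit(
    value: float, src: str, dst: str, tau_ps: float | None = None
) -> float:
    """Small physical-unit conversions used around the analysis.

    Supported: J <-> kcal/mol (per particle via Avogadro), angstrom <-> nm,
    tau <-> ps (requires the model's tau value in ps), K -> J (thermal energy
    kB*T).
    """
    src, dst = src.lower(), dst.lower()
    if (src, dst) in _LENGTH:
        return value * _LENGTH[(src, dst)]
    if src == "j" and dst == "kcal/mol":
        return value * Avogadro / (1e3 * calorie)
    if src == "kcal/mol" and dst == "j":
        return value * 1e3 * calorie / Avogadro
    if src == "k" and dst == "j":
        return value * Boltzmann
    if src == "tau" and dst == "ps":
        if tau_ps is None:
            raise ValueError("tau <-> ps conversion needs tau_ps")
        return value * tau_ps
    if src == "ps" and dst == "tau":
        if tau_ps is None:
            raise ValueError("tau <-> ps conversion needs tau_ps")
        return value / tau_ps
    raise ValueError(f"unsupported conversion {src!r} -> {dst!r}")
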