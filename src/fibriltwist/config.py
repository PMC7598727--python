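"""Analysis configuration: every numeric constant of the pipeline in one
serialisable object, round-tripping unchanged through YAML."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .descriptors import DEFAULT_BETA_REGION
from .helicity import DM2_A_NM, DM2_B_NM, S_PARALLEL, S_PERPENDICULAR
from .kinetics import CRITICAL_RG_NM_DEFAULT, CRITICAL_SIZE_DEFAULT

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """Tunable constants of the aggregation analysis (lengths in nm)."""

    cutoff: float = 0.5  # bead-bead cluster linkage distance
    dm2_a: float = DM2_A_NM  # reference-spacing fit dm2(M) = a/M + b
    dm2_b: float = DM2_B_NM
    s_par: float = S_PARALLEL  # longitudinal ribbon-cutoff scaling
    s_perp: float = S_PERPENDICULAR  # perpendicular ribbon-cutoff scaling
    hist_bin_width: float = 0.02  # mass-center histogram bin
    beta_region: dict = field(default_factory=lambda: {
        "phi": list(DEFAULT_BETA_REGION["phi"]),
        "psi": [list(r) for r in DEFAULT_BETA_REGION["psi"]],
    })
    smooth_window: int = 5  # frames, for the cluster-count peak
    m_star: float = float(CRITICAL_SIZE_DEFAULT)
    rg_star: float = CRITICAL_RG_NM_DEFAULT
    seed: int = 0
    xyz_unit: str = "nm"
    axis_selection: str = "all"  # or "side_chain" (tyrosine representation)

    def __post_init__(self) -> None:
        for name in ("cutoff", "s_par", "s_perp", "hist_bin_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def as_metadata(self) -> dict:
        return asdict(self)
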