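"""Run configuration.

Thresholds default to the values used throughout the analysis: clones are
tracked if they exceed 0.01 %WBC at some time point, per-clone production
changes below 0.1 %WBC are ignored in change counting, and the lineage-bias
eligibility floor is B_min = 0.05 with Gr_min scaled by the mouse's initial
granulocyte-to-B-cell ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml


@dataclass
class KdeSettings:
    """Kernel-density settings for the shift classifier.

    bw_method is passed to the Gaussian KDE ("scott" by default; the
    analysis does not prescribe a bandwidth rule).  grid_size points are
    laid uniformly over [0, max shift + 3 bandwidths].
    """

    bw_method: str | float = "scott"
    grid_size: int = 512
    min_values: int = 30


@dataclass
class RunConfig:
    """Thresholds and switches for a full pipeline run."""

    inclusion_threshold_pct_wbc: float = 0.01
    change_floor_pct_wbc: float = 0.1
    b_min: float = 0.05
    presence_threshold_pct: float = 0.01
    kde_settings: KdeSettings = field(default_factory=KdeSettings)
    plsr_components: int = 2
    seed: int = 0
    # lineage-bias switches (defaults follow the printed procedure)
    bias_scale_to_unit: bool = True       # map theta onto [-1, 1] (vs raw 2*(theta-pi/4))
    eligibility_both_timepoints: bool = True
    normalize_at_predivergent: bool = True
    filter_per_celltype: bool = True      # 0.01% rule per (tp, blood cell type)
    shared_shift_cutoff: bool = True      # one cutoff pooled across groups

    def __post_init__(self) -> None:
        if isinstance(self.kde_settings, dict):
            self.kde_settings = KdeSettings(**self.kde_settings)
        for name in (
            "inclusion_threshold_pct_wbc",
            "change_floor_pct_wbc",
            "b_min",
            "presence_threshold_pct",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.plsr_components < 1:
            raise ValueError("plsr_components must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_dict(self) -> dict:
        return asdict(self)
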