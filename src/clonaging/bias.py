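"""Lineage bias: the clone-level myeloid-lymphoid balance statistic.

Each clone's granulocyte and B-cell abundances are first normalized by the
corresponding population abundance (FACS) at the pre-divergent time point.
The lineage balance is

    theta = arctan(Gr_normalized / B_normalized)  in [0, pi/2]

computed with a two-argument arctangent so B_normalized = 0 maps exactly to
pi/2.  Lineage bias rescales theta onto [-1, 1], where +1 is myeloid
committed and -1 lymphoid committed:

    bias = (4/pi) * theta - 1

(the raw variant 2*(theta - pi/4), which spans [-pi/2, pi/2], is available
via ``scale_to_unit=False``).  Clones with theta in [0, pi/8] are
lymphoid-biased, in (pi/8, 3pi/8) balanced, and in [3pi/8, pi/2]
myeloid-biased (boundaries inclusive on the biased side).

Bias is only computed for clones whose granulocyte or B-cell abundance
reaches the per-mouse eligibility floor: B_min = 0.05 and
Gr_min = (# initial Gr cells / # initial B cells) x B_min.  The shift of a
clone is its bias at the end time point minus its bias at the
pre-divergent time point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .tables import CellType, TimePoint, validate_table

LYMPHOID_CUT = math.pi / 8
MYELOID_CUT = 3 * math.pi / 8


@dataclass(frozen=True)
class EligibilityThresholds:
    """Per-mouse abundance floors for lineage-bias eligibility (%WBC)."""

    gr_min: float
    b_min: float = 0.05


def eligibility_thresholds(
    initial_gr_count: float, initial_b_count: float, b_min: float = 0.05
) -> EligibilityThresholds:
    """Gr_min = (initial Gr count / initial B count) x B_min.

    Counts may be absolute cell counts or any quantity proportional to them
    (e.g. FACS percentages of the same blood draw).
    """
    if initial_gr_count <= 0 or initial_b_count <= 0:
        raise ValueError("initial cell counts must be positive")
    if b_min <= 0:
        raise ValueError("b_min must be positive")
    return EligibilityThresholds(gr_min=(initial_gr_count / initial_b_count) * b_min, b_min=b_min)


def normalize_abundance(clone_abundance: float, population_abundance: float) -> float:
    """Clone abundance divided by its cell population's abundance (dimensionless)."""
    if population_abundance <= 0:
        raise ValueError("population abundance must be positive")
    if clone_abundance < 0:
        raise ValueError("clone abundance must be non-negative")
    return clone_abundance / population_abundance


def theta(gr_normalized: float, b_normalized: float) -> float:
    """Lineage balance angle arctan(Gr_norm / B_norm) in [0, pi/2]."""
    if gr_normalized < 0 or b_normalized < 0:
        raise ValueError("normalized abundances must be non-negative")
    if gr_normalized == 0 and b_normalized == 0:
        raise ValueError("theta undefined when both normalized abundances are zero")
    return math.atan2(gr_normalized, b_normalized)


def lineage_bias_value(theta_value: float, scale_to_unit: bool = True) -> float:
    """Map theta onto the lineage-bias axis.

    With ``scale_to_unit`` (default) the map is affine onto [-1, 1]; the
    raw variant 2*(theta - pi/4) is kept for comparison.
    """
    if not 0.0 <= theta_value <= math.pi / 2 + 1e-12:
        raise ValueError(f"theta out of [0, pi/2]: {theta_value}")
    if scale_to_unit:
        return (4.0 / math.pi) * theta_value - 1.0
    return 2.0 * (theta_value - math.pi / 4)


def bias_category(theta_value: float) -> str:
    """Classify theta into lymphoid_biased / balanced / myeloid_biased."""
    if not 0.0 <= theta_value <= math.pi / 2 + 1e-12:
        raise ValueError(f"theta out of [0, pi/2]: {theta_value}")
    if theta_value <= LYMPHOID_CUT:
        return "lymphoid_biased"
    if theta_value >= MYELOID_CUT:
        return "myeloid_biased"
    return "balanced"


def bias_shift(bias_pre: float, bias_end: float) -> float:
    """Lineage-bias shift: bias at end minus bias at pre-divergent."""
    return bias_end - bias_pre


def mouse_thresholds(panel: pd.DataFrame, b_min: float = 0.05) -> dict[str, EligibilityThresholds]:
    """Eligibility thresholds per mouse from initial-time-point FACS percents."""
    panel = validate_table(panel, "facs_panel")
    initial = panel[panel["time_point"] == TimePoint.INITIAL.value]
    out: dict[str, EligibilityThresholds] = {}
    for mouse, grp in initial.groupby("mouse_id"):
        by_ct = grp.set_index("cell_type")["celltype_pct_of_wbc"]
        try:
            gr0 = float(by_ct[CellType.GR.value])
            b0 = float(by_ct[CellType.B.value])
        except KeyError as exc:
            raise KeyError(f"initial FACS row missing for mouse {mouse}: {exc}") from None
        out[mouse] = eligibility_thresholds(gr0, b0, b_min=b_min)
    return out


def bias_table(
    abundance: pd.DataFrame,
    panel: pd.DataFrame,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Per (mouse, barcode, time point) lineage-bias records.

    Columns: mouse_id, barcode_id, time_point, gr_abundance, b_abundance,
    gr_normalized, b_normalized, theta, bias, category, eligible.  Clones
    absent from both lineages at a time point get no record there (theta is
    undefined).  Normalization denominators are the population granulocyte
    and B-cell percentages at the pre-divergent time point (the printed
    procedure); per-time-point denominators via
    ``config.normalize_at_predivergent=False``.
    """
    config = config or RunConfig()
    abundance = validate_table(abundance, "clone_abundance")
    panel = validate_table(panel, "facs_panel")
    thresholds = mouse_thresholds(panel, b_min=config.b_min)

    pop = panel.set_index(["mouse_id", "time_point", "cell_type"])["celltype_pct_of_wbc"]
    blood = abundance[abundance["cell_type"].isin((CellType.GR.value, CellType.B.value))]
    wide = (
        blood.pivot_table(
            index=["mouse_id", "barcode_id", "time_point"],
            columns="cell_type",
            values="abundance",
            fill_value=0.0,
            aggfunc="sum",
        )
        .reindex(columns=[CellType.GR.value, CellType.B.value], fill_value=0.0)
        .reset_index()
        .rename(columns={CellType.GR.value: "gr_abundance", CellType.B.value: "b_abundance"})
    )

    records = []
    for row in wide.itertuples(index=False):
        denom_tp = (
            TimePoint.PRE_DIVERGENT.value if config.normalize_at_predivergent else row.time_point
        )
        try:
            gr_pop = float(pop[(row.mouse_id, denom_tp, CellType.GR.value)])
            b_pop = float(pop[(row.mouse_id, denom_tp, CellType.B.value)])
        except KeyError:
            raise KeyError(
                f"FACS population abundance missing for mouse {row.mouse_id} at {denom_tp}"
            ) from None
        gr_n = normalize_abundance(row.gr_abundance, gr_pop)
        b_n = normalize_abundance(row.b_abundance, b_pop)
        if gr_n == 0.0 and b_n == 0.0:
            continue
        th = theta(gr_n, b_n)
        thr = thresholds[row.mouse_id]
        records.append(
            {
                "mouse_id": row.mouse_id,
                "barcode_id": row.barcode_id,
                "time_point": row.time_point,
                "gr_abundance": row.gr_abundance,
                "b_abundance": row.b_abundance,
                "gr_normalized": gr_n,
                "b_normalized": b_n,
                "theta": th,
                "bias": lineage_bias_value(th, scale_to_unit=config.bias_scale_to_unit),
                "category": bias_category(th),
                "eligible": bool(
                    row.gr_abundance >= thr.gr_min or row.b_abundance >= thr.b_min
                ),
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "mouse_id",
            "barcode_id",
            "time_point",
            "gr_abundance",
            "b_abundance",
            "gr_normalized",
            "b_normalized",
            "theta",
            "bias",
            "category",
            "eligible",
        ],
    )


def shift_table(bias_records: pd.DataFrame, config: RunConfig | None = None) -> pd.DataFrame:
    """Per-clone lineage-bias shifts between pre-divergent and end time points.

    Returns mouse_id, barcode_id, bias_pre, bias_end, category_pre,
    delta_bias, included.  A clone is included when it has bias records at
    both compared time points and meets the eligibility floor at both
    (default) or at least one (``config.eligibility_both_timepoints=False``).
    Excluded clones are kept with ``included=False`` rather than dropped.
    """
    config = config or RunConfig()
    pre = bias_records[bias_records["time_point"] == TimePoint.PRE_DIVERGENT.value]
    end = bias_records[bias_records["time_point"] == TimePoint.END.value]
    merged = pre.merge(
        end, on=["mouse_id", "barcode_id"], suffixes=("_pre", "_end"), how="inner"
    )
    if config.eligibility_both_timepoints:
        ok = merged["eligible_pre"] & merged["eligible_end"]
    else:
        ok = merged["eligible_pre"] | merged["eligible_end"]
    out = pd.DataFrame(
        {
            "mouse_id": merged["mouse_id"],
            "barcode_id": merged["barcode_id"],
            "bias_pre": merged["bias_pre"],
            "bias_end": merged["bias_end"],
            "category_pre": merged["category_pre"],
            "delta_bias": merged["bias_end"] - merged["bias_pre"],
            "included": ok.astype(bool),
        }
    )
    return out.sort_values(["mouse_id", "barcode_id"]).reset_index(drop=True)
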