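"""Population-level aging phenotype.

The immune-aging readout is the BG ratio: population B-cell abundance
divided by granulocyte abundance in peripheral blood.  Mice are classified
as early aging when their end-time-point BG ratio falls strictly below the
minimum ratio observed across the cohort at the initial time point, and
delayed aging when it stays within that range (boundary counts as
delayed).

The aging phenotype can arise from four categories of clone-level change
between the pre-divergent and end time points: increased myeloid
production, decreased lymphoid production, decreased myeloid production
(its suppression delays aging) and increased lymphoid production (its
suppression promotes aging).  The decomposition sums each category's
signed clone deltas per mouse; per lineage, increase and decrease sums add
up exactly to the net clonal change.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .tables import CellType, TimePoint


def bg_ratio(b_pct: float, gr_pct: float) -> float:
    """Population B-cell % of WBC divided by granulocyte % of WBC."""
    if gr_pct <= 0:
        raise ValueError("granulocyte percentage must be positive")
    if b_pct < 0:
        raise ValueError("B-cell percentage must be non-negative")
    return b_pct / gr_pct


def phenotype_table(panel: pd.DataFrame) -> pd.DataFrame:
    """Per (mouse, time point) population percents and BG ratio from FACS."""
    wide = panel.pivot_table(
        index=["mouse_id", "time_point"],
        columns="cell_type",
        values="celltype_pct_of_wbc",
        aggfunc="first",
    )
    missing = [c for c in (CellType.B.value, CellType.GR.value) if c not in wide.columns]
    if missing:
        raise ValueError(f"FACS panel lacks blood cell types: {missing}")
    out = wide.reset_index()[["mouse_id", "time_point"]]
    out["b_pct"] = wide[CellType.B.value].to_numpy()
    out["gr_pct"] = wide[CellType.GR.value].to_numpy()
    out["bg_ratio"] = [bg_ratio(b, g) for b, g in zip(out["b_pct"], out["gr_pct"])]
    return out


def classify_mice(phenotypes: pd.DataFrame, reference: pd.DataFrame | None = None) -> pd.DataFrame:
    """Early vs delayed aging from end-time-point BG ratios.

    The threshold is the minimum BG ratio across the reference cohort at
    the initial time point (``reference`` defaults to the phenotype table
    itself).  ``group`` is ``early`` iff end ratio < threshold, ``delayed``
    otherwise; mice without an end ratio stay unclassified (NaN group,
    flagged).
    """
    ref = reference if reference is not None else phenotypes
    initial = ref[ref["time_point"] == TimePoint.INITIAL.value]
    if len(initial) < 2:
        raise ValueError("need initial-time-point ratios from at least 2 mice")
    threshold = float(initial["bg_ratio"].min())
    end = phenotypes[phenotypes["time_point"] == TimePoint.END.value].set_index("mouse_id")[
        "bg_ratio"
    ]
    mice = sorted(phenotypes["mouse_id"].unique())
    rows = []
    for mouse in mice:
        if mouse in end.index:
            ratio = float(end[mouse])
            group = "early" if ratio < threshold else "delayed"
            rows.append(
                {"mouse_id": mouse, "end_bg_ratio": ratio, "group": group, "unclassified": False}
            )
        else:
            rows.append(
                {"mouse_id": mouse, "end_bg_ratio": np.nan, "group": None, "unclassified": True}
            )
    out = pd.DataFrame(rows)
    out.attrs["threshold"] = threshold
    return out


def change_decomposition(
    gr_deltas: pd.DataFrame, b_deltas: pd.DataFrame, floor: float | None = None
) -> pd.DataFrame:
    """Sign-partitioned sums of clone production changes per mouse.

    Inputs are per-clone delta tables (mouse_id, barcode_id, delta) for
    granulocytes and B cells.  Per mouse: sum_myeloid_increase (>= 0),
    sum_myeloid_decrease (<= 0), sum_lymphoid_increase, sum_lymphoid_decrease.
    With ``floor`` set, deltas smaller than it in magnitude are ignored
    before partitioning (off by default: all tracked clones count).
    """

    def partition(deltas: pd.DataFrame, prefix: str) -> pd.DataFrame:
        d = deltas.copy()
        if floor is not None:
            d = d[d["delta"].abs() >= floor]
        pos = d[d["delta"] > 0].groupby("mouse_id")["delta"].sum()
        neg = d[d["delta"] < 0].groupby("mouse_id")["delta"].sum()
        return pd.DataFrame({f"sum_{prefix}_increase": pos, f"sum_{prefix}_decrease": neg})

    mice = pd.Index(
        sorted(set(gr_deltas["mouse_id"]).union(b_deltas["mouse_id"])), name="mouse_id"
    )
    out = pd.concat(
        [partition(gr_deltas, "myeloid"), partition(b_deltas, "lymphoid")], axis=1
    ).reindex(mice).fillna(0.0)
    return out.reset_index()


def group_decomposition_summary(
    decomposition: pd.DataFrame, groups: pd.DataFrame
) -> pd.DataFrame:
    """Group means of the four change categories and early-minus-delayed differences."""
    merged = decomposition.merge(groups[["mouse_id", "group"]], on="mouse_id", how="inner")
    cols = [
        "sum_myeloid_increase",
        "sum_myeloid_decrease",
        "sum_lymphoid_increase",
        "sum_lymphoid_decrease",
    ]
    means = merged.groupby("group")[cols].mean()
    summary = means.T
    if {"early", "delayed"} <= set(summary.columns):
        summary["early_minus_delayed"] = summary["early"] - summary["delayed"]
    return summary.reset_index(names="category")


def normalized_population_change(initial_pct: float, end_pct: float) -> float:
    """(end - initial) / initial for a population abundance."""
    if initial_pct <= 0:
        raise ValueError("initial abundance must be positive")
    return (end_pct - initial_pct) / initial_pct


def population_change_correlation(phenotypes: pd.DataFrame, groups: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of normalized Gr vs B population changes per group.

    Normalized change is (end - initial)/initial per mouse; groups with
    fewer than 3 mice get an undefined (NaN) correlation, flagged.
    """
    wide = phenotypes.pivot_table(
        index="mouse_id", columns="time_point", values=["gr_pct", "b_pct"], aggfunc="first"
    )
    rows = []
    merged_groups = groups.set_index("mouse_id")["group"]
    for group in ("early", "delayed"):
        mice = merged_groups[merged_groups == group].index
        gr_ch, b_ch = [], []
        for mouse in mice:
            try:
                gr0 = wide.loc[mouse, ("gr_pct", TimePoint.INITIAL.value)]
                gr1 = wide.loc[mouse, ("gr_pct", TimePoint.END.value)]
                b0 = wide.loc[mouse, ("b_pct", TimePoint.INITIAL.value)]
                b1 = wide.loc[mouse, ("b_pct", TimePoint.END.value)]
            except KeyError:
                continue
            if np.isnan([gr0, gr1, b0, b1]).any():
                continue
            gr_ch.append(normalized_population_change(gr0, gr1))
            b_ch.append(normalized_population_change(b0, b1))
        if len(gr_ch) >= 3:
            r, p = stats.pearsonr(gr_ch, b_ch)
            rows.append({"group": group, "n_mice": len(gr_ch), "pearson_r": float(r),
                         "p_value": float(p), "undefined": False})
        else:
            rows.append({"group": group, "n_mice": len(gr_ch), "pearson_r": np.nan,
                         "p_value": np.nan, "undefined": True})
    return pd.DataFrame(rows)
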