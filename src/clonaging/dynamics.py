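"""Clonal dynamics: expansion, fate labels, change counting, differentiation.

Expansion threshold: per mouse, clones of one cell type are ranked by
pre-divergent abundance; the minimal top prefix whose cumulative abundance
reaches at least half of the summed abundance of all tracked clones is
taken, and the lowest abundance within it recorded.  The cohort threshold
is the mean of the per-mouse values; a clone is "expanded" when its
end-time-point abundance strictly exceeds it.

Fate labels from blood presence at months 4 (initial), 9 (pre-divergent)
and the end time point: persistent (1,1,1), exhausted (1,1,0), activated
(0,0,1); every other pattern is "other".

Change counting: per-clone production changes between the pre-divergent
and end time points smaller than 0.1 %WBC in magnitude are ignored; the
rest are counted and summed separately for increases and decreases.

Myeloid differentiation index: the clone's granulocyte output at the end
time point divided by its HSC abundance there — a surrogate for per-HSC
myeloid output (the underlying study quantifies differentiation from the
same two abundances without printing a formula).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import BLOOD_CELL_TYPES, CellType, TimePoint

FATE_PATTERNS = {
    (True, True, True): "persistent",
    (True, True, False): "exhausted",
    (False, False, True): "activated",
}


def minimal_dominant_abundance(abundances) -> float:
    """Lowest abundance in the minimal top-ranked prefix covering >= half the total."""
    values = np.sort(np.asarray(abundances, dtype=float))[::-1]
    if values.size == 0 or values.sum() <= 0:
        raise ValueError("need at least one clone with positive abundance")
    target = values.sum() / 2.0
    cum = np.cumsum(values)
    k = int(np.argmax(cum >= target))  # first index reaching half
    return float(values[k])


@dataclass
class ExpansionResult:
    cell_type: str
    per_mouse_minimal: dict[str, float]
    threshold: float
    expanded: pd.DataFrame  # mouse_id, barcode_id, abundance_end
    fractions: pd.DataFrame  # mouse_id, n_expanded, n_tracked, fraction


def expansion_threshold(
    abundance: pd.DataFrame, cell_type: str
) -> tuple[dict[str, float], float]:
    """Per-mouse minimal dominant abundances and their cohort mean.

    Uses pre-divergent abundances of the given cell type.  Mice whose total
    abundance is zero are excluded (with no per-mouse value).
    """
    pre = abundance[
        (abundance["time_point"] == TimePoint.PRE_DIVERGENT.value)
        & (abundance["cell_type"] == cell_type)
    ]
    per_mouse: dict[str, float] = {}
    for mouse, grp in pre.groupby("mouse_id"):
        vals = grp["abundance"].to_numpy(dtype=float)
        if vals.sum() <= 0:
            continue
        per_mouse[mouse] = minimal_dominant_abundance(vals)
    if not per_mouse:
        raise ValueError(f"no mouse has positive {cell_type} abundance at pre-divergent")
    return per_mouse, float(np.mean(list(per_mouse.values())))


def expanded_clones(abundance: pd.DataFrame, cell_type: str, threshold: float) -> ExpansionResult:
    """Expanded clones (end abundance strictly above threshold) and per-mouse fractions."""
    if threshold is None or threshold <= 0:
        raise ValueError("threshold must be positive")
    end = abundance[
        (abundance["time_point"] == TimePoint.END.value)
        & (abundance["cell_type"] == cell_type)
    ]
    expanded = end[end["abundance"] > threshold][["mouse_id", "barcode_id", "abundance"]]
    expanded = expanded.rename(columns={"abundance": "abundance_end"}).reset_index(drop=True)
    frac_rows = []
    for mouse, grp in end.groupby("mouse_id"):
        n_tracked = grp["barcode_id"].nunique()
        n_exp = int((grp["abundance"] > threshold).sum())
        frac_rows.append(
            {
                "mouse_id": mouse,
                "n_expanded": n_exp,
                "n_tracked": n_tracked,
                "fraction": n_exp / n_tracked if n_tracked else 0.0,
            }
        )
    return ExpansionResult(
        cell_type=cell_type,
        per_mouse_minimal={},
        threshold=threshold,
        expanded=expanded,
        fractions=pd.DataFrame(frac_rows, columns=["mouse_id", "n_expanded", "n_tracked", "fraction"]),
    )


def expansion_analysis(abundance: pd.DataFrame, cell_type: str) -> ExpansionResult:
    """Full expansion analysis for one cell type (threshold + expanded sets)."""
    per_mouse, threshold = expansion_threshold(abundance, cell_type)
    result = expanded_clones(abundance, cell_type, threshold)
    result.per_mouse_minimal = per_mouse
    return result


def top_k_abundance(abundance: pd.DataFrame, cell_type: str, k: int = 3) -> pd.DataFrame:
    """The k most abundant clones per mouse at the end time point.

    Ties are broken by barcode identifier (lexicographically smaller wins)
    for determinism; mice with fewer than k clones return all of them with
    ``short=True``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    end = abundance[
        (abundance["time_point"] == TimePoint.END.value)
        & (abundance["cell_type"] == cell_type)
    ]
    rows = []
    for mouse, grp in end.groupby("mouse_id"):
        ordered = grp.sort_values(
            ["abundance", "barcode_id"], ascending=[False, True]
        ).head(k)
        short = len(grp) < k
        for rank, row in enumerate(ordered.itertuples(index=False), start=1):
            rows.append(
                {
                    "mouse_id": mouse,
                    "barcode_id": row.barcode_id,
                    "rank": rank,
                    "abundance_end": row.abundance,
                    "short": short,
                }
            )
    return pd.DataFrame(rows, columns=["mouse_id", "barcode_id", "rank", "abundance_end", "short"])


def classify_fate(presence_m4: bool, presence_m9: bool, presence_end: bool) -> str:
    """Fate label from the clone's blood presence pattern over time."""
    return FATE_PATTERNS.get((bool(presence_m4), bool(presence_m9), bool(presence_end)), "other")


def fate_table(abundance: pd.DataFrame, presence_threshold: float = 0.01) -> pd.DataFrame:
    """Fate labels for every clone with blood data.

    Presence at a time point means blood abundance >= ``presence_threshold``
    (%WBC) in any blood cell type at that time point.
    """
    blood = abundance[abundance["cell_type"].isin(BLOOD_CELL_TYPES)]
    present = (
        blood.assign(present=blood["abundance"] >= presence_threshold)
        .groupby(["mouse_id", "barcode_id", "time_point"])["present"]
        .any()
        .unstack(fill_value=False)
    )
    for tp in (TimePoint.INITIAL.value, TimePoint.PRE_DIVERGENT.value, TimePoint.END.value):
        if tp not in present.columns:
            present[tp] = False
    rows = []
    for (mouse, barcode), row in present.iterrows():
        rows.append(
            {
                "mouse_id": mouse,
                "barcode_id": barcode,
                "label": classify_fate(
                    row[TimePoint.INITIAL.value],
                    row[TimePoint.PRE_DIVERGENT.value],
                    row[TimePoint.END.value],
                ),
            }
        )
    return pd.DataFrame(rows, columns=["mouse_id", "barcode_id", "label"])


def clone_deltas(abundance: pd.DataFrame, cell_type: str) -> pd.DataFrame:
    """Per-clone abundance change (end minus pre-divergent) for one cell type.

    Clones missing at one of the two time points contribute zero abundance
    there (a clone absent at the end lost everything it had).
    """
    sub = abundance[abundance["cell_type"] == cell_type]
    wide = sub.pivot_table(
        index=["mouse_id", "barcode_id"],
        columns="time_point",
        values="abundance",
        fill_value=0.0,
        aggfunc="sum",
    )
    for tp in (TimePoint.PRE_DIVERGENT.value, TimePoint.END.value):
        if tp not in wide.columns:
            wide[tp] = 0.0
    out = wide.reset_index()[["mouse_id", "barcode_id"]]
    out["delta"] = (
        wide[TimePoint.END.value].to_numpy() - wide[TimePoint.PRE_DIVERGENT.value].to_numpy()
    )
    return out


def change_counts(deltas: pd.DataFrame, floor: float = 0.1) -> pd.DataFrame:
    """Counts and aggregate sums of clones with production changes >= floor.

    Per mouse: n_increased (delta >= floor), n_decreased (delta <= -floor),
    aggregate_increase (sum of counted positive deltas, %WBC) and
    aggregate_decrease (sum of counted negative deltas, <= 0).
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    rows = []
    for mouse, grp in deltas.groupby("mouse_id"):
        d = grp["delta"].to_numpy(dtype=float)
        inc = d[d >= floor]
        dec = d[d <= -floor]
        rows.append(
            {
                "mouse_id": mouse,
                "n_increased": int(inc.size),
                "n_decreased": int(dec.size),
                "aggregate_increase": float(inc.sum()),
                "aggregate_decrease": float(dec.sum()),
                "floor": floor,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mouse_id",
            "n_increased",
            "n_decreased",
            "aggregate_increase",
            "aggregate_decrease",
            "floor",
        ],
    )


def differentiation_index(abundance: pd.DataFrame) -> pd.DataFrame:
    """Granulocyte-to-HSC abundance ratio per clone at the end time point.

    Clones with zero or missing HSC abundance are excluded and flagged in
    the ``excluded`` frame attribute of the result (returned as a second
    frame).  Returns (index_frame, excluded_frame).
    """
    end = abundance[abundance["time_point"] == TimePoint.END.value]
    gr = end[end["cell_type"] == CellType.GR.value].set_index(["mouse_id", "barcode_id"])[
        "abundance"
    ]
    hsc = end[end["cell_type"] == CellType.HSC.value].set_index(["mouse_id", "barcode_id"])[
        "abundance"
    ]
    joined = pd.DataFrame({"gr": gr, "hsc": hsc}).fillna({"gr": 0.0})
    ok = joined["hsc"] > 0
    idx = joined[ok].copy()
    idx["index"] = idx["gr"] / idx["hsc"]
    excluded = joined[~ok].reset_index()[["mouse_id", "barcode_id"]]
    return idx.reset_index()[["mouse_id", "barcode_id", "gr", "hsc", "index"]], excluded


def stem_input_export(
    abundance: pd.DataFrame, cell_type: str, min_change: float = 0.01
) -> pd.DataFrame:
    """Clone-by-time-point table for external short-time-series clustering.

    Only clones with values at all four time points (initial, mid,
    pre-divergent, end) are eligible; a clone is retained when its
    abundance at some later time point differs from the initial one by at
    least ``min_change`` %WBC.  Output is one row per clone with one column
    per time point (log-normalization is left to the downstream tool).
    """
    sub = abundance[abundance["cell_type"] == cell_type]
    wide = sub.pivot_table(
        index=["mouse_id", "barcode_id"],
        columns="time_point",
        values="abundance",
        aggfunc="sum",
    )
    needed = [
        TimePoint.INITIAL.value,
        TimePoint.MID.value,
        TimePoint.PRE_DIVERGENT.value,
        TimePoint.END.value,
    ]
    missing_cols = [tp for tp in needed if tp not in wide.columns]
    if missing_cols or wide.empty:
        return pd.DataFrame(columns=["mouse_id", "barcode_id"] + needed)
    complete = wide.dropna(subset=needed)
    initial = complete[TimePoint.INITIAL.value]
    later = complete[needed[1:]]
    keep = (later.sub(initial, axis=0).abs() >= min_change).any(axis=1)
    return complete[keep].reset_index()[["mouse_id", "barcode_id"] + needed]
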