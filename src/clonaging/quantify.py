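"""Clonal abundance quantification.

Barcode read counts are scaled to population abundance with the FACS panel
fractions.  For a blood cell type::

    abundance_b (%WBC) = (celltype % of WBC / 100)
                       x (donor % in the cell type / 100)
                       x (GFP % among donor cells / 100)
                       x (reads_b / total reads) x 100

and for the HSC compartment (bone marrow, no cell-type fraction)::

    abundance_b (% of all HSCs) = (donor % / 100) x (GFP % / 100)
                                x (reads_b / total reads) x 100

Clones are kept for analysis only if their blood abundance exceeds
0.01 %WBC (strict) in at least one (time point, blood cell type); the
filter removes a failing clone from every compartment and time point so
clone identity sets stay consistent downstream.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .tables import BLOOD_CELL_TYPES, CellType, validate_table

log = logging.getLogger(__name__)


def _scaled_fractions(counts) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1:
        raise ValueError("counts must be one-dimensional")
    if (counts < 0).any():
        raise ValueError("read counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ZeroDivisionError("total read count is zero; abundance undefined")
    return counts / total


def _check_pct(name: str, value: float) -> float:
    value = float(value)
    if not 0.0 <= value <= 100.0:
        raise ValueError(f"{name} must be in [0, 100], got {value}")
    return value


def blood_clonal_abundance(
    counts,
    celltype_pct_of_wbc: float,
    donor_pct: float,
    gfp_pct_among_donor: float,
) -> np.ndarray:
    """Per-barcode abundance in %WBC for one (mouse, time point, blood cell type)."""
    frac = _scaled_fractions(counts)
    ct = _check_pct("celltype_pct_of_wbc", celltype_pct_of_wbc)
    d = _check_pct("donor_pct", donor_pct)
    g = _check_pct("gfp_pct_among_donor", gfp_pct_among_donor)
    return (ct / 100.0) * (d / 100.0) * (g / 100.0) * frac * 100.0


def hsc_clonal_abundance(counts, donor_pct: float, gfp_pct_among_donor: float) -> np.ndarray:
    """Per-barcode abundance as % of all HSCs for one (mouse, time point)."""
    frac = _scaled_fractions(counts)
    d = _check_pct("donor_pct", donor_pct)
    g = _check_pct("gfp_pct_among_donor", gfp_pct_among_donor)
    return (d / 100.0) * (g / 100.0) * frac * 100.0


def quantify_abundance(counts: pd.DataFrame, panel: pd.DataFrame) -> pd.DataFrame:
    """Convert a barcode-count table plus FACS panel into a clone-abundance table.

    Groups with zero total reads are dropped with a warning (abundance is
    undefined there, not zero).
    """
    counts = validate_table(counts, "barcode_counts")
    panel = validate_table(panel, "facs_panel")
    panel_idx = panel.set_index(["mouse_id", "time_point", "cell_type"])

    out = []
    for (mouse, tp, ct), grp in counts.groupby(
        ["mouse_id", "time_point", "cell_type"], sort=True
    ):
        try:
            row = panel_idx.loc[(mouse, tp, ct)]
        except KeyError:
            raise KeyError(
                f"FACS panel row missing for (mouse={mouse}, time_point={tp}, cell_type={ct})"
            ) from None
        total = grp["read_count"].sum()
        if total <= 0:
            log.warning(
                "zero total reads for (%s, %s, %s); group dropped", mouse, tp, ct
            )
            continue
        if ct == CellType.HSC.value:
            ab = hsc_clonal_abundance(
                grp["read_count"].to_numpy(), row["donor_pct"], row["gfp_pct_among_donor"]
            )
        else:
            ab = blood_clonal_abundance(
                grp["read_count"].to_numpy(),
                row["celltype_pct_of_wbc"],
                row["donor_pct"],
                row["gfp_pct_among_donor"],
            )
        sub = grp[["mouse_id", "time_point", "cell_type", "barcode_id"]].copy()
        sub["abundance"] = ab
        out.append(sub)
    if not out:
        raise ValueError("no quantifiable groups: every group had zero total reads")
    return pd.concat(out, ignore_index=True)


def filter_tracked_clones(
    abundance: pd.DataFrame,
    threshold: float = 0.01,
    per_celltype: bool = True,
) -> pd.DataFrame:
    """Apply the 0.01 %WBC tracking filter.

    A clone is retained (all its rows, all compartments) iff its blood
    abundance is strictly greater than ``threshold`` at at least one
    (time point, blood cell type).  HSC abundance alone never qualifies a
    clone.  With ``per_celltype=False`` the granulocyte and B-cell
    abundances at each time point are pooled (summed) before comparison.
    """
    abundance = validate_table(abundance, "clone_abundance")
    blood = abundance[abundance["cell_type"].isin(BLOOD_CELL_TYPES)]
    if per_celltype:
        peak = blood.groupby(["mouse_id", "barcode_id"])["abundance"].max()
    else:
        pooled = blood.groupby(["mouse_id", "barcode_id", "time_point"])["abundance"].sum()
        peak = pooled.groupby(["mouse_id", "barcode_id"]).max()
    keep = peak[peak > threshold].index
    n_before = abundance.groupby(["mouse_id", "barcode_id"]).ngroups
    mask = pd.MultiIndex.from_frame(abundance[["mouse_id", "barcode_id"]]).isin(keep)
    result = abundance[mask].reset_index(drop=True)
    log.info(
        "tracking filter (> %.4g %%WBC): %d of %d clones retained",
        threshold,
        len(keep),
        n_before,
    )
    return result
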