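"""Synthetic barcoded-transplant cohorts.

Generates complete cohorts — barcode read counts, FACS panels, mouse
metadata and a ground-truth record — with the statistical structure the
analysis assumes, so every downstream stage can be tested without external
data.

Clone model
-----------
Each clone has a heavy-tailed (log-normal) size and a lineage-balance
angle theta per time point; its granulocyte output is proportional to
sin(theta) and its B-cell output to cos(theta), so bias maps exactly onto
the analysis' arctangent statistic.  Archetypes:

``stable_myeloid`` / ``stable_balanced`` / ``stable_lymphoid``
    keep their bias (small Gaussian jitter) in the respective category.
``aging``
    initially balanced, bias shifts toward myeloid (granulocyte output
    rises, B output held flat).
``anti_aging``
    initially balanced, bias shifts toward lymphoid by *reducing*
    granulocyte output while B output stays flat (the mechanism the
    delayed-aging phenotype points to).
``exhausted``
    present at the initial and pre-divergent time points, absent at the
    end; drawn lymphoid-leaning (lymphoid-biased clones are the ones prone
    to exhaustion).
``activated``
    absent until the end time point.
``expanded``
    an oversized clone (dominant-clone tail of the size distribution).

Cohort model
------------
Two groups of mice (default 9 early-aging + 9 delayed-aging) differ only
in their archetype mix: early mice are aging-clone-enriched so their
end-point B-to-granulocyte (BG) ratio falls below the cohort's initial
minimum; delayed mice are anti-aging-enriched so it does not.  The true
shifting-clone fraction is 30% in both groups.  Sequencing applies
multinomial noise at fixed depth; FACS percents get truncated
multiplicative noise.  With ``facs_noise=0`` the emitted panel satisfies
the conservation identity exactly: per (mouse, time point, cell type) the
ground-truth %WBC abundances sum to
``celltype_pct x donor_pct x gfp_pct / 10^4``.

A per-cell-type rescaling enforcing that identity maps the drawn theta
through a fixed monotone distortion; the ground truth records the implied
(post-rescale) theta and bias, which the pipeline recovers exactly in the
noiseless, exact-count limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .tables import CellType, TimePoint

ARCHETYPES = (
    "stable_myeloid",
    "stable_balanced",
    "stable_lymphoid",
    "aging",
    "anti_aging",
    "exhausted",
    "activated",
    "expanded",
)

SHIFTING_ARCHETYPES = ("aging", "anti_aging")

DEFAULT_MIX_EARLY = {
    "stable_myeloid": 0.14,
    "stable_balanced": 0.28,
    "stable_lymphoid": 0.12,
    "aging": 0.22,
    "anti_aging": 0.08,
    "exhausted": 0.04,
    "activated": 0.05,
    "expanded": 0.07,
}

DEFAULT_MIX_DELAYED = {
    "stable_myeloid": 0.14,
    "stable_balanced": 0.28,
    "stable_lymphoid": 0.12,
    "aging": 0.03,
    "anti_aging": 0.27,
    "exhausted": 0.04,
    "activated": 0.05,
    "expanded": 0.07,
}


@dataclass
class CohortConfig:
    """Generator parameters; defaults encode the emulated study conditions."""

    n_mice_early: int = 9
    n_mice_delayed: int = 9
    n_clones_per_mouse: int = 100
    archetype_mix_early: dict = field(default_factory=lambda: dict(DEFAULT_MIX_EARLY))
    archetype_mix_delayed: dict = field(default_factory=lambda: dict(DEFAULT_MIX_DELAYED))
    sequencing_depth: int = 50_000
    facs_noise: float = 0.02          # relative sd of FACS percents, truncated to [0, 100]
    stable_bias_jitter: float = 0.06  # sd of stable clones' bias drift
    shift_magnitude: tuple[float, float] = (0.4, 0.9)  # |delta bias| of shifting clones
    clone_size_sigma: float = 1.0     # log-normal spread of clone sizes
    expanded_size_factor: float = 4.0
    gr_pop_pre: float = 20.0          # population Gr % of WBC at pre-divergent
    b_pop_pre: float = 45.0           # population B % of WBC at pre-divergent
    donor_pct: float = 85.0
    gfp_pct: float = 75.0
    include_mid: bool = True
    exact_counts: bool = False        # analytic (infinite-depth) counts instead of multinomial
    aging_b_loss: float = 0.3         # early mice: B loss coupled to their Gr gain
    delayed_drift: float = 0.1        # delayed mice: common drift of both lineages
    seed: int = 0

    def __post_init__(self) -> None:
        for mix in (self.archetype_mix_early, self.archetype_mix_delayed):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"archetype proportions sum to {total}, not 1")
            unknown = set(mix) - set(ARCHETYPES)
            if unknown:
                raise ValueError(f"unknown archetypes: {sorted(unknown)}")
        if self.sequencing_depth <= 0:
            raise ValueError("sequencing_depth must be positive")


@dataclass
class CohortGroundTruth:
    """Generator-side truth for recovery tests."""

    clones: pd.DataFrame       # per clone: archetype, size, implied bias/theta, shifting
    abundances: pd.DataFrame   # per (mouse, tp, cell type, barcode): true abundance
    mice: pd.DataFrame         # per mouse: mix group, rule-based group truth, BG ratios
    panel_true: pd.DataFrame   # noiseless FACS panel
    threshold_true: float      # cohort minimum initial BG ratio (noiseless)
    config: dict


def largest_remainder_counts(proportions: dict[str, float], n: int) -> dict[str, int]:
    """Integer archetype counts summing to n (largest-remainder apportionment).

    Remainder ties are broken by archetype name for determinism.
    """
    raw = {k: proportions.get(k, 0.0) * n for k in ARCHETYPES}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    order = sorted(raw, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in order[:short]:
        counts[k] += 1
    return {k: v for k, v in counts.items() if v > 0}


def simulate_reads(true_proportions, depth: int, rng: np.random.Generator,
                   exact: bool = False) -> np.ndarray:
    """Multinomial read counts over barcodes (plus an untracked remainder bin).

    ``true_proportions`` are non-negative and sum to at most 1; the
    remainder is drawn into an untracked bin that is not returned.  With
    ``exact=True`` the analytic expectation ``proportions * depth`` is
    returned instead (the infinite-depth limit used by recovery tests).
    """
    p = np.asarray(true_proportions, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be non-negative")
    total = p.sum()
    if total > 1 + 1e-9:
        raise ValueError("proportions sum above 1")
    if depth <= 0:
        raise ValueError("depth must be positive")
    if exact:
        return p * depth
    full = np.append(p, max(1.0 - total, 0.0))
    full /= full.sum()
    draw = rng.multinomial(depth, full)
    return draw[:-1]


_BIAS_CLIP = 0.98


def _bias_to_theta(bias: np.ndarray) -> np.ndarray:
    return (np.asarray(bias) + 1.0) * math.pi / 4.0


def _draw_clones(archetype: str, n: int, cfg: CohortConfig,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """(bias_pre, bias_end) draws for n clones of one archetype."""
    lo, hi = cfg.shift_magnitude
    jit = cfg.stable_bias_jitter
    if archetype == "stable_myeloid":
        pre = rng.uniform(0.55, 0.90, n)
        end = pre + rng.normal(0.0, jit, n)
    elif archetype == "stable_balanced":
        pre = rng.uniform(-0.30, 0.30, n)
        end = pre + rng.normal(0.0, jit, n)
    elif archetype == "stable_lymphoid":
        pre = rng.uniform(-0.90, -0.55, n)
        end = pre + rng.normal(0.0, jit, n)
    elif archetype == "aging":
        pre = rng.uniform(-0.25, 0.10, n)
        end = pre + rng.uniform(lo, hi, n)
    elif archetype == "anti_aging":
        pre = rng.uniform(0.05, 0.35, n)
        end = pre - rng.uniform(lo, hi, n)
    elif archetype == "exhausted":
        pre = rng.uniform(-0.80, -0.20, n)
        end = pre.copy()  # never observed: absent at the end time point
    elif archetype == "activated":
        pre = rng.uniform(-0.30, 0.30, n)  # applies at the end time point only
        end = pre.copy()
    elif archetype == "expanded":
        pre = rng.uniform(0.00, 0.60, n)
        end = pre + rng.normal(0.0, jit, n)
    else:  # pragma: no cover
        raise ValueError(f"unknown archetype {archetype!r}")
    return np.clip(pre, -_BIAS_CLIP, _BIAS_CLIP), np.clip(end, -_BIAS_CLIP, _BIAS_CLIP)


def _noisy_pct(value: float, rel_sd: float, rng: np.random.Generator) -> float:
    if rel_sd <= 0:
        return float(value)
    return float(np.clip(value * (1.0 + rng.normal(0.0, rel_sd)), 0.0, 100.0))


def simulate_cohort(
    config: CohortConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, CohortGroundTruth]:
    """Generate (barcode_counts, facs_panel, mice, ground_truth) tables.

    Fully deterministic given the seed (``seed`` overrides ``config.seed``).
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    timepoints = [TimePoint.INITIAL.value]
    if cfg.include_mid:
        timepoints.append(TimePoint.MID.value)
    timepoints += [TimePoint.PRE_DIVERGENT.value, TimePoint.END.value]
    dg = (cfg.donor_pct / 100.0) * (cfg.gfp_pct / 100.0)

    count_rows, panel_rows, mouse_rows = [], [], []
    clone_rows, truth_ab_rows, panel_true_rows = [], [], []

    groups = [("early", f"E{i + 1:02d}", cfg.archetype_mix_early)
              for i in range(cfg.n_mice_early)]
    groups += [("delayed", f"D{i + 1:02d}", cfg.archetype_mix_delayed)
               for i in range(cfg.n_mice_delayed)]

    for mix_group, mouse_id, mix in groups:
        n = cfg.n_clones_per_mouse
        counts_by_arch = largest_remainder_counts(mix, n)
        archetypes, bias_pre, bias_end = [], [], []
        for arch in ARCHETYPES:
            k = counts_by_arch.get(arch, 0)
            if k == 0:
                continue
            pre, end = _draw_clones(arch, k, cfg, rng)
            archetypes += [arch] * k
            bias_pre.append(pre)
            bias_end.append(end)
        archetypes = np.array(archetypes)
        bias_pre = np.concatenate(bias_pre)
        bias_end = np.concatenate(bias_end)

        size = rng.lognormal(mean=0.0, sigma=cfg.clone_size_sigma, size=n)
        size[archetypes == "expanded"] *= cfg.expanded_size_factor

        theta_pre = _bias_to_theta(bias_pre)
        theta_end = _bias_to_theta(bias_end)
        g_pre = size * np.sin(theta_pre)
        c_pre = size * np.cos(theta_pre)
        # B output held flat across the shift; Gr output follows the new angle
        c_end = c_pre.copy()
        g_end = c_pre * np.tan(theta_end)

        absent_pre = archetypes == "activated"       # absent at initial/mid/pre
        absent_end = archetypes == "exhausted"       # absent at end
        g_pre = np.where(absent_pre, 0.0, g_pre)
        c_pre = np.where(absent_pre, 0.0, c_pre)
        g_end_act = size * np.sin(theta_end)         # activated appear fresh at end
        c_end_act = size * np.cos(theta_end)
        g_end = np.where(absent_pre, g_end_act, g_end)
        c_end = np.where(absent_pre, c_end_act, c_end)
        g_end = np.where(absent_end, 0.0, g_end)
        c_end = np.where(absent_end, 0.0, c_end)

        # group-level modulation: in early mice the B-cell loss scales with the
        # mouse's granulocyte gain (their population changes anticorrelate);
        # delayed mice drift in both lineages together (ratio-neutral)
        if mix_group == "early" and cfg.aging_b_loss > 0:
            gr_gain = g_end.sum() / g_pre.sum() - 1.0
            c_end = c_end * max(1.0 - cfg.aging_b_loss * gr_gain, 0.5)
        elif mix_group == "delayed" and cfg.delayed_drift > 0:
            drift = 1.0 + cfg.delayed_drift * (rng.uniform() - 0.5)
            g_end = g_end * drift
            c_end = c_end * drift

        # rescale each lineage so pre-divergent sums hit the conservation target
        alpha = dg / g_pre.sum()
        beta = dg / c_pre.sum()
        outputs = {  # true %WBC abundances per time point and cell type
            tp: {
                CellType.GR.value: alpha * (g_end if tp == TimePoint.END.value else g_pre)
                * cfg.gr_pop_pre,
                CellType.B.value: beta * (c_end if tp == TimePoint.END.value else c_pre)
                * cfg.b_pop_pre,
            }
            for tp in timepoints
        }

        # implied (post-rescale) lineage balance: what a noiseless pipeline measures
        def implied(g_arr, c_arr):
            gn, cn = alpha * g_arr, beta * c_arr
            ok = (gn > 0) | (cn > 0)
            th = np.where(ok, np.arctan2(gn, cn), np.nan)
            return th, (4.0 / math.pi) * th - 1.0

        theta_pre_true, bias_pre_true = implied(g_pre, c_pre)
        theta_end_true, bias_end_true = implied(g_end, c_end)

        barcodes = np.array([f"{mouse_id}_bc{i + 1:04d}" for i in range(n)])
        hsc = np.where(absent_end, 0.0, size)
        hsc_true = hsc / hsc.sum() * dg * 100.0

        end_month = int(rng.choice([15, 12], p=(0.6, 0.4) if mix_group == "early" else (0.9, 0.1)))

        for i in range(n):
            clone_rows.append(
                {
                    "mouse_id": mouse_id,
                    "barcode_id": barcodes[i],
                    "archetype": archetypes[i],
                    "size": size[i],
                    "theta_pre": theta_pre_true[i],
                    "theta_end": theta_end_true[i],
                    "bias_pre": bias_pre_true[i],
                    "bias_end": bias_end_true[i],
                    "delta_bias": bias_end_true[i] - bias_pre_true[i],
                    "shifting": archetypes[i] in SHIFTING_ARCHETYPES,
                }
            )

        for tp in timepoints:
            for ct in (CellType.GR.value, CellType.B.value):
                ab = outputs[tp][ct]
                total = ab.sum()
                celltype_true = total / dg
                panel_true_rows.append(
                    {
                        "mouse_id": mouse_id,
                        "time_point": tp,
                        "cell_type": ct,
                        "celltype_pct_of_wbc": celltype_true,
                        "donor_pct": cfg.donor_pct,
                        "gfp_pct_among_donor": cfg.gfp_pct,
                    }
                )
                panel_rows.append(
                    {
                        "mouse_id": mouse_id,
                        "time_point": tp,
                        "cell_type": ct,
                        "celltype_pct_of_wbc": _noisy_pct(celltype_true, cfg.facs_noise, rng),
                        "donor_pct": _noisy_pct(cfg.donor_pct, cfg.facs_noise, rng),
                        "gfp_pct_among_donor": _noisy_pct(cfg.gfp_pct, cfg.facs_noise, rng),
                    }
                )
                reads = simulate_reads(
                    ab / total, cfg.sequencing_depth, rng, exact=cfg.exact_counts
                )
                present = ab > 0
                for i in np.flatnonzero(present | (reads > 0)):
                    count_rows.append(
                        {
                            "mouse_id": mouse_id,
                            "time_point": tp,
                            "cell_type": ct,
                            "barcode_id": barcodes[i],
                            "read_count": reads[i],
                        }
                    )
                    truth_ab_rows.append(
                        {
                            "mouse_id": mouse_id,
                            "time_point": tp,
                            "cell_type": ct,
                            "barcode_id": barcodes[i],
                            "true_abundance": ab[i],
                        }
                    )

        # HSC compartment: bone marrow collected at the end time point only
        tp = TimePoint.END.value
        for holder in (panel_true_rows, panel_rows):
            noisy = holder is panel_rows
            holder.append(
                {
                    "mouse_id": mouse_id,
                    "time_point": tp,
                    "cell_type": CellType.HSC.value,
                    "celltype_pct_of_wbc": 100.0,
                    "donor_pct": _noisy_pct(cfg.donor_pct, cfg.facs_noise if noisy else 0, rng),
                    "gfp_pct_among_donor": _noisy_pct(cfg.gfp_pct, cfg.facs_noise if noisy else 0, rng),
                }
            )
        hsc_reads = simulate_reads(
            hsc / hsc.sum(), cfg.sequencing_depth, rng, exact=cfg.exact_counts
        )
        for i in np.flatnonzero((hsc > 0) | (hsc_reads > 0)):
            count_rows.append(
                {
                    "mouse_id": mouse_id,
                    "time_point": tp,
                    "cell_type": CellType.HSC.value,
                    "barcode_id": barcodes[i],
                    "read_count": hsc_reads[i],
                }
            )
            truth_ab_rows.append(
                {
                    "mouse_id": mouse_id,
                    "time_point": tp,
                    "cell_type": CellType.HSC.value,
                    "barcode_id": barcodes[i],
                    "true_abundance": hsc_true[i],
                }
            )

        bg_initial = (
            outputs[TimePoint.INITIAL.value][CellType.B.value].sum()
            / outputs[TimePoint.INITIAL.value][CellType.GR.value].sum()
        )
        bg_end = (
            outputs[TimePoint.END.value][CellType.B.value].sum()
            / outputs[TimePoint.END.value][CellType.GR.value].sum()
        )
        mouse_rows.append(
            {
                "mouse_id": mouse_id,
                "mix_group": mix_group,
                "end_month": end_month,
                "bg_initial_true": bg_initial,
                "bg_end_true": bg_end,
            }
        )

    mice_truth = pd.DataFrame(mouse_rows)
    threshold_true = float(mice_truth["bg_initial_true"].min())
    mice_truth["group_truth"] = np.where(
        mice_truth["bg_end_true"] < threshold_true, "early", "delayed"
    )

    counts = pd.DataFrame(count_rows)
    panel = pd.DataFrame(panel_rows)
    mice = mice_truth[["mouse_id", "group_truth", "end_month"]].copy()
    truth = CohortGroundTruth(
        clones=pd.DataFrame(clone_rows),
        abundances=pd.DataFrame(truth_ab_rows),
        mice=mice_truth,
        panel_true=pd.DataFrame(panel_true_rows),
        threshold_true=threshold_true,
        config=asdict(cfg),
    )
    return counts, panel, mice, truth
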