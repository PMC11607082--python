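"""Lineage stable vs lineage shifting clones.

The absolute lineage-bias shifts of all clones (pooled across mice) form a
distribution dominated by a peak near zero — clones that kept their bias —
plus a heavier tail of genuinely shifting clones.  The classifier:

1. estimates a Gaussian kernel density ``y0`` of the absolute shifts
   (reflected about zero so no probability mass leaks to negative shifts),
2. fits a Gaussian around the highest peak of ``y0`` — the lineage-stable
   component ``y_unchanged`` — using only the window where the density
   decreases monotonically away from the peak,
3. takes ``y_changed = max(y0 - y_unchanged, 0)`` and sets the cutoff at
   the first grid point beyond the peak where ``y_changed`` reaches
   ``y_unchanged``.

Clones with ``|delta_bias| < cutoff`` are lineage stable; shifts at or
beyond the cutoff toward the myeloid lineage (positive delta) mark "aging"
clones and toward the lymphoid lineage (negative delta) "anti-aging"
clones.  If the fitted Gaussian never intersects the residual density the
cutoff falls back to ``mu + 3*sigma`` and the result is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import KdeSettings
from .tables import TimePoint


@dataclass(frozen=True)
class GaussianFit:
    mu: float
    sigma: float
    amplitude: float

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        return self.amplitude * np.exp(-((x - self.mu) ** 2) / (2.0 * self.sigma**2))


def estimate_shift_density(
    abs_shifts, settings: KdeSettings | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Gaussian KDE of absolute bias shifts on a uniform grid.

    The kernel density is reflected about zero (boundary correction), so it
    integrates to one over [0, inf).  Returns (grid, y0, bandwidth); the
    grid spans [0, max shift + 3 bandwidths].
    """
    settings = settings or KdeSettings()
    values = np.asarray(abs_shifts, dtype=float)
    if values.ndim != 1:
        raise ValueError("abs_shifts must be one-dimensional")
    if (values < 0).any():
        raise ValueError("abs_shifts must be absolute (non-negative) values")
    if values.size < settings.min_values:
        raise ValueError(
            f"need at least {settings.min_values} shift values, got {values.size}"
        )
    if np.ptp(values) == 0:
        raise ValueError("all shift values identical; kernel bandwidth degenerate")
    kde = stats.gaussian_kde(values, bw_method=settings.bw_method)
    bandwidth = float(np.sqrt(kde.covariance[0, 0]))
    grid = np.linspace(0.0, values.max() + 3.0 * bandwidth, settings.grid_size)
    y0 = kde(grid) + kde(-grid)  # reflect about zero
    return grid, y0, bandwidth


def _peak_window(grid: np.ndarray, y0: np.ndarray) -> slice:
    """Indices around the highest peak where y0 is non-increasing outward."""
    p = int(np.argmax(y0))
    lo = p
    while lo > 0 and y0[lo - 1] <= y0[lo]:
        lo -= 1
    hi = p
    while hi < len(y0) - 1 and y0[hi + 1] <= y0[hi]:
        hi += 1
    return slice(lo, hi + 1)


def fit_stable_gaussian(grid: np.ndarray, y0: np.ndarray) -> GaussianFit:
    """Least-squares Gaussian fitted around the highest peak of the density."""
    grid = np.asarray(grid, dtype=float)
    y0 = np.asarray(y0, dtype=float)
    win = _peak_window(grid, y0)
    x, y = grid[win], y0[win]
    if x.size < 4:
        raise RuntimeError(
            f"peak window too narrow for a Gaussian fit ({x.size} points)"
        )
    p = int(np.argmax(y0))
    amp0 = float(y0[p])
    mu0 = float(grid[p])
    # initial sigma from the half-maximum width inside the window
    above = x[y >= amp0 / 2.0]
    sigma0 = max((above.max() - above.min()) / 2.355, (grid[1] - grid[0]))

    def gauss(xv, amplitude, mu, sigma):
        return amplitude * np.exp(-((xv - mu) ** 2) / (2.0 * sigma**2))

    try:
        popt, _ = optimize.curve_fit(
            gauss,
            x,
            y,
            p0=(amp0, mu0, sigma0),
            bounds=((0.0, -np.inf, 1e-12), (np.inf, np.inf, np.inf)),
            maxfev=10_000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"stable-Gaussian fit did not converge (window {x[0]:.4g}..{x[-1]:.4g}, "
            f"{x.size} points): {exc}"
        ) from exc
    amplitude, mu, sigma = (float(v) for v in popt)
    return GaussianFit(mu=mu, sigma=abs(sigma), amplitude=amplitude)


def shift_cutoff(
    grid: np.ndarray, y0: np.ndarray, gaussian: GaussianFit
) -> tuple[float, bool]:
    """First intersection of the residual and stable densities beyond the peak.

    Returns (cutoff, fallback_used).  The cutoff is the smallest grid value
    beyond the density peak where ``y_changed >= y_unchanged``; when no such
    point exists the fallback ``mu + 3*sigma`` is returned flagged.
    """
    grid = np.asarray(grid, dtype=float)
    y0 = np.asarray(y0, dtype=float)
    y_unchanged = gaussian(grid)
    y_changed = np.clip(y0 - y_unchanged, 0.0, None)
    p = int(np.argmax(y0))
    beyond = np.arange(len(grid)) > p
    crossing = beyond & (y_changed >= y_unchanged)
    if crossing.any():
        return float(grid[np.argmax(crossing)]), False
    return float(gaussian.mu + 3.0 * gaussian.sigma), True


def classify_shifts(shifts: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Label included clones as stable / aging / anti_aging at a given cutoff.

    ``shifts`` is a shift table (mouse_id, barcode_id, delta_bias, included).
    A shift at exactly the cutoff counts as shifting.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    sub = shifts.loc[shifts["included"]].copy() if "included" in shifts else shifts.copy()
    delta = sub["delta_bias"].to_numpy(dtype=float)
    label = np.where(
        delta >= cutoff, "aging", np.where(delta <= -cutoff, "anti_aging", "stable")
    )
    sub = sub.assign(label=label)
    cols = ["mouse_id", "barcode_id", "delta_bias", "label"]
    extra = [c for c in ("category_pre",) if c in sub.columns]
    return sub[cols + extra].reset_index(drop=True)


def shift_fractions(labels: pd.DataFrame, mice: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-mouse fractions of stable / anti_aging / aging clones.

    When a mouse table with a ``group`` (or ``group_truth``) column is
    supplied, the group is attached for group-level comparison.
    """
    counts = (
        labels.groupby(["mouse_id", "label"]).size().unstack(fill_value=0)
        .reindex(columns=["stable", "anti_aging", "aging"], fill_value=0)
    )
    frac = counts.div(counts.sum(axis=1), axis=0)
    frac.columns = [f"frac_{c}" for c in frac.columns]
    frac = frac.reset_index()
    if mice is not None:
        col = "group" if "group" in mice.columns else "group_truth"
        frac = frac.merge(mice[["mouse_id", col]].rename(columns={col: "group"}),
                          on="mouse_id", how="left")
    return frac


def category_transition_table(labels: pd.DataFrame) -> pd.DataFrame:
    """Fraction of clones per pre-divergent bias category that shifted vs stayed.

    Requires a ``category_pre`` column on the labels.  Fractions are
    computed per mouse and the median across mice is reported per category.
    """
    if "category_pre" not in labels.columns:
        raise ValueError("labels must carry category_pre for the transition table")
    df = labels.assign(shifted=labels["label"] != "stable")
    per_mouse = (
        df.groupby(["mouse_id", "category_pre"])["shifted"].mean().rename("frac_shifted")
    )
    med = per_mouse.groupby("category_pre").median().rename("median_frac_shifted")
    out = med.reset_index()
    out["median_frac_stable"] = 1.0 - out["median_frac_shifted"]
    return out


def label_contributions(labels: pd.DataFrame, abundance: pd.DataFrame) -> pd.DataFrame:
    """%WBC contributed by each shift-label class to Gr and B at the end time point."""
    end = abundance[abundance["time_point"] == TimePoint.END.value]
    merged = end.merge(labels[["mouse_id", "barcode_id", "label"]],
                       on=["mouse_id", "barcode_id"], how="inner")
    out = (
        merged.groupby(["mouse_id", "cell_type", "label"])["abundance"].sum()
        .rename("abundance_pct_wbc")
        .reset_index()
    )
    totals = out.groupby(["mouse_id", "cell_type"])["abundance_pct_wbc"].transform("sum")
    out["fraction_of_labelled"] = np.where(totals > 0, out["abundance_pct_wbc"] / totals, 0.0)
    return out


class LineageShiftModel:
    """Density model separating lineage-stable from lineage-shifting clones.

    Parameters
    ----------
    shifts : DataFrame or array-like
        Either a shift table with ``delta_bias`` (and optional ``included``
        flag) or a plain array of signed bias shifts, pooled over all
        clones and mice.
    kde_settings : KdeSettings, optional
        Bandwidth rule (Scott by default), grid size and the minimum number
        of shift values required.
    """

    def __init__(self, shifts, kde_settings: KdeSettings | None = None):
        if isinstance(shifts, pd.DataFrame):
            sub = shifts.loc[shifts["included"]] if "included" in shifts else shifts
            self.shifts = sub.reset_index(drop=True)
            self.delta = self.shifts["delta_bias"].to_numpy(dtype=float)
        else:
            self.delta = np.asarray(shifts, dtype=float)
            self.shifts = pd.DataFrame({
                "mouse_id": "pooled",
                "barcode_id": np.arange(self.delta.size),
                "delta_bias": self.delta,
            })
        self.kde_settings = kde_settings or KdeSettings()

    def fit(self) -> "LineageShiftResults":
        grid, y0, bandwidth = estimate_shift_density(np.abs(self.delta), self.kde_settings)
        gaussian = fit_stable_gaussian(grid, y0)
        cutoff, fallback = shift_cutoff(grid, y0, gaussian)
        return LineageShiftResults(
            model=self,
            grid=grid,
            y0=y0,
            bandwidth=bandwidth,
            gaussian=gaussian,
            cutoff=cutoff,
            fallback_used=fallback,
        )


@dataclass
class LineageShiftResults:
    """Fitted shift-density model: stable Gaussian, cutoff, clone labels."""

    model: LineageShiftModel
    grid: np.ndarray
    y0: np.ndarray
    bandwidth: float
    gaussian: GaussianFit
    cutoff: float
    fallback_used: bool
    y_unchanged: np.ndarray = field(init=False)
    y_changed: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.y_unchanged = self.gaussian(self.grid)
        self.y_changed = np.clip(self.y0 - self.y_unchanged, 0.0, None)

    def classify(self, shifts: pd.DataFrame | None = None) -> pd.DataFrame:
        """Label clones using the fitted cutoff (defaults to the fitted data)."""
        table = shifts if shifts is not None else self.model.shifts
        return classify_shifts(table, self.cutoff)

    def params_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "fallback_used": self.fallback_used,
            "bandwidth": self.bandwidth,
            "gaussian_mu": self.gaussian.mu,
            "gaussian_sigma": self.gaussian.sigma,
            "gaussian_amplitude": self.gaussian.amplitude,
            "n_shifts": int(self.model.delta.size),
        }

    def summary(self) -> str:
        labels = self.classify()
        frac = labels["label"].value_counts(normalize=True)
        lines = [
            "Lineage shift classification",
            "============================",
            f"clones (included shifts): {self.model.delta.size}",
            f"KDE bandwidth (Scott):    {self.bandwidth:.5f}",
            f"stable Gaussian:          mu={self.gaussian.mu:.5f} "
            f"sigma={self.gaussian.sigma:.5f} amplitude={self.gaussian.amplitude:.4f}",
            f"cutoff |delta bias|:      {self.cutoff:.5f}"
            + ("  [fallback mu+3sigma]" if self.fallback_used else ""),
            f"fraction stable:          {frac.get('stable', 0.0):.4f}",
            f"fraction aging:           {frac.get('aging', 0.0):.4f}",
            f"fraction anti-aging:      {frac.get('anti_aging', 0.0):.4f}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plain density plot: y0, stable Gaussian, residual, cutoff line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.fill_between(self.grid, self.y0, color="0.85", label="all clones (y0)")
        ax.plot(self.grid, self.y_unchanged, color="tab:blue", label="lineage stable fit")
        ax.plot(self.grid, self.y_changed, color="tab:pink", label="lineage shifting")
        ax.axvline(self.cutoff, color="k", linestyle="--", label=f"cutoff {self.cutoff:.3f}")
        ax.set_xlabel("|lineage bias shift|")
        ax.set_ylabel("density")
        ax.legend()
        return ax
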