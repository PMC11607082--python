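import numpy as np
import pandas as pd
import pytest

from clonaging.config import KdeSettings
from clonaging.shifts import (
    GaussianFit,
    LineageShiftModel,
    classify_shifts,
    estimate_shift_density,
    fit_stable_gaussian,
    shift_cutoff,
)


def brute_force_cutoff(grid, y0, gaussian):
    """Independent first-crossing scan on the same grid."""
    y_un = gaussian(grid)
    y_ch = np.maximum(y0 - y_un, 0.0)
    peak = int(np.argmax(y0))
    for i in range(peak + 1, len(grid)):
        if y_ch[i] >= y_un[i]:
            return float(grid[i]), False
    return float(gaussian.mu + 3 * gaussian.sigma), True


def half_normal_mixture(n=2000, stable_frac=0.7, scale=0.1, lo=0.4, hi=0.9, seed=0):
    """Signed shifts: stable Gaussian core + uniform-magnitude shifting tail."""
    rng = np.random.default_rng(seed)
    n_stable = int(round(n * stable_frac))
    stable = rng.normal(0.0, scale, n_stable)
    n_shift = n - n_stable
    shifting = rng.uniform(lo, hi, n_shift) * rng.choice([-1, 1], n_shift)
    delta = np.concatenate([stable, shifting])
    truth = np.array(["stable"] * n_stable + ["shifting"] * n_shift)
    return delta, truth


class TestDensity:
    def test_half_normal_peak_at_zero(self):
        rng = np.random.default_rng(3)
        values = np.abs(rng.normal(0.0, 0.1, 10_000))
        grid, y0, _ = estimate_shift_density(values)
        step = grid[1] - grid[0]
        assert grid[np.argmax(y0)] <= step  # mode within one grid step of 0

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(4)
        values = np.abs(rng.normal(0.0, 0.2, 5_000))
        grid, y0, _ = estimate_shift_density(values)
        assert np.trapezoid(y0, grid) == pytest.approx(1.0, abs=0.01)
        assert (y0 >= 0).all()

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            estimate_shift_density(np.abs(np.random.default_rng(0).normal(size=10)))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            estimate_shift_density(np.array([]))

    def test_identical_values_degenerate(self):
        with pytest.raises(ValueError, match="identical"):
            estimate_shift_density(np.full(100, 0.3))


class TestStableGaussianFit:
    def test_exact_gaussian_curve_recovered(self):
        grid = np.linspace(0, 1, 500)
        true = GaussianFit(mu=0.2, sigma=0.08, amplitude=3.0)
        fit = fit_stable_gaussian(grid, true(grid))
        assert fit.mu == pytest.approx(0.2, abs=1e-6)
        assert fit.sigma == pytest.approx(0.08, abs=1e-6)
        assert fit.amplitude == pytest.approx(3.0, abs=1e-6)

    def test_half_normal_scale_recovered_within_ten_percent(self):
        rng = np.random.default_rng(5)
        values = np.abs(rng.normal(0.0, 0.1, 20_000))
        grid, y0, _ = estimate_shift_density(values)
        fit = fit_stable_gaussian(grid, y0)
        assert fit.sigma == pytest.approx(0.1, rel=0.10)

    def test_bimodal_density_fits_taller_mode(self):
        grid = np.linspace(0, 1, 1000)
        tall = GaussianFit(mu=0.15, sigma=0.05, amplitude=4.0)
        short = GaussianFit(mu=0.7, sigma=0.05, amplitude=1.5)
        fit = fit_stable_gaussian(grid, tall(grid) + short(grid))
        assert fit.mu == pytest.approx(0.15, abs=0.02)


class TestCutoff:
    def test_matches_brute_force_scan_exactly(self):
        delta, _ = half_normal_mixture(seed=6)
        grid, y0, _ = estimate_shift_density(np.abs(delta))
        fit = fit_stable_gaussian(grid, y0)
        got, flag = shift_cutoff(grid, y0, fit)
        expected, eflag = brute_force_cutoff(grid, y0, fit)
        assert got == expected
        assert flag == eflag
        assert 0.15 < got < 0.40

    def test_pure_gaussian_density_triggers_fallback(self):
        grid = np.linspace(0, 1, 400)
        g = GaussianFit(mu=0.1, sigma=0.05, amplitude=4.0)
        cutoff, flag = shift_cutoff(grid, g(grid), g)
        assert flag
        assert cutoff == pytest.approx(0.1 + 3 * 0.05)

    def test_grid_refinement_moves_cutoff_less_than_coarse_step(self):
        delta, _ = half_normal_mixture(seed=7)
        coarse = KdeSettings(grid_size=256)
        fine = KdeSettings(grid_size=2560)
        res_c = LineageShiftModel(delta, coarse).fit()
        res_f = LineageShiftModel(delta, fine).fit()
        coarse_step = res_c.grid[1] - res_c.grid[0]
        assert abs(res_c.cutoff - res_f.cutoff) < coarse_step


class TestClassification:
    def test_labels_follow_cutoff_and_sign(self):
        shifts = pd.DataFrame(
            {
                "mouse_id": "m",
                "barcode_id": ["a", "b", "c", "d"],
                "delta_bias": [0.1, 0.3, -0.3, -0.1],
                "included": True,
            }
        )
        labels = classify_shifts(shifts, cutoff=0.3)
        assert list(labels["label"]) == ["stable", "aging", "anti_aging", "stable"]

    def test_boundary_shift_counts_as_shifting(self):
        shifts = pd.DataFrame(
            {"mouse_id": "m", "barcode_id": ["a"], "delta_bias": [0.25], "included": True}
        )
        assert classify_shifts(shifts, 0.25)["label"].iloc[0] == "aging"

    def test_inflating_shifts_cannot_reduce_shifting_count(self):
        delta, _ = half_normal_mixture(seed=8, n=500)
        cutoff = 0.25
        base = pd.DataFrame(
            {"mouse_id": "m", "barcode_id": range(500), "delta_bias": delta}
        )
        n1 = (classify_shifts(base, cutoff)["label"] != "stable").sum()
        inflated = base.assign(delta_bias=base["delta_bias"] * 1.5)
        n2 = (classify_shifts(inflated, cutoff)["label"] != "stable").sum()
        assert n2 >= n1

    def test_mixture_recovery(self):
        """Seeded 70/30 mixture: fraction within 5 points, directions >= 90%."""
        delta, truth = half_normal_mixture(n=2000, seed=9)
        results = LineageShiftModel(delta).fit()
        labels = results.classify()
        measured = (labels["label"] != "stable").mean()
        assert abs(measured - 0.30) <= 0.05
        big = np.abs(delta) >= 0.2
        expected = np.where(delta >= 0, "aging", "anti_aging")
        correct = (labels["label"].to_numpy() == expected) & big
        assert correct.sum() / big.sum() >= 0.90

    def test_stable_fraction_unbiased_over_seeds(self):
        errors = []
        for seed in range(20):
            delta, _ = half_normal_mixture(n=1000, seed=100 + seed)
            res = LineageShiftModel(delta).fit()
            frac_stable = (res.classify()["label"] == "stable").mean()
            errors.append(frac_stable - 0.70)
        assert abs(np.mean(errors)) <= 0.03


def test_summary_reports_model_parameters():
    delta, _ = half_normal_mixture(seed=10)
    res = LineageShiftModel(delta).fit()
    text = res.summary()
    assert "cutoff" in text and "sigma" in text
    params = res.params_dict()
    assert params["cutoff"] > 0 and not params["fallback_used"]
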