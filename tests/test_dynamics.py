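import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonaging.dynamics import (
    change_counts,
    classify_fate,
    clone_deltas,
    differentiation_index,
    expanded_clones,
    expansion_analysis,
    expansion_threshold,
    fate_table,
    minimal_dominant_abundance,
    stem_input_export,
    top_k_abundance,
)


def brute_force_minimal_dominant(values):
    """Try every top-k prefix of the descending ranking; smallest k covering half."""
    ordered = sorted(values, reverse=True)
    half = sum(ordered) / 2.0
    for k in range(1, len(ordered) + 1):
        if sum(ordered[:k]) >= half:
            return ordered[k - 1]
    raise AssertionError("unreachable")


class TestExpansionThreshold:
    def test_worked_example(self):
        # {40, 30, 20, 10}: top prefix {40, 30} reaches 70 >= 50 -> value 30
        assert minimal_dominant_abundance([40, 30, 20, 10]) == 30

    def test_cohort_threshold_is_mean_of_per_mouse_values(self):
        ab = pd.DataFrame(
            {
                "mouse_id": ["m1"] * 4 + ["m2"] * 2,
                "time_point": "pre_divergent",
                "cell_type": "GR",
                "barcode_id": [f"b{i}" for i in range(6)],
                "abundance": [40.0, 30.0, 20.0, 10.0, 25.0, 20.0],
            }
        )
        per_mouse, threshold = expansion_threshold(ab, "GR")
        assert per_mouse == {"m1": 30.0, "m2": 25.0}
        assert threshold == pytest.approx(27.5)

    def test_single_clone_mouse(self):
        assert minimal_dominant_abundance([7.5]) == 7.5

    def test_matches_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = rng.integers(1, 13)
            values = rng.uniform(0.01, 50, size=n)
            assert minimal_dominant_abundance(values) == brute_force_minimal_dominant(values)

    def test_zero_total_mouse_excluded(self):
        ab = pd.DataFrame(
            {
                "mouse_id": ["m1", "m2"],
                "time_point": "pre_divergent",
                "cell_type": "GR",
                "barcode_id": ["a", "b"],
                "abundance": [10.0, 0.0],
            }
        )
        per_mouse, _ = expansion_threshold(ab, "GR")
        assert "m2" not in per_mouse


class TestExpandedClones:
    def _end(self, values):
        return pd.DataFrame(
            {
                "mouse_id": "m",
                "time_point": "end",
                "cell_type": "GR",
                "barcode_id": [f"b{i}" for i in range(len(values))],
                "abundance": values,
            }
        )

    def test_fraction_of_clones_above_threshold(self):
        res = expanded_clones(self._end([50.0, 10.0, 5.0]), "GR", 27.5)
        assert len(res.expanded) == 1
        assert res.fractions["fraction"].iloc[0] == pytest.approx(1 / 3)

    def test_all_below_gives_zero_fraction(self):
        res = expanded_clones(self._end([1.0, 2.0]), "GR", 27.5)
        assert res.fractions["fraction"].iloc[0] == 0.0

    def test_threshold_boundary_is_strict(self):
        res = expanded_clones(self._end([27.5, 30.0]), "GR", 27.5)
        assert list(res.expanded["barcode_id"]) == ["b1"]


class TestTopK:
    def _end(self, pairs):
        return pd.DataFrame(
            {
                "mouse_id": "m",
                "time_point": "end",
                "cell_type": "GR",
                "barcode_id": [b for b, _ in pairs],
                "abundance": [a for _, a in pairs],
            }
        )

    def test_top_three(self):
        df = self._end([("a", 50.0), ("b", 30.0), ("c", 10.0), ("d", 5.0), ("e", 5.0)])
        top = top_k_abundance(df, "GR", k=3)
        assert list(top["barcode_id"]) == ["a", "b", "c"]

    def test_k_one_is_maximum(self):
        df = self._end([("a", 1.0), ("b", 9.0)])
        assert list(top_k_abundance(df, "GR", k=1)["barcode_id"]) == ["b"]

    def test_tie_broken_by_barcode_id(self):
        df = self._end([("z", 10.0), ("a", 3.0), ("m", 3.0)])
        top = top_k_abundance(df, "GR", k=2)
        assert list(top["barcode_id"]) == ["z", "a"]

    def test_short_mouse_flagged(self):
        df = self._end([("a", 1.0)])
        top = top_k_abundance(df, "GR", k=3)
        assert len(top) == 1 and top["short"].all()


class TestFateLabels:
    @pytest.mark.parametrize(
        "pattern,expected",
        [
            ((1, 1, 1), "persistent"),
            ((1, 1, 0), "exhausted"),
            ((0, 0, 1), "activated"),
            ((1, 0, 1), "other"),
            ((0, 1, 1), "other"),
            ((1, 0, 0), "other"),
            ((0, 1, 0), "other"),
            ((0, 0, 0), "other"),
        ],
    )
    def test_all_eight_patterns(self, pattern, expected):
        assert classify_fate(*pattern) == expected

    def test_exactly_three_named_labels(self):
        labels = {classify_fate(*p) for p in itertools.product([0, 1], repeat=3)}
        assert labels == {"persistent", "exhausted", "activated", "other"}

    @given(st.lists(st.tuples(st.booleans(), st.booleans(), st.booleans()), min_size=1))
    @settings(max_examples=100, derandomize=True)
    def test_total_over_random_presence_tables(self, patterns):
        for p in patterns:
            assert classify_fate(*p) in {"persistent", "exhausted", "activated", "other"}

    def test_fate_table_uses_presence_threshold(self):
        ab = pd.DataFrame(
            {
                "mouse_id": "m",
                "time_point": ["initial", "pre_divergent", "end"],
                "cell_type": "GR",
                "barcode_id": "bc",
                "abundance": [0.5, 0.5, 0.005],  # below the 0.01 presence floor at end
            }
        )
        assert fate_table(ab)["label"].iloc[0] == "exhausted"

    def test_generator_archetypes_recovered(self, cohort, report):
        _, _, _, truth = cohort
        fates = report.tables["fate_labels"].merge(
            truth.clones[["mouse_id", "barcode_id", "archetype"]],
            on=["mouse_id", "barcode_id"],
        )
        exh = fates[fates["archetype"] == "exhausted"]
        act = fates[fates["archetype"] == "activated"]
        assert (exh["label"] == "exhausted").mean() > 0.9
        assert (act["label"] == "activated").mean() > 0.9


class TestChangeCounts:
    def _deltas(self, values):
        return pd.DataFrame(
            {"mouse_id": "m", "barcode_id": range(len(values)), "delta": values}
        )

    def test_floor_excludes_small_changes(self):
        out = change_counts(self._deltas([0.05, 0.2, -0.5]), floor=0.1)
        row = out.iloc[0]
        assert row["n_increased"] == 1 and row["n_decreased"] == 1
        assert row["aggregate_increase"] == pytest.approx(0.2)
        assert row["aggregate_decrease"] == pytest.approx(-0.5)

    def test_all_subfloor_gives_zeros(self):
        row = change_counts(self._deltas([0.05, -0.09]), floor=0.1).iloc[0]
        assert row["n_increased"] == 0 and row["aggregate_decrease"] == 0.0

    def test_conservation_of_net_change(self):
        values = [0.05, 0.2, -0.5, -0.03, 0.4]
        row = change_counts(self._deltas(values), floor=0.1).iloc[0]
        subfloor = sum(v for v in values if abs(v) < 0.1)
        assert row["aggregate_increase"] + row["aggregate_decrease"] + subfloor == (
            pytest.approx(sum(values))
        )


class TestDifferentiationIndex:
    def test_ratio_and_exclusion(self):
        ab = pd.DataFrame(
            {
                "mouse_id": "m",
                "time_point": "end",
                "cell_type": ["GR", "HSC", "GR", "HSC"],
                "barcode_id": ["a", "a", "b", "b"],
                "abundance": [2.0, 1.0, 3.0, 0.0],
            }
        )
        idx, excluded = differentiation_index(ab)
        assert idx["index"].iloc[0] == pytest.approx(2.0)
        assert list(excluded["barcode_id"]) == ["b"]

    def test_anti_aging_clones_have_lower_index(self, cohort, report):
        """Anti-aging clones differentiate less toward myeloid than stable ones."""
        _, _, _, truth = cohort
        idx, _ = differentiation_index(report.tables["abundance"])
        merged = idx.merge(
            truth.clones[["mouse_id", "barcode_id", "archetype"]],
            on=["mouse_id", "barcode_id"],
        )
        anti = merged[merged["archetype"] == "anti_aging"]["index"]
        stable = merged[merged["archetype"].str.startswith("stable")]["index"]
        assert anti.median() < stable.median()


class TestStemExport:
    def _series(self, values):
        tps = ["initial", "mid", "pre_divergent", "end"]
        return pd.DataFrame(
            {
                "mouse_id": "m",
                "time_point": tps,
                "cell_type": "GR",
                "barcode_id": "bc",
                "abundance": values,
            }
        )

    def test_subthreshold_series_excluded(self):
        assert stem_input_export(self._series([1.0, 1.0, 1.0, 1.005]), "GR").empty

    def test_changing_series_retained(self):
        out = stem_input_export(self._series([1.0, 1.0, 1.0, 1.02]), "GR")
        assert len(out) == 1
        assert out["end"].iloc[0] == pytest.approx(1.02)

    def test_empty_input_gives_empty_output(self):
        empty = self._series([1.0, 1.0, 1.0, 1.0]).iloc[:0]
        assert stem_input_export(empty, "GR").empty

    def test_incomplete_series_excluded(self):
        df = self._series([1.0, 1.0, 1.0, 2.0]).iloc[:3]  # missing end
        assert stem_input_export(df, "GR").empty


def test_clone_deltas_treat_missing_as_zero():
    ab = pd.DataFrame(
        {
            "mouse_id": "m",
            "time_point": ["pre_divergent", "end", "pre_divergent"],
            "cell_type": "GR",
            "barcode_id": ["a", "a", "gone"],
            "abundance": [1.0, 3.0, 2.0],
        }
    )
    deltas = clone_deltas(ab, "GR").set_index("barcode_id")["delta"]
    assert deltas["a"] == pytest.approx(2.0)
    assert deltas["gone"] == pytest.approx(-2.0)


def test_expansion_analysis_on_cohort(report):
    res = report.tables["expansion_GR"]
    assert (res["fraction"] >= 0).all() and (res["fraction"] <= 1).all()
    assert len(res) == 18
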