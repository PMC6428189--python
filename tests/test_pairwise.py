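"""Tests for the survey configuration, composites and all-pairs engine."""

import logging

import numpy as np
import pandas as pd
import pytest

import groupsim as gs
from groupsim.errors import ConfigError
from groupsim.pairwise import (
    PairwiseTable,
    SurveyConfig,
    count_pairs,
    prepare_table,
    reverse_code,
)


@pytest.fixture
def tiny_config():
    return SurveyConfig.from_dict(
        {
            "grouping": [{"name": "region"}],
            "variables": {
                "mood": {
                    "items": ["mood"],
                    "scale": {"min": 1, "max": 6, "categories": 6},
                },
                "trust": {
                    "items": ["trust_1", "trust_2"],
                    "scale": {"min": 1, "max": 4, "categories": 4},
                    "reverse": ["trust_2"],
                },
            },
            "min_group_size": 3,
            "statistics": ["d", "pcr", "pcs", "ae"],
        }
    )


@pytest.fixture
def tiny_table(rng):
    n = 30
    return pd.DataFrame(
        {
            "region": np.repeat(["east", "north", "west"], n // 3),
            "mood": rng.integers(1, 7, n),
            "trust_1": rng.integers(1, 5, n),
            "trust_2": rng.integers(1, 5, n),
        }
    )


class TestCountPairs:
    @pytest.mark.parametrize(
        "g, expected",
        [(60, 1770), (7, 21), (2, 1), (9, 36), (10, 45), (1, 0), (3, 3)],
    )
    def test_unordered_pair_counts(self, g, expected):
        assert count_pairs(g) == expected

    def test_six_category_survey_block(self):
        # religious denominations + gender + education + income + age
        assert sum(count_pairs(g) for g in (7, 2, 9, 10, 10)) == 148

    def test_invalid_input(self):
        with pytest.raises(ValueError):
            count_pairs(0)


class TestConfig:
    def test_roundtrip_through_yaml(self, tiny_config, tmp_path):
        path = tmp_path / "config.yaml"
        tiny_config.to_yaml(path)
        again = SurveyConfig.from_yaml(path)
        assert again == tiny_config
        assert again.digest() == tiny_config.digest()

    def test_reverse_item_must_be_listed(self):
        with pytest.raises(ConfigError):
            SurveyConfig.from_dict(
                {
                    "grouping": [{"name": "g"}],
                    "variables": {
                        "v": {
                            "items": ["a"],
                            "scale": {"min": 1, "max": 6, "categories": 6},
                            "reverse": ["zzz"],
                        }
                    },
                }
            )

    def test_unknown_statistic_rejected(self):
        with pytest.raises(ConfigError):
            SurveyConfig.from_dict(
                {
                    "grouping": [{"name": "g"}],
                    "variables": {
                        "v": {"items": ["a"],
                              "scale": {"min": 1, "max": 6, "categories": 6}}
                    },
                    "statistics": ["d", "eta"],
                }
            )

    def test_missing_item_column_named_in_error(self, tiny_config, tiny_table):
        broken = tiny_table.drop(columns=["trust_2"])
        with pytest.raises(ConfigError, match="trust_2"):
            prepare_table(broken, tiny_config)

    def test_missing_codes_mapped_to_nan(self, tiny_config, tiny_table):
        cfg = SurveyConfig.from_dict(
            {**tiny_config.to_dict(), "missing_codes": [-1]}
        )
        t = tiny_table.copy()
        t.loc[0, "mood"] = -1
        out = prepare_table(t, cfg)
        assert np.isnan(out.loc[0, "mood"])

    def test_out_of_bounds_values_rejected(self, tiny_config, tiny_table):
        t = tiny_table.copy()
        t.loc[0, "mood"] = 99
        with pytest.raises(ConfigError, match="mood"):
            prepare_table(t, tiny_config)


class TestComposites:
    def test_reverse_coding_is_an_involution(self, likert6):
        x = np.array([1.0, 2.5, 6.0])
        assert np.allclose(reverse_code(reverse_code(x, likert6), likert6), x)

    def test_single_item_composite_equals_item(self, tiny_config, tiny_table):
        out, _ = gs.build_composites(tiny_table, tiny_config)
        assert np.allclose(out["mood"], tiny_table["mood"])

    def test_reverse_coded_mean_of_available_items(self, tiny_config):
        t = pd.DataFrame(
            {
                "region": ["east"] * 3,
                "mood": [1, 2, 3],
                "trust_1": [1.0, 2.0, np.nan],
                "trust_2": [4.0, np.nan, np.nan],
            }
        )
        out, _ = gs.build_composites(t, tiny_config)
        # trust_2 reflected on the 1-4 scale: 4 -> 1; composite means
        assert out["trust"].tolist()[0] == pytest.approx((1.0 + 1.0) / 2)
        assert out["trust"].tolist()[1] == pytest.approx(2.0)  # only trust_1
        assert np.isnan(out["trust"].tolist()[2])  # all items missing

    def test_alpha_for_perfectly_correlated_items(self, tiny_config, rng):
        base = rng.integers(1, 5, 50).astype(float)
        t = pd.DataFrame(
            {
                "region": ["east"] * 50,
                "mood": rng.integers(1, 7, 50),
                "trust_1": base,
                "trust_2": reverse_code(base, gs.ScaleSpec(1, 4, 4)),
            }
        )
        # after reverse coding, the two items are identical -> alpha = 1
        _, alphas = gs.build_composites(t, tiny_config)
        assert alphas["trust"] == pytest.approx(1.0)
        assert np.isnan(alphas["mood"])  # single item: undefined

    def test_alpha_matches_textbook_formula_on_toy_matrix(self):
        items = pd.DataFrame(
            {"a": [1, 2, 3, 4, 5.0], "b": [2, 2, 4, 4, 5.0], "c": [1, 3, 3, 5, 4.0]}
        )
        k = 3
        expected = k / (k - 1) * (
            1 - items.var(ddof=1).sum() / items.sum(axis=1).var(ddof=1)
        )
        assert gs.cronbach_alpha(items) == pytest.approx(expected)


class TestAgeBands:
    def test_equal_sized_bands(self):
        years = pd.Series(np.arange(1000))
        bands = gs.age_bands(years, k=10)
        assert bands.value_counts().nunique() == 1
        assert bands.value_counts().iloc[0] == 100

    def test_boundary_value_goes_to_lower_band(self):
        vals = pd.Series([1.0, 2.0, 3.0, 4.0])
        bands = gs.age_bands(vals, k=2)
        # the k=2 edge is the median (2.5); 2.0 stays in the lower band
        assert bands.tolist() == ["band_1", "band_1", "band_2", "band_2"]

    def test_missing_stays_missing(self):
        vals = pd.Series([1.0, np.nan, 3.0, 4.0])
        bands = gs.age_bands(vals, k=2)
        assert bands.isna().tolist() == [False, True, False, False]


class TestRunPairwise:
    def test_record_count_identity(self, tiny_table, tiny_config):
        pt = gs.run_pairwise(tiny_table, tiny_config)
        # 3 groups -> 3 pairs, times 2 variables
        assert len(pt.records) == 6
        assert pt.provenance["n_statistic_results"] == 24
        for (_, _), block in pt.records.groupby(["category", "variable"]):
            assert len(block) == count_pairs(3)

    def test_pair_order_is_lexicographic(self, tiny_table, tiny_config):
        pt = gs.run_pairwise(tiny_table, tiny_config)
        assert (pt.records["group_a"] < pt.records["group_b"]).all()

    def test_row_shuffle_leaves_records_identical(self, tiny_table, tiny_config):
        pt1 = gs.run_pairwise(tiny_table, tiny_config)
        shuffled = tiny_table.sample(frac=1.0, random_state=5).reset_index(drop=True)
        pt2 = gs.run_pairwise(shuffled, tiny_config)
        pd.testing.assert_frame_equal(pt1.records, pt2.records)

    def test_pairwise_deletion_is_variable_local(self, tiny_table, tiny_config):
        t = tiny_table.copy().astype({"mood": float})
        t.loc[0, "mood"] = np.nan  # respondent 0 is in region east
        pt_full = gs.run_pairwise(tiny_table, tiny_config)
        pt_miss = gs.run_pairwise(t, tiny_config)
        trust_full = pt_full.records.query("variable == 'trust'").reset_index(drop=True)
        trust_miss = pt_miss.records.query("variable == 'trust'").reset_index(drop=True)
        pd.testing.assert_frame_equal(trust_full, trust_miss)
        mood_miss = pt_miss.records.query("variable == 'mood'")
        assert (
            mood_miss.loc[mood_miss["group_a"] == "east", "n_a"] == 9
        ).all()

    def test_small_groups_excluded_and_skip_logged(self, tiny_table, caplog):
        config = SurveyConfig.from_dict(
            {
                "grouping": [{"name": "region"}, {"name": "empty_cat"}],
                "variables": {
                    "mood": {"items": ["mood"],
                             "scale": {"min": 1, "max": 6, "categories": 6}}
                },
                "min_group_size": 3,
            }
        )
        t = tiny_table.copy()
        t["empty_cat"] = "only_level"
        with caplog.at_level(logging.WARNING, logger="groupsim.pairwise"):
            pt = gs.run_pairwise(t, config)
        assert set(pt.records["category"]) == {"region"}
        assert any("empty_cat" in r.message for r in caplog.records)

    def test_group_below_minimum_size_dropped(self, tiny_table, tiny_config):
        t = tiny_table.copy()
        t.loc[t.index[:8], "region"] = "tiny"  # leaves east with 2 < min 3
        pt = gs.run_pairwise(t, tiny_config)
        assert "east" not in set(pt.records["group_a"]) | set(pt.records["group_b"])

    def test_verdict_and_statistics_columns(self, tiny_table, tiny_config):
        pt = gs.run_pairwise(tiny_table, tiny_config)
        for col in ("d", "pcr", "pcs", "ae", "verdict", "t", "df", "p"):
            assert col in pt.records.columns
        assert pt.records["pcr"].between(0, 100).all()
        assert pt.records["pcs"].between(0, 100).all()
        assert pt.records["ae"].between(0, 100).all()

    def test_records_match_compare_groups(self, tiny_table, tiny_config):
        # the vectorized engine must agree with the single-pair path
        out, _ = gs.build_composites(tiny_table, tiny_config)
        pt = gs.run_pairwise(tiny_table, tiny_config)
        row = pt.records.query(
            "variable == 'mood' and group_a == 'east' and group_b == 'north'"
        ).iloc[0]
        scale = tiny_config.variables["mood"].scale
        a = gs.GroupSample(
            "east", out.loc[out.region == "east", "mood"].to_numpy(), scale
        )
        b = gs.GroupSample(
            "north", out.loc[out.region == "north", "mood"].to_numpy(), scale
        )
        ref = gs.compare_groups(a, b, min_n=2)
        assert row["d"] == pytest.approx(ref.effects.d)
        assert row["pcr"] == pytest.approx(ref.effects.pcr)
        assert row["pcs"] == pytest.approx(ref.effects.pcs)
        assert row["ae"] == pytest.approx(ref.effects.ae)
        assert row["t"] == pytest.approx(ref.welch.t)
        assert row["df"] == pytest.approx(ref.welch.df)
        assert row["verdict"] == ref.verdict.verdict

    def test_bootstrap_cis_attached_when_enabled(self, tiny_table, tiny_config):
        cfg = SurveyConfig.from_dict(
            {
                **tiny_config.to_dict(),
                "bootstrap": {"enabled": True, "n_boot": 100, "level": 0.95},
            }
        )
        pt = gs.run_pairwise(tiny_table, cfg, seed=1)
        assert {"pcr_ci_low", "pcr_ci_high", "ae_ci_low", "ae_ci_high"} <= set(
            pt.records.columns
        )
        ok = pt.records["pcr"].notna()
        assert (pt.records.loc[ok, "pcr_ci_low"]
                <= pt.records.loc[ok, "pcr"] + 1e-9).all()
        assert (pt.records.loc[ok, "pcr_ci_high"]
                >= pt.records.loc[ok, "pcr"] - 1e-9).all()
        pt2 = gs.run_pairwise(tiny_table, cfg, seed=1)
        pd.testing.assert_frame_equal(pt.records, pt2.records)


class TestSummaries:
    def _table_from_rows(self, rows):
        return PairwiseTable(records=pd.DataFrame(rows))

    def test_single_pair_summary_equals_value(self):
        pt = self._table_from_rows(
            [{"category": "c", "variable": "v", "group_a": "a",
              "group_b": "b", "pcr": 77.0}]
        )
        s = pt.summarize_category("c", "pcr")
        assert s["mean"] == s["median"] == s["min"] == s["max"] == 77.0
        assert s["per_variable"]["v"]["extreme_pair"]["value"] == 77.0

    def test_all_full_overlap(self):
        rows = [
            {"category": "c", "variable": f"v{i}", "group_a": "a",
             "group_b": "b", "pcr": 100.0}
            for i in range(3)
        ]
        s = self._table_from_rows(rows).summarize_category("c", "pcr")
        assert s["mean"] == s["median"] == 100.0
        assert (s["min"], s["max"]) == (100.0, 100.0)

    def test_category_mean_averages_per_variable_means(self):
        rows = [
            {"category": "c", "variable": "v1", "group_a": "a", "group_b": "b",
             "pcr": 78.0},
            {"category": "c", "variable": "v1", "group_a": "a", "group_b": "c",
             "pcr": 82.0},
            {"category": "c", "variable": "v2", "group_a": "a", "group_b": "b",
             "pcr": 90.0},
        ]
        s = self._table_from_rows(rows).summarize_category("c", "pcr")
        # per-variable means (80, 90) -> category mean 85
        assert s["mean"] == pytest.approx(85.0)
        assert s["per_variable"]["v1"]["mean"] == pytest.approx(80.0)

    def test_extreme_pair_is_least_similar(self):
        rows = [
            {"category": "c", "variable": "v", "group_a": "a", "group_b": "b",
             "pcr": 90.0, "ae": 5.0},
            {"category": "c", "variable": "v", "group_a": "a", "group_b": "c",
             "pcr": 40.0, "ae": 60.0},
        ]
        pt = self._table_from_rows(rows)
        assert pt.summarize_category("c", "pcr")["per_variable"]["v"][
            "extreme_pair"]["group_b"] == "c"
        assert pt.summarize_category("c", "ae")["per_variable"]["v"][
            "extreme_pair"]["value"] == 60.0

    def test_empty_selection_signals(self):
        pt = self._table_from_rows(
            [{"category": "c", "variable": "v", "group_a": "a",
              "group_b": "b", "pcr": 77.0}]
        )
        with pytest.raises(ValueError):
            pt.summarize_category("nope", "pcr")
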