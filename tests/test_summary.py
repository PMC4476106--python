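"""Network-level summaries: counts, panel, class statistics, coverage."""

import math

import numpy as np
import pandas as pd
import pytest

from mirlink.summary import (
    build_panel,
    class_count_summary,
    class_target_stats,
    coverage_stats,
    round_pct,
    targets_per_mirna,
    targets_histogram,
)
from mirlink.tables_io import load_panel_fixture


def _pairs(records):
    return pd.DataFrame(
        records, columns=["mirna_id", "gene_id", "pearson_r", "fdr", "selected"]
    )


def _de_from_fixture(fx):
    """A differential table in which the fixture miRNAs are all q_associated."""
    return pd.DataFrame(
        {
            "feature_id": fx["mirna_id"],
            "feature_kind": "miRNA",
            "fc_q_vs_a": fx["fc_q_vs_a"],
            "p_value": fx["p_value"],
            "class_label": "q_associated",
        }
    )


class TestTargetsPerMirna:
    def test_no_selected_pairs_all_zero(self):
        pairs = _pairs([("m1", "g1", -0.9, 0.01, False)])
        counts = targets_per_mirna(pairs, mirna_ids=["m1", "m2"])
        assert counts.tolist() == [0, 0]

    def test_hand_built_count(self):
        pairs = _pairs(
            [
                ("m1", "g1", -0.9, 0.01, True),
                ("m1", "g2", -0.8, 0.01, True),
                ("m1", "g3", -0.7, 0.01, True),
                ("m1", "g4", 0.7, 0.01, False),
                ("m2", "g1", -0.6, 0.01, True),
            ]
        )
        counts = targets_per_mirna(pairs)
        assert counts["m1"] == 3 and counts["m2"] == 1

    def test_counts_match_recount_and_sum_to_selected(self, small_dataset):
        from mirlink.config import PipelineConfig
        from mirlink.pipeline import run_pipeline
        from mirlink.simulate import SimulationConfig

        cfg = PipelineConfig(simulation=SimulationConfig(seed=11, n_mirna_q=5,
                             n_mirna_a=8, n_genes_q=10, n_genes_a=30, n_genes_bg=10,
                             targets_per_q_mirna=6.0, targets_per_a_mirna=1.0))
        res = run_pipeline(cfg)
        counts = targets_per_mirna(res.pairs)
        recount = res.pairs[res.pairs["selected"]].groupby("mirna_id").size()
        for m, n in recount.items():
            assert counts[m] == n
        assert counts.sum() == res.pairs["selected"].sum()


class TestBuildPanel:
    def test_exactly_panel_min_excluded(self):
        de = _de_from_fixture(load_panel_fixture())
        counts = pd.Series(6, index=de["feature_id"])
        assert len(build_panel(de, counts, panel_min=6)) == 0
        assert len(build_panel(de, counts, panel_min=6, strict=False)) == len(de)

    def test_fixture_retained_in_full_at_default_cut(self):
        fx = load_panel_fixture()
        de = _de_from_fixture(fx)
        counts = pd.Series(fx["n_targets"].to_numpy(), index=fx["mirna_id"])
        panel = build_panel(de, counts, panel_min=6)
        assert len(panel) == 31
        assert panel["n_targets"].is_monotonic_decreasing

    def test_high_cut_leaves_only_the_top_mirna(self):
        fx = load_panel_fixture()
        de = _de_from_fixture(fx)
        counts = pd.Series(fx["n_targets"].to_numpy(), index=fx["mirna_id"])
        panel = build_panel(de, counts, panel_min=44)
        assert panel["mirna_id"].tolist() == ["miR-200b"]
        assert panel["n_targets"].tolist() == [45]

    def test_membership_monotone_in_panel_min(self):
        fx = load_panel_fixture()
        de = _de_from_fixture(fx)
        counts = pd.Series(fx["n_targets"].to_numpy(), index=fx["mirna_id"])
        sizes = [len(build_panel(de, counts, panel_min=k)) for k in range(0, 50)]
        assert sizes == sorted(sizes, reverse=True)


class TestClassTargetStats:
    def _de(self, q_ids, a_ids):
        return pd.DataFrame(
            {
                "feature_id": list(q_ids) + list(a_ids),
                "feature_kind": "miRNA",
                "fc_q_vs_a": 2.0,
                "p_value": 0.01,
                "class_label": ["q_associated"] * len(q_ids)
                + ["a_associated"] * len(a_ids),
            }
        )

    def test_constant_counts(self):
        de = self._de(["m1", "m2", "m3"], [])
        counts = pd.Series([2, 2, 2], index=["m1", "m2", "m3"])
        out = class_target_stats(de, counts).set_index("class_label")
        assert out.loc["q_associated", "mean_targets"] == 2.0
        assert out.loc["q_associated", "sd_targets"] == 0.0

    def test_31_of_47_is_66_percent(self):
        # a q-class of 47 miRNAs, 31 of them above the panel threshold
        q = [f"m{i}" for i in range(47)]
        de = self._de(q, [])
        counts = pd.Series([10] * 31 + [3] * 16, index=q)
        out = class_target_stats(de, counts, panel_min=6).set_index("class_label")
        assert out.loc["q_associated", "pct_above_panel_min"] == 66

    def test_mean_sd_match_hand_computation(self):
        de = self._de(["a", "b", "c"], [])
        counts = pd.Series([45, 38, 35], index=["a", "b", "c"])
        out = class_target_stats(de, counts).set_index("class_label")
        assert out.loc["q_associated", "mean_targets"] == pytest.approx(
            (45 + 38 + 35) / 3
        )
        assert out.loc["q_associated", "sd_targets"] == pytest.approx(
            np.std([45, 38, 35], ddof=1)
        )

    def test_empty_class_missing_stats(self):
        de = self._de(["m1"], [])
        counts = pd.Series([3], index=["m1"])
        out = class_target_stats(de, counts).set_index("class_label")
        assert math.isnan(out.loc["a_associated", "mean_targets"])


class TestCoverage:
    def _setup(self, n_panel_genes, n_a_genes):
        fx = load_panel_fixture()
        de_m = _de_from_fixture(fx)
        gene_ids = [f"G{i:04d}" for i in range(n_a_genes)]
        de_g = pd.DataFrame(
            {
                "feature_id": gene_ids,
                "feature_kind": "gene",
                "fc_q_vs_a": 0.3,
                "p_value": 0.01,
                "class_label": "a_associated",
            }
        )
        de = pd.concat([de_m, de_g], ignore_index=True)
        # distribute each panel miRNA's published target count over a pool of
        # n_panel_genes genes, round-robin, so the union is exactly that pool
        records = []
        pos = 0
        for _, row in fx.iterrows():
            for _ in range(int(row["n_targets"])):
                records.append(
                    (row["mirna_id"], gene_ids[pos % n_panel_genes], -0.8, 0.01, True)
                )
                pos += 1
        pairs = _pairs(records)
        counts = targets_per_mirna(pairs)
        panel = build_panel(de, counts, panel_min=6)
        return pairs, de, panel

    def test_267_of_998_rounds_to_27_percent(self):
        pairs, de, panel = self._setup(n_panel_genes=267, n_a_genes=998)
        cov = coverage_stats(pairs, de, panel)
        assert cov["n_panel_target_genes"] == 267
        assert cov["coverage_pct"] == 27

    def test_full_coverage_is_one(self):
        pairs, de, panel = self._setup(n_panel_genes=20, n_a_genes=20)
        assert coverage_stats(pairs, de, panel)["coverage"] == 1.0

    def test_most_targeted_gene_matches_recount(self, small_dataset):
        from mirlink.config import PipelineConfig
        from mirlink.pipeline import run_pipeline
        from mirlink.simulate import SimulationConfig

        res = run_pipeline(PipelineConfig(simulation=SimulationConfig(seed=4)))
        cov = res.report["coverage"]
        sel = res.pairs[res.pairs["selected"]]
        best = sel.groupby("gene_id")["mirna_id"].nunique()
        assert cov["most_targeted_n_mirnas"] == best.max()
        assert set(cov["most_targeted_genes"]) == set(
            best.index[best == best.max()]
        )

    def test_no_a_genes_is_an_error(self):
        de = _de_from_fixture(load_panel_fixture())
        pairs = _pairs([])
        with pytest.raises(ValueError, match="denominator"):
            coverage_stats(pairs, de, de.iloc[:0])


class TestClassCounts:
    def _de(self, n_q, n_a, n_unchanged=0):
        labels = (
            ["q_associated"] * n_q
            + ["a_associated"] * n_a
            + ["unchanged"] * n_unchanged
        )
        return pd.DataFrame(
            {
                "feature_id": [f"m{i}" for i in range(len(labels))],
                "feature_kind": "miRNA",
                "fc_q_vs_a": 1.0,
                "p_value": 0.5,
                "class_label": labels,
            }
        )

    def test_47_vs_212_gives_18_and_82_percent(self):
        out = class_count_summary(self._de(47, 212)).set_index("class_label")
        assert out.loc["q_associated", "n_features"] == 47
        assert out.loc["q_associated", "pct_of_deregulated"] == 18
        assert out.loc["a_associated", "pct_of_deregulated"] == 82

    def test_one_empty_class(self):
        out = class_count_summary(self._de(0, 10)).set_index("class_label")
        assert out.loc["q_associated", "pct_of_deregulated"] == 0
        assert out.loc["a_associated", "pct_of_deregulated"] == 100

    def test_percentages_match_recount(self):
        rng = np.random.default_rng(0)
        n_q, n_a, n_u = rng.integers(1, 100, size=3)
        out = class_count_summary(self._de(n_q, n_a, n_u)).set_index("class_label")
        assert out.loc["q_associated", "pct_of_deregulated"] == round_pct(
            n_q / (n_q + n_a)
        )
        assert out["n_features"].sum() == n_q + n_a


def test_histogram_totals_match_counts():
    counts = pd.Series([3, 3, 1, 0], index=["a", "b", "c", "d"])
    h = targets_histogram(counts)
    assert h.set_index("n_targets")["n_mirnas"].to_dict() == {0: 1, 1: 1, 3: 2}
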