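"""Single-cell cytotoxicity stage: naive exclusion, signature selection,
scoring, binning, hurdle DE, shared-repertoire intersection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import rbprofiler as rb
from rbprofiler.cytotox import HurdleDE, _two_means_1d


def _sc_from_lognorm(lognorm: pd.DataFrame) -> rb.SingleCellMatrix:
    """Build a matrix whose cached log-normalized layer is exactly
    ``lognorm`` (counts themselves are placeholders)."""
    counts = pd.DataFrame(
        np.ones_like(lognorm.to_numpy(), dtype=int),
        index=lognorm.index,
        columns=lognorm.columns,
    )
    sc = rb.SingleCellMatrix(counts)
    sc._lognorm = lognorm.astype(float)
    return sc


class TestLognormalize:
    def test_depth_normalisation_formula(self):
        counts = pd.DataFrame({"c1": [90, 10], "c2": [450, 50]}, index=["g1", "g2"])
        ln = rb.lognormalize(counts)
        # identical composition at different depth -> identical lognorm
        assert np.allclose(ln["c1"], ln["c2"])
        assert ln.loc["g1", "c1"] == pytest.approx(np.log2(1 + 1e4 * 0.9))

    def test_integer_and_total_validation(self):
        with pytest.raises(ValueError, match="zero total"):
            rb.SingleCellMatrix(pd.DataFrame({"c1": [0, 0]}, index=["g1", "g2"]))
        with pytest.raises(ValueError, match="integer"):
            rb.SingleCellMatrix(pd.DataFrame({"c1": [0.5, 1.0]}, index=["g1", "g2"]))


class TestTwoMeans:
    def test_exact_split_of_bimodal_values(self):
        x = np.array([0.0, 0.1, 0.2, 5.0, 5.1])
        hi, gap = _two_means_1d(x)
        assert hi.tolist() == [False, False, False, True, True]
        assert gap == pytest.approx(4.95)


class TestExcludeNaive:
    def test_constant_markers_exclude_nothing(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.poisson(5, size=(4, 30)),
            index=["CCR7", "LEF1", "SELL", "g1"],
            columns=[f"c{i}" for i in range(30)],
        )
        counts.iloc[:3] = 0
        counts.iloc[3] += 1
        sc = rb.SingleCellMatrix(counts)
        with pytest.warns(UserWarning):
            kept, flags = rb.exclude_naive(sc)
        assert not flags.any()
        assert len(kept.cells) == 30

    def test_no_marker_present_errors(self):
        counts = pd.DataFrame({"c1": [1], "c2": [2]}, index=["g1"])
        with pytest.raises(ValueError, match="naive markers"):
            rb.exclude_naive(rb.SingleCellMatrix(counts))

    def test_planted_naive_population_recovered(self, sc_default):
        sc, truth = sc_default
        kept, flags = rb.exclude_naive(sc)
        excluded = set(flags[flags].index)
        naive = truth.naive_cells
        assert len(excluded & naive) / len(naive) >= 0.95
        others = set(sc.cells) - naive
        assert len(excluded & others) / len(others) <= 0.05

    def test_exclusion_is_idempotent(self, sc_default):
        sc, _ = sc_default
        kept, _ = rb.exclude_naive(sc)
        with pytest.warns(UserWarning):
            kept2, flags2 = rb.exclude_naive(kept)
        assert not flags2.any()
        assert list(kept2.cells) == list(kept.cells)


class TestSelectSignature:
    def test_planted_module_recovered_exactly(self, scored_default):
        scorer, truth = scored_default
        assert set(scorer.signature_) == set(truth.module_genes)
        assert scorer.signature_[0] == "FGFBP2"

    def test_signature_length_is_anchor_plus_n_top(self, scored_default):
        scorer, _ = scored_default
        assert len(scorer.signature_) == 8

    def test_n_top_zero_returns_anchor_only(self, sc_default):
        sc, _ = sc_default
        sig, _ = rb.select_signature(sc, n_top=0)
        assert sig == ["FGFBP2"]

    def test_absent_or_constant_anchor_errors(self):
        counts = pd.DataFrame(
            {"c1": [1, 2], "c2": [1, 3]}, index=["FGFBP2", "g1"]
        )
        sc = rb.SingleCellMatrix(counts)
        with pytest.raises(ValueError, match="not present"):
            rb.select_signature(sc, anchor="GZMB")
        constant = pd.DataFrame({"c1": [1, 2], "c2": [2, 4]}, index=["FGFBP2", "g1"])
        with pytest.raises(ValueError, match="zero variance"):
            rb.select_signature(rb.SingleCellMatrix(constant), anchor="FGFBP2")

    def test_ties_broken_alphabetically(self):
        ln = pd.DataFrame(
            {
                "c1": [1.0, 1.0, 1.0, 0.0],
                "c2": [2.0, 2.0, 2.0, 0.0],
                "c3": [3.0, 3.0, 3.0, 5.0],
            },
            index=["FGFBP2", "gb", "ga", "gz"],
        )
        sc = _sc_from_lognorm(ln)
        sig, _ = rb.select_signature(sc, n_top=1)
        assert sig == ["FGFBP2", "ga"]


class TestCytotoxicScore:
    def test_hand_computed_zscores(self):
        ln = pd.DataFrame(
            {"c1": [1.0, 2.0], "c2": [2.0, 2.0], "c3": [3.0, 5.0]},
            index=["g1", "g2"],
        )
        sc = _sc_from_lognorm(ln)
        score = rb.cytotoxic_score(sc, ["g1", "g2"])
        assert score.tolist() == pytest.approx([-0.7887, -0.2887, 1.0774], abs=1e-4)

    def test_per_gene_location_invariance(self):
        rng = np.random.default_rng(1)
        ln = pd.DataFrame(
            rng.normal(2, 1, size=(3, 20)),
            index=["g1", "g2", "g3"],
            columns=[f"c{i}" for i in range(20)],
        )
        s1 = rb.cytotoxic_score(_sc_from_lognorm(ln), ["g1", "g2", "g3"])
        ln2 = ln.copy()
        ln2.loc["g2"] += 7.0
        s2 = rb.cytotoxic_score(_sc_from_lognorm(ln2), ["g1", "g2", "g3"])
        assert np.allclose(s1, s2)

    def test_per_gene_scale_invariance(self):
        rng = np.random.default_rng(2)
        ln = pd.DataFrame(
            rng.normal(2, 1, size=(2, 15)),
            index=["g1", "g2"],
            columns=[f"c{i}" for i in range(15)],
        )
        s1 = rb.cytotoxic_score(_sc_from_lognorm(ln), ["g1", "g2"])
        ln2 = ln.copy()
        ln2.loc["g1"] = ln2.loc["g1"] * 3.0 + 1.0
        s2 = rb.cytotoxic_score(_sc_from_lognorm(ln2), ["g1", "g2"])
        assert np.allclose(s1, s2)

    def test_single_gene_signature_equals_its_zscore(self):
        ln = pd.DataFrame(
            {"c1": [1.0], "c2": [2.0], "c3": [3.0]}, index=["g1"]
        )
        score = rb.cytotoxic_score(_sc_from_lognorm(ln), ["g1"])
        assert score.tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_zero_variance_gene_dropped_with_warning(self):
        ln = pd.DataFrame(
            {"c1": [1.0, 5.0], "c2": [2.0, 5.0], "c3": [3.0, 5.0]},
            index=["g1", "gflat"],
        )
        with pytest.warns(UserWarning, match="gflat"):
            score = rb.cytotoxic_score(_sc_from_lognorm(ln), ["g1", "gflat"])
        assert score.tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_all_constant_signature_errors(self):
        ln = pd.DataFrame({"c1": [1.0], "c2": [1.0]}, index=["g1"])
        with pytest.warns(UserWarning), pytest.raises(ValueError, match="constant"):
            rb.cytotoxic_score(_sc_from_lognorm(ln), ["g1"])


class TestBinning:
    def test_hundred_distinct_scores_split_10_80_10(self):
        scores = pd.Series(
            np.arange(100, dtype=float), index=[f"c{i:03d}" for i in range(100)]
        )
        bins = rb.bin_by_score(scores)
        assert (bins == "low").sum() == 10
        assert (bins == "high").sum() == 10
        assert (bins == "intermediate").sum() == 80

    def test_twenty_cells_extremes_by_rank(self):
        scores = pd.Series(
            np.arange(20, dtype=float), index=[f"c{i:02d}" for i in range(20)]
        )
        bins = rb.bin_by_score(scores)
        assert set(bins[bins == "low"].index) == {"c00", "c01"}
        assert set(bins[bins == "high"].index) == {"c18", "c19"}

    def test_monotone_transform_leaves_bins_unchanged(self):
        rng = np.random.default_rng(3)
        scores = pd.Series(rng.normal(size=50), index=[f"c{i:02d}" for i in range(50)])
        b1 = rb.bin_by_score(scores)
        b2 = rb.bin_by_score(np.exp(scores))
        assert (b1 == b2).all()

    def test_ties_resolved_by_cell_identifier(self):
        scores = pd.Series(0.0, index=[f"c{i:02d}" for i in range(10)])
        scores.iloc[5:] = 1.0
        bins = rb.bin_by_score(scores)
        assert bins["c00"] == "low"
        assert bins["c09"] == "high"

    def test_degenerate_distribution_errors(self):
        scores = pd.Series(1.0, index=[f"c{i}" for i in range(20)])
        with pytest.raises(ValueError, match="degenerate"):
            rb.bin_by_score(scores)

    def test_fewer_than_ten_cells_errors(self):
        with pytest.raises(ValueError, match="10"):
            rb.bin_by_score(pd.Series([1.0, 2.0], index=["a", "b"]))

    def test_extreme_bins_hold_floor_tenth(self):
        rng = np.random.default_rng(4)
        for n in (10, 23, 57, 101, 250):
            scores = pd.Series(
                rng.normal(size=n), index=[f"c{i:04d}" for i in range(n)]
            )
            bins = rb.bin_by_score(scores)
            assert (bins == "low").sum() == n // 10
            assert (bins == "high").sum() == n // 10


from conftest import hurdle_grid_oracle as _hurdle_grid_oracle


class TestHurdle:
    def test_identical_groups_zero_lfc(self):
        rng = np.random.default_rng(0)
        block = rng.poisson(2, size=(30, 8))
        X = pd.DataFrame(
            np.vstack([block, block]), columns=[f"g{i}" for i in range(8)]
        )
        y = ["a"] * 30 + ["b"] * 30
        res = HurdleDE().fit(X, y).results_
        assert np.allclose(res["lfc_raw"], 0.0)

    def test_combined_lr_matches_grid_likelihood_oracle(self):
        # hand-built 10-cell toy with dropout and a location shift
        values = np.array([0.0, 1.2, 2.1, 0.0, 1.8, 3.1, 2.9, 0.0, 3.5, 2.7])
        groups = np.array(list("aaaaabbbbb"))
        X = pd.DataFrame({"g1": values})
        res = HurdleDE(reference="a").fit(X, groups).results_
        oracle = _hurdle_grid_oracle(values, groups)
        assert res.loc["g1", "lr"] == pytest.approx(oracle, abs=5e-3)
        assert res.loc["g1", "df"] == 2

    def test_degenerate_components_reduce_df(self):
        # all cells detected -> detection part uninformative (df 1)
        full = pd.DataFrame({"g1": [1.0, 2.0, 1.5, 2.5, 3.0, 2.8]})
        res = HurdleDE().fit(full, list("aaabbb")).results_
        assert res.loc["g1", "df"] == 1
        # detected in one group only, single positive -> detection only
        sparse = pd.DataFrame({"g1": [0.0, 0.0, 0.0, 2.0, 0.0, 0.0]})
        res2 = HurdleDE().fit(sparse, list("aaabbb")).results_
        assert res2.loc["g1", "df"] == 1

    def test_undetected_gene_skipped(self):
        X = pd.DataFrame({"g0": [0.0] * 6, "g1": [0, 1, 2, 0, 1, 2.0]})
        res = HurdleDE().fit(X, list("aaabbb")).results_
        assert res.loc["g0", "p"] == 1.0
        assert res.loc["g0", "lfc_raw"] == 0.0

    def test_null_rejection_rate_controlled(self, sc_null_groups):
        sc, labels = sc_null_groups
        res = rb.hurdle_de_test(sc, labels, reference="low")
        tested = res["df"] > 0
        rate = (res.loc[tested, "p"] < 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_planted_module_recovered_between_bins(self, scored_default):
        scorer, truth = scored_default
        bins = scorer.bins_[scorer.bins_.isin(["low", "high"])]
        res = rb.hurdle_de_test(scorer.scored_, bins, reference="low")
        de = set(res.index[res["de_flag"]])
        true = set(truth.module_genes)
        assert len(de & true) / len(true) > 0.8
        assert len(de - true) / max(1, len(de)) < 0.1

    def test_min_cells_enforced(self, sc_default):
        sc, _ = sc_default
        labels = pd.Series(
            ["low"] * 5 + ["high"] * 30, index=sc.cells[:35]
        )
        with pytest.raises(ValueError, match="cells"):
            rb.hurdle_de_test(sc, labels)


class TestSharedDe:
    def _table(self, signs):
        idx = list(signs)
        return pd.DataFrame(
            {
                "lfc_raw": [signs[g] for g in idx],
                "de_flag": True,
                "padj": 1e-4,
            },
            index=idx,
        )

    def test_hand_intersection(self):
        t1 = self._table({"A": 1.0, "B": 1.0, "C": -1.0})
        t2 = self._table({"A": 1.0, "C": -1.0, "D": 1.0})
        high, low = rb.shared_de(t1, t2)
        assert high == {"A"}
        assert low == {"C"}

    def test_empty_inputs_empty_outputs(self):
        t = self._table({})
        assert rb.shared_de(t, t) == (set(), set())

    def test_direction_conflict_excluded(self):
        t1 = self._table({"A": 1.0})
        t2 = self._table({"A": -1.0})
        assert rb.shared_de(t1, t2) == (set(), set())

    def test_non_significant_genes_ignored(self):
        t1 = self._table({"A": 1.0, "B": 1.0})
        t2 = self._table({"A": 1.0, "B": 1.0})
        t2.loc["B", "de_flag"] = False
        high, _ = rb.shared_de(t1, t2)
        assert high == {"A"}


class TestCytotoxicScorer:
    def test_score_tracks_planted_activity(self, scored_default):
        scorer, truth = scored_default
        act = truth.cytotox_activity.loc[scorer.scores_.index]
        rho = stats.spearmanr(scorer.scores_, act).statistic
        assert rho > 0.9

    def test_transform_table_complete(self, scored_default):
        scorer, truth = scored_default
        table = scorer.transform()
        assert set(table.columns) == {"score", "bin", "naive_excluded"}
        assert table["naive_excluded"].sum() == scorer.naive_excluded_.sum()
        scored = table[~table["naive_excluded"]]
        n = len(scored)
        assert (scored["bin"] == "low").sum() == n // 10
        assert (scored["bin"] == "high").sum() == n // 10
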