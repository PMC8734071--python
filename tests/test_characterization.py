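import itertools

import numpy as np
import pandas as pd
import pytest

from stackstate import ChromSizes, HMMParams
from stackstate.characterization import (
    DatasetMetadata,
    differential_emission_tests,
    emission_cv,
    expression_by_state,
    expression_summary,
    greedy_summary_selection,
    mean_signal_by_state,
    naive_bayes_states,
    positional_expression,
    positional_expression_table,
)
from stackstate.segmentation import Segmentation


def seg_from(states, size, n_states, binsize=200):
    cs = ChromSizes({"chr1": size})
    return Segmentation.from_states({"chr1": np.asarray(states)}, cs, binsize=binsize, n_states=n_states)


def gene_df(rows):
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    return df.set_index("gene_id")


class TestExpressionByState:
    def test_single_gene_inside_single_state_returns_its_expression(self):
        seg = seg_from([0] * 10 + [1] * 10, 4_000, 2)
        genes = gene_df([("g1", "chr1", 200, 1_000, "+")])
        expr = pd.Series({"g1": 3.7})
        out = expression_by_state(seg, genes, expr)
        assert out[0] == pytest.approx(3.7)
        assert np.isnan(out[1])

    def test_two_genes_over_one_bin_length_normalized_average(self):
        # E = (2, 4), L = (100, 200): (2/100 + 4/200) / (1/100 + 1/200) = 8/3
        seg = seg_from([0], 200, 1)
        genes = gene_df([("g1", "chr1", 0, 100, "+"), ("g2", "chr1", 0, 200, "+")])
        expr = pd.Series({"g1": 2.0, "g2": 4.0})
        assert expression_by_state(seg, genes, expr)[0] == pytest.approx(8 / 3)

    def test_state_without_genes_is_missing(self):
        seg = seg_from([0, 1], 400, 2)
        genes = gene_df([("g1", "chr1", 0, 150, "+")])
        out = expression_by_state(seg, genes, pd.Series({"g1": 1.0}))
        assert np.isnan(out[1])

    def test_invariant_to_splitting_gene_across_bins_of_same_state(self):
        # the formula sums over bins: a gene spanning k bins of one state
        # contributes k identical terms to numerator and denominator
        seg = seg_from([0] * 20, 4_000, 1)
        one_bin = gene_df([("g1", "chr1", 0, 200, "+")])
        many_bins = gene_df([("g1", "chr1", 0, 2_000, "+")])
        expr = pd.Series({"g1": 5.0})
        assert expression_by_state(seg, one_bin, expr)[0] == pytest.approx(
            expression_by_state(seg, many_bins, expr)[0]
        )

    def test_summary_mean_and_cv_across_samples(self):
        seg = seg_from([0] * 10, 2_000, 1)
        genes = gene_df([("g1", "chr1", 0, 2_000, "+")])
        expr = pd.DataFrame({"s1": [1.0], "s2": [3.0]}, index=["g1"])
        out = expression_summary(seg, genes, expr)
        assert out["mean"].iloc[0] == pytest.approx(2.0)
        assert out["cv"].iloc[0] == pytest.approx(np.std([1, 3], ddof=1) / 2.0)


class TestPositionalExpression:
    def test_default_window_produces_251_offset_columns(self):
        seg = seg_from([0] * 300, 60_000, 1)
        genes = gene_df([("g1", "chr1", 30_000, 32_000, "+")])
        raw = positional_expression_table(seg, genes, pd.Series({"g1": 1.0}))
        assert raw.shape[1] == 251
        assert list(raw.columns[:2]) == [-25_000, -24_800]

    def test_constant_expression_survives_smoothing_unchanged(self):
        seg = seg_from([0] * 300, 60_000, 1)
        genes = gene_df(
            [("g1", "chr1", 30_000, 32_000, "+"), ("g2", "chr1", 31_000, 33_000, "-")]
        )
        expr = pd.DataFrame({"s1": [2.5, 2.5]}, index=["g1", "g2"])
        out = positional_expression(seg, genes, expr)
        assert out.shape[1] == 231
        np.testing.assert_allclose(out.to_numpy(), 2.5)

    def test_interior_smoothed_value_matches_moving_average_oracle(self, rng):
        states = rng.integers(0, 2, 600)
        seg = seg_from(states, 120_000, 2)
        genes = gene_df([("g1", "chr1", 60_000, 62_000, "+")])
        expr = pd.DataFrame({"s1": [4.0]}, index=["g1"])
        raw = positional_expression_table(seg, genes, expr["s1"]).to_numpy()
        out = positional_expression(seg, genes, expr).to_numpy()
        j = 50  # arbitrary interior offset (in the retained 231 columns)
        for s in range(2):
            window = raw[s, j : j + 21]
            expect = np.nanmean(window) if not np.isnan(window).all() else np.nan
            if np.isnan(expect):
                assert np.isnan(out[s, j])
            else:
                assert out[s, j] == pytest.approx(expect)

    def test_minus_strand_offsets_run_against_genome_orientation(self):
        states = np.array([0] * 100 + [1] * 200)
        seg = seg_from(states, 60_000, 2)
        # minus-strand gene with outer TSS at its end: downstream = lower coords
        genes = gene_df([("g1", "chr1", 10_000, 30_000, "-")])
        raw = positional_expression_table(seg, genes, pd.Series({"g1": 7.0}))
        # TSS base 29_999 -> bin 149 (state 1); offset +25000 -> bin 24 (state 0)
        assert raw.loc["S2", 0] == pytest.approx(7.0)
        assert raw.loc["S1", 25_000] == pytest.approx(7.0)
        assert np.isnan(raw.loc["S1", 0])

    def test_gene_without_strand_rejected(self):
        seg = seg_from([0] * 10, 2_000, 1)
        genes = gene_df([("g1", "chr1", 0, 400, ".")])
        with pytest.raises(ValueError):
            positional_expression_table(seg, genes, pd.Series({"g1": 1.0}))


class TestMeanSignalByState:
    def test_constant_values_give_constant_means(self, rng):
        seg = seg_from(rng.integers(0, 3, 50), 10_000, 3)
        pos = pd.DataFrame({"chrom": "chr1", "pos": rng.choice(10_000, 30, replace=False), "value": 0.5})
        np.testing.assert_allclose(mean_signal_by_state(seg, pos), 0.5)

    def test_two_values_average(self):
        seg = seg_from([0, 0], 400, 1)
        pos = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [10, 250], "value": [0.2, 0.8]})
        assert mean_signal_by_state(seg, pos)[0] == pytest.approx(0.5)

    def test_matches_brute_force_loop_with_missing_values(self, rng):
        states = rng.integers(0, 3, 50)
        seg = seg_from(states, 10_000, 3)
        n = 200
        positions = rng.choice(10_000, n, replace=False)
        values = rng.random(n)
        values[rng.random(n) < 0.2] = np.nan
        pos = pd.DataFrame({"chrom": "chr1", "pos": positions, "value": values})
        out = mean_signal_by_state(seg, pos)
        for s in range(3):
            vals = [
                v for p, v in zip(positions, values)
                if states[p // 200] == s and np.isfinite(v)
            ]
            if vals:
                assert out[s] == pytest.approx(np.mean(vals))
            else:
                assert np.isnan(out[s])


class TestEmissionCV:
    def _params(self, emissions):
        S = emissions.shape[0]
        return HMMParams(
            emissions=emissions,
            transitions=np.full((S, S), 1.0 / S),
            initial=np.full(S, 1.0 / S),
        )

    def test_identical_group_means_give_zero_cv(self):
        meta = DatasetMetadata(
            ["E1", "E2", "E3", "E4"], ["DNase"] * 4, ["Blood", "Blood", "Brain", "Brain"]
        )
        emissions = np.array([[0.3, 0.5, 0.4, 0.4]])  # both groups average 0.4
        out = emission_cv(self._params(emissions), meta, marks=("DNase",))
        assert out.loc[0, "DNase"] == pytest.approx(0.0)

    def test_hand_computed_cv_with_sample_sd(self):
        meta = DatasetMetadata(["E1", "E2"], ["H3K27ac"] * 2, ["Blood", "Brain"])
        emissions = np.array([[0.2, 0.4]])
        out = emission_cv(self._params(emissions), meta, marks=("H3K27ac",))
        assert out.loc[0, "H3K27ac"] == pytest.approx(np.std([0.2, 0.4], ddof=1) / 0.3)

    def test_state_group_of_one_state_is_identity(self):
        meta = DatasetMetadata(["E1", "E2"], ["DNase"] * 2, ["Blood", "Brain"])
        emissions = np.array([[0.2, 0.4], [0.1, 0.1]])
        per_state = emission_cv(self._params(emissions), meta, marks=("DNase",))
        grouped = emission_cv(
            self._params(emissions), meta, marks=("DNase",), state_groups={"solo": [0]}
        )
        assert grouped.loc["solo", "DNase"] == pytest.approx(per_state.loc[0, "DNase"])


class TestDifferentialEmissionTests:
    def _metadata_with_combo_count(self, n_groups=19):
        """Synthetic dataset metadata emulating the reference feature panel:
        five marks profiled in every tissue group, three sparser marks missing
        from some groups, yielding 142 testable (mark, group) pairs."""
        groups = [f"G{i:02d}" for i in range(n_groups)]
        eids, marks, gps = [], [], []
        full = ["H3K9me3", "H3K4me1", "H3K4me3", "H3K27me3", "H3K36me3"]
        sparse = {"H3K27ac": 19, "H3K9ac": 16, "DNase": 12}
        for m in full:
            for g in groups:
                for r in range(2):
                    eids.append(f"E{len(eids):04d}")
                    marks.append(m)
                    gps.append(g)
        for m, k in sparse.items():
            for g in groups[:k]:
                for r in range(2):
                    eids.append(f"E{len(eids):04d}")
                    marks.append(m)
                    gps.append(g)
        return DatasetMetadata(eids, marks, gps)

    def test_family_of_14200_tests_yields_published_bonferroni_threshold(self, rng):
        meta = self._metadata_with_combo_count()
        S = 100
        params = HMMParams(
            emissions=rng.uniform(0.05, 0.95, (S, len(meta))),
            transitions=np.full((S, S), 1.0 / S),
            initial=np.full(S, 1.0 / S),
        )
        result = differential_emission_tests(params, meta, alpha=0.05)
        assert result.n_tests == 14_200
        assert result.threshold == pytest.approx(0.05 / 14_200)
        assert float(f"{result.threshold:.1e}") == 3.5e-6
        assert result.threshold * result.n_tests == 0.05

    def test_identically_distributed_groups_are_not_significant(self, rng):
        meta = DatasetMetadata(
            [f"E{i}" for i in range(60)],
            ["DNase"] * 60,
            ["Blood"] * 30 + ["Brain"] * 30,
        )
        emissions = rng.uniform(0, 1, (3, 60))
        params = HMMParams(
            emissions=emissions, transitions=np.full((3, 3), 1 / 3), initial=np.full(3, 1 / 3)
        )
        result = differential_emission_tests(params, meta, marks=("DNase",), alpha=0.05)
        assert not result.table["significant"].any()

    def test_small_sample_pvalue_matches_exact_rank_enumeration(self):
        meta = DatasetMetadata(
            ["E1", "E2", "E3", "E4"], ["DNase"] * 4, ["Blood", "Blood", "Brain", "Brain"]
        )
        emissions = np.array([[0.9, 0.9, 0.1, 0.1]])
        params = HMMParams(
            emissions=emissions, transitions=np.array([[1.0]]), initial=np.array([1.0])
        )
        result = differential_emission_tests(params, meta, marks=("DNase",))
        p = result.table.set_index("group").loc["Blood", "p_value"]
        # exhaustive enumeration over the 4!/(2!2!) = 6 rank assignments:
        # only the observed one has U = 4, so one-sided p = 1/6
        x, y = [0.9, 0.9], [0.1, 0.1]
        count = 0
        total = 0
        pool = x + y
        observed_u = sum(1 for a in x for b in y if a > b)
        for labels in set(itertools.permutations([1, 1, 0, 0])):
            xs = [v for v, l in zip(pool, labels) if l]
            ys = [v for v, l in zip(pool, labels) if not l]
            u = sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
                1 for a in xs for b in ys if a == b
            )
            total += 1
            if u >= observed_u:
                count += 1
        assert p == pytest.approx(count / total)
        assert p == pytest.approx(1 / 6)


class TestGreedySummarySelection:
    def _fixture(self, rng):
        # 3 states, 4 features; feature 0 alone separates all states
        emissions = np.array(
            [
                [0.99, 0.5, 0.5, 0.5],
                [0.01, 0.5, 0.5, 0.5],
                [0.50, 0.6, 0.4, 0.5],
            ]
        )
        params = HMMParams(
            emissions=emissions, transitions=np.full((3, 3), 1 / 3), initial=np.full(3, 1 / 3)
        )
        assign = rng.integers(0, 3, 500)
        obs = (rng.random((500, 4)) < emissions[assign]).astype(np.uint8)
        return params, obs, assign

    def test_zero_features_requested_gives_empty_selection(self, rng):
        params, obs, assign = self._fixture(rng)
        selected, agreements = greedy_summary_selection(params, obs, assign, k=0)
        assert selected == [] and agreements == []

    def test_single_feature_model_selects_that_feature(self, rng):
        params = HMMParams(
            emissions=np.array([[0.9], [0.1]]),
            transitions=np.full((2, 2), 0.5),
            initial=np.array([0.5, 0.5]),
        )
        obs = rng.integers(0, 2, (50, 1)).astype(np.uint8)
        assign = rng.integers(0, 2, 50)
        selected, _ = greedy_summary_selection(params, obs, assign, k=1)
        assert selected == [0]

    def test_most_discriminative_feature_selected_first(self, rng):
        params, obs, assign = self._fixture(rng)
        selected, agreements = greedy_summary_selection(params, obs, assign, k=3)
        assert selected[0] == 0

    def test_agreement_non_decreasing_on_separable_fixture(self, rng):
        params, obs, assign = self._fixture(rng)
        _, agreements = greedy_summary_selection(params, obs, assign, k=4)
        assert all(b >= a - 1e-12 for a, b in zip(agreements, agreements[1:]))

    def test_requesting_more_features_than_exist_rejected(self, rng):
        params, obs, assign = self._fixture(rng)
        with pytest.raises(ValueError):
            greedy_summary_selection(params, obs, assign, k=10)

    def test_naive_bayes_matches_direct_computation(self, rng):
        params, obs, assign = self._fixture(rng)
        priors = np.bincount(assign, minlength=3) / len(assign)
        out = naive_bayes_states(params, obs, [0, 2], priors)
        # direct per-row computation
        for t in rng.choice(len(obs), 20, replace=False):
            scores = np.log(priors).copy()
            for d in (0, 2):
                p = params.emissions[:, d]
                scores += np.log(p) if obs[t, d] == 1 else np.log(1 - p)
            assert out[t] == np.argmax(scores)
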