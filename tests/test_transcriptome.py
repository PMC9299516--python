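"""CPM, DEG filter, BH/hypergeometric oracles, activation scores, trajectories, PCA."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nocicalc import (
    GeneSet,
    SimCountsConfig,
    activation_score,
    bh_adjust,
    compute_cpm,
    differential_expression,
    find_overrepresented,
    group_trajectories,
    over_representation,
    score_matrix,
    simulate_counts,
    top_variable_pca,
)
from nocicalc.errors import InputError, StatisticsError


# ---------------------------------------------------------------- oracles
def bh_stepup_oracle(p):
    """Literal Benjamini–Hochberg step-up: adj_(i) = min_{j≥i} p_(j)·m/j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * m / rank)
        adjusted[idx] = running_min
    return adjusted


def hypergeom_tail_oracle(k, universe, set_size, n_draws):
    """P(X ≥ k) by explicit enumeration of the hypergeometric tail."""
    total = 0.0
    for i in range(k, min(set_size, n_draws) + 1):
        total += (math.comb(set_size, i) * math.comb(universe - set_size, n_draws - i)
                  / math.comb(universe, n_draws))
    return total


class TestComputeCPM:
    def test_ten_reads_per_million_is_ten_cpm(self):
        counts = pd.DataFrame({"s1": [10, 999_990]}, index=["gA", "filler"])
        cpm = compute_cpm(counts)
        assert cpm.loc["gA", "s1"] == pytest.approx(10.0)

    def test_all_zero_gene_and_column_sums(self):
        counts = pd.DataFrame({"s1": [0, 100], "s2": [0, 50]}, index=["gA", "gB"])
        cpm = compute_cpm(counts)
        assert (cpm.loc["gA"] == 0).all()
        assert np.allclose(cpm.sum(axis=0), 1e6)

    def test_zero_total_sample_rejected(self):
        with pytest.raises(InputError):
            compute_cpm(pd.DataFrame({"s1": [0, 0]}, index=["gA", "gB"]))


class TestBHAdjust:
    def test_hand_computed_stepup(self):
        adjusted = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adjusted, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            bh_adjust([0.5, 1.5])

    def test_agrees_with_exhaustive_oracle_over_many_seeds(self):
        for seed in range(1000):
            rng = np.random.default_rng(seed)
            p = rng.random(rng.integers(1, 21))
            np.testing.assert_allclose(bh_adjust(p), bh_stepup_oracle(p), atol=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_adjusted_values_are_valid(self, p):
        adjusted = bh_adjust(p)
        assert np.all(adjusted >= np.asarray(p) - 1e-12)
        assert np.all(adjusted <= 1.0 + 1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adjusted[order]) >= -1e-12)  # order-preserving


class TestOverRepresentation:
    def test_full_overlap_exact_value(self):
        universe = [f"g{i}" for i in range(20)]
        gene_set = universe[:5]
        p = over_representation(set(gene_set), gene_set, universe)
        assert p == pytest.approx(1.0 / math.comb(20, 5), rel=1e-9)  # ≈ 6.45e-5

    def test_degenerate_all_equal_sets(self):
        universe = [f"g{i}" for i in range(10)]
        assert over_representation(set(universe), universe, universe) == pytest.approx(1.0)

    def test_overlap_at_expectation_not_enriched(self):
        # 10 of 30 genes in the set, 9 DEGs → expected overlap 3; observing 3 is typical
        universe = [f"g{i}" for i in range(30)]
        gene_set = universe[:10]
        degs = set(universe[:3]) | set(universe[10:16])  # overlap exactly 3
        assert over_representation(degs, gene_set, universe) >= 0.5

    def test_empty_universe_rejected(self):
        with pytest.raises(InputError):
            over_representation({"g1"}, ["g1"], [])

    def test_agrees_with_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            m = int(rng.integers(5, 31))
            universe = [f"g{i}" for i in range(m)]
            set_size = int(rng.integers(1, m + 1))
            n_deg = int(rng.integers(1, m + 1))
            gene_set = list(rng.choice(universe, size=set_size, replace=False))
            degs = set(rng.choice(universe, size=n_deg, replace=False))
            k = len(degs & set(gene_set))
            expected = hypergeom_tail_oracle(k, m, set_size, n_deg) if k > 0 else 1.0
            assert over_representation(degs, gene_set, universe) == pytest.approx(
                expected, rel=1e-9)

    def test_find_overrepresented_flags_enriched_set(self):
        universe = [f"g{i}" for i in range(100)]
        enriched = GeneSet("S1", "enriched", tuple(universe[:10]))
        random_set = GeneSet("S2", "background", tuple(universe[50:60]))
        degs = set(universe[:12])
        res = find_overrepresented(degs, [enriched, random_set], universe)
        res = res.set_index("set_id")
        assert res.loc["S1", "is_ogo"]
        assert not res.loc["S2", "is_ogo"]


def _toy_counts(fold_changes, n_rep=2, base=1000, filler_total=10_000_000):
    """Two-group counts with exact CPM fold changes (equal library sizes)."""
    genes = [f"g{i}" for i in range(len(fold_changes))]
    base_col = [base] * len(fold_changes)
    treat_col = [int(round(base * f)) for f in fold_changes]
    filler_base = filler_total - sum(base_col)
    filler_treat = filler_total - sum(treat_col)
    data = {}
    meta = []
    for r in range(n_rep):
        data[f"tp0_rep{r}"] = base_col + [filler_base]
        meta.append({"sample": f"tp0_rep{r}", "timepoint": 0, "replicate": r})
    for r in range(n_rep):
        data[f"tp1_rep{r}"] = treat_col + [filler_treat]
        meta.append({"sample": f"tp1_rep{r}", "timepoint": 1, "replicate": r})
    counts = pd.DataFrame(data, index=genes + ["filler"])
    return counts, pd.DataFrame(meta), genes


class TestDifferentialExpression:
    def test_identical_groups_are_not_deg(self):
        counts, meta, genes = _toy_counts([1.0, 1.0, 1.0])
        res = differential_expression(counts, meta)
        sub = res[res["gene"].isin(genes)]
        assert np.allclose(sub["log2fc"], 0.0)
        assert not sub["is_deg"].any()

    def test_fold_change_two_boundary(self):
        # all genes significant → retained DEGs are exactly those with FC ≥ 2
        fold_changes = [1.2, 1.5, 1.9, 2.0, 3.0]
        counts, meta, genes = _toy_counts(fold_changes)
        pvals = pd.DataFrame({1: [0.001] * len(counts)}, index=counts.index)
        res = differential_expression(counts, meta, pseudocount=0.0, p_values=pvals)
        retained = set(res.loc[res["is_deg"], "gene"])
        expected = {g for g, f in zip(genes, fold_changes) if f >= 2.0}
        assert retained == expected

    def test_deg_filter_is_idempotent_and_order_independent(self):
        counts, meta, _ = _toy_counts([1.0, 2.5, 4.0, 0.2])
        res1 = differential_expression(counts, meta)
        shuffled = counts.sample(frac=1.0, random_state=1)
        res2 = differential_expression(shuffled, meta)
        merged = res1.set_index("gene")["is_deg"].sort_index()
        merged2 = res2.set_index("gene")["is_deg"].sort_index()
        pd.testing.assert_series_equal(merged, merged2)

    def test_missing_baseline_rejected(self):
        counts, meta, _ = _toy_counts([1.0])
        with pytest.raises(InputError):
            differential_expression(counts, meta, baseline=99)

    def test_planted_deg_recovery_sensitivity_and_fdr(self):
        cfg = SimCountsConfig(n_genes=2000, n_timepoints=2, n_replicates=3,
                              library_size_mean=2e6, dispersion=0.05,
                              deg_fraction=0.05, effect_log2fc_range=(1.5, 3.0),
                              seed=10)
        counts, meta, truth = simulate_counts(cfg)
        res = differential_expression(counts, meta)
        called = set(res.loc[res["is_deg"], "gene"])
        planted = set(truth["gene"])
        sensitivity = len(called & planted) / len(planted)
        fdr = len(called - planted) / max(len(called), 1)
        assert sensitivity >= 0.8
        assert fdr <= 0.1


class TestActivationScore:
    def _stats(self, log2fcs, degs):
        genes = [f"g{i}" for i in range(len(log2fcs))]
        return pd.DataFrame({
            "gene": genes, "timepoint": 1, "log2fc": log2fcs,
            "fc": np.power(2.0, log2fcs), "is_deg": degs,
        })

    def test_worked_example_product_is_eighty(self):
        # 10 measured members, 4 DEGs with |log2FC| {1, 2, 3, 2} → 40% × 2.0 = 80
        log2fcs = [1.0, 2.0, -3.0, 2.0] + [0.1] * 6
        degs = [True] * 4 + [False] * 6
        gs = GeneSet("S", "s", tuple(f"g{i}" for i in range(10)))
        score = activation_score(gs, self._stats(log2fcs, degs))
        assert score.pct_significant == pytest.approx(40.0)
        assert score.mean_fold_change == pytest.approx(2.0)
        assert score.score == pytest.approx(80.0)

    def test_no_deg_members_scores_zero(self):
        gs = GeneSet("S", "s", ("g0", "g1"))
        score = activation_score(gs, self._stats([0.5, 0.2], [False, False]))
        assert score.score == 0.0

    def test_all_members_deg_at_unit_log2fc_scores_hundred(self):
        gs = GeneSet("S", "s", ("g0", "g1"))
        score = activation_score(gs, self._stats([1.0, -1.0], [True, True]))
        assert score.score == pytest.approx(100.0)

    def test_denominator_is_measured_members_only(self):
        # the set names 4 genes but only 2 are measured; 1 DEG → 50%
        gs = GeneSet("S", "s", ("g0", "g1", "unmeasured_a", "unmeasured_b"))
        score = activation_score(gs, self._stats([2.0, 0.0], [True, False]))
        assert score.pct_significant == pytest.approx(50.0)

    def test_no_measured_members_rejected(self):
        gs = GeneSet("S", "s", ("absent",))
        with pytest.raises(InputError):
            activation_score(gs, self._stats([1.0], [True]))

    def test_score_equals_product_of_reported_factors(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(2, 30))
            log2fcs = rng.normal(0, 2, n)
            degs = rng.random(n) < 0.4
            gs = GeneSet("S", "s", tuple(f"g{i}" for i in range(n)))
            score = activation_score(gs, self._stats(log2fcs, degs))
            assert score.score == pytest.approx(
                score.pct_significant * score.mean_fold_change)


class TestGroupTrajectories:
    def test_two_member_group_mean_and_sem(self):
        scores = pd.DataFrame({0: [0.0, 0.0], 1: [10.0, 20.0]},
                              index=["S1", "S2"]).rename_axis("set_id")
        traj = group_trajectories(scores, {"S1": "g", "S2": "g"}, reference_timepoint=0)
        row = traj[(traj["group"] == "g") & (traj["timepoint"] == 1)].iloc[0]
        assert row["mean_score"] == pytest.approx(15.0)
        assert row["sem"] == pytest.approx(5.0)

    def test_constant_scores_give_null_p(self):
        scores = pd.DataFrame({0: [5.0, 7.0], 1: [5.0, 7.0], 2: [5.0, 7.0]},
                              index=["S1", "S2"]).rename_axis("set_id")
        traj = group_trajectories(scores, {"S1": "g", "S2": "g"}, reference_timepoint=0)
        later = traj[traj["timepoint"] != 0]
        assert np.allclose(later["p_vs_reference"], 1.0)

    def test_monotone_increase_becomes_significant(self):
        rng = np.random.default_rng(1)
        sets = [f"S{i}" for i in range(8)]
        data = {t: 10.0 * t + rng.normal(0, 0.5, 8) for t in range(4)}
        scores = pd.DataFrame(data, index=sets).rename_axis("set_id")
        traj = group_trajectories(scores, {s: "g" for s in sets}, reference_timepoint=0)
        last = traj[traj["timepoint"] == 3].iloc[0]
        assert last["p_vs_reference"] < 0.05

    def test_unknown_reference_rejected(self):
        scores = pd.DataFrame({0: [1.0]}, index=["S1"]).rename_axis("set_id")
        with pytest.raises(StatisticsError):
            group_trajectories(scores, {"S1": "g"}, reference_timepoint=9)


class TestTopVariablePCA:
    def test_duplicated_samples_have_identical_coordinates(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.integers(0, 1000, (100, 3)),
                              index=[f"g{i}" for i in range(100)],
                              columns=["a", "b", "c"])
        counts["b"] = counts["a"]
        cpm = compute_cpm(counts)
        coords, _ = top_variable_pca(cpm, n=50)
        np.testing.assert_allclose(coords.loc["a"], coords.loc["b"], atol=1e-9)

    def test_explained_variance_fractions_sum_to_at_most_one(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.integers(1, 1000, (60, 6)),
                              index=[f"g{i}" for i in range(60)],
                              columns=[f"s{i}" for i in range(6)])
        _, explained = top_variable_pca(compute_cpm(counts), n=30)
        assert explained.sum() <= 1.0 + 1e-9

    def test_n_larger_than_gene_count_clamps_with_warning(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(rng.integers(1, 1000, (20, 4)),
                              index=[f"g{i}" for i in range(20)],
                              columns=[f"s{i}" for i in range(4)])
        with pytest.warns(UserWarning, match="clamping"):
            top_variable_pca(compute_cpm(counts), n=500)

    def test_maturation_gradient_dominates_first_component(self):
        # ramped planted effects create a time gradient; PC1 must track it
        cfg = SimCountsConfig(n_genes=1000, n_timepoints=7, n_replicates=3,
                              library_size_mean=1e6, dispersion=0.05,
                              deg_fraction=0.2, effect_log2fc_range=(1.0, 3.0),
                              effect_profile="ramp", seed=6)
        counts, meta, _ = simulate_counts(cfg)
        coords, _ = top_variable_pca(compute_cpm(counts), n=500)
        tp = meta.set_index("sample").loc[coords.index, "timepoint"].to_numpy()
        r = np.corrcoef(coords["PC1"], tp)[0, 1]
        assert abs(r) >= 0.9


class TestScoreMatrixIntegration:
    def test_planted_module_scores_rise_over_time(self):
        cfg = SimCountsConfig(n_genes=600, n_timepoints=3, n_replicates=3,
                              library_size_mean=1e6, dispersion=0.05,
                              deg_fraction=0.1, effect_log2fc_range=(2.0, 3.0),
                              effect_profile="ramp", seed=7)
        counts, meta, truth = simulate_counts(cfg)
        res = differential_expression(counts, meta)
        planted = list(truth["gene"])[:20]
        unaffected = [g for g in counts.index if g not in set(truth["gene"])][:20]
        sets = [GeneSet("HIT", "planted", tuple(planted)),
                GeneSet("BG", "background", tuple(unaffected))]
        scores = score_matrix(sets, res)
        assert scores.loc["HIT", 2] > scores.loc["HIT", 1] >= 0.0
        assert scores.loc["HIT", 2] > 10 * max(scores.loc["BG", 2], 1e-9)
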