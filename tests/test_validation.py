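import numpy as np
import pandas as pd
import pytest

from neurocpm import (
    CPMDataset,
    EdgeMask,
    compute_confound_masks,
    cross_site_validation,
    evaluate_spearman,
    generate_cohort,
    loo_cross_validation,
    permutation_pvalue,
    permutation_test,
    split_half_validation,
    stratified_split,
)
from neurocpm.validation import consensus_edges

import oracles
from conftest import small_config


class TestEvaluateSpearman:
    def test_monotone_agreement(self):
        assert evaluate_spearman([1, 2, 3], [10, 20, 30])[0] == pytest.approx(1.0)

    def test_monotone_disagreement(self):
        assert evaluate_spearman([1, 2, 3], [30, 20, 10])[0] == pytest.approx(-1.0)

    def test_midrank_tie_handling_by_hand(self):
        # x=[1,2,2,3] -> ranks [1, 2.5, 2.5, 4]; rs = 4.5/sqrt(22.5)
        rs, _ = evaluate_spearman([1, 2, 2, 3], [1, 3, 2, 4])
        assert rs == pytest.approx(4.5 / np.sqrt(22.5), abs=1e-12)
        assert rs == pytest.approx(0.9486832980505138, abs=1e-12)

    def test_matches_hand_ranking_oracle_with_ties(self, rng):
        for _ in range(20):
            x = rng.integers(0, 5, 8).astype(float)  # ties likely
            y = rng.integers(0, 5, 8).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rs, _ = evaluate_spearman(x, y)
            assert rs == pytest.approx(oracles.spearman_loop(x, y), abs=1e-12)

    def test_constant_vector_degenerate(self):
        rs, p = evaluate_spearman([1.0, 1.0, 1.0], [1, 2, 3])
        assert np.isnan(rs) and np.isnan(p)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            evaluate_spearman([1, 2], [3, 4])


class TestPermutationPvalue:
    def test_observed_above_all_nulls(self):
        null = np.linspace(-0.5, 0.4, 5000)
        assert permutation_pvalue(0.5, null) == pytest.approx(1 / 5001)

    def test_partial_exceedance(self):
        null = np.concatenate([np.full(184, 0.9), np.full(4816, -0.9)])
        assert permutation_pvalue(0.5, null) == pytest.approx(185 / 5001)

    def test_observed_below_all_nulls(self):
        assert permutation_pvalue(-1.0, np.zeros(100)) == 1.0

    def test_ties_count_as_exceedance(self):
        assert permutation_pvalue(0.3, np.array([0.3, 0.1])) == pytest.approx(2 / 3)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            permutation_pvalue(0.5, [])


def _dataset(cohort):
    return cohort.to_dataset()


class TestLOOCrossValidation:
    def test_matches_naive_per_fold_oracle(self, rng):
        # tiny cohort: full per-fold protocol spelled out with scalar calls
        cfg = small_config(seed=3, node_count=10, n_signal_edges=6,
                           n_motion_edges=4, n_site_edges=4,
                           n_per_site_group={("GU", "TD"): 8, ("GU", "ASD"): 7,
                                             ("KK", "TD"): 9, ("KK", "ASD"): 6})
        cohort = generate_cohort(cfg)
        ds = _dataset(cohort)
        valid = rng.random(ds.edges.shape[1]) > 0.15
        mask = EdgeMask(ds.node_count, valid)
        res = loo_cross_validation(ds, "inhibit", "negative", mask)
        expected = oracles.naive_loo_predictions(
            ds.edges, ds.behavior("inhibit"), valid, 0.01, "negative"
        )
        assert np.max(np.abs(res.predicted - expected)) <= 1e-10

    def test_planted_effect_recovered(self, small_cohort):
        ds = _dataset(small_cohort)
        mask = compute_confound_masks(ds)
        res = loo_cross_validation(ds, "inhibit", "negative", mask)
        assert res.rs > 0.3
        assert res.gate_passed()

    def test_order_invariance(self, small_cohort, rng):
        ds = _dataset(small_cohort)
        mask = compute_confound_masks(ds)
        res = loo_cross_validation(ds, "inhibit", "negative", mask)
        order = rng.permutation(ds.n)
        res_perm = loo_cross_validation(ds.subset(order), "inhibit", "negative", mask)
        assert np.allclose(res.predicted[order], res_perm.predicted, atol=1e-10)
        assert res_perm.rs == pytest.approx(res.rs, abs=1e-12)

    def test_determinism(self, small_cohort):
        ds = _dataset(small_cohort)
        mask = compute_confound_masks(ds)
        r1 = loo_cross_validation(ds, "inhibit", "negative", mask)
        r2 = loo_cross_validation(ds, "inhibit", "negative", mask)
        assert np.array_equal(r1.predicted, r2.predicted)

    def test_small_cohort_refused(self, rng):
        pheno = pd.DataFrame(
            {"participant_id": [f"s{i}" for i in range(8)],
             "brief_inhibit_t": rng.normal(50, 10, 8)}
        )
        ds = CPMDataset(pheno, rng.standard_normal((8, 45)), 10)
        with pytest.raises(ValueError, match="at least 10"):
            loo_cross_validation(ds, "inhibit", "negative", EdgeMask.all_valid(10))

    def test_consensus_frequencies_bounded(self, small_cohort):
        ds = _dataset(small_cohort)
        mask = compute_confound_masks(ds)
        res = loo_cross_validation(ds, "inhibit", "negative", mask)
        freq = res.metadata["selection_frequency"]
        assert freq.min() >= 0 and freq.max() <= 1
        cons = consensus_edges(res, ds.node_count, threshold=1.0)
        planted = set(map(tuple, small_cohort.ground_truth["signal_edges"]))
        # every consensus edge should overwhelmingly be a planted one
        hits = sum(1 for (e, _) in cons if e in planted)
        assert hits / max(len(cons), 1) > 0.8


class TestTrainOnlyMaskScope:
    def test_foldwise_rows_match_subset_masks(self, rng):
        from neurocpm import combine_masks, compute_motion_mask, compute_site_mask
        from neurocpm.masking import foldwise_confound_valid

        node_count, n = 10, 24
        E = rng.standard_normal((n, 45))
        motion = rng.uniform(0.1, 3.0, n)
        site = np.array(["GU"] * 12 + ["KK"] * 12)
        valid = foldwise_confound_valid(E, motion, site, node_count=node_count)
        assert valid.shape == (n, 45)
        for i in (0, 7, 23):
            train = np.arange(n) != i
            expected = combine_masks([
                compute_motion_mask(E[train], motion[train], node_count=node_count),
                compute_site_mask(E[train], site[train], node_count=node_count),
            ]).valid
            assert np.array_equal(valid[i], expected)

    def test_foldwise_mask_confines_edges_per_fold(self, small_cohort):
        # invalidating a strongly planted edge in fold 0 only must change
        # fold 0's prediction and no other
        ds = small_cohort.to_dataset()
        mask = compute_confound_masks(ds)
        base = loo_cross_validation(ds, "inhibit", "negative", mask,
                                    consensus=False)
        freq_mask = loo_cross_validation(ds, "inhibit", "negative", mask)
        freq = freq_mask.metadata["selection_frequency"]
        strong = int(np.argmax(freq))
        per_fold = np.tile(mask.valid, (ds.n, 1))
        per_fold[0, strong] = False
        altered = loo_cross_validation(ds, "inhibit", "negative", per_fold,
                                       consensus=False)
        assert altered.predicted[0] != base.predicted[0]
        assert np.array_equal(altered.predicted[1:], base.predicted[1:])

    def test_pipeline_runs_with_train_only_scope(self, small_cohort):
        from neurocpm import AnalysisConfig, analyze

        ds = small_cohort.to_dataset()
        cfg = AnalysisConfig(mask_scope="train_only", n_perm=30)
        result = analyze(ds, "inhibit", "negative", config=cfg, seed=1)
        assert result.loo.rs > 0.3
        assert isinstance(result.mask, np.ndarray)
        gl = analyze(ds, "inhibit", "negative",
                     config=AnalysisConfig(mask_scope="global"),
                     run_permutation=False)
        # the two scopes agree closely on a clean planted cohort
        assert result.loo.rs == pytest.approx(gl.loo.rs, abs=0.15)


class TestPermutationTest:
    def test_shuffled_behavior_is_null(self, small_cohort, rng):
        ds = _dataset(small_cohort)
        pheno = ds.phenotype.copy()
        pheno["brief_inhibit_t"] = rng.permutation(pheno["brief_inhibit_t"].to_numpy())
        shuffled = CPMDataset(pheno, ds.edges, ds.node_count)
        mask = compute_confound_masks(shuffled)
        perm = permutation_test(shuffled, "inhibit", "negative", mask,
                                n_perm=100, seed=7)
        lo, hi = np.quantile(perm.null_rs, [0.025, 0.975])
        assert lo - 0.1 <= perm.observed_rs <= hi + 0.1
        assert perm.p_perm > 1 / 101

    def test_planted_effect_significant(self, small_cohort):
        ds = _dataset(small_cohort)
        mask = compute_confound_masks(ds)
        perm = permutation_test(ds, "inhibit", "negative", mask, n_perm=100, seed=3)
        assert perm.p_perm <= 0.05
        assert perm.p_perm >= 1 / 101  # lattice lower bound

    def test_seed_reproducibility(self, small_cohort):
        ds = _dataset(small_cohort)
        mask = compute_confound_masks(ds)
        p1 = permutation_test(ds, "inhibit", "negative", mask, n_perm=30, seed=5)
        p2 = permutation_test(ds, "inhibit", "negative", mask, n_perm=30, seed=5)
        assert np.array_equal(p1.null_rs, p2.null_rs)
        p3 = permutation_test(ds, "inhibit", "negative", mask, n_perm=30, seed=6)
        assert not np.array_equal(p1.null_rs, p3.null_rs)

    def test_strength_refit_mode_agrees_on_planted_effect(self, small_cohort):
        # the reduced mode freezes observed-data selections; on a strong
        # planted effect both modes must call the result significant and
        # report the same observed rs
        ds = _dataset(small_cohort)
        mask = compute_confound_masks(ds)
        full = permutation_test(ds, "inhibit", "negative", mask,
                                n_perm=60, seed=2, perm_loo="full")
        fast = permutation_test(ds, "inhibit", "negative", mask,
                                n_perm=60, seed=2, perm_loo="strength_refit")
        assert fast.observed_rs == pytest.approx(full.observed_rs, abs=1e-12)
        assert full.p_perm <= 0.05 and fast.p_perm <= 0.05
        with pytest.raises(ValueError, match="perm_loo"):
            permutation_test(ds, "inhibit", "negative", mask,
                             n_perm=10, perm_loo="nope")

    def test_invalid_n_perm_rejected(self, small_cohort):
        ds = _dataset(small_cohort)
        with pytest.raises(ValueError):
            permutation_test(ds, "inhibit", "negative",
                             EdgeMask.all_valid(ds.node_count), n_perm=0)


class TestStratifiedSplit:
    def test_study_strata_arithmetic(self):
        # strata GU-TD 46, GU-ASD 36, KK-TD 145, KK-ASD 49 -> halves of 138
        site = ["GU"] * 82 + ["KK"] * 194
        group = ["TD"] * 46 + ["ASD"] * 36 + ["TD"] * 145 + ["ASD"] * 49
        a, b = stratified_split(site, group, seed=0)
        assert len(a) == len(b) == 138
        site = np.asarray(site)
        group = np.asarray(group)
        for st, (ca, cb) in {
            ("GU", "TD"): (23, 23),
            ("GU", "ASD"): (18, 18),
        }.items():
            na = np.sum((site[a] == st[0]) & (group[a] == st[1]))
            nb = np.sum((site[b] == st[0]) & (group[b] == st[1]))
            assert (na, nb) == (ca, cb)
        # odd strata split 72/73 and 24/25 in some order
        kk_td = (np.sum((site[a] == "KK") & (group[a] == "TD")),
                 np.sum((site[b] == "KK") & (group[b] == "TD")))
        kk_asd = (np.sum((site[a] == "KK") & (group[a] == "ASD")),
                  np.sum((site[b] == "KK") & (group[b] == "ASD")))
        assert sorted(kk_td) == [72, 73]
        assert sorted(kk_asd) == [24, 25]

    def test_same_seed_same_split(self):
        site = ["GU"] * 20 + ["KK"] * 20
        group = (["TD"] * 10 + ["ASD"] * 10) * 2
        a1, b1 = stratified_split(site, group, seed=42)
        a2, b2 = stratified_split(site, group, seed=42)
        assert np.array_equal(a1, a2) and np.array_equal(b1, b2)

    def test_halves_partition_cohort(self):
        site = ["GU"] * 21 + ["KK"] * 20
        group = ["TD"] * 11 + ["ASD"] * 10 + ["TD"] * 10 + ["ASD"] * 10
        a, b = stratified_split(site, group, seed=1)
        assert sorted(a.tolist() + b.tolist()) == list(range(41))

    def test_tiny_stratum_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            stratified_split(["GU", "GU", "KK"], ["TD", "TD", "TD"], seed=0)


class TestSplitHalf:
    def test_planted_effect_predicts_across_halves(self):
        cfg = small_config(seed=21, n_per_site_group={
            ("GU", "TD"): 30, ("GU", "ASD"): 24, ("KK", "TD"): 40, ("KK", "ASD"): 26})
        ds = _dataset(generate_cohort(cfg))
        res12, res21 = split_half_validation(ds, "inhibit", "negative", seed=9)
        assert res12.rs > 0
        assert res21.rs > 0
        assert res12.metadata["train_half"] == "1"
        assert "gate" in res12.metadata

    def test_split_half_deterministic_given_seed(self, small_cohort):
        ds = _dataset(small_cohort)
        a1, b1 = split_half_validation(ds, "inhibit", "negative", seed=4)
        a2, b2 = split_half_validation(ds, "inhibit", "negative", seed=4)
        assert np.array_equal(a1.predicted, a2.predicted)
        assert np.array_equal(b1.predicted, b2.predicted)


class TestCrossSite:
    def test_single_site_rejected(self, small_cohort):
        ds = _dataset(small_cohort)
        one_site = ds.subset(ds.column("site") == "GU")
        with pytest.raises(ValueError, match="two sites"):
            cross_site_validation(one_site, "inhibit", "negative")

    def test_confound_dominated_cohort_not_attempted(self):
        # site confound >> signal: within-site gates fail, no cross-prediction
        cfg = small_config(
            seed=5, node_count=30, beta_signal=0.01, delta_site=0.6,
            n_signal_edges=30, n_site_edges=60,
            n_per_site_group={("GU", "TD"): 25, ("GU", "ASD"): 15,
                              ("KK", "TD"): 40, ("KK", "ASD"): 20},
        )
        ds = _dataset(generate_cohort(cfg))
        directions = cross_site_validation(ds, "inhibit", "negative")
        assert all(not d.attempted for d in directions)
        assert all(d.prediction is None for d in directions)

    def test_strong_shared_signal_crosses_sites(self):
        cfg = small_config(
            seed=13, beta_signal=0.15, delta_site=0.0, n_site_edges=0,
            n_per_site_group={("GU", "TD"): 30, ("GU", "ASD"): 20,
                              ("KK", "TD"): 40, ("KK", "ASD"): 25},
        )
        ds = _dataset(generate_cohort(cfg))
        directions = cross_site_validation(ds, "inhibit", "negative")
        attempted = [d for d in directions if d.attempted]
        assert attempted, "strong shared signal should pass at least one gate"
        assert all(d.prediction.rs > 0 for d in attempted)
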