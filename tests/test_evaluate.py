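import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lymphoscape import (Signature, evaluate_signatures, gene_overlap,
                         gsz_correlation_clusters, joint_detection, pat_assign,
                         preprocess, resample_stability, roc)
from lymphoscape.evaluate import EMPTY_PAT, auc_score
from lymphoscape.scoring import GSZProfile, gsz
from lymphoscape.som import Portrait


def pair_count_auc(scores, positive_mask):
    """Brute-force oracle: fraction of (pos, neg) pairs correctly ordered,
    ties counted 1/2."""
    pos = scores[positive_mask]
    neg = scores[~positive_mask]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        r = roc(np.array([3.0, 2.5, 1.0, 0.5]), np.array([1, 1, 0, 0]), positive=1)
        assert r.auc == 1.0
        assert r.tpr[0] == 0.0 and r.tpr[-1] == 1.0
        assert r.fpr[0] == 0.0 and r.fpr[-1] == 1.0

    def test_all_ties_give_half(self):
        r = roc(np.ones(6), np.array([1, 1, 1, 0, 0, 0]), positive=1)
        assert r.auc == 0.5

    def test_worked_pair_example(self):
        scores = np.array([0.9, 0.4, 0.5, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert roc(scores, labels, positive=1).auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            roc(np.array([1.0, 2.0]), np.array([1, 1]), positive=1)

    def test_curve_monotone(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[0], labels[1] = 0, 1
        r = roc(scores, labels, positive=1)
        assert np.all(np.diff(r.tpr) >= 0) and np.all(np.diff(r.fpr) >= 0)

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.integers(-5, 5), min_size=2, max_size=12),
           st.data())
    def test_rank_formula_matches_pair_counting(self, raw, data):
        scores = np.array(raw, dtype=float)
        mask = np.array(data.draw(
            st.lists(st.booleans(), min_size=len(raw), max_size=len(raw))))
        if mask.all() or not mask.any():
            mask[0] = not mask[0]
        assert auc_score(scores, mask) == pytest.approx(
            pair_count_auc(scores, mask), abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(13)
        scores = rng.normal(size=50).round(1)  # force ties
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        assert auc_score(scores, y.astype(bool)) == pytest.approx(
            roc_auc_score(y, scores))


class TestEvaluateSignatures:
    def test_planted_signature_noise_free_auc_one(self):
        import pandas as pd

        from lymphoscape import generate_cohort
        from lymphoscape.simulate import CohortSpec, ModuleDef
        spec = CohortSpec(strata={"X": 10, "Y": 10},
                          modules=[ModuleDef("M", 20)],
                          activation=pd.DataFrame({"M": [1.0, 0.0]}, index=["X", "Y"]),
                          sigma_act=0.0, sigma_noise=0.0, background_genes=100, seed=2)
        em, truth = generate_cohort(spec)
        emc = preprocess(em)
        sig = Signature("m_up", "up", frozenset(truth.module_genes["M"]))
        table = evaluate_signatures(emc, [sig], em.sample_labels, ("X", "Y"))
        assert table.loc["m_up", "auc"] == 1.0

    def test_invariant_to_sample_and_gene_order(self, mini_cohort):
        from lymphoscape import ExpressionMatrix
        em, truth = mini_cohort
        emc = preprocess(em)
        sig = Signature("m_up", "up", frozenset(truth.module_genes["M"]))
        base = evaluate_signatures(emc, [sig], em.sample_labels, ("X", "Y"))
        rng = np.random.default_rng(0)
        gp = rng.permutation(emc.n_genes)
        sp = rng.permutation(emc.n_samples)
        shuffled = ExpressionMatrix([emc.gene_ids[i] for i in gp],
                                    [emc.sample_ids[j] for j in sp],
                                    emc.values[np.ix_(gp, sp)],
                                    em.sample_labels)
        perm = evaluate_signatures(shuffled, [sig], em.sample_labels, ("X", "Y"))
        assert perm.loc["m_up", "auc"] == pytest.approx(base.loc["m_up", "auc"])

    def test_unmatched_signature_flagged_not_dropped(self, mini_cohort):
        em, _ = mini_cohort
        emc = preprocess(em)
        ghost = Signature("ghost_up", "up", frozenset({"zz1", "zz2"}))
        table = evaluate_signatures(emc, [ghost], em.sample_labels, ("X", "Y"))
        assert bool(table.loc["ghost_up", "flagged"])
        assert np.isnan(table.loc["ghost_up", "auc"])


class TestDetectionMatrices:
    def _profiles(self):
        a = GSZProfile("a", ["s0", "s1", "s2", "s3"], np.array([1.0, 2.0, -1.0, -1.0]), 3, 10)
        b = GSZProfile("b", ["s0", "s1", "s2", "s3"], np.array([-1.0, -2.0, 1.0, 2.0]), 3, 10)
        return a, b

    def test_self_detection_is_one(self):
        a, _ = self._profiles()
        jd = joint_detection([a, a])
        assert jd.iloc[0, 1] == 1.0

    def test_disjoint_detections_zero(self):
        a, b = self._profiles()
        assert joint_detection([a, b]).iloc[0, 1] == 0.0

    def test_gene_overlap_counts(self):
        s1 = Signature("a_up", "up", frozenset({"g1", "g2", "g3"}))
        s2 = Signature("b_up", "up", frozenset({"g3", "g4"}))
        ov = gene_overlap([s1, s2])
        assert ov.loc["a_up", "a_up"] == 3
        assert ov.loc["a_up", "b_up"] == 1


class TestResampleStability:
    def test_full_fraction_equals_full_set(self, mini_cohort):
        em, truth = mini_cohort
        emc = preprocess(em)
        genes = set(truth.module_genes["M"])
        out = resample_stability(genes, [1.0], 5, emc, em.sample_labels,
                                 ("X", "Y"), seed=1)
        full = gsz(emc, genes, name="full")
        labels = em.labels_array()
        keep = np.isin(labels, ["X", "Y"])
        expected = auc_score(full.scores[keep], (labels == "X")[keep])
        assert np.allclose(out.loc[1.0, "aucs"], expected)

    def test_seeded_determinism(self, mini_cohort):
        em, truth = mini_cohort
        emc = preprocess(em)
        genes = set(truth.module_genes["M"])
        o1 = resample_stability(genes, [0.5], 10, emc, em.sample_labels, ("X", "Y"), seed=4)
        o2 = resample_stability(genes, [0.5], 10, emc, em.sample_labels, ("X", "Y"), seed=4)
        np.testing.assert_array_equal(o1.loc[0.5, "aucs"], o2.loc[0.5, "aucs"])

    def test_tiny_subset_rejected(self, mini_cohort):
        em, truth = mini_cohort
        emc = preprocess(em)
        with pytest.raises(ValueError, match="subset"):
            resample_stability(set(truth.module_genes["M"]), [0.02], 3, emc,
                               em.sample_labels, ("X", "Y"), seed=1)


class TestCorrelationClusters:
    def test_self_correlation_unity_and_anticorrelated_negative(self):
        a = GSZProfile("a", list("abcd"), np.array([1.0, 2.0, 3.0, 4.0]), 3, 10)
        b = GSZProfile("b", list("abcd"), -np.array([1.0, 2.0, 3.0, 4.0]), 3, 10)
        corr, _ = gsz_correlation_clusters([a, b])
        assert corr.loc["a", "a"] == pytest.approx(1.0)
        assert corr.loc["a", "b"] < 0

    def test_two_cluster_split_recovers_construction(self):
        rng = np.random.default_rng(3)
        base1 = rng.normal(size=40)
        base2 = -base1 + rng.normal(0, 0.2, size=40)
        mk = lambda n, b: GSZProfile(n, [f"s{i}" for i in range(40)],
                                     b + rng.normal(0, 0.1, 40), 5, 100)
        profiles = [mk("bl_up", base1), mk("gcb_up", base1), mk("dhl_up", base1),
                    mk("dlbcl_up", base2), mk("abc_up", base2)]
        _, cut = gsz_correlation_clusters(profiles)
        assert cut["bl_up"] == cut["gcb_up"] == cut["dhl_up"]
        assert cut["dlbcl_up"] == cut["abc_up"]
        assert cut["bl_up"] != cut["dlbcl_up"]


class TestPAT:
    def test_all_negative_portrait_empty_label(self, mini_landscape):
        res = mini_landscape
        neg = Portrait("neg", -np.ones(res.model.n_pixels),
                       res.model.grid_rows, res.model.grid_cols)
        labels, _ = pat_assign([neg], res.spots)
        assert str(labels[0]) == EMPTY_PAT

    def test_constructed_ad_pattern(self):
        from lymphoscape.spots import Spot, SpotSet
        values = np.zeros(25)
        spots = SpotSet([Spot("A", {0, 1}, {"g"}, 0, 1.0),
                         Spot("D", {5, 6}, {"h"}, 5, 1.0),
                         Spot("B", {20, 21}, {"k"}, 20, 1.0)], 5, 5, 0.0, 0.9)
        values[[0, 1]] = 2.0
        values[[5, 6]] = 1.5
        values[[20, 21]] = -1.0
        p = Portrait("s", values, 5, 5)
        labels, table = pat_assign([p], spots, activation_quantile=0.80)
        assert str(labels[0]) == "AD"
        assert table.loc["AD", "n_samples"] == 1

    def test_scaling_invariance(self, mini_landscape):
        res = mini_landscape
        base, _ = pat_assign(res.sample_portraits, res.spots)
        scaled_ports = [Portrait(p.sample_id, 7.3 * p.pixel_values,
                                 p.grid_rows, p.grid_cols)
                        for p in res.sample_portraits]
        scaled, _ = pat_assign(scaled_ports, res.spots)
        assert [str(l) for l in base] == [str(l) for l in scaled]

    @pytest.mark.parametrize("q_low,q_high", [(0.7, 0.9), (0.8, 0.95)])
    def test_raising_quantile_only_removes_letters(self, mini_landscape, q_low, q_high):
        res = mini_landscape
        low, _ = pat_assign(res.sample_portraits, res.spots, activation_quantile=q_low)
        high, _ = pat_assign(res.sample_portraits, res.spots, activation_quantile=q_high)
        for a, b in zip(low, high):
            assert set(b.letters) <= set(a.letters)
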