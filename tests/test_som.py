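import numpy as np
import pytest

from lymphoscape import (ExpressionMatrix, correlation_map, difference_portrait,
                         group_mean_portrait, portrait, portraits, preprocess,
                         quantile_normalize, train_som)
from lymphoscape.som import Portrait, _assign_bmu

from conftest import make_mini_spec
from lymphoscape import generate_cohort


def centered(values, n_genes=None, n_samples=None):
    values = np.asarray(values, dtype=float)
    g, s = values.shape
    em = ExpressionMatrix([f"g{i}" for i in range(g)], [f"s{j}" for j in range(s)], values)
    return preprocess(em)


class TestPreprocess:
    def test_row_means_zero(self, small_matrix):
        out = preprocess(small_matrix)
        assert np.abs(out.values.mean(axis=1)).max() < 1e-10

    def test_centering_idempotent(self, small_matrix):
        once = preprocess(small_matrix)
        twice = preprocess(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_quantile_normalization_of_permuted_samples(self):
        rng = np.random.default_rng(5)
        col = rng.normal(size=50)
        values = np.column_stack([col, rng.permutation(col), rng.permutation(col)])
        qn = quantile_normalize(values)
        for j in range(1, 3):
            np.testing.assert_allclose(np.sort(qn[:, j]), np.sort(qn[:, 0]))

    def test_single_sample_rejected(self):
        em = ExpressionMatrix(["g1", "g2"], ["s1"], [[1.0], [2.0]])
        with pytest.raises(ValueError, match="2 samples"):
            preprocess(em)


class TestTrainSOM:
    def test_non_centered_input_rejected(self, small_matrix):
        with pytest.raises(ValueError, match="centered"):
            train_som(small_matrix, rows=3, cols=3, epochs=2)

    def test_identical_genes_share_bmu(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(20, 10))
        base[5] = base[3]  # duplicated profile
        em = centered(base)
        em.values[5] = em.values[3]
        model = train_som(em, rows=3, cols=3, epochs=5)
        assert model.bmu["g3"] == model.bmu["g5"]

    def test_1x1_grid_prototype_is_mean_profile(self, small_matrix):
        em = preprocess(small_matrix)
        model = train_som(em, rows=1, cols=1, epochs=3)
        np.testing.assert_allclose(model.prototypes[0], em.values.mean(axis=0),
                                   atol=1e-10)

    def test_quantization_error_non_increasing(self, mini_cohort):
        # the first history entry measures the PCA initialization; the
        # non-increase property holds across the batch updates that follow
        em, _ = mini_cohort
        model = train_som(preprocess(em), rows=8, cols=8, epochs=10, seed=7)
        qe = np.array(model.quantization_errors)[1:]
        assert np.all(np.diff(qe) <= 1e-9)

    def test_bmu_matches_brute_force(self, mini_cohort):
        em, _ = mini_cohort
        emc = preprocess(em)
        model = train_som(emc, rows=4, cols=4, epochs=4, seed=7)
        X = emc.values
        brute = np.array([np.argmin(((model.prototypes - x) ** 2).sum(axis=1))
                          for x in X[:50]])
        fast, _ = _assign_bmu(X[:50], model.prototypes)
        np.testing.assert_array_equal(fast, brute)
        assert [model.bmu[g] for g in emc.gene_ids[:50]] == list(
            np.array([np.argmin(((model.prototypes - x) ** 2).sum(axis=1)) for x in X[:50]]))

    def test_anticorrelated_modules_separate_on_grid(self):
        """Planted anti-correlated modules land farther apart (Chebyshev)
        than genes within one module, across seeds."""
        for seed in (7, 8, 9):
            em, truth = generate_cohort(make_mini_spec(seed=seed))
            model = train_som(preprocess(em), rows=10, cols=10, epochs=10, seed=seed)
            coords = {g: np.array(divmod(p, 10)) for g, p in model.bmu.items()}

            def cheb(ga, gb):
                return np.abs(coords[ga] - coords[gb]).max()

            m_genes = truth.module_genes["M"]
            n_genes = truth.module_genes["N"]
            within = np.mean([cheb(a, b) for a in m_genes[:15] for b in m_genes[15:30]])
            across = np.mean([cheb(a, b) for a in m_genes[:15] for b in n_genes[:15]])
            assert across > within


class TestPortraits:
    def test_1x1_portrait_is_sample_mean(self, small_matrix):
        em = preprocess(small_matrix)
        model = train_som(em, rows=1, cols=1, epochs=2)
        p = portrait(model, "s0")
        assert p.pixel_values.shape == (1,)
        np.testing.assert_allclose(p.pixel_values[0], em.values[:, 0].mean(), atol=1e-10)

    def test_duplicated_samples_identical_portraits(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(60, 6))
        values[:, 5] = values[:, 2]
        em = ExpressionMatrix([f"g{i}" for i in range(60)],
                              [f"s{j}" for j in range(6)], values)
        model = train_som(preprocess(em), rows=3, cols=3, epochs=5)
        p2 = portrait(model, "s2")
        p5 = portrait(model, "s5")
        np.testing.assert_allclose(p2.pixel_values, p5.pixel_values)

    def test_unknown_sample_rejected(self, mini_landscape):
        with pytest.raises(KeyError):
            portrait(mini_landscape.model, "nope")

    def test_module_pixels_higher_in_activated_group(self, mini_landscape):
        """Pixels hosting module-M genes show higher portrait values in the
        subtype where M is planted up."""
        res = mini_landscape
        m_pixels = sorted({res.model.bmu[g] for g in res.truth.module_genes["M"]})
        x_mean = res.group_portraits["X"].pixel_values[m_pixels].mean()
        y_mean = res.group_portraits["Y"].pixel_values[m_pixels].mean()
        assert x_mean > y_mean


class TestGroupAndDifference:
    def test_self_difference_zero(self, mini_landscape):
        p = mini_landscape.sample_portraits[0]
        d = difference_portrait(p, p)
        np.testing.assert_array_equal(d.pixel_values, 0.0)

    def test_single_member_group(self, mini_landscape):
        res = mini_landscape
        sid = res.expression.sample_ids[0]
        solo = group_mean_portrait(res.sample_portraits, {sid: "solo"}, "solo")
        np.testing.assert_array_equal(solo.pixel_values,
                                      res.sample_portraits[0].pixel_values)

    def test_empty_group_rejected(self, mini_landscape):
        with pytest.raises(ValueError, match="no samples"):
            group_mean_portrait(mini_landscape.sample_portraits, {}, "ghost")

    def test_difference_extremes_in_planted_modules(self, mini_landscape):
        """The X-vs-Y difference portrait peaks inside module M pixels and
        dips inside module N pixels (the planted up/down pattern)."""
        res = mini_landscape
        diff = difference_portrait(res.group_portraits["X"], res.group_portraits["Y"])
        m_pixels = {res.model.bmu[g] for g in res.truth.module_genes["M"]}
        n_pixels = {res.model.bmu[g] for g in res.truth.module_genes["N"]}
        assert int(np.argmax(diff.pixel_values)) in m_pixels
        assert int(np.argmin(diff.pixel_values)) in n_pixels


def test_render_portrait_writes_png(tmp_path, mini_landscape):
    from lymphoscape.som import render_portrait
    out = tmp_path / "p.png"
    render_portrait(mini_landscape.sample_portraits[0], out)
    assert out.stat().st_size > 0


class TestCorrelationMap:
    def test_self_and_mirror(self):
        p = Portrait("a", np.array([1.0, -2.0, 3.0, 0.5]), 2, 2)
        q = Portrait("b", -p.pixel_values, 2, 2)
        corr = correlation_map([p, q])
        assert corr[0, 0] == pytest.approx(1.0)
        assert corr[0, 1] == pytest.approx(-1.0)
        np.testing.assert_allclose(corr, corr.T)

    def test_zero_variance_portrait_zeroed(self):
        p = Portrait("a", np.array([1.0, 2.0, 3.0, 4.0]), 2, 2)
        flat = Portrait("b", np.ones(4), 2, 2)
        corr = correlation_map([p, flat])
        assert corr[0, 1] == 0.0 and corr[1, 0] == 0.0

    def test_subtype_block_structure(self, mini_landscape):
        res = mini_landscape
        corr = correlation_map(res.sample_portraits)
        labels = res.expression.labels_array()
        same = labels[:, None] == labels[None, :]
        iu = np.triu_indices(len(labels), 1)
        assert corr[iu][same[iu]].mean() > corr[iu][~same[iu]].mean()
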