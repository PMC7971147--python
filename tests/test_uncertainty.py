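import numpy as np
import pytest

from microdl.models import build_unet
from microdl.uncertainty import (classification_uncertainty,
                                 compare_uncertainty_distributions,
                                 mc_dropout_predict, otsu_threshold,
                                 pixel_uncertainty)


def otsu_variance_curve(values, nbins=256):
    """Exhaustive between-class variance for every candidate bin threshold.

    Returns ``(thresholds, variances)``: candidate threshold k is the center
    of the last bin assigned to the background class.
    """
    counts, edges = np.histogram(values.ravel(), bins=nbins,
                                 range=(values.min(), values.max()))
    centers = (edges[:-1] + edges[1:]) / 2.0
    total = counts.sum()
    thresholds, variances = [], []
    for k in range(1, nbins):
        w0 = counts[:k].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (counts[:k] * centers[:k]).sum() / w0
        m1 = (counts[k:] * centers[k:]).sum() / w1
        thresholds.append(centers[k - 1])
        variances.append(w0 * w1 * (m0 - m1) ** 2)
    return np.array(thresholds), np.array(variances)


def otsu_oracle_check(values, thr, rel_tol=1e-12):
    """True if thr attains the exhaustive-search maximum variance."""
    thresholds, variances = otsu_variance_curve(values)
    attained = variances[np.argmin(np.abs(thresholds - thr))]
    return attained >= variances.max() * (1.0 - rel_tol)


class TestOtsu:
    def test_bimodal_map_separated_exactly(self):
        pm = np.concatenate([np.full(128, 0.1), np.full(128, 0.9)]).reshape(16, 16)
        thr, mask = otsu_threshold(pm)
        assert 0.1 < thr < 0.9
        np.testing.assert_array_equal(mask, pm > 0.5)

    def test_constant_map_yields_empty_mask(self):
        thr, mask = otsu_threshold(np.full((8, 8), 0.3))
        assert thr == pytest.approx(0.3)
        assert not mask.any()

    @pytest.mark.parametrize("seed", range(10))
    def test_threshold_maximizes_between_class_variance(self, seed):
        pm = np.random.default_rng(seed).random((16, 16))
        thr, mask = otsu_threshold(pm)
        assert otsu_oracle_check(pm, thr)
        np.testing.assert_array_equal(mask, pm > thr)


@pytest.fixture(scope="module")
def dropout_net():
    return build_unet(depth=2, base_filters=4, dropout_rate=0.25,
                      rng=np.random.default_rng(0))


class TestMCDropout:
    def test_returns_exactly_t_passes(self, dropout_net):
        x = np.random.default_rng(1).random((1, 16, 16)).astype(np.float32)
        passes = mc_dropout_predict(dropout_net, x, T=20,
                                    rng=np.random.default_rng(2))
        assert len(passes) == 20

    def test_zero_rate_dropout_gives_identical_passes(self):
        net = build_unet(depth=2, base_filters=4, dropout_rate=0.0,
                         rng=np.random.default_rng(0))
        x = np.random.default_rng(1).random((1, 16, 16)).astype(np.float32)
        passes = mc_dropout_predict(net, x, T=5, rng=np.random.default_rng(2))
        for p in passes[1:]:
            np.testing.assert_array_equal(p, passes[0])

    def test_fixed_seed_reproduces_pass_set(self, dropout_net):
        x = np.random.default_rng(1).random((1, 16, 16)).astype(np.float32)
        a = mc_dropout_predict(dropout_net, x, T=4, rng=np.random.default_rng(7))
        b = mc_dropout_predict(dropout_net, x, T=4, rng=np.random.default_rng(7))
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa, pb)

    def test_model_without_dropout_units_is_a_contract_error(self):
        class NoDropout:
            has_dropout = False
        with pytest.raises(ValueError, match="dropout"):
            mc_dropout_predict(NoDropout(), np.zeros((1, 8, 8)), T=3)

    def test_fewer_than_two_passes_rejected(self, dropout_net):
        with pytest.raises(ValueError, match="2"):
            mc_dropout_predict(dropout_net, np.zeros((1, 8, 8)), T=1)


class TestPixelUncertainty:
    def test_identical_passes_have_zero_uncertainty(self, rng):
        p = rng.random((8, 8))
        umap, u = pixel_uncertainty([p, p.copy(), p.copy()])
        assert umap.sum() == 0.0
        assert u == 0.0

    def test_two_pass_population_sd(self):
        umap, u = pixel_uncertainty([np.array([[0.4]]), np.array([[0.6]])])
        assert umap[0, 0] == pytest.approx(0.1, abs=1e-7)
        assert u == pytest.approx(0.1, abs=1e-7)

    def test_scalar_u_is_mean_of_map(self, rng):
        passes = [rng.random((6, 6)) for _ in range(5)]
        umap, u = pixel_uncertainty(passes)
        assert u == pytest.approx(float(umap.mean()), abs=1e-7)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="shape"):
            pixel_uncertainty([rng.random((4, 4)), rng.random((5, 5))])


class TestClassificationUncertainty:
    def test_unanimous_one_hot_passes_score_zero(self):
        passes = [np.array([1.0, 0.0])] * 4
        assert classification_uncertainty(passes) == 0.0

    def test_uniform_mean_scores_one(self):
        passes = [np.array([0.25, 0.25, 0.25, 0.25])] * 3
        assert classification_uncertainty(passes) == pytest.approx(1.0)

    def test_symmetric_disagreement_scores_one(self):
        passes = [np.array([0.4, 0.6]), np.array([0.6, 0.4])]
        assert classification_uncertainty(passes) == pytest.approx(1.0, abs=1e-12)

    def test_unequal_vector_lengths_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            classification_uncertainty([np.ones(2) / 2, np.ones(3) / 3])


def mann_whitney_oracle(a, b):
    """U statistic by exhaustive pair counting (a < b pairs + half ties)."""
    u = 0.0
    for x in a:
        for y in b:
            if x < y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


class TestRankComparison:
    def test_full_separation_gives_small_p(self):
        stat, p = compare_uncertainty_distributions(
            [0.0, 0.0, 0.0, 0.01, 0.02], [1.0, 1.0, 0.99, 0.98, 1.0])
        assert p < 0.05
        assert stat == 0.0   # every "correct" score below every "incorrect"

    def test_identical_lists_are_indistinguishable(self):
        _, p = compare_uncertainty_distributions([1, 2, 3], [1, 2, 3])
        assert p >= 0.99

    @pytest.mark.parametrize("seed", range(5))
    def test_statistic_matches_pair_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 10, size=5).astype(float)
        b = rng.integers(0, 10, size=5).astype(float)
        stat, _ = compare_uncertainty_distributions(b, a)
        # scipy reports U for the first sample: pairs where first > second
        assert stat == pytest.approx(mann_whitney_oracle(a, b), abs=1e-10)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            compare_uncertainty_distributions([], [1.0])
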