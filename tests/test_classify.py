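import numpy as np
import pytest

from spectex import (
    ClassSignature,
    RasterStack,
    SampleSet,
    classify,
    classify_md,
    classify_mlc,
    classify_sam,
    classify_sid,
)
from spectex.classify import pooled_covariance, sid_divergence

BANDS = ("b1", "b2", "b3")


def _sigs(means, covs=None, ns=None):
    k = len(means)
    covs = covs if covs is not None else [np.eye(len(means[0])) * 0.01] * k
    ns = ns or [50] * k
    return [
        ClassSignature(i + 1, np.asarray(m), np.asarray(c), n)
        for i, (m, c, n) in enumerate(zip(means, covs, ns))
    ]


def _stack(pixels):
    """n pixels on a 1 x n grid."""
    arr = np.asarray(pixels, dtype=float)[None, :, :]
    return RasterStack(arr, BANDS[: arr.shape[2]])


@pytest.fixture()
def random_instance(rng):
    """100 random pixels, 3 well-spread classes with distinct covariances."""
    means = rng.uniform(0.1, 0.9, size=(3, 3))
    covs = []
    for _ in range(3):
        a = rng.normal(size=(3, 6))
        covs.append(a @ a.T / 60 + 0.02 * np.eye(3))
    sigs = _sigs(means, covs, ns=[30, 50, 70])
    pixels = rng.uniform(0.05, 1.0, size=(100, 3))
    return sigs, _stack(pixels), pixels


class TestMlc:
    def test_class_mean_pixels_recover_labels(self):
        means = [[0.1, 0.1, 0.1], [0.5, 0.5, 0.5], [0.9, 0.1, 0.9]]
        sigs = _sigs(means)
        res = classify_mlc(_stack(means), sigs)
        np.testing.assert_array_equal(res.label_map[0], [1, 2, 3])

    def test_equal_covariances_reduce_to_md(self, rng):
        means = rng.uniform(0, 1, size=(4, 3))
        cov = np.diag([0.02, 0.05, 0.03])
        sigs = _sigs(means, [cov] * 4)
        stack = _stack(rng.uniform(0, 1, size=(60, 3)))
        np.testing.assert_array_equal(
            classify_mlc(stack, sigs).label_map,
            classify_md(stack, sigs).label_map,
        )

    def test_matches_density_oracle(self, random_instance):
        """Labels equal a per-pixel argmax over explicitly evaluated
        Gaussian log-densities."""
        sigs, stack, pixels = random_instance
        res = classify_mlc(stack, sigs)
        for px, got in zip(pixels, res.label_map[0]):
            scores = []
            for s in sigs:
                d = px - s.mean
                scores.append(
                    np.log(1 / 3)
                    - 0.5 * np.linalg.slogdet(s.covariance)[1]
                    - 0.5 * d @ np.linalg.inv(s.covariance) @ d
                )
            assert got == sigs[int(np.argmax(scores))].species_code

    def test_priors_shift_boundaries(self):
        sigs = _sigs([[0.4] * 3, [0.6] * 3])
        stack = _stack([[0.5, 0.5, 0.5]])
        heavy1 = classify_mlc(stack, sigs, priors={1: 0.999, 2: 0.001})
        heavy2 = classify_mlc(stack, sigs, priors={1: 0.001, 2: 0.999})
        assert heavy1.label_map[0, 0] == 1
        assert heavy2.label_map[0, 0] == 2

    def test_affine_band_transform_invariance(self, random_instance):
        """MLC labels survive a joint invertible affine transform applied
        to pixels and signatures alike."""
        sigs, stack, pixels = random_instance
        rng = np.random.default_rng(8)
        a = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        b = rng.normal(size=3)
        t_stack = _stack(pixels @ a.T + b)
        t_sigs = [
            ClassSignature(s.species_code, a @ s.mean + b,
                           a @ s.covariance @ a.T, s.n)
            for s in sigs
        ]
        np.testing.assert_array_equal(
            classify_mlc(stack, sigs).label_map,
            classify_mlc(t_stack, t_sigs).label_map,
        )

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            classify_mlc(_stack([[0.1, 0.2]]), _sigs([[0.1, 0.2, 0.3]]))


class TestMd:
    def test_mean_pixel_distance_zero(self):
        means = [[0.2, 0.2, 0.2], [0.7, 0.7, 0.7]]
        res = classify_md(_stack(means), _sigs(means))
        np.testing.assert_array_equal(res.label_map[0], [1, 2])
        np.testing.assert_allclose(res.score_map[0], 0.0, atol=1e-12)

    def test_identity_pooled_covariance_is_nearest_mean(self, rng):
        means = rng.uniform(0, 1, size=(3, 3))
        sigs = _sigs(means, [np.eye(3)] * 3)
        pixels = rng.uniform(0, 1, size=(40, 3))
        res = classify_md(_stack(pixels), sigs)
        nearest = 1 + np.argmin(
            ((pixels[:, None, :] - means[None]) ** 2).sum(axis=2), axis=1
        )
        np.testing.assert_array_equal(res.label_map[0], nearest)

    def test_matches_distance_oracle(self, random_instance):
        sigs, stack, pixels = random_instance
        res = classify_md(stack, sigs)
        pooled = pooled_covariance(sigs)
        inv = np.linalg.inv(pooled)
        for px, got in zip(pixels, res.label_map[0]):
            d = [(px - s.mean) @ inv @ (px - s.mean) for s in sigs]
            assert got == sigs[int(np.argmin(d))].species_code

    def test_pooled_covariance_weighting(self):
        sigs = _sigs([[0] * 3, [1] * 3],
                     covs=[np.eye(3), 3 * np.eye(3)], ns=[10, 30])
        np.testing.assert_allclose(
            pooled_covariance(sigs), (10 * 1 + 30 * 3) / 40 * np.eye(3)
        )


class TestSam:
    def test_scaled_mean_pixel_angle_zero(self):
        means = [[0.1, 0.2, 0.4], [0.4, 0.2, 0.1]]
        sigs = _sigs(means)
        res = classify_sam(_stack([np.array(means[1]) * 7.3]), sigs)
        assert res.label_map[0, 0] == 2
        assert res.score_map[0, 0] == pytest.approx(0.0, abs=1e-7)

    def test_orthogonal_pixel_angle_is_right(self):
        sigs = _sigs([[1.0, 0.0, 0.0]])
        res = classify_sam(_stack([[0.0, 1.0, 0.0]]), sigs)
        assert res.score_map[0, 0] == pytest.approx(np.pi / 2)

    def test_matches_angle_oracle(self, random_instance):
        sigs, stack, pixels = random_instance
        res = classify_sam(stack, sigs)
        for px, got in zip(pixels, res.label_map[0]):
            ang = [
                np.arccos(px @ s.mean
                          / (np.linalg.norm(px) * np.linalg.norm(s.mean)))
                for s in sigs
            ]
            assert got == sigs[int(np.argmin(ang))].species_code

    def test_per_pixel_scale_invariance(self, random_instance):
        sigs, stack, pixels = random_instance
        scales = np.random.default_rng(2).uniform(0.1, 10, size=(100, 1))
        res_a = classify_sam(stack, sigs)
        res_b = classify_sam(_stack(pixels * scales), sigs)
        np.testing.assert_array_equal(res_a.label_map, res_b.label_map)

    def test_zero_norm_pixel_masked(self):
        sigs = _sigs([[0.1, 0.2, 0.3]])
        res = classify_sam(_stack([[0.0, 0.0, 0.0], [0.1, 0.2, 0.3]]), sigs)
        assert res.label_map[0, 0] == 0
        assert res.label_map[0, 1] == 1


class TestSid:
    def test_proportional_spectrum_divergence_zero(self):
        means = [[0.1, 0.2, 0.4], [0.4, 0.1, 0.1]]
        sigs = _sigs(means)
        res = classify_sid(_stack([np.array(means[0]) * 2.0]), sigs)
        assert res.label_map[0, 0] == 1
        assert res.score_map[0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_two_band_hand_value(self):
        """SID((0.8,0.2),(0.5,0.5)) = 0.3 ln 1.6 - 0.3 ln 0.4 = 0.4159."""
        p = np.array([0.8, 0.2])
        q = np.array([0.5, 0.5])
        val = sid_divergence(p, q)
        assert val == pytest.approx(0.3 * np.log(1.6) - 0.3 * np.log(0.4),
                                    rel=1e-12)
        assert val == pytest.approx(0.4159, abs=5e-5)

    def test_symmetry_on_random_simplex_pairs(self, rng):
        p = rng.dirichlet(np.ones(4), size=20)
        q = rng.dirichlet(np.ones(4), size=20)
        np.testing.assert_allclose(sid_divergence(p, q), sid_divergence(q, p),
                                   rtol=1e-10)

    def test_matches_direct_summation_oracle(self, random_instance):
        sigs, stack, pixels = random_instance
        res = classify_sid(stack, sigs)
        eps = 1e-12
        for px, got in zip(pixels, res.label_map[0]):
            pn = np.maximum(px, eps); pn = pn / pn.sum()
            divs = []
            for s in sigs:
                qn = np.maximum(s.mean, eps); qn = qn / qn.sum()
                divs.append(np.sum(pn * np.log(pn / qn))
                            + np.sum(qn * np.log(qn / pn)))
            assert got == sigs[int(np.argmin(divs))].species_code

    def test_all_zero_spectrum_masked(self):
        sigs = _sigs([[0.1, 0.2, 0.3]])
        res = classify_sid(_stack([[0.0, 0.0, 0.0]]), sigs)
        assert res.label_map[0, 0] == 0

    def test_negative_spectrum_rejected(self):
        sigs = _sigs([[0.1, 0.2, 0.3]])
        with pytest.raises(ValueError):
            classify_sid(_stack([[-0.2, 0.1, 0.1]]), sigs)


class TestDispatchAndPlugin:
    def test_dispatch_equals_direct_call(self, random_instance):
        sigs, stack, _ = random_instance
        np.testing.assert_array_equal(
            classify(stack, sigs, method="mlc").label_map,
            classify_mlc(stack, sigs).label_map,
        )

    def test_every_unmasked_pixel_gets_a_trained_label(self, random_instance):
        sigs, stack, _ = random_instance
        stack.nodata_mask[0, :5] = True
        for method in ("mlc", "md", "sam", "sid"):
            res = classify(stack, sigs, method=method)
            assert set(np.unique(res.label_map[0, 5:])) <= {1, 2, 3}
            assert np.all(res.label_map[0, :5] == 0)

    def test_plugin_constant_label(self, random_instance):
        sigs, stack, pixels = random_instance
        training = SampleSet(np.array([1, 2]), pixels[:2], BANDS)
        res = classify(
            stack, sigs, method="plugin",
            plugin=lambda tr, x: np.full(len(x), 2), training=training,
        )
        assert np.all(res.label_map == 2)

    def test_plugin_contract_violation(self, random_instance):
        sigs, stack, pixels = random_instance
        training = SampleSet(np.array([1]), pixels[:1], BANDS)
        with pytest.raises(ValueError, match="plugin returned"):
            classify(stack, sigs, method="plugin",
                     plugin=lambda tr, x: np.zeros(3), training=training)

    def test_unknown_method(self, random_instance):
        sigs, stack, _ = random_instance
        with pytest.raises(ValueError, match="unknown method"):
            classify(stack, sigs, method="svm")
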