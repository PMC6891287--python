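"""CSP fitting, whitening/projection identities and the one-vs-rest extension."""

import numpy as np
import pytest
from scipy import linalg

from cspcwt.csp import (
    CoverageError,
    DegenerateEpochError,
    RankDeficiencyError,
    average_covariance,
    csp_fit,
    csp_project,
    csp_reconstruct,
    one_vs_rest_fit,
    rest_pool_orderings,
    singular_energy_profile,
    spatial_covariance,
    whitening_transform,
)
from cspcwt.io_gal import EVENT_NAMES, EpochSet


def _random_spd(rng, n):
    a = rng.normal(size=(n, n))
    r = a @ a.T + 0.05 * np.eye(n)
    return r / np.trace(r)


def _epochs_with_cov(R):
    """A single epoch whose spatial covariance is exactly R (Cholesky factor)."""
    return [linalg.cholesky(R, lower=True)]


class TestSpatialCovariance:
    def test_identity_epoch(self):
        assert np.allclose(spatial_covariance(np.eye(2)), 0.5 * np.eye(2))

    def test_rank_one_epoch(self):
        # XX^T = [[2,2],[2,2]], trace 4 -> R = [[.5,.5],[.5,.5]] (trace 1)
        R = spatial_covariance(np.ones((2, 2)))
        assert np.allclose(R, np.full((2, 2), 0.5))

    def test_trace_is_one(self, rng):
        for _ in range(10):
            R = spatial_covariance(rng.normal(size=(4, 50)))
            assert abs(np.trace(R) - 1.0) < 1e-9
            assert np.allclose(R, R.T, atol=1e-12)

    def test_zero_epoch_rejected(self):
        with pytest.raises(DegenerateEpochError):
            spatial_covariance(np.zeros((3, 10)))


class TestAverageCovariance:
    def test_single_and_equal_inputs(self):
        R = np.array([[0.25, 0.25], [0.25, 0.25]])
        assert np.allclose(average_covariance([R]), R)
        assert np.allclose(average_covariance([R, R]), R)

    def test_elementwise_mean(self):
        out = average_covariance(
            [0.5 * np.eye(2), np.full((2, 2), 0.25)]
        )
        assert np.allclose(out, [[0.375, 0.125], [0.125, 0.375]])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_covariance([])


class TestWhitening:
    def test_diagonal_closed_form(self):
        U, Delta, Pw = whitening_transform(np.diag([4.0, 1.0]))
        assert np.allclose(Delta, [4.0, 1.0])
        assert np.allclose(np.abs(Pw), np.diag([0.5, 1.0]))

    def test_whitens_random_spd(self, rng):
        for n in (2, 4, 6):
            Rc = _random_spd(rng, n)
            _, Delta, Pw = whitening_transform(Rc)
            assert np.all(np.diff(Delta) <= 1e-12)  # descending
            assert np.allclose(Pw @ Rc @ Pw.T, np.eye(n), atol=1e-8)

    def test_rank_deficient_rejected(self):
        with pytest.raises(RankDeficiencyError):
            whitening_transform(np.diag([1.0, 0.0]))


class TestCspFit:
    def test_diagonal_toy_problem(self):
        model = csp_fit(
            _epochs_with_cov(np.diag([0.8, 0.2])),
            _epochs_with_cov(np.diag([0.2, 0.8])),
        )
        assert np.allclose(model.Delta1, [0.8, 0.2], atol=1e-10)
        assert np.allclose(model.Delta2, [0.2, 0.8], atol=1e-10)
        assert np.allclose(np.abs(model.W), np.eye(2), atol=1e-8)

    def test_variance_ratio_after_projection(self, rng):
        # event epochs drawn with source variances (0.8, 0.2): the projected
        # row-variance ratio approaches 0.8/0.2 = 4
        n_t = 20000
        X1 = np.diag([np.sqrt(0.8), np.sqrt(0.2)]) @ rng.normal(size=(2, n_t))
        X2 = np.diag([np.sqrt(0.2), np.sqrt(0.8)]) @ rng.normal(size=(2, n_t))
        model = csp_fit([X1], [X2])
        Z = csp_project(model, X1)
        ratio = Z[0].var() / Z[1].var()
        assert abs(ratio - 4.0) < 0.4

    def test_identical_classes_are_inseparable(self, rng):
        eps = [rng.normal(size=(3, 40)) for _ in range(5)]
        model = csp_fit(eps, eps)
        assert np.allclose(model.Delta1, 0.5, atol=1e-10)

    def test_paired_spectra_sum_to_one(self, rng):
        e1 = [rng.normal(size=(4, 60)) for _ in range(6)]
        e2 = [rng.normal(size=(4, 60)) for _ in range(6)]
        model = csp_fit(e1, e2)
        assert np.allclose(model.Delta1 + model.Delta2, 1.0, atol=1e-8)
        assert np.all(np.diff(model.Delta1) <= 1e-12)

    def test_scale_invariance(self, rng):
        e1 = [rng.normal(size=(3, 50)) for _ in range(4)]
        e2 = [rng.normal(size=(3, 50)) for _ in range(4)]
        a = csp_fit(e1, e2)
        b = csp_fit([7.3 * x for x in e1], [7.3 * x for x in e2])
        assert np.allclose(a.Delta1, b.Delta1, atol=1e-10)

    def test_spectrum_matches_generalized_eigensolver(self, rng):
        """Delta1 equals the eigenvalues of R1 v = lambda (R1+R2) v."""
        for _ in range(20):
            n = rng.integers(2, 7)
            R1, R2 = _random_spd(rng, n), _random_spd(rng, n)
            model = csp_fit(_epochs_with_cov(R1), _epochs_with_cov(R2))
            oracle = np.sort(linalg.eigh(R1, R1 + R2, eigvals_only=True))[::-1]
            assert np.allclose(model.Delta1, oracle, atol=1e-8)

    def test_extreme_rows_maximize_rayleigh_quotient(self, rng):
        R1, R2 = _random_spd(rng, 4), _random_spd(rng, 4)
        model = csp_fit(_epochs_with_cov(R1), _epochs_with_cov(R2))
        Rc = R1 + R2

        def quot(w):
            return (w @ R1 @ w) / (w @ Rc @ w)

        probes = rng.normal(size=(10_000, 4))
        probes /= np.linalg.norm(probes, axis=1, keepdims=True)
        vals = np.einsum("ij,jk,ik->i", probes, R1, probes) / np.einsum(
            "ij,jk,ik->i", probes, Rc, probes
        )
        assert vals.max() <= quot(model.W[0]) + 1e-10
        assert vals.min() >= quot(model.W[-1]) - 1e-10


class TestProjection:
    def test_identity_filter_passes_through(self, rng):
        # R1 = R2 = I/2 sum to the identity, so whitening (and W) is identity
        R = np.eye(2) / 2
        model = csp_fit(_epochs_with_cov(R), _epochs_with_cov(R))
        X = rng.normal(size=(2, 20))
        assert np.allclose(np.abs(model.W), np.eye(2), atol=1e-8)
        assert np.allclose(np.abs(csp_project(model, X)), np.abs(X), atol=1e-8)

    def test_project_reconstruct_round_trip(self, rng):
        e1 = [rng.normal(size=(5, 80)) for _ in range(4)]
        e2 = [rng.normal(size=(5, 80)) for _ in range(4)]
        model = csp_fit(e1, e2)
        X = rng.normal(size=(5, 80))
        assert np.allclose(csp_reconstruct(model, csp_project(model, X)), X,
                           atol=1e-8)
        assert np.allclose(model.W @ model.W_inv, np.eye(5), atol=1e-8)
        assert not csp_reconstruct(model, np.zeros((5, 10))).any()

    def test_projection_concentrates_class_contrast(self, rng):
        """The top CSP axis separates the two scatter clouds more sharply than
        any raw channel axis: the event/rest variance ratio along W row 0
        exceeds the best ratio achievable on the unprojected axes."""
        mix = rng.normal(size=(3, 3)) + 2 * np.eye(3)
        e1 = [mix @ np.diag([3.0, 1.0, 0.3]) @ rng.normal(size=(3, 200))
              for _ in range(20)]
        e2 = [mix @ np.diag([0.3, 1.0, 3.0]) @ rng.normal(size=(3, 200))
              for _ in range(20)]
        model = csp_fit(e1, e2)
        raw1, raw2 = np.hstack(e1), np.hstack(e2)
        proj1 = np.hstack([csp_project(model, x) for x in e1])
        proj2 = np.hstack([csp_project(model, x) for x in e2])
        channel_ratios = raw1.var(axis=1) / raw2.var(axis=1)
        top_ratio = proj1[0].var() / proj2[0].var()
        bottom_ratio = proj1[-1].var() / proj2[-1].var()
        assert top_ratio > channel_ratios.max()
        assert bottom_ratio < channel_ratios.min()


class TestOneVsRest:
    def _epoch_set(self, rng, per_class=8):
        epochs, labels = [], []
        for k in range(6):
            scale = np.ones(6)
            scale[k] = 3.0
            for _ in range(per_class):
                epochs.append(np.diag(scale) @ rng.normal(size=(6, 50)))
                labels.append(k)
        return EpochSet(
            epochs=np.stack(epochs), labels=np.array(labels),
            window_length=50, step=50, channel_names=list("abcdef"),
        )

    def test_six_models_keyed_by_event(self, rng):
        models = one_vs_rest_fit(self._epoch_set(rng), seed=0)
        assert list(models) == list(EVENT_NAMES)
        for model in models.values():
            n = model.n_channels
            assert np.allclose(model.Delta1 + model.Delta2, 1.0, atol=1e-8)
            assert np.allclose(model.W @ model.W_inv, np.eye(n), atol=1e-8)
            comp = model.Pw @ (model.U @ np.diag(model.Delta) @ model.U.T) @ model.Pw.T
            assert np.allclose(comp, np.eye(n), atol=1e-8)

    def test_rest_pool_has_120_orderings(self):
        for event in EVENT_NAMES:
            assert rest_pool_orderings(event) == 120

    def test_missing_class_rejected(self, rng):
        ep = self._epoch_set(rng)
        ep.labels[ep.labels == 3] = 2
        with pytest.raises(CoverageError, match="HD"):
            one_vs_rest_fit(ep)


class TestSingularEnergy:
    def test_rank_one_profile(self):
        profile = singular_energy_profile(np.outer([1.0, 2.0], np.arange(5)))
        assert np.allclose(profile, 1.0)

    def test_identity_profile(self):
        assert np.allclose(singular_energy_profile(np.eye(3)),
                           [1 / 3, 2 / 3, 1.0])

    def test_six_channel_projection_saturates_by_six(self, rng):
        e1 = [rng.normal(size=(6, 100)) for _ in range(10)]
        e2 = [rng.normal(size=(6, 100)) for _ in range(10)]
        model = csp_fit(e1, e2)
        Z_all = np.hstack([csp_project(model, x) for x in e1])
        profile = singular_energy_profile(Z_all)
        assert np.all(np.diff(profile) >= -1e-12)
        assert abs(profile[-1] - 1.0) < 1e-12
        assert profile[5] >= 0.99
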