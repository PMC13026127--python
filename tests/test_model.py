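"""Count accumulation, circular smoothing, Dirichlet posteriors, prediction."""

import itertools

import numpy as np
import pytest

from rotalib import context as ctx
from rotalib import model as mdl
from rotalib import synthetic as syn
from rotalib.context import AxisSpec, ContextGrid
from rotalib.model import (ModelError, SmoothingKernel, accumulate_counts,
                           apply_fill_missing_only, build_model,
                           dirichlet_posterior, gaussian_kernel_1d, predict,
                           predict_batch, smooth_counts)
from tests.conftest import make_rotamer_set


def brute_force_smooth(raw, kernel, grid):
    """Direct neighbourhood sum of the smoothing definition (oracle).

    Periodic axes wrap indices; truncated axes drop out-of-range neighbours
    and renormalize the per-axis weights over the surviving offsets.
    """
    out = np.zeros_like(raw, dtype=float)
    shape = raw.shape[1:]
    d = len(shape)
    offsets = [range(-kernel.radii[i], kernel.radii[i] + 1) for i in range(d)]
    weights = [kernel.weights(i) for i in range(d)]
    for x in np.ndindex(*shape):
        # per-axis normalizers at this position (truncated axes only)
        norms = []
        for i in range(d):
            if kernel.periodic[i]:
                norms.append(1.0)
            else:
                s = sum(weights[i][o + kernel.radii[i]]
                        for o in offsets[i] if 0 <= x[i] + o < shape[i])
                norms.append(s)
        for dy in itertools.product(*offsets):
            w = 1.0
            y = []
            valid = True
            for i in range(d):
                yi = x[i] + dy[i]
                if kernel.periodic[i]:
                    yi %= shape[i]
                elif not (0 <= yi < shape[i]):
                    valid = False
                    break
                w *= weights[i][dy[i] + kernel.radii[i]] / norms[i]
                y.append(yi)
            if valid:
                out[(slice(None),) + x] += w * raw[(slice(None),) + tuple(y)]
    return out


class TestKernel:
    def test_identity(self):
        assert np.array_equal(gaussian_kernel_1d(0, 1.0), [1.0])

    def test_radius1_values(self):
        w = gaussian_kernel_1d(1, 1.0)
        np.testing.assert_allclose(w, [0.27406, 0.45186, 0.27406], atol=1e-4)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_symmetric(self):
        for r, s in [(1, 1.0), (2, 1.5), (3, 0.7)]:
            w = gaussian_kernel_1d(r, s)
            np.testing.assert_allclose(w, w[::-1])

    def test_validation(self):
        with pytest.raises(ModelError):
            gaussian_kernel_1d(-1, 1.0)
        with pytest.raises(ModelError):
            gaussian_kernel_1d(1, 0.0)


class TestSmoothing:
    def test_radius_zero_identity(self):
        grid = ctx.backbone_grid()
        k = SmoothingKernel.for_grid(grid, radius=0)
        raw = np.random.default_rng(0).poisson(2.0, size=(3, 36, 36)).astype(float)
        assert np.array_equal(smooth_counts(raw, k, grid), raw)

    def test_unit_impulse_wraps(self):
        grid = ContextGrid((AxisSpec("phi", "periodic_angle", 10.0),))
        k = SmoothingKernel.for_grid(grid, radius=1, sigma=1.0)
        raw = np.zeros((1, 36))
        raw[0, 0] = 1.0
        sm = smooth_counts(raw, k, grid)
        np.testing.assert_allclose([sm[0, 35], sm[0, 0], sm[0, 1]],
                                   [0.27406, 0.45186, 0.27406], atol=1e-4)
        assert sm.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("radius,sigma", [(1, 1.0), (2, 1.5)])
    def test_matches_brute_force_mixed_axes(self, radius, sigma):
        grid = ContextGrid((AxisSpec("phi", "periodic_angle", 30.0),
                            AxisSpec("psi", "periodic_angle", 30.0),
                            AxisSpec("c", "categorical",
                                     categories=("a", "b", "c"))))
        k = SmoothingKernel.for_grid(grid, radius=radius, sigma=sigma)
        rng = np.random.default_rng(radius)
        for _ in range(5):
            raw = rng.poisson(1.5, size=(2, 12, 12, 3)).astype(float)
            fast = smooth_counts(raw, k, grid)
            slow = brute_force_smooth(raw, k, grid)
            assert np.max(np.abs(fast - slow)) < 1e-9

    def test_mass_conserved_on_periodic_grid(self):
        grid = ctx.backbone_grid()
        k = SmoothingKernel.for_grid(grid, radius=2, sigma=1.5)
        raw = np.random.default_rng(5).poisson(2.0, size=(4, 36, 36)).astype(float)
        sm = smooth_counts(raw, k, grid)
        np.testing.assert_allclose(sm.sum(axis=(1, 2)), raw.sum(axis=(1, 2)),
                                   atol=1e-9)

    def test_dimension_mismatch(self):
        grid = ctx.backbone_grid()
        k = SmoothingKernel((1,), (1.0,), (True,))
        with pytest.raises(ModelError):
            smooth_counts(np.zeros((2, 36, 36)), k, grid)


class TestFillMissingOnly:
    def test_occupied_keeps_raw_empty_takes_smoothed(self):
        grid = ContextGrid((AxisSpec("phi", "periodic_angle", 30.0),))
        k = SmoothingKernel.for_grid(grid, radius=1, sigma=1.0)
        raw = np.zeros((2, 12))
        raw[0, 4] = 6.0
        raw[1, 6] = 2.0
        sm = smooth_counts(raw, k, grid)
        hybrid = apply_fill_missing_only(raw, sm)
        occupied = raw.sum(0) > 0
        assert np.array_equal(hybrid[:, occupied], raw[:, occupied])
        assert np.array_equal(hybrid[:, ~occupied], sm[:, ~occupied])
        # bin 5 is empty but adjacent to occupied bins: takes smoothed values
        assert hybrid[0, 5] > 0 and raw[0, 5] == 0

    def test_limits(self):
        raw = np.ones((2, 5))
        sm = raw * 0.5
        assert np.array_equal(apply_fill_missing_only(raw, sm), raw)
        raw0 = np.zeros((2, 5))
        assert np.array_equal(apply_fill_missing_only(raw0, sm), sm)


class TestDirichletPosterior:
    def test_empty_bin_returns_prior(self):
        counts = np.zeros((5, 4))
        prior = np.full(5, 0.2)
        p = dirichlet_posterior(counts, 40.0, prior)
        np.testing.assert_allclose(p, 0.2)

    def test_worked_example(self):
        counts = np.array([[8.0], [2.0]])
        p = dirichlet_posterior(counts, 10.0, np.array([0.5, 0.5]))
        np.testing.assert_allclose(p[:, 0], [0.65, 0.35])

    def test_alpha_zero_empirical(self):
        counts = np.array([[3.0], [1.0]])
        p = dirichlet_posterior(counts, 0.0, np.array([0.5, 0.5]))
        np.testing.assert_allclose(p[:, 0], [0.75, 0.25])

    def test_alpha_zero_empty_bin_raises(self):
        with pytest.raises(ModelError):
            dirichlet_posterior(np.zeros((2, 3)), 0.0, np.array([0.5, 0.5]))

    def test_normalization_fuzz(self):
        rng = np.random.default_rng(10)
        for _ in range(25):
            counts = rng.poisson(1.0, size=(rng.integers(2, 7), 6, 6)).astype(float)
            alpha = float(rng.uniform(0.1, 100))
            k = counts.shape[0]
            prior = rng.dirichlet(np.ones(k))
            p = dirichlet_posterior(counts, alpha, prior)
            assert np.max(np.abs(p.sum(0) - 1.0)) < 1e-9
            assert np.all(p > 0)

    def test_monotone_prior_influence(self):
        """|P(r|x) - pi_r| never increases with alpha, for every r and x."""
        rng = np.random.default_rng(4)
        counts = rng.poisson(3.0, size=(4, 8)).astype(float)
        prior = rng.dirichlet(np.ones(4))
        alphas = [0.5, 1, 5, 20, 80, 400]
        devs = [np.abs(dirichlet_posterior(counts, a, prior)
                       - prior[:, None]) for a in alphas]
        for lo, hi in zip(devs, devs[1:]):
            assert np.all(hi <= lo + 1e-12)


class TestAccumulateAndPredict:
    def _setup(self, n=300, seed=0):
        field = syn.make_field("LEU", 3, seed=seed)
        recs, labels = syn.sample_residues(field, n, seed=seed + 1,
                                           with_coordinates=False,
                                           return_labels=True)
        grid = ctx.backbone_grid()
        rset = make_rotamer_set("LEU", field.rotamer_chis, 0.40)
        return field, recs, labels, grid, rset

    def test_counts_empty_and_single(self):
        _, recs, _, grid, rset = self._setup(n=1)
        assert accumulate_counts([], grid, rset).sum() == 0
        assert accumulate_counts(recs, grid, rset).sum() == 1

    def test_planted_label_marginals(self):
        """With well-separated rotamers, nearest-centroid assignment recovers
        the planted labels exactly (noise sigma 8 deg << 60 deg spacing)."""
        field, recs, labels, grid, rset = self._setup(n=300)
        raw = accumulate_counts(recs, grid, rset)
        marg = raw.sum(axis=(1, 2))
        want = np.bincount(labels, minlength=3)
        np.testing.assert_array_equal(marg, want)

    def test_wrong_aa_type_raises(self):
        _, recs, _, grid, _ = self._setup(n=5)
        rset_ser = make_rotamer_set("SER", [(60.0,), (180.0,)], 0.35)
        with pytest.raises(ModelError):
            accumulate_counts(recs, grid, rset_ser)

    def test_build_model_defaults_and_determinism(self):
        _, recs, _, grid, rset = self._setup(n=200)
        m1 = build_model(recs, grid, rset)
        m2 = build_model(recs, grid, rset)
        assert m1.alpha == 40.0
        assert m1.kernel.radii == (1, 1)
        assert np.array_equal(m1.posterior, m2.posterior)
        assert np.max(np.abs(m1.posterior.sum(0) - 1.0)) < 1e-9

    def test_reduction_to_frequency_table(self):
        """radius 0 and alpha -> 0 on an occupied grid reproduces raw
        relative frequencies: the classical frequency-library limit."""
        grid = ContextGrid((AxisSpec("phi", "periodic_angle", 90.0),
                            AxisSpec("psi", "periodic_angle", 90.0)))
        field, recs, _, _, rset = self._setup(n=800)
        kernel = SmoothingKernel.for_grid(grid, radius=0)
        raw = accumulate_counts(recs, grid, rset)
        assert np.all(raw.sum(0) > 0)  # coarse grid fully occupied
        m = build_model(None, grid, rset, kernel=kernel, alpha=0.0,
                        raw_counts=raw)
        np.testing.assert_allclose(m.posterior, raw / raw.sum(0), atol=1e-12)

    def test_predict_argmax_and_tie(self):
        grid = ContextGrid((AxisSpec("phi", "periodic_angle", 120.0),))
        rset = make_rotamer_set("SER", [(60.0,), (180.0,)], 0.35)
        m = build_model(None, grid, rset, raw_counts=np.array(
            [[7.0, 2.0, 5.0], [3.0, 8.0, 5.0]]),
            kernel=SmoothingKernel.for_grid(grid, radius=0), alpha=0.0)
        assert predict(m, (0,)).rotamer_id == 0
        assert predict(m, (1,)).rotamer_id == 1
        tie = predict(m, (2,))
        assert tie.rotamer_id == 0  # exact tie -> lowest id
        assert tie.posterior_prob == pytest.approx(0.5)
        assert tie.canonical_chi.chi == (60.0,)

    def test_out_of_grid(self):
        grid = ContextGrid((AxisSpec("phi", "periodic_angle", 120.0),))
        grid.set_global_bins({(0,), (1,)})
        rset = make_rotamer_set("SER", [(60.0,), (180.0,)], 0.35)
        m = build_model(None, grid, rset,
                        raw_counts=np.ones((2, 3)),
                        kernel=SmoothingKernel.for_grid(grid, radius=0))
        res = predict(m, (2,))
        assert res.status == "out_of_grid"
        assert res.rotamer_id is None and res.canonical_chi is None
        ids, mask = predict_batch(m, [(0,), (2,), (1,)])
        assert list(ids) == [predict(m, (0,)).rotamer_id, -1,
                             predict(m, (1,)).rotamer_id]
        assert list(mask) == [True, False, True]

    def test_predict_batch_matches_scalar(self):
        _, recs, _, grid, rset = self._setup(n=150)
        m = build_model(recs, grid, rset)
        xs = [(i % 36, (3 * i) % 36) for i in range(40)]
        ids, _ = predict_batch(m, xs)
        for x, i in zip(xs, ids):
            assert predict(m, x).rotamer_id == i
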