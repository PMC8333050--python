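"""De-autocorrelation solvers: fixed points, monotonicity, the
delta-anchor reduction and small-scale recovery."""

import numpy as np
import pytest

from corrtomo import corr
from corrtomo.errors import (DegenerateInputError, NumericalFailureError,
                             ValidationError)
from corrtomo.inversion import SolverState, au_step, i_divergence, solve, ss_step


def _acorr(o):
    return np.maximum(corr.autocorrelate(o, "circular").data, 0.0)


def _centered_delta(shape):
    d = np.zeros(shape)
    d[tuple(s // 2 for s in shape)] = 1.0
    return d


def _toy_1d(pad=16):
    sig = np.array([0.0, 0.0, 1.0, 2.0, 1.0, 0.0, 0.0])
    return corr.embed_centered(sig, (pad,))


def _score_up_to_flip_and_shift(rec, truth):
    best = -np.inf
    t0 = truth - truth.mean()
    for cand in (rec, corr.flip(rec)):
        c0 = cand - cand.mean()
        cc = corr.correlate(c0, t0, "circular").data
        best = max(best, cc.max() / (np.linalg.norm(c0) * np.linalg.norm(t0)))
    return best


class TestIDivergence:
    def test_zero_iff_equal(self, rng):
        x = rng.random((6, 6)) + 0.1
        assert i_divergence(x, x) < 1e-12
        assert i_divergence(x, x + 0.05) > 0

    def test_single_element_closed_form(self):
        val = i_divergence(np.array([2.0]), np.array([1.0]))
        assert np.isclose(val, 2 * np.log(2) - 1, rtol=1e-12)

    def test_zero_target_entries_allowed(self):
        val = i_divergence(np.array([0.0, 1.0]), np.array([0.5, 1.0]))
        assert np.isclose(val, 0.5)


class TestSsStep:
    def test_exact_solution_is_fixed_point(self):
        o = _toy_1d()
        new = ss_step(SolverState(o.copy()), _acorr(o))
        np.testing.assert_allclose(new.iterate, o, rtol=1e-12, atol=1e-14)

    def test_fixed_point_3d(self, tiny_phantom):
        o = tiny_phantom + 0.0
        new = ss_step(SolverState(o.copy()), _acorr(o))
        np.testing.assert_allclose(new.iterate, o,
                                   atol=1e-12 * o.max())

    def test_support_preservation(self, rng):
        o = rng.random(16) + 0.1
        o[5] = 0.0
        chi = _acorr(_toy_1d())
        st = SolverState(o)
        for _ in range(25):
            st = ss_step(st, chi)
        assert st.iterate[5] == 0.0
        assert np.all(st.iterate >= 0)

    def test_zero_mass_state_rejected(self):
        with pytest.raises(DegenerateInputError):
            ss_step(SolverState(np.zeros(8)), np.ones(8))


class TestAuStep:
    def test_exact_pair_is_fixed_point(self):
        o = _toy_1d(24)
        h = np.exp(-0.5 * ((np.arange(24) - 12) / 1.2) ** 2)
        h /= h.sum()
        H = np.maximum(corr.autocorrelate(h, "circular").data, 0.0)
        chi = np.maximum(
            corr.convolve(corr.autocorrelate(o, "circular").data, H,
                          "circular"), 0.0)
        new = au_step(SolverState(o.copy()), chi, H)
        np.testing.assert_allclose(new.iterate, o, rtol=1e-12, atol=1e-14)

    def test_kernel_recomputed_from_iterate(self):
        o = _toy_1d(24)
        H = _centered_delta((24,))
        new = au_step(SolverState(o.copy()), _acorr(o), H)
        # with a delta anchor the effective kernel is the flipped iterate
        np.testing.assert_allclose(new.kernel, corr.flip(new.iterate),
                                   atol=1e-12)

    def test_delta_anchor_matches_ss_divergence(self):
        """AU with 𝓗 = δ solves the same model as SS (o⋆δ = õ, so
        o*𝒦 = o⋆o); final I-divergences agree to 1e-6 from the same
        init."""
        o = _toy_1d(16)
        chi = _acorr(o)
        init = corr.embed_centered(np.full(8, 0.5), (16,))
        _, s_ss = solve(chi, "SS", init=init, n_iter=5000)
        _, s_au = solve(chi, "AU", H=_centered_delta((16,)), init=init,
                        n_iter=5000)
        assert abs(s_ss.divergences[-1] - s_au.divergences[-1]) < 1e-6


class TestSolve:
    def test_zero_iterations_returns_init(self):
        o = _toy_1d()
        chi = _acorr(o)
        out, state = solve(chi, "SS", init=o.copy(), n_iter=0)
        np.testing.assert_allclose(out, o)
        assert state.t == 0

    def test_1d_recovery_up_to_flip_and_shift(self):
        o = _toy_1d()
        rec, state = solve(_acorr(o), "SS", n_iter=30000,
                           checkpoint_every=1000)
        assert state.divergences[-1] < 1e-5
        assert _score_up_to_flip_and_shift(rec, o) > 0.99

    def test_divergence_trace_non_increasing(self):
        o = _toy_1d()
        _, state = solve(_acorr(o), "SS", n_iter=2000, checkpoint_every=100)
        assert np.all(np.diff(state.divergences) <= 1e-10)

    def test_mass_converges_to_sqrt_of_target_sum(self):
        o = _toy_1d()
        chi = _acorr(o)
        _, state = solve(chi, "SS", init=1.3 * o, n_iter=3000)
        mass = state.trace[-1][2]
        assert abs(mass**2 - chi.sum()) / chi.sum() < 1e-3

    def test_tol_stops_early(self):
        o = _toy_1d()
        _, state = solve(_acorr(o), "SS", init=o.copy(), n_iter=10_000,
                         checkpoint_every=50, tol=1e-8)
        assert state.t < 10_000

    def test_au_sharper_than_ss_on_blurred_blobs(self):
        """On a two-blob signal blurred by a known Gaussian, AU (which
        deconvolves the PSF) reaches a peakier solution than SS."""
        n = 48
        o = np.zeros(n)
        o[18], o[30] = 1.0, 1.0
        h = np.exp(-0.5 * ((np.arange(n) - n // 2) / 2.0) ** 2)
        h /= h.sum()
        blurred = corr.convolve(o, h, "circular")
        chi = np.maximum(corr.autocorrelate(blurred, "circular").data, 0.0)
        H = np.maximum(corr.autocorrelate(h, "circular").data, 0.0)
        rec_ss, _ = solve(chi, "SS", init=blurred, n_iter=4000)
        rec_au, _ = solve(chi, "AU", H=H, init=blurred, n_iter=4000)
        assert rec_au.max() > rec_ss.max()

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValidationError):
            solve(np.ones(8), "RL")

    def test_au_without_kernel_rejected(self):
        with pytest.raises(ValidationError):
            solve(np.ones(8), "AU")

    def test_negative_target_rejected(self):
        with pytest.raises(ValidationError):
            solve(np.array([1.0, -0.5, 1.0]), "SS")

    def test_nonfinite_iterate_reported_with_iteration(self):
        chi = _acorr(_toy_1d())
        bad = np.full(16, 1e308)
        with pytest.raises((NumericalFailureError, FloatingPointError)):
            with np.errstate(over="raise"):
                solve(chi, "SS", init=bad, n_iter=10, checkpoint_every=1)


@pytest.mark.parametrize("seed", range(6))
def test_monotone_divergence_on_random_2d_toys(seed):
    rng = np.random.default_rng(seed)
    o = np.zeros((12, 12))
    o[3:9, 3:9] = rng.random((6, 6))
    chi = np.maximum(corr.autocorrelate(corr.embed_centered(o, (24, 24)),
                                        "circular").data, 0.0)
    _, state = solve(chi, "SS", n_iter=400, checkpoint_every=20)
    d = state.divergences
    assert np.all(np.diff(d) <= 1e-9 * max(1.0, d[0]))
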