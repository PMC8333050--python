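"""De-autocorrelation solvers.

Recovering a volume from its auto-correlation is a phase-retrieval
problem: the auto-correlation fixes the Fourier modulus and discards the
phase, so the solution is defined up to a global shift and a point
reflection (flip).  Two multiplicative fixed-point schemes are provided,
both of the Richardson–Lucy/Bayesian family and both preserving
non-negativity by construction:

Schulz–Snyder (SS)
    minimizes the Csiszár I-divergence between a target auto-correlation
    χ and the iterate's auto-correlation o⋆o:

        o ← o / (2 Σo) · [ (χ/(o⋆o)) * o  +  (χ/(o⋆o)) ⋆ o ]

    (lag convention (a⋆b)(ξ) = Σ a(y) b(y+ξ); under the opposite sign
    convention the convolution term is written with the reflected
    iterate õ)

Anchor-Update (AU)
    simultaneously de-autocorrelates and deconvolves a known lag-space
    PSF 𝓗 = 𝒜{h}, modelling χ = o * 𝒦 with the *effective kernel*
    𝒦 = o ⋆ 𝓗 re-derived from the current iterate at every step:

        o ← o / Σ𝒦 · [ (χ/(o * 𝒦)) * 𝒦̃ ],   𝒦 = o ⋆ 𝓗

The leading normalizations 1/(2Σo) and 1/Σ𝒦 make the exact solution a
true fixed point (without them each step rescales the iterate); they
follow the original Schulz–Snyder formulation.  With 𝓗 a delta the AU
model collapses to o⋆o and AU reproduces SS.

All lag-space algebra is cyclic on the grid the target lives on; build
the target in a zero-padded geometry (translation space 2n-1 long per
axis) for wrap-around-free linear algebra, or work unpadded from a close
initial guess.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft

from . import corr
from .corr import LagVolume
from .errors import DegenerateInputError, NumericalFailureError, ValidationError

__all__ = ["SolverState", "i_divergence", "ss_step", "au_step", "solve"]

#: relative denominator floor of the multiplicative updates
EPS_DIV = 1e-12


@dataclass
class SolverState:
    """State of a de-autocorrelation run.

    ``trace`` rows are ``(t, I-divergence, Σo)`` recorded at checkpoints;
    for SS the I-divergence is non-increasing at every checkpoint.
    """

    iterate: np.ndarray
    t: int = 0
    trace: list = field(default_factory=list)
    kernel: np.ndarray | None = None
    mode: str = "circular"

    @property
    def divergences(self) -> np.ndarray:
        return np.array([row[1] for row in self.trace])


def _floor(model: np.ndarray) -> np.ndarray:
    eps = EPS_DIV * float(model.max())
    if eps <= 0:
        raise DegenerateInputError("model is identically zero")
    return np.maximum(model, eps)


def i_divergence(target, model) -> float:
    """Csiszár I-divergence  Σ [ χ log(χ/m) − χ + m ]  (0·log 0 = 0).

    Non-negative, and zero iff the arrays coincide almost everywhere.
    The natural objective of Poisson-type multiplicative algorithms.
    """
    t = np.asarray(corr._as_array(target), dtype=float)
    m = np.asarray(corr._as_array(model), dtype=float)
    mf = _floor(m)
    pos = t > 0
    logterm = np.zeros_like(t)
    logterm[pos] = t[pos] * np.log(t[pos] / mf[pos])
    return float(np.sum(logterm - t + m))


# ---------------------------------------------------------------------------
# rolled-layout fast kernels (origin at index 0; fft(flip a) = conj(fft a))

def _ss_update(o0: np.ndarray, chi0: np.ndarray) -> np.ndarray:
    shape = o0.shape
    O = scipy.fft.rfftn(o0)
    ac0 = scipy.fft.irfftn(np.conj(O) * O, s=shape)
    r0 = chi0 / _floor(ac0)
    R = scipy.fft.rfftn(r0)
    # bracket of the multiplicative update: Σ_ξ r(ξ)[o(x-ξ) + o(x+ξ)],
    # i.e. (r * o) + (r ⋆ o); the two terms coincide when r is exactly
    # symmetric, and their pairing is what makes the I-divergence
    # non-increasing (majorization-minimization step)
    term = scipy.fft.irfftn(R * O, s=shape)            # (r * o)
    term += scipy.fft.irfftn(np.conj(R) * O, s=shape)  # (r ⋆ o)
    out = o0 * term / (2.0 * o0.sum())
    np.maximum(out, 0.0, out=out)  # clamp spectral round-off negatives
    return out


def _au_update(o0: np.ndarray, chi0: np.ndarray, Hf: np.ndarray) -> np.ndarray:
    shape = o0.shape
    O = scipy.fft.rfftn(o0)
    Kf = np.conj(O) * Hf                     # F[𝒦], 𝒦 = o ⋆ 𝓗
    sum_K = float(Kf.flat[0].real)           # DC term = Σ𝒦
    model0 = scipy.fft.irfftn(O * Kf, s=shape)  # o * 𝒦
    r0 = chi0 / _floor(model0)
    R = scipy.fft.rfftn(r0)
    out = o0 * scipy.fft.irfftn(R * np.conj(Kf), s=shape) / sum_K  # (r * 𝒦̃)
    np.maximum(out, 0.0, out=out)
    return out


def _model_ss(o0):
    O = scipy.fft.rfftn(o0)
    return scipy.fft.irfftn(np.conj(O) * O, s=o0.shape)


def _model_au(o0, Hf):
    O = scipy.fft.rfftn(o0)
    return scipy.fft.irfftn(O * np.conj(O) * Hf, s=o0.shape)


# ---------------------------------------------------------------------------
# public single-step API (centered layout in and out)

def _check_state(o: np.ndarray):
    if np.any(o < 0):
        raise ValidationError("iterate must be non-negative")
    if o.sum() <= 0:
        raise DegenerateInputError("iterate has zero total mass")


def ss_step(state: SolverState, chi_target: LagVolume) -> SolverState:
    """One Schulz–Snyder update of ``state`` toward ``chi_target``.

    Preserves non-negativity and the support of the iterate (a zero voxel
    stays zero); leaves an exact solution unchanged.
    """
    o = state.iterate
    _check_state(o)
    chi = corr._as_array(chi_target)
    if chi.shape != o.shape:
        raise ValidationError("iterate and target must share one grid")
    o0 = corr._to_rolled(np.asarray(o, dtype=float))
    chi0 = corr._to_rolled(np.asarray(chi, dtype=float))
    new = corr._to_centered(_ss_update(o0, chi0))
    return SolverState(new, state.t + 1, list(state.trace), None, state.mode)


def au_step(state: SolverState, chi_target: LagVolume,
            H: LagVolume) -> SolverState:
    """One Anchor-Update step: recompute 𝒦 = o ⋆ 𝓗 from the current
    iterate, then apply the multiplicative deconvolution update."""
    o = state.iterate
    _check_state(o)
    chi = corr._as_array(chi_target)
    Harr = corr._as_array(H)
    if chi.shape != o.shape or Harr.shape != o.shape:
        raise ValidationError("iterate, target and H must share one grid")
    if np.any(Harr < 0):
        raise ValidationError("H must be non-negative")
    o0 = corr._to_rolled(np.asarray(o, dtype=float))
    chi0 = corr._to_rolled(np.asarray(chi, dtype=float))
    Hf = scipy.fft.rfftn(corr._to_rolled(np.asarray(Harr, dtype=float)))
    new0 = _au_update(o0, chi0, Hf)
    O = scipy.fft.rfftn(new0)
    K = corr._to_centered(scipy.fft.irfftn(np.conj(O) * Hf, s=o.shape))
    return SolverState(corr._to_centered(new0), state.t + 1,
                       list(state.trace), K, state.mode)


def solve(chi_target, scheme: str = "SS", H=None, init=None,
          n_iter: int = 5000, checkpoint_every: int = 100,
          tol: float | None = None, mode: str = "circular",
          dtype=np.float64, callback=None):
    """Run a de-autocorrelation to ``n_iter`` iterations.

    Parameters
    ----------
    chi_target : LagVolume or ndarray
        Target auto-correlation (non-negative, centered zero lag).  The
        solver works cyclically on this grid.
    scheme : {"SS", "AU"}
    H : LagVolume or ndarray, required for AU
        Lag-space PSF 𝒜{h}; embedded onto the target grid if smaller.
    init : ndarray, optional
        Non-negative initial guess (a close guess — e.g. the reference
        view — speeds convergence and permits unpadded grids).  Defaults
        to a flat positive volume with mass √(Σχ).  Embedded onto the
        target grid if smaller.
    n_iter : int
        Fixed iteration budget, the method's only essential parameter.
    checkpoint_every : int
        Trace-recording (and convergence-test) stride.
    tol : float, optional
        If set, stop once the relative drop of the I-divergence over one
        checkpoint window falls below ``tol``.
    callback : callable, optional
        ``callback(t, idiv, mass)`` at each checkpoint.

    Returns
    -------
    (ndarray, SolverState)
        Final iterate (centered layout, same grid as the target) and the
        full state with the divergence trace.
    """
    scheme = scheme.upper()
    if scheme not in ("SS", "AU"):
        raise ValidationError(f"unknown scheme {scheme!r}")
    chi = np.asarray(corr._as_array(chi_target), dtype=dtype)
    if chi.min() < -1e-9 * abs(chi.max()):
        raise ValidationError("chi_target must be non-negative (sanitize first)")
    chi = np.maximum(chi, 0.0)  # clamp spectral round-off negatives only
    if init is None:
        # flat guess on the central half-grid window: the largest support
        # whose autocorrelation fits the grid without wrap-around.  (A flat
        # guess over the *whole* cyclic grid is a symmetric fixed point of
        # the update and never moves.)
        win = tuple((s + 1) // 2 for s in chi.shape)
        init = corr.embed_centered(np.ones(win, dtype=dtype), chi.shape)
        init *= np.sqrt(chi.sum()) / init.sum()
    init = np.asarray(corr._as_array(init), dtype=dtype)
    if init.shape != chi.shape:
        init = corr.embed_centered(init, chi.shape)
    _check_state(init)
    # pin the initial mass to the value the data dictates: both updates
    # map Σo -> Σχ/Σo (for unit-sum 𝓗), so any other scale oscillates
    # with period 2 instead of damping; Σχ = (Σo)² fixes Σo = √Σχ
    init = init * (np.sqrt(chi.sum()) / init.sum())

    Hf = None
    if scheme == "AU":
        if H is None:
            raise ValidationError("AU requires the lag-space PSF H")
        Harr = np.asarray(corr._as_array(H), dtype=dtype)
        if Harr.shape != chi.shape:
            Harr = corr.embed_centered(Harr, chi.shape)
        if np.any(Harr < 0):
            raise ValidationError("H must be non-negative")
        Hf = scipy.fft.rfftn(corr._to_rolled(Harr))

    o0 = corr._to_rolled(init).copy()
    chi0 = corr._to_rolled(chi)
    model = _model_ss(o0) if scheme == "SS" else _model_au(o0, Hf)
    trace = [(0, i_divergence(chi0, model), float(o0.sum()))]
    if callback:
        callback(*trace[-1])

    t = 0
    while t < n_iter:
        span = min(checkpoint_every, n_iter - t)
        for _ in range(span):
            o0 = _ss_update(o0, chi0) if scheme == "SS" else _au_update(o0, chi0, Hf)
        t += span
        if not np.all(np.isfinite(o0)):
            raise NumericalFailureError(
                f"non-finite iterate at iteration {t}", iteration=t)
        model = _model_ss(o0) if scheme == "SS" else _model_au(o0, Hf)
        trace.append((t, i_divergence(chi0, model), float(o0.sum())))
        if callback:
            callback(*trace[-1])
        if tol is not None and len(trace) >= 2:
            prev, cur = trace[-2][1], trace[-1][1]
            # prev can sit at float-noise level when starting from an
            # exact solution: that counts as converged
            if prev <= 0 or (prev - cur) / prev < tol:
                break

    final = corr._to_centered(o0)
    kernel = None
    if scheme == "AU":
        O = scipy.fft.rfftn(o0)
        kernel = corr._to_centered(scipy.fft.irfftn(np.conj(O) * Hf, s=o0.shape))
    return final, SolverState(final, t, trace, kernel, mode)
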