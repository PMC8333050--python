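"""Fusion of multi-view stacks, in direct space and in auto-correlation
space.

Two competing products are built from the same pre-processed views:

* ``fuse_direct`` — the classical route: optionally register every view
  against the reference by the peak of their cross-correlation, translate
  and average.  This is the "standard reconstruction" baseline o̅_µ.
* ``fuse_acorr`` — the alignment-free route: average the per-view
  auto-correlations.  Because the auto-correlation is centered by
  definition, rigid per-view shifts drop out and no registration is
  performed (or permitted).

The PSF-side counterpart ``fuse_psf_acorr`` builds the direct-space
average h̄ and the lag-space average 𝓗̄ = mean of 𝒜{h^φ}; their
difference (the second-order cross-terms of the PSF present in 𝒜{h̄}
but absent from 𝓗̄) is the origin of the resolution gain of the
auto-correlation route.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import corr
from .corr import LagVolume
from .errors import DegenerateInputError, ValidationError
from .preprocess import sanitize_acorr
from .psf import PSFModel, render_psf
from .simulate import ViewSet

__all__ = [
    "Displacement",
    "register_pair",
    "fuse_direct",
    "fuse_acorr",
    "fuse_psf_acorr",
]


@dataclass
class Displacement:
    """Rigid displacement of a moving volume relative to a reference:
    moving(y) = reference(y - m).  Aligning the moving volume means
    translating it by -m."""

    m: np.ndarray

    def __post_init__(self):
        self.m = np.asarray(self.m, dtype=int)


def register_pair(reference: np.ndarray, moving: np.ndarray,
                  search_radius: float | None = None) -> Displacement:
    """Integer-pixel registration by the cross-correlation peak.

    Returns the lag (relative to the zero-lag center) maximizing
    ``correlate(reference, moving)``.  Exact ties are broken first by the
    smallest Euclidean norm, then lexicographically in (z, y, x).
    """
    if reference.shape != moving.shape:
        raise ValidationError("register_pair requires equal shapes")
    if not np.any(reference) or not np.any(moving):
        raise DegenerateInputError("cannot register an all-zero volume")
    cc = corr.correlate(reference, moving, mode="circular")
    data = cc.data
    peak = data.max()
    cand = np.argwhere(data >= peak)  # exact ties only, barring round-off
    cand = cand[data[tuple(cand.T)] == peak]
    lags = cand - np.asarray(cc.center_index)
    order = np.lexsort(tuple(lags.T[::-1]) + ((lags**2).sum(axis=1),))
    m = lags[order[0]]
    if search_radius is not None and np.linalg.norm(m) > search_radius:
        raise ValidationError(
            f"registration peak {m} outside search radius {search_radius}"
        )
    return Displacement(m)


def fuse_direct(vs: ViewSet, registered: bool = True) -> np.ndarray:
    """Direct-space average of the views, optionally registered.

    With ``registered=True`` every view is registered against the
    reference view by :func:`register_pair` and translated by -m before
    averaging (the classical, pixel-accurate baseline).  With
    ``registered=False`` the raw views are averaged as-is, so residual
    misalignments blur the result.
    """
    if len(vs) == 0:
        raise ValidationError("empty ViewSet")
    ref = vs.views[vs.reference_index]
    acc = np.zeros(vs.shape)
    for i, view in enumerate(vs.views):
        v = view
        if registered and i != vs.reference_index:
            d = register_pair(ref, view)
            v = np.roll(view, tuple(-d.m), axis=(0, 1, 2))
        acc += v
    return acc / len(vs)


def fuse_acorr(vs: ViewSet, mode: str = "circular") -> LagVolume:
    """Average of the per-view auto-correlations, then absolute value.

    No registration is performed: the auto-correlation is inherently
    centered, so the output is identical whether or not the views carry
    rigid shifts (exactly so in circular mode; up to edge effects in
    linear mode).
    """
    if len(vs) == 0:
        raise ValidationError("empty ViewSet")
    acc = None
    for view in vs.views:
        a = corr.autocorrelate(view, mode=mode)
        if acc is None:
            acc = a.data.copy()
            center, m = a.center_index, a.mode
        else:
            acc += a.data
    return sanitize_acorr(LagVolume(acc / len(vs), center, m))


def fuse_psf_acorr(psf_model: PSFModel, angles, voxel_pitch=(1.0, 1.0, 1.0),
                   support=None):
    """PSF averages over the view angles.

    Returns ``(h_bar, H_bar, acorr_h_bar)`` where ``h_bar`` is the
    direct-space mean PSF, ``H_bar`` the mean of the per-angle
    auto-correlations 𝒜{h^φ} (the kernel blurring the averaged
    auto-correlation), and ``acorr_h_bar`` = 𝒜{h̄} for comparison.  The
    two lag volumes coincide only for a single angle; for N ≥ 2 their
    difference is the PSF cross-term average (1/N²-weighted) that the
    auto-correlation route discards.
    """
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    if angles.size < 1:
        raise ValidationError("at least one angle required")
    if support is None:
        # one common grid large enough for every rotated kernel
        support = psf_model.default_support(tuple(voxel_pitch))
    kernels = [render_psf(psf_model, a, voxel_pitch, support=support)
               for a in angles]
    h_bar = np.mean(kernels, axis=0)
    acs = [corr.autocorrelate(k, mode="linear") for k in kernels]
    H_bar = LagVolume(np.mean([a.data for a in acs], axis=0),
                      acs[0].center_index, "linear")
    return h_bar, H_bar, corr.autocorrelate(h_bar, mode="linear")
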