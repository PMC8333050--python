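"""Resolution and reconstruction-quality metrics.

The analysis mirrors the PSF-centric argument of the method: the
resolution of a reconstruction is read out as per-axis FWHM of pointlike
structures (beads or the effective PSF itself), and reconstructions are
scored against ground truth by a normalized cross-correlation maximized
over the solution ambiguity group of de-autocorrelation (global integer
shift × point reflection).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage

from . import corr
from .corr import LagVolume
from .errors import DegenerateInputError, MeasurementError, ValidationError
from .inversion import solve

__all__ = [
    "effective_psf",
    "fwhm",
    "gaussian_fwhm",
    "bead_fwhm",
    "line_profile",
    "recovery_score",
    "best_alignment",
    "align_to",
]


def gaussian_fwhm(sigma: float) -> float:
    """Closed-form FWHM of a Gaussian: 2 sqrt(2 ln 2) σ."""
    return 2.0 * math.sqrt(2.0 * math.log(2.0)) * sigma


def effective_psf(H_bar: LagVolume, n_iter: int = 2000,
                  init_sigma: float = 2.0) -> np.ndarray:
    """Effective direct-space PSF implied by the averaged lag-space PSF:
    h_eff = 𝒜⁻¹{𝓗̄}, computed by Schulz–Snyder inversion.

    Initialized from a centered isotropic Gaussian (σ ``init_sigma``
    voxels); the result is re-centered on its centroid (integer shift)
    and normalized to unit sum.
    """
    H = np.asarray(corr._as_array(H_bar), dtype=float)
    shape = H.shape
    c = [s // 2 for s in shape]
    grids = np.indices(shape)
    quad = sum((g - ci) ** 2 for g, ci in zip(grids, c))
    init = np.exp(-0.5 * quad / init_sigma**2)
    rec, _ = solve(H, "SS", init=init, n_iter=n_iter)
    total = rec.sum()
    if total <= 0:
        raise DegenerateInputError("effective PSF collapsed to zero")
    centroid = [float((g * rec).sum() / total) for g in grids]
    shift = [int(round(ci - mi)) for ci, mi in zip(c, centroid)]
    rec = np.roll(rec, shift, axis=tuple(range(rec.ndim)))
    return rec / rec.sum()


def _profile_through_argmax(v: np.ndarray, axis: int) -> np.ndarray:
    peak = np.unravel_index(int(np.argmax(v)), v.shape)
    sl = list(peak)
    sl[axis] = slice(None)
    return v[tuple(sl)]


def fwhm(v: np.ndarray, axis: int, voxel_pitch: float = 1.0) -> float:
    """Full width at half maximum of the 1D profile through the global
    argmax along ``axis``, with linear interpolation between voxels;
    returned in µm via ``voxel_pitch``.

    A delta spike (no neighbour above half maximum) reports at most one
    voxel pitch.
    """
    prof = np.asarray(_profile_through_argmax(v, axis), dtype=float)
    if prof.size < 2:
        raise MeasurementError("profile too short")
    if prof.max() <= 0:
        raise MeasurementError("profile peak is not positive")
    # oversample the profile (cubic when possible) so the half-maximum
    # crossings are located to well under a voxel even for sigma ~ 1 voxel
    up = 64
    fine_x = np.linspace(0, prof.size - 1, (prof.size - 1) * up + 1)
    order = 3 if prof.size >= 4 else 1
    pc = int(np.argmax(prof))
    nb = [prof[i] for i in (pc - 1, pc + 1) if 0 <= i < prof.size]
    if nb and max(nb) <= prof[pc] / 2.0:
        order = 1  # spike-like peak: cubic overshoot would inflate the width
    fine = ndimage.map_coordinates(prof, fine_x[None, :], order=order,
                                   mode="nearest")
    p = int(np.argmax(fine))
    half = fine[p] / 2.0

    def cross(idx_range):
        prev = p
        for i in idx_range:
            if fine[i] <= half:
                frac = (fine[prev] - half) / (fine[prev] - fine[i])
                return prev + (i - prev) * frac
            prev = i
        raise MeasurementError("profile never crosses half maximum")

    left = cross(range(p - 1, -1, -1))
    right = cross(range(p + 1, len(fine)))
    return float(right - left) / up * voxel_pitch


def line_profile(v: np.ndarray, start_voxel, end_voxel,
                 voxel_pitch=(1.0, 1.0, 1.0), order: int = 1):
    """Interpolated intensities along the segment start→end at unit-voxel
    spacing.

    Returns ``(positions_um, intensities)``; positions are Euclidean
    distances from the start, in µm.  Reversing the endpoints reverses
    the sequence.
    """
    start = np.asarray(start_voxel, dtype=float)
    end = np.asarray(end_voxel, dtype=float)
    for pt in (start, end):
        if np.any(pt < 0) or np.any(pt > np.asarray(v.shape) - 1):
            raise ValidationError(f"endpoint {pt} outside the volume")
    length = np.linalg.norm(end - start)
    npts = max(2, int(round(length)) + 1)
    ts = np.linspace(0.0, 1.0, npts)
    coords = start[:, None] + (end - start)[:, None] * ts[None, :]
    vals = ndimage.map_coordinates(v, coords, order=order, mode="nearest")
    step_um = np.linalg.norm((end - start) * np.asarray(voxel_pitch)) / (npts - 1)
    return ts * (npts - 1) * step_um, vals


def _ncc_max(a0: np.ndarray, b0: np.ndarray):
    """Max over circular shifts of the Pearson correlation; returns
    (score, shift) with shift the lag of b relative to a."""
    cc = corr.correlate(a0, b0, mode="circular")
    idx = np.unravel_index(int(np.argmax(cc.data)), cc.shape)
    shift = tuple(i - c for i, c in zip(idx, cc.center_index))
    denom = np.linalg.norm(a0) * np.linalg.norm(b0)
    return float(cc.data[idx] / denom), shift


def best_alignment(recon: np.ndarray, truth: np.ndarray):
    """Best member of the ambiguity group mapping ``recon`` onto
    ``truth``.

    Returns ``(score, flipped, shift)``: apply ``corrtomo.corr.flip``
    first if ``flipped``, then roll by ``shift``.
    """
    if recon.shape != truth.shape:
        raise ValidationError("recon and truth must share one shape")
    r0 = recon - recon.mean()
    t0 = truth - truth.mean()
    if np.linalg.norm(r0) == 0 or np.linalg.norm(t0) == 0:
        raise DegenerateInputError("zero-variance input")
    best = (-np.inf, False, (0,) * recon.ndim)
    for flipped in (False, True):
        cand = corr.flip(r0) if flipped else r0
        score, shift = _ncc_max(cand, t0)
        if score > best[0]:
            best = (score, flipped, shift)
    return best


def recovery_score(recon: np.ndarray, truth: np.ndarray) -> float:
    """Normalized cross-correlation in [-1, 1], maximized over all global
    integer shifts and the flip ambiguity of de-autocorrelation."""
    return best_alignment(recon, truth)[0]


def bead_fwhm(recon: np.ndarray, truth: np.ndarray, axis: int = 0,
              half_window: int = 10, bead_floor: float = 1.01) -> float:
    """FWHM (voxels) of a reconstructed pointlike bead.

    ``truth`` is the ground-truth phantom whose beads are single voxels
    brighter than ``bead_floor`` (vessel walls sit at 1.0); ``recon``
    must already be aligned to ``truth`` (see :func:`align_to`).  Beads
    are tried from the most isolated one down — a bead shouldered by
    other structure has no clean half-maximum crossing — and the first
    measurable profile wins.
    """
    coords = np.argwhere(truth > 0)
    beads = np.argwhere(truth > bead_floor)
    if beads.size == 0:
        raise MeasurementError("no beads found in the truth volume")

    def isolation(p):
        d = np.linalg.norm(coords - p, axis=1)
        return d[d > 1.5].min() if np.any(d > 1.5) else np.inf

    order = sorted(beads, key=isolation, reverse=True)
    for b in order:
        window = tuple(slice(max(0, c - half_window), c + half_window + 1)
                       for c in b)
        try:
            return fwhm(recon[window], axis)
        except MeasurementError:
            continue
    raise MeasurementError("no bead with a measurable half-maximum profile")


def align_to(recon: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Return ``recon`` flipped/rolled into best registration with
    ``truth`` (for visual comparison and localized metrics)."""
    _, flipped, shift = best_alignment(recon, truth)
    out = corr.flip(recon) if flipped else recon
    return np.roll(out, shift, axis=tuple(range(recon.ndim)))
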