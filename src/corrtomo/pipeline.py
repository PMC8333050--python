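"""End-to-end experiment drivers tying the modules into the full
pipeline: simulate a multi-view acquisition, pre-process, fuse (in
direct or auto-correlation space) and invert.

These are the entry points used by the CLI, the examples and the
acceptance script; each is a thin composition of the module APIs.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import corr
from .errors import ValidationError
from .fusion import fuse_acorr, fuse_direct, fuse_psf_acorr
from .inversion import solve
from .metrics import effective_psf, fwhm, recovery_score
from .phantom import generate_phantom
from .preprocess import preprocess_views
from .psf import PSFModel
from .simulate import NoiseModel, ShiftLaw, ViewSet, simulate_views

__all__ = [
    "study_psf",
    "study_phantom",
    "study_views",
    "reconstruct",
    "psf_report",
    "phantom_experiment",
]

#: study conditions: a full turn in 30° steps (12 views) of a specimen
#: imaged with a 3:1 axially elongated Gaussian PSF, each view carrying a
#: random rigid misalignment of up to 4 voxels.
STUDY_ANGLES = tuple(float(a) for a in range(0, 360, 30))
STUDY_SIGMAS = (1.0, 1.0, 3.0)  # lateral, transverse, scan (µm at 1 µm pitch)
STUDY_SHAPE = (48, 48, 48)
STUDY_MARGIN = 14  # >= 3 sigma_scan (9) + max |shift| (4)


def study_psf() -> PSFModel:
    """The anisotropic PSF of the study conditions (σ_scan/σ_lat = 3)."""
    lat, trans, scan = STUDY_SIGMAS
    return PSFModel(lat, trans, scan)


def study_phantom(seed: int, shape=STUDY_SHAPE, margin=STUDY_MARGIN,
                  n_beads: int = 6) -> np.ndarray:
    """Bead field + hollow vessel tree: beads read out the effective PSF,
    vessel walls probe the resolving of fine paired structures."""
    beads = generate_phantom("bead_field", shape, seed=seed, margin=margin,
                             n_beads=n_beads, amplitude=2.0)
    vessels = generate_phantom("vessel_tree", shape, seed=seed + 1,
                               margin=margin)
    return beads + vessels


def study_views(seed: int, phantom=None, psf_model=None, angles=STUDY_ANGLES,
                max_shift: int = 4, fractional: bool = False,
                noise: NoiseModel | None = None, order: int = 3) -> ViewSet:
    """Simulate the study acquisition (12 views, 30° apart by default)."""
    if phantom is None:
        phantom = study_phantom(seed)
    if psf_model is None:
        psf_model = study_psf()
    return simulate_views(phantom, psf_model, angles,
                          ShiftLaw(max_abs=max_shift, fractional=fractional),
                          noise, seed=seed, order=order)


def _reference_init(pre: ViewSet) -> np.ndarray:
    ref = pre.views[pre.reference_index]
    return np.maximum(ref, 0.0)


def reconstruct(vs: ViewSet, scheme: str, psf_model: PSFModel | None = None,
                n_iter: int = 5000, mode: str | None = None,
                init: str | np.ndarray = "reference",
                registered: bool = True, checkpoint_every: int = 100,
                tol: float | None = None, order: int = 3,
                background: bool = True, callback=None):
    """Reconstruct a ViewSet with one of the three schemes.

    ``direct``
        Pre-process, register (unless ``registered=False``) and average —
        the classical baseline.
    ``ss``
        Pre-process, average the per-view auto-correlations, invert by
        Schulz–Snyder.
    ``au``
        As ``ss`` but additionally renders the lag-space PSF average 𝓗̄
        from ``psf_model`` and runs the Anchor-Update simultaneous
        deconvolution.

    ``mode="circular"`` works on the acquisition grid itself (valid with
    the default close initial guess, the pre-processed reference view);
    ``mode="linear"`` builds the target on the zero-padded 2n-1 lag grid.

    Returns ``(volume, state)``; ``state`` is ``None`` for the direct
    scheme.
    """
    scheme = scheme.lower()
    if scheme not in ("direct", "ss", "au"):
        raise ValidationError(f"unknown scheme {scheme!r}")
    if mode is None:
        mode = "linear" if max(vs.shape) <= 128 else "circular"
    if mode == "circular" and scheme != "direct":
        warnings.warn(
            "circular (unpadded) inversion: convergence relies on a close "
            "initial guess", stacklevel=2)
    pre = preprocess_views(vs, order=order, background=background)
    if scheme == "direct":
        return fuse_direct(pre, registered=registered), None

    chi = fuse_acorr(pre, mode=mode)
    target = chi.data
    if mode in ("linear", "linear-padded"):
        target = corr.embed_centered(target, corr.next_fast_shape(chi.shape))
    if isinstance(init, str):
        if init == "reference":
            init_vol = _reference_init(pre)
        elif init == "mean":
            init_vol = np.maximum(fuse_direct(pre, registered=True), 0.0)
        elif init == "flat":
            init_vol = None
        else:
            raise ValidationError(f"unknown init {init!r}")
    else:
        init_vol = np.asarray(init)

    if scheme == "ss":
        vol, state = solve(target, "SS", init=init_vol, n_iter=n_iter,
                           checkpoint_every=checkpoint_every, tol=tol,
                           mode=mode, callback=callback)
    else:
        if psf_model is None:
            raise ValidationError("the AU scheme requires PSF parameters")
        _, H_bar, _ = fuse_psf_acorr(psf_model, vs.angles, vs.voxel_pitch)
        H = corr.fit_centered(np.maximum(H_bar.data, 0.0), target.shape)
        H /= H.sum()  # keep the lag-space PSF unit-sum after fitting
        vol, state = solve(target, "AU", H=H, init=init_vol, n_iter=n_iter,
                           checkpoint_every=checkpoint_every, tol=tol,
                           mode=mode, callback=callback)
    if vol.shape != vs.shape:
        vol = corr.crop_centered(vol, vs.shape)
    return vol, state


def psf_report(psf_model: PSFModel, angles, voxel_pitch=(1.0, 1.0, 1.0),
               n_iter: int = 10000) -> dict:
    """PSF analysis: h̄, 𝒜{h̄}, 𝓗̄ and h_eff with per-axis FWHM.

    Returns a dict with the four volumes and a FWHM table (µm per axis)
    for h̄ and h_eff.
    """
    h_bar, H_bar, acorr_h_bar = fuse_psf_acorr(psf_model, angles, voxel_pitch)
    h_eff = effective_psf(H_bar, n_iter=n_iter)
    table = {}
    for name, vol in (("h_bar", h_bar), ("h_eff", h_eff)):
        table[name] = {ax_name: fwhm(vol, ax, voxel_pitch[ax])
                       for ax, ax_name in enumerate(("z", "y", "x"))}
    return {"h_bar": h_bar, "H_bar": H_bar, "acorr_h_bar": acorr_h_bar,
            "h_eff": h_eff, "fwhm_um": table}


def phantom_experiment(seed: int, n_iter: int = 5000, mode: str = "circular",
                       max_shift: int = 4, callback=None) -> dict:
    """The headline synthetic experiment: simulate the study acquisition,
    reconstruct with every scheme and score against the known phantom.

    Returns truth, reconstructions and their recovery scores.
    """
    phantom = study_phantom(seed)
    psf_model = study_psf()
    vs = study_views(seed, phantom=phantom, psf_model=psf_model,
                     max_shift=max_shift)
    out = {"phantom": phantom, "views": vs}
    direct_un, _ = reconstruct(vs, "direct", registered=False)
    direct_reg, _ = reconstruct(vs, "direct", registered=True)
    ss, ss_state = reconstruct(vs, "ss", n_iter=n_iter, mode=mode,
                               callback=callback)
    au, au_state = reconstruct(vs, "au", psf_model=psf_model, n_iter=n_iter,
                               mode=mode, callback=callback)
    out.update(direct_unregistered=direct_un, direct_registered=direct_reg,
               ss=ss, au=au, ss_state=ss_state, au_state=au_state)
    out["scores"] = {
        name: recovery_score(out[name], phantom)
        for name in ("direct_unregistered", "direct_registered", "ss", "au")
    }
    return out
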