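"""Multi-view acquisition simulator.

A measurement of the object ``o`` is modelled as a blurred, possibly
noisy view ``o_mu = o * h + eps``.  A multi-view acquisition rotates the
sample about the transverse (y) axis between stacks, so view *i* taken at
angle φ_i is, in the acquisition frame,

    view_i = shift_{m_i}( rotate_{φ_i}(o) * h ) + eps

where ``h`` is the (angle-independent) instrument PSF, elongated along
the scan axis, and ``m_i`` is a small rigid misalignment of the rotation
stage.  Equivalently, after rotating the view back to the reference
frame, the same data is the unrotated object blurred by the rotated PSF
h^{φ_i} — both paths are available and agree to interpolation accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.fft
from scipy import ndimage

from .errors import GeometryError, ValidationError
from .psf import PSFModel, render_psf
from . import corr

__all__ = [
    "NoiseModel",
    "ShiftLaw",
    "ViewSet",
    "rotate_volume",
    "simulate_views",
    "blur_with_rotated_psf",
    "fractional_shift",
    "save_viewset",
    "load_viewset",
]


@dataclass
class NoiseModel:
    """Additive/counting noise applied to each simulated view.

    ``kind="none"`` (the default) is the high-SNR regime in which the
    additive term is neglected; the other kinds exist to stress-test the
    pipeline beyond that assumption.
    """

    kind: str = "none"
    gaussian_sigma: float = 0.0
    photon_scale: float = 100.0
    background_level: float = 0.0

    _KINDS = ("none", "gaussian", "poisson", "poisson+gaussian")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValidationError(f"noise kind must be one of {self._KINDS}")
        if min(self.gaussian_sigma, self.photon_scale, self.background_level) < 0:
            raise ValidationError("noise parameters must be non-negative")

    def apply(self, v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = v + self.background_level
        if self.kind in ("poisson", "poisson+gaussian"):
            # spectral blurring can leave -1e-18-level values; counting
            # noise needs a non-negative rate
            lam = np.maximum(out * self.photon_scale, 0.0)
            out = rng.poisson(lam) / self.photon_scale
        if self.kind in ("gaussian", "poisson+gaussian"):
            out = out + rng.normal(scale=self.gaussian_sigma, size=v.shape)
        return out


@dataclass
class ShiftLaw:
    """Per-view rigid misalignment: uniform integer shifts in
    ``[-max_abs, max_abs]`` voxels, plus an optional fractional component
    in ``[-0.5, 0.5)`` applied by a spectral phase ramp."""

    max_abs: int = 4
    fractional: bool = False

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        s = rng.integers(-self.max_abs, self.max_abs + 1, size=3).astype(float)
        if self.fractional:
            s += rng.uniform(-0.5, 0.5, size=3)
        return s


@dataclass
class ViewSet:
    """Ordered multi-view acquisition with shared geometry.

    ``views[i]`` is the stack acquired at ``angles[i]`` (degrees, strictly
    increasing in [0, 360)), carrying the rigid shift ``true_shifts[i]``
    in voxels.  The reference view (angle 0) has zero shift by
    construction.
    """

    views: list
    angles: np.ndarray
    true_shifts: np.ndarray
    voxel_pitch: tuple = (1.0, 1.0, 1.0)
    reference_index: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        self.true_shifts = np.asarray(self.true_shifts, dtype=float)
        if len(self.views) != len(self.angles):
            raise ValidationError("views and angles length mismatch")
        if len(self.views) == 0:
            raise ValidationError("empty ViewSet")
        if np.any(np.diff(self.angles) <= 0) or not (
            0 <= self.angles[0] and self.angles[-1] < 360
        ):
            raise ValidationError("angles must be strictly increasing in [0, 360)")
        shapes = {v.shape for v in self.views}
        if len(shapes) != 1:
            raise ValidationError(f"views must share one shape, got {shapes}")
        if np.any(self.true_shifts[self.reference_index] != 0):
            raise ValidationError("reference view must carry zero shift")

    def __len__(self):
        return len(self.views)

    @property
    def shape(self):
        return self.views[0].shape


def rotate_volume(v: np.ndarray, angle: float, order: int = 3) -> np.ndarray:
    """Rotate about the y (transverse) axis through the volume center.

    Positive angles move content from +x toward +z.  ``order`` selects
    trilinear (1) or cubic-spline (3) interpolation; multiples of 90° are
    grid-exact either way.
    """
    if order not in (1, 3):
        raise ValidationError("interpolation order must be 1 or 3")
    if angle % 360 == 0:
        return v.copy()
    return ndimage.rotate(v, -angle, axes=(0, 2), reshape=False, order=order,
                          mode="constant", cval=0.0)


def fractional_shift(v: np.ndarray, shift) -> np.ndarray:
    """Circular shift by a possibly fractional voxel vector.

    Integer parts are applied exactly with ``np.roll``; any fractional
    remainder is applied by a Fourier phase ramp (periodic, band-limited
    interpolation).
    """
    shift = np.asarray(shift, dtype=float)
    whole = np.round(shift).astype(int)
    frac = shift - whole
    out = np.roll(v, whole, axis=tuple(range(v.ndim)))
    if np.any(frac != 0):
        F = scipy.fft.fftn(out)
        for ax, f in enumerate(frac):
            k = np.fft.fftfreq(v.shape[ax])
            ramp = np.exp(-2j * np.pi * k * f)
            F *= ramp.reshape([-1 if a == ax else 1 for a in range(v.ndim)])
        out = scipy.fft.ifftn(F).real
    return out


def blur_with_rotated_psf(phantom: np.ndarray, psf_model: PSFModel,
                          angle: float, voxel_pitch=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Reference-frame view of a rotated acquisition, computed without
    rotating the object: convolve the phantom with h^{φ} (the PSF whose
    scan axis is rotated by -φ into the reference frame).

    This is the interpolation-free counterpart of rotate-then-blur-then-
    derotate and is used to validate that path.
    """
    h = render_psf(psf_model, angle, voxel_pitch)
    return corr.convolve(corr.embed_centered(h, phantom.shape), phantom,
                         mode="circular")


def simulate_views(phantom: np.ndarray, psf_model: PSFModel, angles,
                   shift_law: ShiftLaw | None = None,
                   noise: NoiseModel | None = None, *, seed: int,
                   order: int = 3, voxel_pitch=(1.0, 1.0, 1.0)) -> ViewSet:
    """Simulate a multi-view LSFM acquisition of ``phantom``.

    For each angle the phantom is rotated into the acquisition frame,
    blurred with the angle-0 PSF, shifted by a random rigid misalignment
    drawn from ``shift_law`` (the reference view at angle 0 is pinned to
    zero shift) and corrupted by ``noise``.  Deterministic given ``seed``.
    """
    angles = np.asarray(angles, dtype=float)
    if seed is None:
        raise ValidationError("a seed is mandatory for simulation")
    shift_law = shift_law if shift_law is not None else ShiftLaw()
    noise = noise if noise is not None else NoiseModel()
    rng = np.random.default_rng(seed)

    h0 = render_psf(psf_model, 0.0, voxel_pitch)
    if any(hs > ps for hs, ps in zip(h0.shape, phantom.shape)):
        raise GeometryError("phantom smaller than the PSF kernel support")
    h0_embedded = corr.embed_centered(h0, phantom.shape)

    ref = int(np.argmin(np.abs(angles)))
    views, shifts = [], []
    for i, phi in enumerate(angles):
        rot = rotate_volume(phantom, phi, order=order)
        view = corr.convolve(rot, h0_embedded, mode="circular")
        if i == ref:
            m = np.zeros(3)
        else:
            m = shift_law.draw(rng)
        if np.any(m != 0):
            view = fractional_shift(view, m)
        view = noise.apply(view, rng)
        views.append(view)
        shifts.append(m)
    return ViewSet(views, angles, np.array(shifts), tuple(voxel_pitch),
                   reference_index=ref,
                   meta={"seed": seed, "order": order,
                         "psf": psf_model.sigmas_zyx, "noise": noise.kind})


# ---------------------------------------------------------------------------
# on-disk representation: one multi-page TIFF per angle + YAML sidecar

def save_viewset(directory, vs: ViewSet) -> None:
    import tifffile
    import yaml

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, (view, phi, m) in enumerate(zip(vs.views, vs.angles, vs.true_shifts)):
        stem = f"view_{i:03d}"
        tifffile.imwrite(directory / f"{stem}.tif",
                         np.asarray(view, dtype=np.float32))
        sidecar = {
            "index": i,
            "angle_deg": float(phi),
            "true_shift_voxels": [float(x) for x in m],
            "voxel_pitch_um": [float(p) for p in vs.voxel_pitch],
            "reference_index": int(vs.reference_index),
            "meta": {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in vs.meta.items()},
        }
        (directory / f"{stem}.yml").write_text(yaml.safe_dump(sidecar))


def load_viewset(directory) -> ViewSet:
    import tifffile
    import yaml

    directory = Path(directory)
    tifs = sorted(directory.glob("view_*.tif"))
    if not tifs:
        raise ValidationError(f"no view_*.tif stacks found in {directory}")
    views, angles, shifts = [], [], []
    ref, pitch, meta = 0, (1.0, 1.0, 1.0), {}
    for t in tifs:
        side = yaml.safe_load(t.with_suffix(".yml").read_text())
        views.append(tifffile.imread(t).astype(np.float64))
        angles.append(side["angle_deg"])
        shifts.append(side["true_shift_voxels"])
        ref = side.get("reference_index", 0)
        pitch = tuple(side.get("voxel_pitch_um", pitch))
        meta = side.get("meta", {})
    return ViewSet(views, np.array(angles), np.array(shifts), pitch,
                   reference_index=ref, meta=meta)
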