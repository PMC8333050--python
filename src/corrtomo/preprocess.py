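"""Pre-processing of raw multi-view stacks.

The pipeline order is fixed by the API:

1. :func:`subtract_background` on each raw stack,
2. :func:`to_reference_frame` — rotating each stack back to the φ=0
   orientation is the only geometric pre-processing required,
3. auto-correlate and average (see :mod:`corrtomo.fusion`),
4. :func:`sanitize_acorr` — absolute value of the averaged
   auto-correlation, removing the small negatives introduced by
   background subtraction and FFT round-off.

Negative voxels created by background subtraction are deliberately kept
until step 4: removal happens in lag space, not in direct space.
"""

from __future__ import annotations

import numpy as np

from .corr import LagVolume
from .errors import ValidationError
from .simulate import ViewSet, rotate_volume

__all__ = [
    "default_dark_region",
    "subtract_background",
    "to_reference_frame",
    "sanitize_acorr",
    "preprocess_views",
]


def default_dark_region(shape, size: int = 8) -> tuple:
    """Corner box at the index origin, clipped to the volume: the default
    stand-in for 'a dark region where the sample is not present'."""
    return tuple(slice(0, min(size, s)) for s in shape)


def subtract_background(view: np.ndarray, dark_region=None) -> np.ndarray:
    """Subtract the mean intensity of a dark region from the whole stack.

    The output may contain negative voxels; they are handled downstream
    by :func:`sanitize_acorr`.  The mean of the output over the dark
    region is zero to float precision.
    """
    if dark_region is None:
        dark_region = default_dark_region(view.shape)
    patch = view[tuple(dark_region)]
    if patch.size == 0:
        raise ValidationError("dark region is empty")
    return view - patch.mean()


def to_reference_frame(view: np.ndarray, angle: float, order: int = 3) -> np.ndarray:
    """Rotate a view acquired at ``angle`` back to the 0° reference
    orientation (rotation by -angle about the y axis)."""
    if angle == 0:
        return view.copy()
    return rotate_volume(view, -angle, order=order)


def sanitize_acorr(chi: LagVolume) -> LagVolume:
    """Element-wise absolute value of an (averaged) auto-correlation.

    Idempotent; preserves the centro-symmetric structure since |·| is
    even.
    """
    return LagVolume(np.abs(chi.data), chi.center_index, chi.mode)


def preprocess_views(vs: ViewSet, dark_region=None, order: int = 3,
                     background: bool = True) -> ViewSet:
    """Background-subtract and rotate every view to the reference frame.

    Returns a new ViewSet (angles and true shifts are carried over; the
    views themselves are now all in the φ=0 orientation)."""
    out = []
    for view, phi in zip(vs.views, vs.angles):
        v = subtract_background(view, dark_region) if background else view
        out.append(to_reference_frame(v, phi, order=order))
    meta = dict(vs.meta)
    meta["preprocessed"] = True
    return ViewSet(out, vs.angles, vs.true_shifts, vs.voxel_pitch,
                   reference_index=vs.reference_index, meta=meta)
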