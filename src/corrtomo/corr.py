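"""Exact n-dimensional convolution/correlation algebra.

All spatial quantities follow a *centered* convention: the origin of a
volume (and the zero lag of a correlation) lives at ``floor(shape/2)`` on
every axis, so results are directly inspectable and the centro-symmetry of
real auto-correlations is testable by index arithmetic.

Two computation modes are supported:

``circular``
    Cyclic algebra on the input grid itself.  Integer circular shifts of
    the input leave the auto-correlation *exactly* unchanged (see
    :func:`autocorrelate`), which is the property the whole multi-view
    fusion strategy rests on.

``linear``
    Zero-padded ("linear-padded") algebra: each axis is padded to at least
    ``n_a + n_b - 1`` samples (rounded up to a fast FFT length) before the
    spectral product, then cropped, so no wrap-around occurs.  The full
    correlation of two n-signals lives on a translation space 2n-1 long.

The lag-space sign convention is ``(a ⋆ b)(ξ) = Σ_y a(y) · b(y + ξ)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft

from .errors import GeometryError

__all__ = [
    "LagVolume",
    "convolve",
    "correlate",
    "autocorrelate",
    "flip",
    "embed_centered",
    "crop_centered",
]

#: canonical mode names; "linear-padded" is accepted as an alias of "linear"
MODES = ("circular", "linear")


def _check_mode(mode: str) -> str:
    if mode == "linear-padded":
        return "linear"
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    return mode


def center_index(shape) -> tuple:
    """Origin voxel of a centered grid: floor(shape/2) per axis."""
    return tuple(int(s) // 2 for s in shape)


@dataclass
class LagVolume:
    """A grid over correlation lags ξ with the zero lag at ``center_index``.

    Parameters
    ----------
    data : ndarray
        Real-valued lag-space samples.
    center_index : tuple of int
        Voxel holding ξ = 0 (``floor(shape/2)`` per axis for equal-shape
        inputs).
    mode : {"circular", "linear"}
        Algebra the volume was produced under.
    """

    data: np.ndarray
    center_index: tuple
    mode: str

    @property
    def shape(self):
        return self.data.shape

    @property
    def center_value(self) -> float:
        return float(self.data[self.center_index])

    def __array__(self, dtype=None, copy=None):
        if dtype is not None:
            return self.data.astype(dtype)
        return self.data


def _as_array(x) -> np.ndarray:
    if isinstance(x, LagVolume):
        return x.data
    return np.asarray(x)


# ---------------------------------------------------------------------------
# centered <-> rolled layout helpers
#
# "rolled" layout has the origin at index 0 (the native FFT convention);
# ifftshift maps centered -> rolled and fftshift maps back, exactly, for
# both even and odd sizes.

def _to_rolled(a: np.ndarray) -> np.ndarray:
    return np.fft.ifftshift(a)


def _to_centered(a: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(a)


def _flip_rolled(a: np.ndarray) -> np.ndarray:
    """x -> -x mod n on every axis (origin at index 0 stays put)."""
    out = a
    for ax in range(a.ndim):
        out = np.roll(np.flip(out, axis=ax), 1, axis=ax)
    return out


def flip(a: np.ndarray) -> np.ndarray:
    """Point reflection ã(x) = a(-x) about the centered origin.

    The reflection is circular about ``floor(shape/2)``, so it is an exact
    involution on any grid size and maps a grid-symmetric function to
    itself.
    """
    a = _as_array(a)
    return _to_centered(_flip_rolled(_to_rolled(a)))


# ---------------------------------------------------------------------------
# circular (cyclic, centered) algebra on equal-shape grids

def _cconv(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cyclic convolution, centered layout in and out."""
    A = scipy.fft.rfftn(_to_rolled(a))
    B = scipy.fft.rfftn(_to_rolled(b))
    return _to_centered(scipy.fft.irfftn(A * B, s=a.shape))


def _ccorr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cyclic correlation (a ⋆ b)(ξ) = Σ a(y) b(y+ξ), centered layout."""
    A = scipy.fft.rfftn(_to_rolled(a))
    B = scipy.fft.rfftn(_to_rolled(b))
    return _to_centered(scipy.fft.irfftn(np.conj(A) * B, s=a.shape))


# ---------------------------------------------------------------------------
# padded-grid embedding

def next_fast_shape(shape) -> tuple:
    return tuple(scipy.fft.next_fast_len(int(s), real=True) for s in shape)


def embed_centered(a: np.ndarray, shape) -> np.ndarray:
    """Zero-embed ``a`` into a larger grid, keeping centers coincident."""
    a = _as_array(a)
    shape = tuple(int(s) for s in shape)
    if any(s < n for s, n in zip(shape, a.shape)):
        raise GeometryError(f"cannot embed shape {a.shape} into {shape}")
    out = np.zeros(shape, dtype=a.dtype)
    starts = [c - ci for c, ci in zip(center_index(shape), center_index(a.shape))]
    sl = tuple(slice(s, s + n) for s, n in zip(starts, a.shape))
    out[sl] = a
    return out


def crop_centered(a: np.ndarray, shape) -> np.ndarray:
    """Inverse of :func:`embed_centered`: central crop to ``shape``."""
    a = _as_array(a)
    shape = tuple(int(s) for s in shape)
    if any(s > n for s, n in zip(shape, a.shape)):
        raise GeometryError(f"cannot crop shape {a.shape} to {shape}")
    starts = [c - ci for c, ci in zip(center_index(a.shape), center_index(shape))]
    sl = tuple(slice(s, s + n) for s, n in zip(starts, shape))
    return a[sl]


def fit_centered(a: np.ndarray, shape) -> np.ndarray:
    """Pad or crop per axis (whichever each axis needs) to ``shape``,
    keeping centers coincident."""
    a = _as_array(a)
    inter = tuple(min(s, n) for s, n in zip(shape, a.shape))
    return embed_centered(crop_centered(a, inter), shape)


def _pad_pair_transform(a, b, op) -> np.ndarray:
    """Linear (full) conv/corr of possibly unequal shapes via zero padding.

    Returns the full-size result (n_a + n_b - 1 per axis).
    """
    full = tuple(na + nb - 1 for na, nb in zip(a.shape, b.shape))
    fshape = next_fast_shape(full)
    A = scipy.fft.rfftn(a, fshape)
    B = scipy.fft.rfftn(b, fshape)
    out = scipy.fft.irfftn(op(A, B), s=fshape)
    return out[tuple(slice(0, f) for f in full)]


# ---------------------------------------------------------------------------
# public operations

def convolve(a, b, mode: str = "linear") -> np.ndarray:
    """Convolution a*b.

    Circular mode requires equal shapes and returns an equal-shape cyclic
    convolution in the centered layout (a delta at the center is the
    identity element).  Linear mode zero-pads to the full output size
    ``n_a + n_b - 1`` per axis.  Commutative in both modes.
    """
    a, b = _as_array(a), _as_array(b)
    mode = _check_mode(mode)
    if a.ndim != b.ndim:
        raise GeometryError(f"dimensionality mismatch: {a.ndim} vs {b.ndim}")
    if mode == "circular":
        if a.shape != b.shape:
            raise GeometryError(
                f"circular mode requires equal shapes, got {a.shape} vs {b.shape}"
            )
        return _cconv(a, b)
    return _pad_pair_transform(a, b, lambda A, B: A * B)


def correlate(a, b, mode: str = "linear") -> LagVolume:
    """Cross-correlation (a ⋆ b)(ξ) = Σ_y a(y) b(y+ξ).

    The zero lag maps to ``center_index``.  Equivalent to
    ``convolve(flip(a), b)`` re-centered.  In linear mode the output spans
    lags ``-(n_a-1) … n_b-1`` per axis, with ξ=0 at index ``n_a - 1``.
    """
    a, b = _as_array(a), _as_array(b)
    mode = _check_mode(mode)
    if a.ndim != b.ndim:
        raise GeometryError(f"dimensionality mismatch: {a.ndim} vs {b.ndim}")
    if mode == "circular":
        if a.shape != b.shape:
            raise GeometryError(
                f"circular mode requires equal shapes, got {a.shape} vs {b.shape}"
            )
        data = _ccorr(a, b)
        return LagVolume(data, center_index(data.shape), "circular")
    # linear: correlate = conv(flip(a), b); flip the *unpadded* a so the
    # full output indexes lags -(n_a-1)..(n_b-1) with 0 at n_a-1
    a_rev = a[tuple(slice(None, None, -1) for _ in range(a.ndim))]
    data = _pad_pair_transform(a_rev, b, lambda A, B: A * B)
    return LagVolume(data, tuple(n - 1 for n in a.shape), "linear")


def autocorrelate(a, mode: str = "linear") -> LagVolume:
    """Auto-correlation 𝒜{a} = a ⋆ a.

    The value at the zero lag equals Σa² and, in linear mode, the total sum
    equals (Σa)².  In circular mode the result is *exactly* invariant to
    any integer circular shift of ``a``: the input is first rolled so its
    global argmax sits at the grid origin (a mathematical no-op for a
    shift-invariant quantity) and only then transformed, so two inputs that
    differ by an integer roll produce bit-identical outputs.
    """
    a = _as_array(a)
    mode = _check_mode(mode)
    if mode == "circular":
        anchor = np.unravel_index(int(np.argmax(a)), a.shape)
        a0 = np.roll(a, tuple(-i for i in anchor), axis=tuple(range(a.ndim)))
        A = scipy.fft.rfftn(a0)
        data = _to_centered(scipy.fft.irfftn(np.conj(A) * A, s=a.shape))
        return LagVolume(data, center_index(a.shape), "circular")
    full = tuple(2 * n - 1 for n in a.shape)
    fshape = next_fast_shape(full)
    A = scipy.fft.rfftn(a, fshape)
    data0 = scipy.fft.irfftn(np.conj(A) * A, s=fshape)
    # lags 0..n-1 are at 0.., lags -(n-1)..-1 wrapped at the end; re-center
    shift = tuple(c for c in center_index(full))
    data = np.roll(data0, shift, axis=tuple(range(a.ndim)))
    data = data[tuple(slice(0, f) for f in full)]
    return LagVolume(data, center_index(full), "linear")
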