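"""Synthetic phantoms standing in for a fluorescently labelled specimen.

Three families are provided:

* ``bead_field`` — pointlike fluorescent beads, the classic resolution
  target: each bead is a single bright voxel (optionally a small Gaussian
  blob), so the width of its reconstructed image reads out the effective
  PSF directly.
* ``vessel_tree`` — branching tubular structures with hollow lumina,
  emulating stained vasculature (walls bright, interior dark).
* ``shell`` — a hollow spherical shell.

All phantoms are non-negative, deterministic given their seed, and keep a
zero margin on every face at least as wide as the requested ``margin`` so
that PSF blurring, per-view shifts and rotations about the y axis never
push signal across the volume boundary.  Content is additionally confined
to the sphere inscribed in the (z, x) rotation plane.
"""

from __future__ import annotations

import numpy as np

from .errors import GeometryError, ValidationError

__all__ = ["generate_phantom"]

_KINDS = ("bead_field", "vessel_tree", "shell")


def _interior_box(shape, margin):
    lo = [margin] * 3
    hi = [s - margin for s in shape]
    if any(h <= l for l, h in zip(lo, hi)):
        raise GeometryError(
            f"margin {margin} leaves no interior for shape {tuple(shape)}"
        )
    return lo, hi


def _inscribed_radius(shape, margin):
    # rotation happens in the (z, x) plane: confine to its inscribed circle
    return min(shape[0], shape[2]) / 2.0 - margin


def _radial_sq(shape):
    c = [s // 2 for s in shape]
    z, y, x = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (z - c[0]) ** 2, (y - c[1]) ** 2, (x - c[2]) ** 2


def _bead_field(shape, margin, rng, n_beads=12, amplitude=1.0, min_sep=5):
    vol = np.zeros(shape)
    if n_beads == 0:
        return vol
    lo, hi = _interior_box(shape, margin)
    r_max = _inscribed_radius(shape, margin)
    c = np.array([s // 2 for s in shape], dtype=float)
    placed = []
    attempts = 0
    while len(placed) < n_beads:
        attempts += 1
        if attempts > 20000:
            raise GeometryError("could not place beads with requested separation")
        p = np.array([rng.integers(l, h) for l, h in zip(lo, hi)])
        if np.hypot(p[0] - c[0], p[2] - c[2]) > r_max:
            continue
        if placed and min(np.linalg.norm(p - q) for q in placed) < min_sep:
            continue
        placed.append(p)
        vol[tuple(p)] = amplitude * float(rng.uniform(0.5, 1.0))
    return vol


def _stamp_ball(vol, center, radius, value):
    shape = vol.shape
    lo = [max(0, int(np.floor(c - radius - 1))) for c in center]
    hi = [min(s, int(np.ceil(c + radius + 2))) for c, s in zip(center, shape)]
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    grids = np.ogrid[sl]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    vol[sl][d2 <= radius**2] = value


def _vessel_tree(shape, margin, rng, n_seeds=2, wall_radius=2.5,
                 lumen_radius=1.2, branch_prob=0.03, step=1.0,
                 n_steps=200, amplitude=1.0):
    """Random-walk tubes with branchings; walls bright, lumen carved dark."""
    outer = np.zeros(shape)
    inner = np.zeros(shape)
    r_max = _inscribed_radius(shape, margin)
    lo, hi = _interior_box(shape, margin)
    c = np.array([s // 2 for s in shape], dtype=float)

    def inside(p):
        # the stamped ball must stay inside the margin in full
        in_box = all(l + wall_radius <= pi <= h - wall_radius - 1
                     for pi, l, h in zip(p, lo, hi))
        return in_box and np.hypot(p[0] - c[0], p[2] - c[2]) <= r_max - wall_radius

    walkers = []
    for _ in range(n_seeds):
        p = c + rng.uniform(-0.25, 0.25, size=3) * (np.array(shape) - 2 * margin)
        d = rng.normal(size=3)
        walkers.append([p, d / np.linalg.norm(d), n_steps])
    while walkers:
        p, d, budget = walkers.pop()
        for _ in range(budget):
            if not inside(p):
                break
            _stamp_ball(outer, p, wall_radius, amplitude)
            _stamp_ball(inner, p, lumen_radius, 1.0)
            d = d + rng.normal(scale=0.25, size=3)
            d /= np.linalg.norm(d)
            p = p + step * d
            if rng.uniform() < branch_prob and len(walkers) < 8:
                db = d + rng.normal(scale=0.8, size=3)
                walkers.append([p.copy(), db / np.linalg.norm(db), budget // 2])
    vol = outer.copy()
    vol[inner > 0] = 0.0  # hollow lumen: walls only
    return vol


def _shell(shape, margin, rng, radius=None, thickness=2.0, amplitude=1.0):
    r_max = _inscribed_radius(shape, margin)
    if radius is None:
        radius = 0.6 * r_max
    if radius + thickness / 2 > r_max:
        raise GeometryError("shell does not fit inside the rotation-safe sphere")
    z2, y2, x2 = _radial_sq(shape)
    r = np.sqrt(z2 + y2 + x2)
    vol = np.zeros(shape)
    vol[np.abs(r - radius) <= thickness / 2.0] = amplitude
    return vol


def generate_phantom(kind: str, shape, *, seed: int, margin: int = 10,
                     **params) -> np.ndarray:
    """Build a deterministic synthetic phantom.

    Parameters
    ----------
    kind : {"bead_field", "vessel_tree", "shell"}
    shape : tuple of int
        Volume shape (z, y, x).
    seed : int
        Mandatory; the same seed always yields a bit-identical volume.
    margin : int
        Guaranteed zero border on every face, in voxels.  Must be at least
        the PSF support half-width plus the largest misalignment shift of
        the planned acquisition.
    **params
        Family-specific parameters (e.g. ``n_beads``, ``wall_radius``).
    """
    if kind not in _KINDS:
        raise ValidationError(f"unknown phantom kind {kind!r}; choose from {_KINDS}")
    shape = tuple(int(s) for s in shape)
    if min(shape) <= 0:
        raise GeometryError("shape must be strictly positive per axis")
    _interior_box(shape, margin)
    if _inscribed_radius(shape, margin) <= 0:
        raise GeometryError("margin leaves no rotation-safe interior")
    rng = np.random.default_rng(seed)
    fn = {"bead_field": _bead_field, "vessel_tree": _vessel_tree, "shell": _shell}[kind]
    vol = fn(shape, margin, rng, **params)
    assert vol.min() >= 0.0
    return vol
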