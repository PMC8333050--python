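"""Parametric anisotropic Gaussian PSF model for light-sheet acquisitions.

In LSFM the detection/scanning geometry elongates the point-spread
function along the scan (longitudinal, z) axis, while the in-plane
(lateral x, transverse y) widths stay close to the diffraction limit.
The model here is a separable Gaussian with per-axis standard deviations,
optionally rotated about the transverse (y) axis to express the PSF of a
rotated acquisition in the reference frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

from .errors import GeometryError, ValidationError

__all__ = ["PSFModel", "render_psf", "rotation_matrix_y"]


@dataclass
class PSFModel:
    """Anisotropic Gaussian PSF, elongated along the scan (z) axis.

    Parameters
    ----------
    sigma_lateral : float
        Standard deviation along x, in µm.
    sigma_transverse : float
        Standard deviation along y, in µm.
    sigma_scan : float
        Standard deviation along z (the elongated scanning axis), in µm.
        Must be >= ``sigma_lateral``.
    support : tuple of int, optional
        Rendered kernel size in voxels per (z, y, x) axis.  Defaults to an
        odd size covering at least 6σ per axis at the given pitch.
    """

    sigma_lateral: float
    sigma_transverse: float
    sigma_scan: float
    support: tuple | None = field(default=None)

    def __post_init__(self):
        if min(self.sigma_lateral, self.sigma_transverse, self.sigma_scan) <= 0:
            raise ValidationError("PSF sigmas must be strictly positive")
        if self.sigma_scan < self.sigma_lateral:
            raise ValidationError(
                "sigma_scan must be >= sigma_lateral (LSFM axial elongation)"
            )

    @property
    def sigmas_zyx(self) -> tuple:
        return (self.sigma_scan, self.sigma_transverse, self.sigma_lateral)

    def default_support(self, voxel_pitch=(1.0, 1.0, 1.0)) -> tuple:
        """Smallest odd voxel counts holding ±3σ per axis.  Pass a larger
        explicit support where truncation-free moments matter.

        The in-plane (z, x) axes share the worst-case extent so that a
        rotation about y never truncates the elongated lobe.
        """
        s_zx = max(self.sigma_scan, self.sigma_lateral)
        need = (s_zx, self.sigma_transverse, s_zx)
        out = []
        for sig, pitch in zip(need, voxel_pitch):
            n = int(math.ceil(6.0 * sig / pitch)) + 1
            out.append(n + 1 - n % 2)
        return tuple(out)


def rotation_matrix_y(angle_deg: float) -> np.ndarray:
    """Rotation about the transverse (y) axis in (z, y, x) coordinates.

    Positive angles map +x toward +z, matching
    :func:`corrtomo.simulate.rotate_volume`.
    """
    c, s = math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def render_psf(model: PSFModel, angle: float = 0.0,
               voxel_pitch=(1.0, 1.0, 1.0), support=None) -> np.ndarray:
    """Render h^φ: the unit-sum PSF of a view at ``angle``, expressed in
    the reference frame.

    The elongated (scan) axis of the kernel is the z axis rotated by
    ``-angle`` about y, i.e. the direction the rotated acquisition was
    scanned along, brought back to the φ=0 frame.  Rendering evaluates the
    rotated-covariance Gaussian analytically on the voxel grid (no image
    interpolation), so second moments are exact up to truncation.

    Raises
    ------
    GeometryError
        If the requested support cannot hold ±3σ on some axis.
    """
    pitch = np.asarray(voxel_pitch, dtype=float)
    if support is None:
        support = model.support or model.default_support(tuple(pitch))
    support = tuple(int(s) for s in support)

    R = rotation_matrix_y(-angle)
    cov = R @ np.diag(np.square(model.sigmas_zyx)) @ R.T
    # truncation check: marginal std along each grid axis is sqrt(cov_ii)
    for ax, (n, p) in enumerate(zip(support, pitch)):
        if (n - 1) * p / 2.0 < 3.0 * math.sqrt(cov[ax, ax]):
            raise GeometryError(
                f"support {support} too small to hold 6 sigma on axis {ax}"
            )
    prec = np.linalg.inv(cov)
    axes = [ (np.arange(n) - n // 2) * p for n, p in zip(support, pitch) ]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    u = np.stack([zz, yy, xx], axis=-1)
    quad = np.einsum("...i,ij,...j->...", u, prec, u)
    k = np.exp(-0.5 * quad)
    return k / k.sum()
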