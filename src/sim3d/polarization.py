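"""Fluorescent dipole-orientation mapping from angle-resolved SIM data.

Under linearly polarized excitation the detected intensity of a fluorophore
with in-plane transition-dipole angle theta follows Malus-type modulation
``I(alpha) = dc + A cos(2 (alpha - theta))`` as the polarization azimuth alpha
rotates with the pattern angle.  Three pattern angles determine (dc, A,
theta) exactly through the linear basis {1, cos 2a, sin 2a}; theta is
pi-periodic and reported in [0, pi).

Illumination non-uniformity between the three angles biases theta.  It is
calibrated from three widefield bead images (the per-angle phase averages of
a bead acquisition): bead intensities are interpolated into smooth per-angle
intensity maps calib_ang1..3 and the per-pixel ratios

    calib1 = calib_ang2 / calib_ang1,   calib2 = calib_ang3 / calib_ang1

divide the second and third angle images before the fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import interpolate, ndimage

from .data_model import RawStack


@dataclass
class CalibrationRatios:
    """Per-pixel inter-angle illumination ratios (angle 2 / 1 and 3 / 1)."""

    calib1: np.ndarray
    calib2: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        for name in ("calib1", "calib2"):
            r = getattr(self, name)
            if np.any(~np.isfinite(r[self.mask])) or np.any(r[self.mask] <= 0):
                raise ValueError(f"{name} must be positive and finite on the mask")


@dataclass
class OrientationMap:
    """Per-pixel dipole orientation with modulation amplitude and mean."""

    theta: np.ndarray       # rad, in [0, pi); meaningful only where mask
    amplitude: np.ndarray
    dc: np.ndarray
    mask: np.ndarray


def _smooth_intensity_map(image: np.ndarray, bead_mask: np.ndarray,
                          smooth_sigma: float) -> np.ndarray:
    """Interpolate bead intensities over the field into a smooth map."""
    pts = np.argwhere(bead_mask)
    vals = image[bead_mask]
    yy, xx = np.mgrid[: image.shape[0], : image.shape[1]]
    filled = interpolate.griddata(pts, vals, (yy, xx), method="linear")
    nearest = interpolate.griddata(pts, vals, (yy, xx), method="nearest")
    filled = np.where(np.isfinite(filled), filled, nearest)
    return ndimage.gaussian_filter(filled, smooth_sigma)


def calibration_ratios(beads_ang1: np.ndarray, beads_ang2: np.ndarray,
                       beads_ang3: np.ndarray, *, bead_threshold: float = 0.2,
                       smooth_sigma: float = 5.0) -> CalibrationRatios:
    """Build illumination-ratio maps from three same-field bead images.

    ``bead_threshold`` is the fraction of each image's maximum above which a
    pixel counts as bead coverage; gaps between beads are filled by
    interpolation and the maps lightly smoothed.
    """
    imgs = [np.asarray(b, dtype=float) for b in (beads_ang1, beads_ang2, beads_ang3)]
    if len({im.shape for im in imgs}) != 1:
        raise ValueError("bead images must share a shape")
    bead_mask = np.ones(imgs[0].shape, dtype=bool)
    for im in imgs:
        if im.max() <= 0:
            raise ValueError("empty bead image")
        bead_mask &= im > bead_threshold * im.max()
    if not bead_mask.any():
        raise ValueError("empty bead mask — no pixels exceed the threshold "
                         "in all three angles")
    maps = [_smooth_intensity_map(im, bead_mask, smooth_sigma) for im in imgs]
    valid = maps[0] > 1e-12 * maps[0].max()
    with np.errstate(divide="ignore", invalid="ignore"):
        c1 = np.where(valid, maps[1] / maps[0], 1.0)
        c2 = np.where(valid, maps[2] / maps[0], 1.0)
    return CalibrationRatios(calib1=c1, calib2=c2, mask=valid)


def estimate_dipole_orientation(angle_means, pattern_angles,
                                calib: CalibrationRatios | None = None, *,
                                amplitude_floor: float = 0.05,
                                background_sd: float = 0.0) -> OrientationMap:
    """Per-pixel dipole orientation from three per-angle widefield images.

    ``angle_means`` is a (3, y, x) array of phase-averaged images, one per
    pattern angle; ``pattern_angles`` the corresponding polarization azimuths
    (rad, distinct modulo pi).  With ``calib`` supplied the second and third
    images are divided by calib1 and calib2 first.  Pixels whose relative
    modulation ``A/dc`` falls below ``amplitude_floor`` (or whose mean is not
    above ``3 * background_sd``) are masked: the angle of near-zero modulation
    is noise.
    """
    I = np.array(angle_means, dtype=float)
    alphas = np.asarray(pattern_angles, dtype=float)
    if I.shape[0] != 3 or alphas.size != 3:
        raise ValueError("exactly three pattern angles are required")
    wrapped = np.sort(np.mod(alphas, np.pi))
    if np.min(np.diff(np.concatenate([wrapped, [wrapped[0] + np.pi]]))) < 1e-6:
        raise ValueError("pattern angles must be distinct modulo pi")
    if calib is not None:
        I = I.copy()
        I[1] = I[1] / calib.calib1
        I[2] = I[2] / calib.calib2

    # exact three-point solution of I_a = c0 + c1 cos 2a + c2 sin 2a
    A = np.stack([np.ones(3), np.cos(2 * alphas), np.sin(2 * alphas)], axis=1)
    coeff = np.linalg.solve(A, I.reshape(3, -1))
    dc = coeff[0].reshape(I.shape[1:])
    c_cos = coeff[1].reshape(I.shape[1:])
    c_sin = coeff[2].reshape(I.shape[1:])
    amplitude = np.hypot(c_cos, c_sin)
    theta = np.mod(0.5 * np.arctan2(c_sin, c_cos), np.pi)

    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(dc > 0, amplitude / dc, 0.0)
    mask = (rel >= amplitude_floor) & (dc > 3.0 * background_sd) & (dc > 0)
    theta = np.where(mask, theta, np.nan)
    return OrientationMap(theta=theta, amplitude=amplitude, dc=dc, mask=mask)


def per_angle_widefield(stack: RawStack, z: int | None = None) -> np.ndarray:
    """Phase-averaged image per angle at one focal slice (default: central z)."""
    if z is None:
        z = stack.n_z // 2
    return stack.data[:, :, z].mean(axis=1)


def render_orientation_hsv(omap: OrientationMap) -> np.ndarray:
    """HSV composite (hue = theta, value = mean intensity) as an RGB array."""
    from matplotlib.colors import hsv_to_rgb

    h = np.where(omap.mask, omap.theta / np.pi, 0.0)
    v = omap.dc / omap.dc.max() if omap.dc.max() > 0 else omap.dc
    s = omap.mask.astype(float)
    return hsv_to_rgb(np.stack([h, s, np.clip(v, 0, 1)], axis=-1))


__all__ = [
    "CalibrationRatios", "OrientationMap", "calibration_ratios",
    "estimate_dipole_orientation", "per_angle_widefield",
    "render_orientation_hsv",
]
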