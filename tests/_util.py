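"""Shared test helpers."""

import numpy as np


def wrap_angle(a):
    """Wrap to (-pi, pi]."""
    return (a + np.pi) % (2 * np.pi) - np.pi


def center_phase_error(p_hat, phi_hat, p_true, phi_true, shape_yx):
    """Circular pattern-phase error evaluated at the field-of-view center.

    The pattern phase is referenced to the real-space origin; comparing there
    inflates the error by (frequency error) x (full field of view).  At the
    center — where the estimate is conditioned — the comparison is meaningful.
    """
    rc = np.array([shape_yx[0] / 2.0, shape_yx[1] / 2.0])
    a = phi_hat + 2 * np.pi * np.dot(np.asarray(p_hat), rc)
    b = phi_true + 2 * np.pi * np.dot(np.asarray(p_true), rc)
    return abs(wrap_angle(a - b))


def pattern_profile(flat, azimuth, r_max, n=512):
    """1-D profile of a 2-D spectrum magnitude along one azimuth from DC."""
    from scipy import ndimage

    cy, cx = flat.shape[0] // 2, flat.shape[1] // 2
    r = np.linspace(0.0, r_max, n)
    vals = ndimage.map_coordinates(
        flat, [cy + r * np.sin(azimuth), cx + r * np.cos(azimuth)], order=1)
    return r, vals


def profile_peak_ratio(r, prof, r0, half=10.0, exclude=2.0):
    """Local maximum near r0 over the median of its neighborhood."""
    peak = prof[np.abs(r - r0) <= 1.5].max()
    neigh = prof[(np.abs(r - r0) > exclude) & (np.abs(r - r0) <= half)]
    return peak / np.median(neigh)


def z_contrast(volume):
    """Michelson contrast of the laterally averaged axial profile."""
    prof = volume.mean(axis=(1, 2))
    return (prof.max() - prof.min()) / (prof.max() + prof.min())
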