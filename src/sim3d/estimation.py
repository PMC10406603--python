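"""Illumination-pattern parameter estimation by cross-correlation.

The lateral pattern frequency is found from the correlation between the zero
band and a moved band over lateral shifts: the +1 band peaks at ``p``, the +2
band at ``2p``.  The second order is traditionally preferred (twice the
displacement per unit frequency error), but its peak is weak — at low photon
counts it drowns before the +1 peak does — so a peak-contrast reliability
criterion decides per angle whether the second-order refinement is trusted;
if not, the estimator falls back to the +1 result.

For high pattern frequencies ``2|p|`` exceeds the acquisition Nyquist: the
second-order content is aliased in the raw sampling and its correlation peak
appears at ``2p`` wrapped into the original Nyquist square.  The +1 peak
(always below Nyquist inside the search annulus) therefore seeds a local
search around the wrapped position of ``2 p_hat``, and the refined wrapped
peak is unwrapped back with the integer lattice offset implied by the seed.

The correlation over all integer lateral shifts is one lateral FFT of the
z-summed real-space product of the two bands; a zoomed DFT plus a simplex
polish refines the peak far below the sample spacing (the pattern phase read
off the correlation argument is first-order sensitive to residual frequency
error).  Everything runs on the 2x laterally padded grid.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
from scipy import fft as spfft
from scipy import ndimage
from scipy.optimize import minimize

from ._fft import embed_lateral, ift3
from .otf import OTF3D, axial_pattern_freq, band_otf
from .separation import BandSet

logger = logging.getLogger(__name__)


class Source(enum.Enum):
    SECOND_ORDER = "second_order"
    FIRST_ORDER_FALLBACK = "first_order_fallback"


class EstimationError(RuntimeError):
    """No reliable pattern peak in either the +2 or the +1 band."""


class PeakOnBorderError(RuntimeError):
    """Correlation maximum sits on the search border — widen the annulus."""


@dataclass
class EstimationConfig:
    r_min: float = 4.0              # +2 peak-contrast acceptance threshold
    r_min_fallback: float = 2.0     # +1 threshold below which estimation fails
    annulus: tuple = (0.3, 1.1)     # search bounds on |p|, fractions of k_cutoff
    upsample: int = 20              # subpixel refinement factor
    m_min: float = 0.15             # modulation-depth floor (Wiener weight)
    otf_floor: float = 5e-3         # |OTF| support threshold for weighting
    dc_exclude: float = 0.15        # lateral DC disc excluded from the
                                    # correlation weight, fraction of k_cutoff
                                    # (the object DC otherwise swamps the
                                    # pattern peaks)
    seed_radius: float = 5.0        # +2 local search radius, samples
    prominence_min: float = 1.3     # +1 peak vs second-highest candidate:
                                    # a patternless stack gives ~1 (two noise
                                    # maxima are alike), a real peak stands out
    pad_factor: int = 2
    contrast_annulus: tuple = (5.0, 15.0)  # px radii for the contrast median
    force_fallback: bool = False


@dataclass
class PatternParams:
    """Estimated illumination parameters for one pattern angle.

    ``p`` is the first-order lateral frequency vector (ky, kx) in cycles per
    original pixel; ``q_z`` the derived axial frequency in cycles per z-step;
    ``phi0`` the initial pattern phase; ``m1``/``m2`` the modulation-depth
    weights used in the Wiener combination.
    """

    p: np.ndarray
    q_z: float
    phi0: float
    m1: float
    m2: float
    source: Source
    reliability: float
    angle_index: int = 0

    @property
    def magnitude(self) -> float:
        return float(np.hypot(*self.p))

    @property
    def azimuth(self) -> float:
        return float(np.arctan2(self.p[0], self.p[1]))

    def to_dict(self) -> dict:
        return {
            "p_cycles_per_px": [float(v) for v in self.p],
            "q_z_cycles_per_px": float(self.q_z),
            "phi0_rad": float(self.phi0),
            "m1": float(self.m1),
            "m2": float(self.m2),
            "source": self.source.value,
            "reliability": float(self.reliability),
            "angle_index": self.angle_index,
        }


class CorrelationSurface:
    """Lateral cross-correlation C(s) = sum_k B_moved(k+s) conj(B_ref(k)).

    Built from the z-summed real-space product of the two (weighted) bands;
    ``values`` holds C on the integer shift grid (DC-centered) and
    :meth:`evaluate` computes C at fractional shifts exactly via a zoomed DFT.
    """

    def __init__(self, q: np.ndarray):
        self.q = q                      # 2-D complex, real-space
        self.values = spfft.fftshift(spfft.fft2(q))

    @property
    def shape(self):
        return self.q.shape

    def evaluate(self, shift_samples) -> np.ndarray:
        """C at fractional shifts; accepts a pair of scalars or 1-D grids."""
        sy, sx = (np.atleast_1d(np.asarray(s, dtype=float)) for s in shift_samples)
        ny, nx = self.q.shape
        ey = np.exp(-2j * np.pi * np.outer(sy, np.arange(ny)) / ny)
        ex = np.exp(-2j * np.pi * np.outer(sx, np.arange(nx)) / nx)
        out = ey @ self.q @ ex.T
        return out[0, 0] if out.size == 1 else out


def cross_correlation_map(band_ref: np.ndarray, band_moved: np.ndarray,
                          weight: np.ndarray | None = None) -> CorrelationSurface:
    """Correlation of two same-angle band spectra over lateral shifts.

    ``weight`` (typically the common OTF support with the DC disc removed)
    multiplies both spectra before the correlation so only frequencies the
    microscope actually passed contribute.
    """
    if band_ref.shape != band_moved.shape:
        raise ValueError("band shapes differ")
    if weight is not None:
        band_ref = band_ref * weight
        band_moved = band_moved * weight
    br = ift3(band_ref)
    bm = ift3(band_moved)
    q = (bm * np.conj(br)).sum(axis=0)
    if not np.any(q):
        raise ValueError("empty overlap region between the two bands")
    return CorrelationSurface(q)


def locate_peak_subpixel(surface: CorrelationSurface, *, upsample: int = 20,
                         search_mask: np.ndarray | None = None,
                         contrast_annulus=(5.0, 15.0),
                         search_values: np.ndarray | None = None):
    """Find the correlation peak to sub-sample precision.

    Returns ``(shift_samples, peak_value, contrast)`` where ``shift_samples``
    is the (sy, sx) peak location in frequency samples relative to DC,
    ``peak_value`` the complex correlation there, and ``contrast`` the ratio
    of the peak magnitude to the median magnitude in a surrounding annulus
    (the reliability statistic; ~1 for a featureless surface).

    ``search_values`` optionally replaces the raw magnitude for the integer
    argmax (e.g. a contrast map whitened against the shift-dependent noise
    floor); refinement and contrast always use the raw correlation.
    """
    mag = np.abs(surface.values)
    ny, nx = mag.shape
    search = mag if search_values is None else search_values
    if search_mask is not None:
        search = np.where(search_mask, search, -np.inf)
    finite = search[np.isfinite(search)]
    if finite.size and (finite.max() - finite.min()
                        <= 1e-9 * max(abs(finite.max()), 1e-300)):
        # featureless surface: no peak to locate, flagged unreliable
        center = np.array([0.0, 0.0])
        return center, surface.evaluate(center), 1.0
    iy, ix = np.unravel_index(int(np.argmax(search)), mag.shape)
    if iy in (0, ny - 1) or ix in (0, nx - 1):
        raise PeakOnBorderError(
            "correlation maximum on the surface border; the search annulus "
            "does not bracket the pattern frequency"
        )
    cy, cx = ny // 2, nx // 2

    # contrast: peak vs median magnitude in an annulus around the integer peak
    r_in, r_out = contrast_annulus
    yy, xx = np.ogrid[:ny, :nx]
    rr = np.hypot(yy - iy, xx - ix)
    ring = mag[(rr >= r_in) & (rr <= r_out)]
    med = np.median(ring) if ring.size else 0.0
    peak_mag = mag[iy, ix]
    contrast = float(peak_mag / med) if med > 0 else (1.0 if peak_mag == 0 else np.inf)

    # local zoomed-DFT refinement, +/- 1.5 samples around the integer peak
    half, step = 1.5, 1.0 / max(upsample, 1)
    gy = (iy - cy) + np.arange(-half, half + step / 2, step)
    gx = (ix - cx) + np.arange(-half, half + step / 2, step)
    local = surface.evaluate((gy, gx))
    jy, jx = np.unravel_index(int(np.argmax(np.abs(local))), local.shape)
    start = np.array([gy[jy], gx[jx]])

    res = minimize(lambda s: -np.abs(surface.evaluate(s)), x0=start,
                   method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 0.0, "maxiter": 200})
    shift = np.asarray(res.x)
    if np.max(np.abs(shift - start)) > 1.0:
        shift = start                   # polish wandered; keep the grid fit
    return shift, surface.evaluate(shift), contrast


def _wrap_half(f: np.ndarray) -> np.ndarray:
    """Wrap frequencies (cycles/px) into [-0.5, 0.5)."""
    return (f + 0.5) % 1.0 - 0.5


def _contrast_map(mag: np.ndarray, contrast_annulus) -> np.ndarray:
    """Peak-contrast statistic at every shift: magnitude over the median in a
    surrounding ring.  Whitens the shift-dependent noise floor (overlap area
    and object power both vary with the shift), so the integer search is a
    constant-false-alarm test rather than a raw maximum."""
    r_in, r_out = contrast_annulus
    n = int(r_out)
    yy, xx = np.ogrid[-n:n + 1, -n:n + 1]
    rr = np.hypot(yy, xx)
    ring = (rr >= r_in) & (rr <= r_out)
    med = ndimage.median_filter(mag, footprint=ring, mode="wrap")
    return mag / np.maximum(med, 1e-12 * mag.max() + np.finfo(float).tiny)


def _overlap_norm(weighted_power, o_band_pad, w_pad, shift_samples):
    """sum_k |S O0|^2 (O_band(k+s)/O0(k)) w(k) w(k+s): the self-correlation
    weight the moved-band correlation would have at unit modulation depth."""
    shifted = ndimage.shift(o_band_pad * w_pad,
                            (0.0, -shift_samples[0], -shift_samples[1]),
                            order=1, mode="grid-wrap", prefilter=False)
    return float(np.sum(weighted_power * shifted))


def estimate_pattern(bands: BandSet, otf: OTF3D,
                     config: EstimationConfig | None = None,
                     freq_override=None, phase_override=None) -> PatternParams:
    """Estimate frequency, phase and modulation depths for one angle.

    The +1 peak is located inside the configured annulus; the +2 correlation
    is then refined in a small disc around the (wrapped) position of twice
    that estimate.  If the +2 peak contrast reaches ``config.r_min`` the
    unwrapped second-order frequency is used (source ``SECOND_ORDER``);
    otherwise the +1 estimate stands (``FIRST_ORDER_FALLBACK``), provided its
    own contrast reaches ``r_min_fallback``.  The initial phase is read off
    the +1 correlation at the refined ``p`` (the +2 argument is 2*phi0 with a
    pi ambiguity); modulation depths are the ratio of each order's
    correlation magnitude to the OTF-matched zero-band overlap weight at the
    same shift, floored at ``m_min``.
    """
    config = config or EstimationConfig()
    geom = bands.geometry
    nz, ny, nx = bands.shape
    pf = config.pad_factor
    npix = np.array([ny, nx], dtype=float)

    kc = otf.k_cutoff_lateral_px                   # cycles per original px
    # nominal axial pattern frequency (from the annulus center) fixes the
    # +1 band's two-lobe support for the correlation weighting; the final
    # q_z is recomputed from the refined |p|
    p_nominal = 0.5 * sum(config.annulus) * kc / geom.dxy
    q_z_nominal = axial_pattern_freq(geom, p_nominal) * geom.dz
    o0 = otf.values.real
    o1_orig = band_otf(otf, 1, axial_shift_px=float(q_z_nominal), pad_factor=1)
    fy = (np.arange(ny) - ny // 2) / ny
    fx = (np.arange(nx) - nx // 2) / nx
    r_lat = np.hypot(fy[:, None], fx[None, :])
    dc_mask = (r_lat >= config.dc_exclude * kc)[None, :, :]
    # per-band supports: the +/-1 band lives on the axially two-lobed OTF
    sup0 = ((np.abs(o0) > config.otf_floor) & dc_mask).astype(np.float64)
    sup1 = ((np.abs(o1_orig) > config.otf_floor) & dc_mask).astype(np.float64)
    w0 = embed_lateral(sup0, pf)
    w1 = embed_lateral(sup1, pf)
    b0 = embed_lateral(bands[0], pf) * w0
    b1 = embed_lateral(bands[1], pf) * w1
    b2 = embed_lateral(bands[2], pf) * w0

    lo, hi = config.annulus
    py, px_ = (np.arange(pf * ny) - (pf * ny) // 2), (np.arange(pf * nx) - (pf * nx) // 2)
    radius = np.hypot((py / ny)[:, None], (px_ / nx)[None, :])

    c1 = cross_correlation_map(b0, b1)
    c2 = cross_correlation_map(b0, b2)

    if freq_override is not None:
        # user-supplied (ky, kx) in cycles per original pixel
        p_samples = np.array([freq_override[0] * ny, freq_override[1] * nx])
        source, reliability = Source.SECOND_ORDER, np.inf
    else:
        mask1 = (radius >= lo * kc) & (radius <= hi * kc)
        cmap1 = _contrast_map(np.abs(c1.values), config.contrast_annulus)
        s1, _, contrast1 = locate_peak_subpixel(
            c1, upsample=config.upsample, search_mask=mask1,
            contrast_annulus=config.contrast_annulus, search_values=cmap1)
        # peak prominence over the next-best candidate: self-calibrating
        # against the search's extreme-value inflation
        masked = np.where(mask1, cmap1, 0.0)
        jy, jx = np.unravel_index(int(np.argmax(masked)), masked.shape)
        masked[max(0, jy - 5):jy + 6, max(0, jx - 5):jx + 6] = 0.0
        second = masked.max()
        prominence = cmap1[jy, jx] / second if second > 0 else np.inf

        # wrapped position of 2*p1 seeds the local second-order search
        target = _wrap_half(2 * s1 / npix) * npix
        rr2 = np.hypot((py[:, None] - target[0]), (px_[None, :] - target[1]))
        mask2 = rr2 <= config.seed_radius
        source = None
        if not config.force_fallback:
            try:
                s2w, _, contrast2 = locate_peak_subpixel(
                    c2, upsample=config.upsample, search_mask=mask2,
                    contrast_annulus=config.contrast_annulus)
            except PeakOnBorderError:
                contrast2, s2w = 0.0, None
            if contrast2 >= config.r_min and s2w is not None:
                lattice = np.round((2 * s1 - s2w) / npix) * npix
                p_samples = (s2w + lattice) / 2.0
                source, reliability = Source.SECOND_ORDER, contrast2
        if source is None:
            unreliable = (contrast1 < config.r_min_fallback
                          or prominence < config.prominence_min)
            if unreliable and not config.force_fallback:
                raise EstimationError(
                    f"angle {bands.angle_index}: neither the +2 nor the +1 "
                    f"band shows a reliable pattern peak (+1 contrast "
                    f"{contrast1:.2f}, prominence {prominence:.2f})"
                )
            p_samples = s1
            source, reliability = Source.FIRST_ORDER_FALLBACK, contrast1

    # initial phase from the +1 correlation at the refined frequency
    if phase_override is not None:
        phi0 = float(phase_override)
    else:
        phi0 = float(np.angle(c1.evaluate(p_samples)))

    # modulation depths: correlation magnitude over the OTF-matched overlap
    # weight of the zero band (exact for noiseless data)
    c00 = cross_correlation_map(b0, b0)
    alpha = np.abs(c00.evaluate((0.0, 0.0))) / np.sum(np.abs(b0) ** 2)
    o0_pad = embed_lateral(o0, pf)
    weighted_power = (np.abs(b0) ** 2) / np.maximum(o0_pad, config.otf_floor)
    p_nm = np.hypot(*(p_samples / npix)) / geom.dxy
    q_z = axial_pattern_freq(geom, p_nm) * geom.dz
    o1 = band_otf(otf, 1, axial_shift_px=float(q_z), pad_factor=1)
    o1_pad = embed_lateral(o1, pf)
    s2_wrapped = _wrap_half(2 * p_samples / npix) * npix
    d1 = alpha * _overlap_norm(weighted_power, o1_pad, w1, p_samples)
    d2 = alpha * _overlap_norm(weighted_power, o0_pad, w0, s2_wrapped)
    m1 = np.abs(c1.evaluate(p_samples)) / d1 if d1 > 0 else 0.0
    m2 = np.abs(c2.evaluate(s2_wrapped)) / d2 if d2 > 0 else 0.0
    for name, val in (("m1", m1), ("m2", m2)):
        if not (config.m_min <= val <= 1.0):
            logger.info(
                "angle %d: %s = %.3f clipped to [%.2f, 1]",
                bands.angle_index, name, val, config.m_min,
            )
    m1 = float(np.clip(m1, config.m_min, 1.0))
    m2 = float(np.clip(m2, config.m_min, 1.0))

    p = p_samples / npix                           # cycles per original px
    return PatternParams(p=p, q_z=float(q_z), phi0=phi0, m1=m1, m2=m2,
                         source=source, reliability=float(reliability),
                         angle_index=bands.angle_index)


__all__ = [
    "Source", "EstimationError", "PeakOnBorderError", "EstimationConfig",
    "PatternParams", "CorrelationSurface", "cross_correlation_map",
    "locate_peak_subpixel", "estimate_pattern",
]
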