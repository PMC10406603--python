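"""Forward model: phantoms, three-beam illumination, blur, and noise.

The structured pattern produced by three-beam interference carries five
lateral Fourier orders {0, +/-1, +/-2}; the first orders are additionally
modulated axially at q_z because the tilted side beams beat against the axial
beam.  In a z-stack the pattern is locked to the objective focus, so the
axial modulation rides on the detection PSF rather than on the sample: the
recorded image at stage position z0 is

    D(r, z0) = sum_m  e^{i m (phi0 + 2 pi j / P)}
               [ gt * e^{i m 2 pi p.r_lat} ] (*) [ psf * c_m(z) ]

with c_0 = 1, c_1(z) = m1 cos(2 pi q_z z), c_2 = m2, and (*) a 3-D
convolution.  Shot noise is Poisson at a configurable photon scale with
additive Gaussian read noise (an sCMOS-like model); `peak_photons=None`
yields the noiseless forward model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import fft as spfft

from .data_model import AcquisitionGeometry, Layout, RawStack, write_raw_stack
from .estimation import PatternParams, Source
from .otf import axial_pattern_freq, compute_psf, lateral_cutoff


@dataclass
class SimConfig:
    """Stated world of the synthetic acquisitions.

    Defaults: OMX-like geometry (3 angles x 5 phases, 80/125 nm sampling,
    NA 1.4 oil), pattern frequency at 0.8 of the emission lateral cutoff with
    orientations 0/60/120 degrees, beam-amplitude ratio E0:E1 = 2:1 (hence
    pattern modulation depths m1 = 2/3, m2 = 1/6), and a photon scale of 500
    at the brightest voxel with 1 e- read noise.
    """

    geometry: AcquisitionGeometry = field(default_factory=AcquisitionGeometry)
    pattern_freq_fraction: float = 0.8
    pattern_angles: tuple = (0.0, np.pi / 3, 2 * np.pi / 3)
    modulation_m1: float = 2.0 / 3.0
    modulation_m2: float = 1.0 / 6.0
    initial_phases: tuple = (0.0, 2.1, 4.2)
    peak_photons: float | None = 500.0
    read_noise_sd: float = 1.0
    phase_step_jitter_sd: float = 0.0   # rad; grating-stepper jitter per image
    intensity_flicker_sd: float = 0.0   # relative illumination jitter per image
    seed: int = 0
    phantom: str = "filaments"

    def __post_init__(self):
        if not 0.0 < self.pattern_freq_fraction <= 1.2:
            raise ValueError("pattern_freq_fraction must be in (0, 1.2]")
        for name in ("modulation_m1", "modulation_m2"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.peak_photons is not None and self.peak_photons <= 0:
            raise ValueError("peak_photons must be positive (or None)")

    def pattern_freq_px(self, angle_index: int) -> np.ndarray:
        """Lateral pattern frequency (ky, kx), cycles per pixel."""
        g = self.geometry
        mag = self.pattern_freq_fraction * lateral_cutoff(g) * g.dxy
        az = self.pattern_angles[angle_index]
        return np.array([mag * np.sin(az), mag * np.cos(az)])

    def axial_freq_px(self) -> float:
        """First-order axial modulation frequency, cycles per z-step."""
        g = self.geometry
        p_nm = self.pattern_freq_fraction * lateral_cutoff(g)
        return axial_pattern_freq(g, p_nm) * g.dz


@dataclass
class GroundTruth:
    """Fluorophore density (and, for polarization phantoms, dipole angles)."""

    volume: np.ndarray
    dipole_theta: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.volume = np.asarray(self.volume, dtype=float)
        if (self.volume < 0).any():
            raise ValueError("ground-truth density must be nonnegative")


def make_phantom(kind: str, shape, seed: int = 0, **kwargs) -> GroundTruth:
    """Deterministic test phantoms.

    * ``beads``      — isolated sub-resolution points (``n_beads``,
      ``min_separation`` px, optional ``centered`` single bead).
    * ``filaments``  — smooth random 3-D curves of ~1 px width
      (``n_filaments``, default 24: a dense actin-like network).
    * ``sheet_z``    — laterally uniform with 1 + cos axial modulation at
      ``z_freq`` cycles per z-step.
    * ``uniform``    — constant density.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    vol = np.zeros(shape)
    meta = {"kind": kind, "seed": seed}

    if kind == "uniform":
        vol[:] = 1.0
    elif kind == "sheet_z":
        z_freq = kwargs.get("z_freq", 0.15)
        z = np.arange(nz) - nz // 2
        vol[:] = (1.0 + np.cos(2 * np.pi * z_freq * z))[:, None, None]
        meta["z_freq"] = z_freq
    elif kind == "beads":
        n_beads = kwargs.get("n_beads", 40)
        min_sep = kwargs.get("min_separation", 6.0)
        margin = 4
        placed = []
        if kwargs.get("centered"):
            # one bead exactly at the grid center (e.g. for width measurements)
            placed.append(np.array([nz // 2, ny // 2, nx // 2]))
        attempts = 0
        while len(placed) < n_beads and attempts < 20000:
            attempts += 1
            c = np.array([rng.integers(1, nz - 1),
                          rng.integers(margin, ny - margin),
                          rng.integers(margin, nx - margin)])
            if all(np.linalg.norm(c - q) >= min_sep for q in placed):
                placed.append(c)
        for c in placed:
            vol[tuple(c)] = 1.0
        meta["positions"] = [list(map(int, c)) for c in placed]
        meta["min_separation"] = min_sep
    elif kind == "filaments":
        n_fil = kwargs.get("n_filaments", 24)
        steps = int(2.5 * max(ny, nx))
        for _ in range(n_fil):
            pos = np.array([rng.uniform(1, nz - 1), rng.uniform(0, ny),
                            rng.uniform(0, nx)])
            direction = rng.normal(size=3)
            direction[0] *= 0.15          # keep curves mostly in-plane
            direction /= np.linalg.norm(direction)
            for _ in range(steps):
                turn = rng.normal(scale=[0.01, 0.08, 0.08])
                direction = direction + turn
                direction /= np.linalg.norm(direction)
                pos = pos + 0.5 * direction
                # reflect at volume boundaries
                for ax, n in enumerate(shape):
                    if pos[ax] < 0 or pos[ax] > n - 1:
                        pos[ax] = np.clip(pos[ax], 0, n - 1)
                        direction[ax] *= -1
                iz, iy, ix = np.round(pos).astype(int)
                vol[iz, iy, ix] += 0.5
    else:
        raise ValueError(f"unknown phantom kind {kind!r}")
    return GroundTruth(volume=vol, meta=meta)


def illumination_pattern(config: SimConfig, angle_index: int, phase_index: int,
                         shape) -> np.ndarray:
    """Three-beam interference intensity on a (z, y, x) grid, mean 1.

    I(r) = 1 + 2 m1 cos(2 pi p.r_lat + phi) cos(2 pi q_z z)
             + 2 m2 cos(2 (2 pi p.r_lat + phi)),
    the Fourier-order expansion of |E0 e^{i k0.r} + E+ e^{i(k+.r+phi)} +
    E- e^{i(k-.r-phi)}|^2 with m1 = 2 E0 E1 / (E0^2 + 2 E1^2) and
    m2 = E1^2 / (E0^2 + 2 E1^2) (the complex order weights relative to order
    zero), and the side-beam transverse frequency clamped at the pupil edge
    (see otf.axial_pattern_freq).  z is measured from the grid center (the
    focal plane).  For the default 2:1 beam ratio the minimum intensity is
    exactly zero, as for physical three-beam interference.
    """
    nz, ny, nx = shape
    p = config.pattern_freq_px(angle_index)
    if np.hypot(*p) > 0.5:
        raise ValueError(
            f"pattern frequency |p| = {np.hypot(*p):.3f} cycles/px is beyond "
            "the grid Nyquist"
        )
    # note: the second order 2|p| may exceed Nyquist for high pattern
    # frequencies; it then aliases on the sampled grid, exactly as a real
    # camera would record it
    g = config.geometry
    phases = 2 * np.pi * np.arange(g.n_phases) / g.n_phases
    phi = config.initial_phases[angle_index] + phases[phase_index]
    y = np.arange(ny)[:, None]
    x = np.arange(nx)[None, :]
    lat = 2 * np.pi * (p[0] * y + p[1] * x)
    z = (np.arange(nz) - nz // 2)[:, None, None]
    q_z = config.axial_freq_px()
    return (
        1.0
        + 2 * config.modulation_m1 * np.cos(lat + phi)[None]
        * np.cos(2 * np.pi * q_z * z)
        + 2 * config.modulation_m2 * np.cos(2 * (lat + phi))[None]
    )


def simulate_raw_stack(gt: GroundTruth, config: SimConfig
                       ) -> tuple[RawStack, list[PatternParams]]:
    """Render the raw 15-images-per-plane acquisition of a phantom.

    Returns the stack in canonical order together with the exact pattern
    parameters used (for parameter-recovery tests).  The illumination is
    applied in the focus-locked frame: the axial modulation multiplies the
    PSF, the lateral orders multiply the sample.
    """
    g = config.geometry
    shape = gt.volume.shape
    nz, ny, nx = shape
    psf = compute_psf(g, shape)
    z_c = (np.arange(nz) - nz // 2)[:, None, None]
    q_z = config.axial_freq_px()
    kern0 = spfft.fftn(spfft.ifftshift(psf))
    kern1 = spfft.fftn(spfft.ifftshift(psf * np.cos(2 * np.pi * q_z * z_c)))

    phases = 2 * np.pi * np.arange(g.n_phases) / g.n_phases
    y = np.arange(ny)[:, None]
    x = np.arange(nx)[None, :]

    rng = np.random.default_rng(config.seed)
    jitter = np.zeros((g.n_angles, g.n_phases))
    if config.phase_step_jitter_sd > 0:
        # imperfect grating stepping: the separation matrix still assumes
        # nominal phases, so this leaks band content between orders (the
        # origin of residual pattern-peak artifacts in real data)
        jitter = rng.normal(0.0, config.phase_step_jitter_sd,
                            size=(g.n_angles, g.n_phases))
    flicker = np.ones((g.n_angles, g.n_phases))
    if config.intensity_flicker_sd > 0:
        # illumination intensity fluctuation between exposures: leaks the
        # zero band's strong low frequencies into every side band
        flicker += rng.normal(0.0, config.intensity_flicker_sd,
                              size=(g.n_angles, g.n_phases))

    data = np.empty((g.n_angles, g.n_phases, nz, ny, nx))
    truth = []
    for a in range(g.n_angles):
        p = config.pattern_freq_px(a)
        lat = np.exp(2j * np.pi * (p[0] * y + p[1] * x))[None]
        f0 = spfft.fftn(gt.volume)
        f1 = spfft.fftn(gt.volume * lat)
        f2 = spfft.fftn(gt.volume * lat**2)
        conv0 = spfft.ifftn(f0 * kern0).real
        conv1 = spfft.ifftn(f1 * kern1)
        conv2 = spfft.ifftn(f2 * kern0)
        for j in range(g.n_phases):
            phi = config.initial_phases[a] + phases[j] + jitter[a, j]
            img = (
                conv0
                + 2 * config.modulation_m1 * (np.exp(1j * phi) * conv1).real
                + 2 * config.modulation_m2 * (np.exp(2j * phi) * conv2).real
            )
            data[a, j] = np.clip(img * flicker[a, j], 0.0, None)
        p_nm = np.hypot(*p) / g.dxy
        truth.append(PatternParams(
            p=p, q_z=float(axial_pattern_freq(g, p_nm) * g.dz),
            phi0=float(config.initial_phases[a]),
            m1=config.modulation_m1, m2=config.modulation_m2,
            source=Source.SECOND_ORDER, reliability=np.inf, angle_index=a))

    if config.peak_photons is not None:
        peak = data.max()
        if peak > 0:
            data *= config.peak_photons / peak
        data = rng.poisson(data).astype(np.float64)
        if config.read_noise_sd > 0:
            data += rng.normal(0.0, config.read_noise_sd, size=data.shape)
        data = np.clip(data, 0.0, None)
    stack = RawStack(data=data.astype(np.float32), geometry=g)
    return stack, truth


def polarized_angle_images(dc: np.ndarray, theta: np.ndarray, pattern_angles,
                           *, amplitude_ratio: float = 0.5,
                           illumination=None, photons: float | None = None,
                           read_noise_sd: float = 0.0, seed: int = 0
                           ) -> np.ndarray:
    """Widefield per-angle images of a dipole field under polarized excitation.

    ``I_a = illum_a * dc * (1 + amplitude_ratio cos(2 (alpha_a - theta)))``,
    optionally Poisson-sampled at ``photons`` mean scale.  Used to emulate
    the per-angle phase averages that the orientation fit consumes.
    """
    alphas = np.asarray(pattern_angles, dtype=float)
    rng = np.random.default_rng(seed)
    out = []
    for i, a in enumerate(alphas):
        img = dc * (1.0 + amplitude_ratio * np.cos(2.0 * (a - theta)))
        if illumination is not None:
            img = img * illumination[i]
        if photons is not None:
            lam = img * photons / max(dc.max(), 1e-12)
            img = rng.poisson(lam).astype(float)
            if read_noise_sd > 0:
                img += rng.normal(0.0, read_noise_sd, size=img.shape)
        out.append(img)
    return np.stack(out)


def write_fixture(out_dir, config: SimConfig, *, layout: Layout | None = None,
                  shape=(8, 64, 64), phantom_kwargs=None) -> dict:
    """Write a simulated stack as TIFF plus a JSON ground-truth sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gt = make_phantom(config.phantom, shape, seed=config.seed,
                      **(phantom_kwargs or {}))
    stack, truth = simulate_raw_stack(gt, config)
    layout = layout or config.geometry.layout
    tiff_path = out_dir / f"raw_{layout.value}.tif"
    write_raw_stack(stack, tiff_path, layout=layout)
    sidecar = {
        "layout": layout.value,
        "shape_zyx": list(shape),
        "geometry": config.geometry.to_dict(),
        "phantom": gt.meta,
        "pattern_params": [t.to_dict() for t in truth],
        "peak_photons": config.peak_photons,
        "read_noise_sd": config.read_noise_sd,
        "seed": config.seed,
    }
    side_path = tiff_path.with_suffix(".json")
    side_path.write_text(json.dumps(sidecar, indent=2))
    return {"tiff": str(tiff_path), "sidecar": str(side_path)}


__all__ = [
    "SimConfig", "GroundTruth", "make_phantom", "illumination_pattern",
    "simulate_raw_stack", "polarized_angle_images", "write_fixture",
]
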