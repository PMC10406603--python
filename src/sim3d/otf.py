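"""Scalar 3-D PSF/OTF model.

The widefield point-spread function is computed by defocus propagation of a
uniform circular pupil: for each defocus z the coherent field is the inverse
2-D transform of ``P(k) * exp(i 2 pi z sqrt((n/lambda_em)^2 - |k|^2))`` over
the pupil disc ``|k| <= NA/lambda_em`` and the intensity PSF is its squared
modulus.  The corresponding 3-D OTF has the classic toroidal support with a
*missing cone* around the axial frequency axis: ``OTF(kz != 0, 0, 0) = 0``,
which is what destroys optical sectioning in a conventional widefield stack
and what the axially modulated first-order SIM bands fill.

Frequency bookkeeping:

* lateral cutoff  ``2 NA / lambda_em``                      (cycles/nm)
* axial cutoff    ``(n - sqrt(n^2 - NA^2)) / lambda_em``    (cycles/nm)
* axial pattern frequency of the three-beam illumination
  ``q_z = (n - sqrt(n^2 - |p|^2 lambda_exc^2)) / lambda_exc`` where ``|p|`` is
  the lateral pattern frequency in cycles/nm.  The side-beam transverse
  frequency is clamped at the pupil edge (``|p| lambda_exc <= NA``) so the
  rule stays defined for super-pupil pattern frequencies used in simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import fft as spfft

from ._fft import ft3_centered
from .data_model import AcquisitionGeometry


@dataclass
class OTF3D:
    """DC-centered widefield 3-D OTF, normalized to 1 at DC.

    ``values`` is indexed (kz, ky, kx).  Cutoffs are stored in cycles/nm; the
    ``*_px`` properties convert to cycles per (original) pixel.
    """

    values: np.ndarray
    geometry: AcquisitionGeometry

    @property
    def k_cutoff_lateral(self) -> float:
        return lateral_cutoff(self.geometry)

    @property
    def k_cutoff_axial(self) -> float:
        return axial_cutoff(self.geometry)

    @property
    def k_cutoff_lateral_px(self) -> float:
        return lateral_cutoff(self.geometry) * self.geometry.dxy

    @property
    def k_cutoff_axial_px(self) -> float:
        return axial_cutoff(self.geometry) * self.geometry.dz

    @property
    def shape(self):
        return self.values.shape


def lateral_cutoff(geometry: AcquisitionGeometry) -> float:
    """Widefield lateral cutoff 2*NA/lambda_em, cycles/nm."""
    return 2.0 * geometry.na / geometry.lambda_em


def axial_cutoff(geometry: AcquisitionGeometry) -> float:
    """Widefield axial cutoff (n - sqrt(n^2 - NA^2))/lambda_em, cycles/nm."""
    n = geometry.n_immersion
    return (n - np.sqrt(n**2 - geometry.na**2)) / geometry.lambda_em


def axial_pattern_freq(geometry: AcquisitionGeometry, p_lateral_nm: float) -> float:
    """Axial frequency q_z (cycles/nm) of the first illumination order.

    Fixed by three-beam geometry: the beat between the axial beam and a side
    beam of lateral frequency ``p`` has axial frequency
    ``n/lambda - sqrt((n/lambda)^2 - p^2)``.  ``p`` is clamped at the pupil
    edge (NA/lambda_exc).
    """
    lam, n = geometry.lambda_exc, geometry.n_immersion
    s = min(abs(p_lateral_nm) * lam, geometry.na)
    return (n - np.sqrt(n**2 - s**2)) / lam


def compute_psf(geometry: AcquisitionGeometry, shape,
                lateral_pixel_nm: float | None = None) -> np.ndarray:
    """Intensity PSF on a (nz, ny, nx) grid, centered, normalized to sum 1.

    ``lateral_pixel_nm`` overrides ``geometry.dxy`` (used for the 2x padded
    reconstruction grid, where the lateral pixel is ``dxy/2``).
    """
    nz, ny, nx = shape
    if min(shape) < 4:
        raise ValueError("PSF grid must be at least 4 samples along each axis")
    dxy = geometry.dxy if lateral_pixel_nm is None else lateral_pixel_nm
    lam, n, na = geometry.lambda_em, geometry.n_immersion, geometry.na
    if dxy > lam / (4.0 * na):
        warnings.warn(
            f"lateral sampling {dxy} nm exceeds lambda_em/(4 NA) = "
            f"{lam / (4 * na):.1f} nm; the OTF support will alias",
            stacklevel=2,
        )

    fy = spfft.fftfreq(ny, d=dxy)
    fx = spfft.fftfreq(nx, d=dxy)
    k2 = fy[:, None] ** 2 + fx[None, :] ** 2
    pupil = k2 <= (na / lam) ** 2
    kz = np.sqrt(np.maximum((n / lam) ** 2 - k2, 0.0))

    z = (np.arange(nz) - nz // 2) * geometry.dz
    psf = np.empty((nz, ny, nx))
    for iz, zz in enumerate(z):
        field = spfft.ifft2(pupil * np.exp(2j * np.pi * zz * kz))
        psf[iz] = np.abs(spfft.fftshift(field)) ** 2
    s = psf.sum()
    if s == 0:
        raise ValueError("empty pupil — check NA and sampling")
    return psf / s


def psf_to_otf(psf: np.ndarray, geometry: AcquisitionGeometry) -> OTF3D:
    """3-D DFT of a centered PSF, DC-centered and normalized to OTF(DC)=1."""
    psf = np.asarray(psf, dtype=float)
    if not psf.any():
        raise ValueError("all-zero PSF")
    values = ft3_centered(psf)
    nz, ny, nx = psf.shape
    dc = values[nz // 2, ny // 2, nx // 2]
    return OTF3D(values=values / dc, geometry=geometry)


def band_otf(otf: OTF3D, order: int, axial_shift_px: float = 0.0,
             pad_factor: int = 2) -> np.ndarray:
    """Band transfer function on the laterally padded reconstruction grid.

    * ``|order|`` 0 or 2: a copy of the widefield OTF on the padded grid.
    * ``|order|`` 1: mean of two widefield OTF copies shifted axially by
      +/- ``axial_shift_px`` (cycles per z-step) — the first illumination
      order is modulated axially by ``cos(2 pi q_z z)`` in the focus frame, so
      its information sits at two axial side lobes; the mean of the two lobes
      is exactly ``FT{psf * cos(2 pi q_z z)}``.

    Returned values are real, normalized so the widefield DC is 1.
    """
    if order not in (-2, -1, 0, 1, 2):
        raise ValueError(f"order must be in -2..2, got {order}")
    nz, ny, nx = otf.shape
    if abs(order) == 1 and abs(axial_shift_px) > 0.5:
        raise ValueError(f"axial shift {axial_shift_px} beyond axial Nyquist (0.5)")
    if abs(order) != 1:
        axial_shift_px = 0.0
    shape = (nz, pad_factor * ny, pad_factor * nx)
    psf = compute_psf(otf.geometry, shape,
                      lateral_pixel_nm=otf.geometry.dxy / pad_factor)
    if abs(order) == 1:
        z = np.arange(nz) - nz // 2
        psf = psf * np.cos(2 * np.pi * axial_shift_px * z)[:, None, None]
    values = ft3_centered(psf).real
    # widefield psf sums to 1, so no renormalization needed: FT{psf*cos} is
    # already the two-lobe mean of the DC-normalized widefield OTF.
    return values


def write_otf(otf: OTF3D, path) -> None:
    """Export a (real) OTF as float32 TIFF with a JSON sidecar of cutoffs."""
    import json
    from pathlib import Path

    import tifffile

    path = Path(path)
    tifffile.imwrite(path, otf.values.real.astype(np.float32))
    sidecar = {
        "k_cutoff_lateral_per_nm": otf.k_cutoff_lateral,
        "k_cutoff_axial_per_nm": otf.k_cutoff_axial,
        "geometry": otf.geometry.to_dict(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_otf(path, geometry: AcquisitionGeometry) -> OTF3D:
    """Import a measured (e.g. bead-derived) DC-centered OTF from TIFF.

    The array is renormalized so the DC value is 1; real systems deviate from
    the scalar model and a measured OTF can replace it throughout.
    """
    import tifffile

    values = tifffile.imread(path).astype(np.float64)
    if values.ndim != 3:
        raise ValueError("expected a 3-D OTF stack")
    nz, ny, nx = values.shape
    dc = values[nz // 2, ny // 2, nx // 2]
    if dc == 0:
        raise ValueError("OTF has zero DC value")
    return OTF3D(values=values / dc, geometry=geometry)


__all__ = [
    "OTF3D", "lateral_cutoff", "axial_cutoff", "axial_pattern_freq",
    "compute_psf", "psf_to_otf", "band_otf", "write_otf", "read_otf",
]
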