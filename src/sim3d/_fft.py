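"""Shared FFT conventions.

All spectra in this package are DC-centered (``fftshift`` applied), with the
real-space origin at index 0 unless a function says otherwise.  Frequency
coordinates are cycles per pixel of the grid the array lives on.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as spfft


def ft3(x: np.ndarray) -> np.ndarray:
    """Forward 3-D transform, DC-centered output, real-space origin at [0,0,0]."""
    return spfft.fftshift(spfft.fftn(x))


def ift3(X: np.ndarray) -> np.ndarray:
    """Inverse of :func:`ft3`."""
    return spfft.ifftn(spfft.ifftshift(X))


def ft3_centered(x: np.ndarray) -> np.ndarray:
    """Forward transform of an array whose real-space origin is the grid center.

    Used for PSFs so the resulting OTF is real for a symmetric input.
    """
    return spfft.fftshift(spfft.fftn(spfft.ifftshift(x)))


def freq_axes(shape, spacings=None):
    """DC-centered frequency axes, cycles per sample (or per unit if spacings given)."""
    if spacings is None:
        spacings = (1.0,) * len(shape)
    return tuple(
        spfft.fftshift(spfft.fftfreq(n, d=d)) for n, d in zip(shape, spacings)
    )


def conj_mirror(X: np.ndarray) -> np.ndarray:
    """Return X(-k) for a DC-centered array (handles even-sized axes)."""
    out = spfft.ifftshift(X)
    for ax in range(out.ndim):
        out = np.roll(np.flip(out, axis=ax), 1, axis=ax)
    return spfft.fftshift(out)


def embed_lateral(spec: np.ndarray, factor: int = 2) -> np.ndarray:
    """Embed a DC-centered (z, y, x) spectrum in a laterally padded grid.

    Padding the spectrum by ``factor`` in y and x keeps the frequency sample
    spacing while extending the representable range; in real space this is a
    ``factor``-times finer lateral sampling of the same field of view.
    """
    nz, ny, nx = spec.shape
    out = np.zeros((nz, factor * ny, factor * nx), dtype=spec.dtype)
    oy = (factor * ny) // 2 - ny // 2
    ox = (factor * nx) // 2 - nx // 2
    out[:, oy : oy + ny, ox : ox + nx] = spec
    return out


def phase_ramp(shape, shift) -> np.ndarray:
    """exp(-2*pi*i * shift.r) over integer real-space indices, built per axis."""
    ramps = []
    for n, s in zip(shape, shift):
        r = np.arange(n)
        ramps.append(np.exp(-2j * np.pi * s * r))
    out = ramps[0]
    for r in ramps[1:]:
        out = np.multiply.outer(out, r)
    return out
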