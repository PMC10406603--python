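"""Phase separation of the five illumination orders.

Each raw image is a sum of five frequency bands (orders m = -2..2) carried on
phase factors ``exp(i m phi_p)``; with at least five distinct phase steps the
bands are unmixed by the left pseudo-inverse of the phase matrix
``M[p, m] = exp(i m phi_p)``.  For the standard equally spaced five phases the
matrix columns are orthogonal (``M^H M = 5 I``) and the pseudo-inverse is
``M^H / 5``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import tukey

from ._fft import conj_mirror, ft3
from .data_model import AcquisitionGeometry

ORDERS = (-2, -1, 0, 1, 2)


class SingularPhasesError(ValueError):
    """The supplied phase set cannot separate five bands."""


@dataclass
class BandSet:
    """Separated DC-centered complex spectra, one per order m in -2..2."""

    bands: dict
    angle_index: int
    geometry: AcquisitionGeometry
    phases: np.ndarray

    def __post_init__(self):
        if set(self.bands) != set(ORDERS):
            raise ValueError(f"expected bands for orders {ORDERS}")

    def __getitem__(self, m: int) -> np.ndarray:
        return self.bands[m]

    @property
    def shape(self):
        return self.bands[0].shape


def separation_matrix(phases) -> tuple[np.ndarray, np.ndarray]:
    """Forward phase matrix M[p, m] = exp(i m phi_p) and its left pseudo-inverse.

    Raises :class:`SingularPhasesError` when the phases are degenerate (fewer
    than five distinct values modulo 2*pi).
    """
    phases = np.asarray(phases, dtype=float)
    if phases.size < 5:
        raise SingularPhasesError(
            f"need at least 5 phases to separate 5 bands, got {phases.size}"
        )
    m = np.array(ORDERS)
    M = np.exp(1j * np.outer(phases, m))
    if np.linalg.matrix_rank(M, tol=1e-8) < 5:
        raise SingularPhasesError(
            "phase set is degenerate (separation matrix rank < 5); "
            "phases must be distinct modulo 2*pi"
        )
    return M, np.linalg.pinv(M)


def edge_taper(ny: int, nx: int, fraction: float = 0.1) -> np.ndarray:
    """Separable 2-D Tukey window suppressing lateral spectral leakage."""
    if fraction <= 0:
        return np.ones((ny, nx))
    return np.outer(tukey(ny, fraction), tukey(nx, fraction))


def separate_bands(stack_angle: np.ndarray, phases, *,
                   geometry: AcquisitionGeometry, angle_index: int = 0,
                   taper_fraction: float = 0.1) -> BandSet:
    """Unmix one angle's (phase, z, y, x) series into five band spectra.

    Every phase image is edge-tapered per plane, 3-D Fourier transformed over
    the whole z-stack at once (the axial band structure needs the full
    transform), and the pseudo-inverse is applied across the phase axis,
    pixel-wise in frequency space.
    """
    stack_angle = np.asarray(stack_angle)
    if stack_angle.ndim != 4:
        raise ValueError("expected a 4-D (phase, z, y, x) array")
    phases = np.asarray(phases, dtype=float)
    if stack_angle.shape[0] != phases.size:
        raise ValueError(
            f"phase count mismatch: {stack_angle.shape[0]} images, "
            f"{phases.size} phases"
        )
    _, pinv = separation_matrix(phases)

    win = edge_taper(*stack_angle.shape[2:], fraction=taper_fraction)
    spectra = np.stack([
        ft3((stack_angle[p] * win).astype(np.float64)) for p in range(phases.size)
    ])
    bands = {
        m: np.tensordot(pinv[i], spectra, axes=(0, 0))
        for i, m in enumerate(ORDERS)
    }
    return BandSet(bands=bands, angle_index=angle_index, geometry=geometry,
                   phases=phases)


def recompose(bandset: BandSet) -> np.ndarray:
    """Re-mix bands into the phase-series spectra (inverse of separation)."""
    M, _ = separation_matrix(bandset.phases)
    B = np.stack([bandset[m] for m in ORDERS])
    return np.tensordot(M, B, axes=(1, 0))


def check_conjugate_symmetry(bandset: BandSet) -> float:
    """Max relative deviation of band(-m) from conj(band(+m)) mirrored."""
    worst = 0.0
    for m in (1, 2):
        ref = np.conj(conj_mirror(bandset[m]))
        scale = np.abs(bandset[m]).max() or 1.0
        worst = max(worst, float(np.abs(bandset[-m] - ref).max() / scale))
    return worst


__all__ = [
    "ORDERS", "BandSet", "SingularPhasesError", "separation_matrix",
    "separate_bands", "recompose", "edge_taper", "check_conjugate_symmetry",
]
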