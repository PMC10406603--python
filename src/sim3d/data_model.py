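"""Domain types and raw-stack I/O.

A 3D-SIM acquisition records, for every z-plane, ``n_angles * n_phases`` raw
images (three pattern orientations, five phase steps of the illumination
grating: 15 images per plane for the standard geometry).  Vendors store those
pages in different orders; everything downstream of this module works on the
canonical in-memory order ``(angle, phase, z, y, x)``.

Supported on-disk orderings (page sequence listed fastest-varying first):

* ``OMX``        — phase, depth, channel, time, angle
* ``NSIM``       — one tiled montage page per depth (angle in rows, phase in
  columns), then depth, channel, time
* ``HOMEBUILT``  — phase, angle, depth, channel, time
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile


class Layout(enum.Enum):
    OMX = "omx"
    NSIM = "nsim"
    HOMEBUILT = "homebuilt"


class LayoutError(ValueError):
    """Page count or montage tiling inconsistent with the declared layout."""


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Optical and sampling parameters of a 3D-SIM acquisition.

    Parameters
    ----------
    n_angles, n_phases
        Pattern orientations and phase steps per orientation.  Five phases are
        the minimum that lets the five illumination orders be unmixed.
    lambda_exc, lambda_em
        Excitation / emission wavelengths in nm.
    na
        Objective numerical aperture.
    n_immersion
        Immersion refractive index; must exceed ``na``.
    dxy, dz
        Lateral pixel size and axial step in nm (e.g. 80/125 nm for OMX-type
        systems, 65/120 nm for N-SIM-type systems).
    layout
        On-disk page ordering.
    """

    n_angles: int = 3
    n_phases: int = 5
    lambda_exc: float = 488.0
    lambda_em: float = 525.0
    na: float = 1.4
    n_immersion: float = 1.518
    dxy: float = 80.0
    dz: float = 125.0
    layout: Layout = Layout.OMX

    def __post_init__(self):
        if self.n_phases < 5:
            raise ValueError(
                f"n_phases must be >= 5 to separate five bands, got {self.n_phases}"
            )
        if self.n_angles < 1:
            raise ValueError("n_angles must be >= 1")
        if self.na >= self.n_immersion:
            raise ValueError(
                f"numerical aperture ({self.na}) must be below the immersion "
                f"index ({self.n_immersion})"
            )
        for name in ("lambda_exc", "lambda_em", "dxy", "dz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def frames_per_plane(self) -> int:
        return self.n_angles * self.n_phases

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["layout"] = self.layout.value
        return d


@dataclass
class RawStack:
    """Canonical raw acquisition: ``data[angle, phase, z, y, x]`` plus geometry."""

    data: np.ndarray
    geometry: AcquisitionGeometry
    channel_id: int = 0
    time_id: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError("RawStack.data must be 5-D (angle, phase, z, y, x)")
        a, p = self.data.shape[:2]
        if (a, p) != (self.geometry.n_angles, self.geometry.n_phases):
            raise ValueError(
                f"data shape {self.data.shape[:2]} does not match geometry "
                f"({self.geometry.n_angles} angles, {self.geometry.n_phases} phases)"
            )

    @property
    def n_z(self) -> int:
        return self.data.shape[2]


@dataclass
class Reconstruction:
    """Super-resolved volume on the 2x laterally upsampled grid."""

    volume: np.ndarray
    geometry: AcquisitionGeometry
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.volume = np.asarray(self.volume)
        if self.volume.ndim != 3:
            raise ValueError("Reconstruction.volume must be 3-D (z, y, x)")
        if not np.all(np.isfinite(self.volume)):
            raise ValueError("Reconstruction.volume contains non-finite values")


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


# ---------------------------------------------------------------------------
# page-order bijections


def _pages_to_canonical(pages: np.ndarray, geometry: AcquisitionGeometry,
                        n_channels: int, n_times: int,
                        channel: int, time: int) -> np.ndarray:
    """Map a (pages, Y, X) array to (angle, phase, z, y, x)."""
    a, p = geometry.n_angles, geometry.n_phases
    layout = geometry.layout

    if layout is Layout.NSIM:
        n_z = pages.shape[0] // (n_channels * n_times)
        my, mx = pages.shape[1:]
        if my % a or mx % p:
            raise LayoutError(
                f"N-SIM montage of {my}x{mx} px is not divisible into a "
                f"{a}x{p} (angle x phase) tile grid"
            )
        arr = pages.reshape(n_times, n_channels, n_z, my, mx)[time, channel]
        y, x = my // a, mx // p
        arr = arr.reshape(n_z, a, y, p, x)
        return np.ascontiguousarray(arr.transpose(1, 3, 0, 2, 4))

    n_z = pages.shape[0] // (a * p * n_channels * n_times)
    if layout is Layout.OMX:
        # fastest first: phase, depth, channel, time, angle
        arr = pages.reshape(a, n_times, n_channels, n_z, p, *pages.shape[1:])
        arr = arr[:, time, channel]                      # (a, z, p, y, x)
        return np.ascontiguousarray(arr.transpose(0, 2, 1, 3, 4))
    if layout is Layout.HOMEBUILT:
        # fastest first: phase, angle, depth, channel, time
        arr = pages.reshape(n_times, n_channels, n_z, a, p, *pages.shape[1:])
        arr = arr[time, channel]                         # (z, a, p, y, x)
        return np.ascontiguousarray(arr.transpose(1, 2, 0, 3, 4))
    raise LayoutError(f"unknown layout {layout}")


def _canonical_to_pages(data: np.ndarray, layout: Layout) -> np.ndarray:
    """Inverse of :func:`_pages_to_canonical` for a single channel/time."""
    a, p, z, y, x = data.shape
    if layout is Layout.OMX:
        return data.transpose(0, 2, 1, 3, 4).reshape(a * z * p, y, x)
    if layout is Layout.HOMEBUILT:
        return data.transpose(2, 0, 1, 3, 4).reshape(z * a * p, y, x)
    if layout is Layout.NSIM:
        # montage: angle in rows, phase in columns
        return data.transpose(2, 0, 3, 1, 4).reshape(z, a * y, p * x)
    raise LayoutError(f"unknown layout {layout}")


# ---------------------------------------------------------------------------
# operations


def load_raw_stack(path, geometry: AcquisitionGeometry, *,
                   channel: int = 0, time: int = 0,
                   n_channels: int = 1, n_times: int = 1,
                   camera_offset: float = 0.0) -> RawStack:
    """Load a multi-page TIFF into canonical (angle, phase, z, y, x) order.

    ``camera_offset`` is subtracted and the result clamped at zero so the
    intensities stay on a photon-count-like scale.
    """
    path = Path(path)
    if path.suffix.lower() in {".dv", ".nd2"}:
        raise ValueError(
            f"native {path.suffix} containers are not parsed; export the "
            "acquisition as multi-page TIFF and retry"
        )
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise LayoutError(f"expected a stack of 2-D pages, got shape {pages.shape}")

    a, p = geometry.n_angles, geometry.n_phases
    group = n_channels * n_times
    if geometry.layout is Layout.NSIM:
        if pages.shape[0] % group:
            raise LayoutError(
                f"page count {pages.shape[0]} not divisible by channels*times={group}"
            )
    else:
        if pages.shape[0] % (a * p * group):
            raise LayoutError(
                f"page count {pages.shape[0]} is not divisible by "
                f"n_angles*n_phases*channels*times = {a}*{p}*{group}"
            )
    data = _pages_to_canonical(pages, geometry, n_channels, n_times, channel, time)
    data = data.astype(np.float32)
    if camera_offset:
        data = np.clip(data - camera_offset, 0.0, None)
    return RawStack(data=data, geometry=geometry, channel_id=channel, time_id=time)


def write_raw_stack(stack: RawStack, path, layout: Layout | None = None) -> None:
    """Write a canonical stack back to disk in any of the three orderings."""
    layout = layout or stack.geometry.layout
    pages = _canonical_to_pages(stack.data, layout)
    tifffile.imwrite(path, pages.astype(np.float32))


def validate_stack(stack: RawStack, *, saturation_ceiling: float = 65535.0
                   ) -> ValidationReport:
    """Check a loaded stack; errors abort reconstruction, warnings do not."""
    report = ValidationReport()
    bad = ~np.isfinite(stack.data)
    if bad.any():
        a, p, z = np.argwhere(bad)[0][:3]
        report.errors.append(
            f"non-finite pixel at (angle={a}, phase={p}, z={z})"
        )
    if (stack.data < 0).any():
        report.errors.append("negative intensities present (offset handling failed)")
    if stack.n_z < 6:
        report.warnings.append(
            f"fewer than 6 z-layers ({stack.n_z}); axial reconstruction "
            "quality is reduced — six or more layers are recommended"
        )
    n_sat = int((stack.data >= saturation_ceiling).sum())
    if n_sat:
        report.warnings.append(f"{n_sat} saturated pixels at/above {saturation_ceiling}")
    return report


def write_volume(recon: Reconstruction, path) -> None:
    """Write a 32-bit float TIFF, one page per z-slice, with pixel-size tags.

    The lateral pixel size written is ``dxy/2`` (the reconstruction grid is
    2x upsampled in x and y); the page spacing is ``dz``.
    """
    g = recon.geometry
    dxy_um = (g.dxy / 2.0) / 1000.0
    tifffile.imwrite(
        path,
        recon.volume.astype(np.float32),
        imagej=True,
        resolution=(1.0 / dxy_um, 1.0 / dxy_um),
        metadata={"spacing": g.dz / 1000.0, "unit": "um", "axes": "ZYX"},
    )


def read_volume(path) -> np.ndarray:
    arr = tifffile.imread(path)
    return arr[None] if arr.ndim == 2 else arr


def widefield(stack: RawStack) -> np.ndarray:
    """Conventional diffraction-limited volume: mean over angles and phases."""
    return stack.data.mean(axis=(0, 1))


__all__ = [
    "Layout", "LayoutError", "AcquisitionGeometry", "RawStack",
    "Reconstruction", "ValidationReport", "load_raw_stack", "write_raw_stack",
    "validate_stack", "write_volume", "read_volume", "widefield", "replace",
]
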