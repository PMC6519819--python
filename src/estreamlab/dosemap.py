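"""Planar absolute-dose maps and their summary metrics.

A :class:`DoseMap` is a 2D grid of absolute dose in cGy with a known isotropic
pixel size, the common currency of the whole package: film-style measurements,
simulated panel doses and calculated distributions all live here.  The two
summary statistics are

* ``D_Rx`` -- the mean dose inside a circle of radius *x* cm centred on the
  dose-map maximum (radii 1-4 cm by default), and
* ``A_y%`` -- the area (cm²) of the region at or above *y* % of the
  prescription dose.

Circle membership uses the pixel-centre rule (a pixel belongs to the circle
iff its centre lies within the radius); isodose areas count supra-threshold
pixels times the pixel area, which equals the area enclosed by the isodose
line for the simply-connected single-spot maps this package deals with.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "DoseMap",
    "DrxProfile",
    "IsodoseAreas",
    "DoseMapFormatError",
    "read_dosemap",
    "write_dosemap",
    "rebin",
    "max_point",
    "mean_dose_in_circle",
    "drx_profile",
    "isodose_area",
    "isodose_areas",
]


class DoseMapFormatError(ValueError):
    """Malformed dose-map file or sidecar."""


@dataclass(frozen=True)
class DoseMap:
    """2D absolute dose distribution.

    Parameters
    ----------
    values : ndarray
        Dose in cGy, row-major, shape (n_v, n_u); all finite and >= 0.
    pixel_size : float
        Isotropic pixel pitch in mm.
    origin : tuple of float
        Physical (u, v) coordinate in cm of the first pixel centre in
        panel-local axes.
    label : str
        Free-text description.
    """

    values: np.ndarray
    pixel_size: float = 1.36
    origin: tuple[float, float] = (0.0, 0.0)
    label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("dose map must be a 2D grid of at least 2 x 2 pixels")
        if not np.all(np.isfinite(arr)):
            raise ValueError("dose map contains non-finite values")
        if np.any(arr < 0):
            raise ValueError("dose map contains negative doses")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "values", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def pixel_area_cm2(self) -> float:
        return (self.pixel_size / 10.0) ** 2


@dataclass(frozen=True)
class DrxProfile:
    """Circle-average dose profile around the map maximum."""

    center: tuple[int, int]
    radii: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.radii) != len(self.values):
            raise ValueError("radii and values must have equal length")
        if any(b <= a for a, b in zip(self.radii, self.radii[1:])):
            raise ValueError("radii must be strictly increasing")


@dataclass(frozen=True)
class IsodoseAreas:
    """Suprathreshold areas at fractions of the prescription dose."""

    prescription: float
    levels: tuple[float, ...]
    areas: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.areas):
            raise ValueError("levels and areas must have equal length")
        if any(a < 0 for a in self.areas):
            raise ValueError("areas must be non-negative")


# ---------------------------------------------------------------------------
# I/O: a plain-text grid format plus grayscale image import with a JSON sidecar


def write_dosemap(dmap: DoseMap, path: str | Path) -> None:
    """Write the text-grid format: three header lines then the dose rows."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"pixel_size_mm={dmap.pixel_size!r}\n")
        fh.write(f"origin_cm={dmap.origin[0]!r},{dmap.origin[1]!r}\n")
        fh.write("units=cGy\n")
        for row in dmap.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _read_text_grid(path: Path) -> DoseMap:
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    header: dict[str, str] = {}
    body_start = 0
    for i, ln in enumerate(lines):
        if "=" in ln and not ln.lstrip()[:1].lstrip("-").isdigit():
            key, _, val = ln.partition("=")
            header[key.strip()] = val.strip()
            body_start = i + 1
        else:
            break
    for req in ("pixel_size_mm", "origin_cm", "units"):
        if req not in header:
            raise DoseMapFormatError(f"missing header field '{req}' in {path}")
    if header["units"].lower() != "cgy":
        raise DoseMapFormatError(f"unsupported units '{header['units']}'")
    try:
        pixel_size = float(header["pixel_size_mm"])
        ou, ov = (float(x) for x in header["origin_cm"].split(","))
    except ValueError as exc:
        raise DoseMapFormatError(f"unparseable header in {path}: {exc}") from exc
    try:
        values = np.loadtxt(lines[body_start:], ndmin=2)
    except ValueError as exc:
        raise DoseMapFormatError(f"unparseable dose grid in {path}: {exc}") from exc
    if np.any(values < 0):
        raise DoseMapFormatError(f"negative dose value in {path}")
    return DoseMap(values, pixel_size, (ou, ov), label=path.stem)


def _read_image(path: Path) -> DoseMap:
    """Grayscale image import; requires a JSON sidecar ``<file>.json``.

    The sidecar must provide ``dpi`` (or ``pixel_size_mm``) and
    ``cgy_per_level`` (dose per gray level); ``origin_cm`` is optional.
    """
    import imageio.v3 as iio

    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise DoseMapFormatError(f"missing metadata sidecar '{sidecar.name}'")
    meta = json.loads(sidecar.read_text())
    if "pixel_size_mm" in meta:
        pixel_size = float(meta["pixel_size_mm"])
    elif "dpi" in meta:
        pixel_size = 25.4 / float(meta["dpi"])
    else:
        raise DoseMapFormatError("sidecar lacks 'pixel_size_mm' or 'dpi'")
    if "cgy_per_level" not in meta:
        raise DoseMapFormatError("sidecar lacks 'cgy_per_level'")
    img = np.asarray(iio.imread(path), dtype=float)
    if img.ndim == 3:  # collapse RGB(A) to luminance-style mean
        img = img[..., :3].mean(axis=-1)
    values = img * float(meta["cgy_per_level"])
    origin = tuple(meta.get("origin_cm", (0.0, 0.0)))
    return DoseMap(values, pixel_size, origin, label=path.stem)


def read_dosemap(path: str | Path, format: str = "text_grid") -> DoseMap:
    """Read a dose map from disk (``text_grid`` or ``image``)."""
    path = Path(path)
    if not path.exists():
        raise DoseMapFormatError(f"no such file: {path}")
    if format == "text_grid":
        return _read_text_grid(path)
    if format == "image":
        return _read_image(path)
    raise ValueError(f"unknown format '{format}'")


# ---------------------------------------------------------------------------
# Operations


def rebin(dmap: DoseMap, new_pixel_size: float) -> DoseMap:
    """Block-average rebinning onto a coarser grid.

    The new pitch must be at least the old one; the grid is truncated to whole
    blocks (an integer block size is derived by rounding the pitch ratio, and
    the output pitch is the exact realised one).  Mean dose over the covered
    region is preserved.
    """
    if new_pixel_size < dmap.pixel_size:
        raise ValueError("rebin cannot upsample (new pitch below current)")
    factor = max(1, int(round(new_pixel_size / dmap.pixel_size)))
    n_v, n_u = dmap.shape
    mv, mu = n_v // factor, n_u // factor
    if mv < 2 or mu < 2:
        raise ValueError("rebin factor leaves fewer than 2 x 2 pixels")
    block = dmap.values[: mv * factor, : mu * factor]
    out = block.reshape(mv, factor, mu, factor).mean(axis=(1, 3))
    realised = dmap.pixel_size * factor
    # origin moves to the centre of the first block
    shift = (factor - 1) * dmap.pixel_size / 2.0 / 10.0
    origin = (dmap.origin[0] + shift, dmap.origin[1] + shift)
    return DoseMap(out, realised, origin, label=dmap.label)


def max_point(dmap: DoseMap) -> tuple[int, int]:
    """Index (row, col) of the global maximum; ties take the smallest
    row-major index."""
    flat = int(np.argmax(dmap.values))
    return np.unravel_index(flat, dmap.shape)  # type: ignore[return-value]


def _circle_mask(dmap: DoseMap, center: tuple[int, int], radius_cm: float) -> np.ndarray:
    px_cm = dmap.pixel_size / 10.0
    n_v, n_u = dmap.shape
    rr, cc = np.ogrid[:n_v, :n_u]
    d2 = ((rr - center[0]) ** 2 + (cc - center[1]) ** 2) * px_cm**2
    return d2 <= radius_cm**2 + 1e-12


def mean_dose_in_circle(
    dmap: DoseMap, center: tuple[int, int], radius_cm: float
) -> float:
    """Unweighted mean of pixels whose centres lie within ``radius_cm`` of the
    centre pixel's centre.  Pixels outside the map are simply not part of the
    average (circles truncated at edges use in-map pixels only)."""
    if radius_cm <= 0:
        raise ValueError("radius must be positive")
    mask = _circle_mask(dmap, center, radius_cm)
    if not mask.any():
        raise ValueError("circle selects no pixels")
    return float(dmap.values[mask].mean())


DEFAULT_RADII = (1.0, 2.0, 3.0, 4.0)


def drx_profile(dmap: DoseMap, radii: Sequence[float] = DEFAULT_RADII) -> DrxProfile:
    """``D_Rx`` profile: circle averages around the map maximum."""
    center = max_point(dmap)
    vals = tuple(mean_dose_in_circle(dmap, center, r) for r in radii)
    return DrxProfile(center=center, radii=tuple(radii), values=vals)


def isodose_area(dmap: DoseMap, threshold_cgy: float) -> float:
    """Area (cm²) of the region with dose >= threshold; 0 is a valid result."""
    if threshold_cgy <= 0:
        raise ValueError("threshold must be positive")
    return float(np.count_nonzero(dmap.values >= threshold_cgy) * dmap.pixel_area_cm2)


DEFAULT_LEVELS = (0.30, 0.50, 0.70, 0.90, 1.00)


def isodose_areas(
    dmap: DoseMap,
    prescription_cgy: float = 300.0,
    levels: Sequence[float] = DEFAULT_LEVELS,
) -> IsodoseAreas:
    """``A_y%`` at each level fraction of the prescription dose."""
    if any(not (0 < lv <= 1.5) for lv in levels):
        raise ValueError("levels must lie in (0, 1.5]")
    areas = tuple(isodose_area(dmap, lv * prescription_cgy) for lv in levels)
    return IsodoseAreas(prescription_cgy, tuple(levels), areas)
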