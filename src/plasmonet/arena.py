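"""Arenas: terrain heightfields, habitability masks and region sites.

An arena is the substrate a virtual plasmodium lives on: a boolean
habitability mask (where particles may exist), a list of region sites
(nutrient/attractant positions, e.g. urban centres), and optionally an
8-bit greyscale heightfield whose intensity encodes terrain elevation.

Coordinate convention: 0-based ``(row, col)`` with the origin at the
top-left, matching raster order. All modules share it.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

__all__ = [
    "HeightField",
    "RegionSite",
    "Arena",
    "ArenaError",
    "load_heightfield",
    "write_heightfield",
    "load_sites",
    "write_sites",
    "load_mask",
    "mask_from_height",
    "synth_heightfield",
    "make_arena",
]


class ArenaError(ValueError):
    """Raised for invalid terrain, mask or site inputs."""


@dataclass(frozen=True)
class HeightField:
    """Normalized elevation grid.

    ``values[r, c]`` is elevation in [0, 1]; an 8-bit grey level g maps
    linearly to g/255.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] < 1 or v.shape[1] < 1:
            raise ArenaError("heightfield must be a 2D grid of at least 1x1")
        if not np.all(np.isfinite(v)):
            raise ArenaError("heightfield values must be finite")
        if v.min() < 0.0 or v.max() > 1.0:
            raise ArenaError("heightfield values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def height_px(self) -> int:
        """Number of rows."""
        return self.values.shape[0]

    @property
    def width(self) -> int:
        """Number of columns."""
        return self.values.shape[1]


@dataclass(frozen=True)
class RegionSite:
    """A named attractant site (row, col are 0-based cell coordinates)."""

    region_id: int
    name: str
    row: int
    col: int


@dataclass(frozen=True)
class Arena:
    """Habitability mask, region sites and optional terrain."""

    mask: np.ndarray
    sites: tuple[RegionSite, ...] = field(default_factory=tuple)
    heightfield: HeightField | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_habitable(self) -> int:
        return int(self.mask.sum())

    def site_cells(self) -> np.ndarray:
        """(n_sites, 2) array of site (row, col) cells."""
        return np.array([(s.row, s.col) for s in self.sites], dtype=np.int64).reshape(-1, 2)


_EIGHT_BIT_GREY_MODES = {"L", "P"}


def load_heightfield(path: str | Path) -> HeightField:
    """Read an 8-bit single-channel greyscale raster (PGM P5/P2 or PNG).

    Grey level g becomes elevation g/255 exactly. Multi-channel or
    deeper-than-8-bit rasters are rejected.
    """
    try:
        with Image.open(path) as im:
            mode = im.mode
            if mode == "P":
                # paletted PNGs are only accepted if the palette is a pure grey ramp
                im = im.convert("L")
                mode = "L"
            if mode not in _EIGHT_BIT_GREY_MODES:
                raise ArenaError(
                    f"{path}: expected 8-bit single-channel greyscale, got mode {mode!r}"
                )
            arr = np.asarray(im, dtype=np.uint8)
    except ArenaError:
        raise
    except FileNotFoundError:
        raise
    except OSError as exc:  # unreadable / truncated
        raise OSError(f"cannot read raster {path}: {exc}") from exc
    return HeightField(arr.astype(np.float64) / 255.0)


def write_heightfield(hf: HeightField, path: str | Path) -> None:
    """Write a heightfield as an 8-bit greyscale raster (format from suffix)."""
    grey = np.rint(hf.values * 255.0).astype(np.uint8)
    Image.fromarray(grey, mode="L").save(path)


def load_mask(path: str | Path) -> np.ndarray:
    """Read a habitability mask raster: grey > 0 means habitable."""
    hf = load_heightfield(path)
    return hf.values > 0.0


def mask_from_height(hf: HeightField, cutoff: float) -> np.ndarray:
    """Derive a habitability mask: cells with elevation below ``cutoff``."""
    return hf.values < float(cutoff)


_SITE_COLUMNS = ("region_id", "name", "row", "col")


def load_sites(path: str | Path) -> list[RegionSite]:
    """Read region sites from a CSV with header ``region_id,name,row,col``.

    Row order is preserved; duplicate region ids are rejected. An empty
    file yields an empty list.
    """
    sites: list[RegionSite] = []
    seen: set[int] = set()
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            return []
        header = [h.strip() for h in header]
        if tuple(header[:4]) != _SITE_COLUMNS:
            raise ArenaError(
                f"{path}: expected header {','.join(_SITE_COLUMNS)}, got {','.join(header)}"
            )
        for lineno, rowvals in enumerate(reader, start=2):
            if not rowvals or all(not v.strip() for v in rowvals):
                continue
            try:
                rid = int(rowvals[0])
                name = rowvals[1].strip()
                r, c = int(rowvals[2]), int(rowvals[3])
            except (IndexError, ValueError) as exc:
                raise ArenaError(f"{path}:{lineno}: malformed site row {rowvals!r}") from exc
            if rid in seen:
                raise ArenaError(f"{path}:{lineno}: duplicate region_id {rid}")
            seen.add(rid)
            sites.append(RegionSite(rid, name, r, c))
    return sites


def write_sites(sites: Sequence[RegionSite], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_SITE_COLUMNS)
        for s in sites:
            w.writerow([s.region_id, s.name, s.row, s.col])


def synth_heightfield(
    width: int,
    height_px: int,
    ridges: Sequence[tuple[tuple[float, float], float, float, tuple[float, float] | float]] = (),
    seed: int = 0,
    noise_amp: float = 0.0,
    noise_sigma: float = 6.0,
) -> HeightField:
    """Generate a synthetic terrain as a clipped sum of anisotropic Gaussian ridges.

    Each ridge is ``((center_row, center_col), orientation_deg, amplitude,
    sigma)`` where sigma is ``(sigma_along, sigma_across)`` (a scalar means
    isotropic) and orientation is the ridge axis, degrees counter-clockwise
    from the +col direction. Optional smooth seeded noise (amplitude
    ``noise_amp``) roughens the surface; the result is referentially
    transparent in (arguments, seed).
    """
    field_ = np.zeros((height_px, width), dtype=np.float64)
    rr, cc = np.mgrid[0:height_px, 0:width].astype(np.float64)
    for (cr, ccen), orient, amp, sigma in ridges:
        if not 0.0 <= amp <= 1.0:
            raise ArenaError(f"ridge amplitude {amp} outside [0, 1]")
        if np.isscalar(sigma):
            s_along = s_across = float(sigma)
        else:
            s_along, s_across = map(float, sigma)
        th = np.deg2rad(orient)
        dr, dc = rr - cr, cc - ccen
        # rotate into ridge frame: u along the axis, v across it
        u = dc * np.cos(th) + dr * np.sin(th)
        v = -dc * np.sin(th) + dr * np.cos(th)
        field_ += amp * np.exp(-0.5 * ((u / s_along) ** 2 + (v / s_across) ** 2))
    if noise_amp > 0.0:
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(seed)
        noise = gaussian_filter(rng.standard_normal((height_px, width)), noise_sigma)
        span = np.abs(noise).max()
        if span > 0:
            field_ += noise_amp * noise / span
    return HeightField(np.clip(field_, 0.0, 1.0))


def make_arena(
    mask: np.ndarray,
    sites: Sequence[RegionSite] = (),
    heightfield: HeightField | None = None,
) -> Arena:
    """Assemble and validate an arena.

    All sites must lie on habitable cells; mask and heightfield dimensions
    must agree when both are given.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ArenaError("mask must be 2D")
    if heightfield is not None and heightfield.shape != mask.shape:
        raise ArenaError(
            f"mask dimensions {mask.shape} != heightfield dimensions {heightfield.shape}"
        )
    seen: set[int] = set()
    for s in sites:
        if s.region_id in seen:
            raise ArenaError(f"duplicate region_id {s.region_id}")
        seen.add(s.region_id)
        if not (0 <= s.row < mask.shape[0] and 0 <= s.col < mask.shape[1]):
            raise ArenaError(f"site {s.region_id} ({s.row},{s.col}) outside grid {mask.shape}")
        if not mask[s.row, s.col]:
            raise ArenaError(f"site {s.region_id} ({s.row},{s.col}) on non-habitable cell")
    return Arena(mask=mask, sites=tuple(sites), heightfield=heightfield)
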