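"""Calibrated two-channel image I/O, 200 um tiling, and 5x5-tile ROI assembly.

The on-disk format is a two-page 8-bit grayscale TIFF (page 1 = SHG collagen
channel, page 2 = TPEF parenchyma autofluorescence) with a JSON sidecar next to
it holding the microns-per-pixel calibration. Calibration lives in the sidecar,
not in TIFF tags, so round-trips are bit-exact and dialect-proof.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import tifffile

__all__ = [
    "ChannelImage",
    "CalibrationMissingError",
    "read_section",
    "write_section",
    "TileGrid",
    "tile",
    "Roi",
    "RoiSet",
    "select_rois",
]


class CalibrationMissingError(IOError):
    """Raised when a section file has no readable pixel-size sidecar."""


@dataclass
class ChannelImage:
    """A calibrated two-channel raster: SHG (collagen) and TPEF (parenchyma).

    Pixels are row-major and 0-based; pixel centers sit at
    ``(i + 0.5, j + 0.5) * pixel_size_um``.
    """

    shg: np.ndarray
    tpef: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.shg = np.asarray(self.shg)
        self.tpef = np.asarray(self.tpef)
        if self.shg.ndim != 2 or self.tpef.ndim != 2:
            raise ValueError("channels must be 2-D rasters")
        if self.shg.shape != self.tpef.shape:
            raise ValueError(
                f"channel shapes differ: SHG {self.shg.shape} vs TPEF {self.tpef.shape}"
            )
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.shg.shape

    @property
    def height_um(self) -> float:
        return self.shg.shape[0] * self.pixel_size_um

    @property
    def width_um(self) -> float:
        return self.shg.shape[1] * self.pixel_size_um


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_section(image: ChannelImage, path: str | Path) -> Path:
    """Write a section as a two-page TIFF plus JSON calibration sidecar.

    Returns the sidecar path. ``read_section(write_section(...))`` is the
    identity on raster values and calibration.
    """
    path = Path(path)
    stack = np.stack([np.asarray(image.shg), np.asarray(image.tpef)])
    tifffile.imwrite(path, stack, photometric="minisblack")
    sidecar = _sidecar_path(path)
    sidecar.write_text(
        json.dumps(
            {"pixel_size_um": image.pixel_size_um, "channels": ["SHG", "TPEF"]},
            indent=1,
        )
    )
    return sidecar


def read_section(path: str | Path) -> ChannelImage:
    """Read a two-page TIFF section and its calibration sidecar."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise CalibrationMissingError(
            f"calibration sidecar {sidecar} not found next to {path}"
        )
    meta = json.loads(sidecar.read_text())
    if "pixel_size_um" not in meta:
        raise CalibrationMissingError(f"sidecar {sidecar} lacks 'pixel_size_um'")
    data = tifffile.imread(path)
    if data.ndim != 3 or data.shape[0] != 2:
        raise ValueError(
            f"expected a two-page TIFF (SHG, TPEF); got array of shape {data.shape}"
        )
    return ChannelImage(
        shg=data[0], tpef=data[1], pixel_size_um=float(meta["pixel_size_um"])
    )


# ---------------------------------------------------------------------------
# Tiling
# ---------------------------------------------------------------------------


@dataclass
class TileGrid:
    """Non-overlapping square tiles cropped from the image top-left corner.

    Partial tiles at the right/bottom edges are discarded rather than padded,
    avoiding zero-intensity borders that would bias collagen percentages.
    """

    image: ChannelImage
    tile_px: int
    tile_um: float
    n_rows: int
    n_cols: int

    def bounds(self, row: int, col: int) -> tuple[slice, slice]:
        """Pixel slices of tile (row, col)."""
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"tile ({row}, {col}) outside {self.n_rows}x{self.n_cols} grid")
        t = self.tile_px
        return slice(row * t, (row + 1) * t), slice(col * t, (col + 1) * t)

    def __iter__(self) -> Iterator[tuple[int, int]]:
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                yield r, c


def tile(image: ChannelImage, tile_um: float = 200.0) -> TileGrid:
    """Partition the image into ``tile_um``-sided square tiles.

    The tile side in pixels is ``round(tile_um / pixel_size_um)``; at the
    native calibration of 200/512 um/px a 200 um tile is exactly 512 px.
    """
    if not tile_um > 0:
        raise ValueError("tile_um must be positive")
    tile_px = round(tile_um / image.pixel_size_um)
    if tile_px < 1:
        raise ValueError("tile smaller than one pixel")
    h, w = image.shape
    if h < tile_px or w < tile_px:
        raise ValueError(
            f"image ({h}x{w} px) smaller than one {tile_px} px tile"
        )
    return TileGrid(
        image=image,
        tile_px=tile_px,
        tile_um=tile_um,
        n_rows=h // tile_px,
        n_cols=w // tile_px,
    )


# ---------------------------------------------------------------------------
# ROI selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Roi:
    """A k x k-tile window, addressed by its top-left tile coordinate."""

    row: int
    col: int


@dataclass
class RoiSet:
    """Pairwise-disjoint ROI windows, each ``tiles_per_roi_side`` tiles square."""

    rois: list[Roi]
    tiles_per_roi_side: int
    tile_um: float
    shortfall: bool = False  # fewer qualifying windows than requested

    def __len__(self) -> int:
        return len(self.rois)

    def bounds(self, grid: TileGrid, roi: Roi) -> tuple[slice, slice]:
        k = self.tiles_per_roi_side
        t = grid.tile_px
        return (
            slice(roi.row * t, (roi.row + k) * t),
            slice(roi.col * t, (roi.col + k) * t),
        )


def select_rois(
    grid: TileGrid,
    n_rois: int,
    tissue_mask: np.ndarray,
    min_tissue_fraction: float = 0.8,
    seed: int = 0,
    tiles_per_roi_side: int = 5,
) -> RoiSet:
    """Select ``n_rois`` disjoint 5x5-tile (1 mm^2) ROI windows.

    Candidate windows are scored by tissue coverage; windows below
    ``min_tissue_fraction`` are dropped. Selection is greedy by tissue fraction
    (ties broken by (row, col)), keeping windows disjoint, then thinned to
    ``n_rois`` by a seeded uniform draw -- reproducible and tissue-biased, like
    manual ROI placement. If fewer windows qualify, all of them are returned
    with ``shortfall=True`` and a warning.
    """
    if n_rois < 1:
        raise ValueError("n_rois must be >= 1")
    k = tiles_per_roi_side
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    if tissue_mask.shape != grid.image.shape:
        raise ValueError("tissue mask shape differs from image shape")

    t = grid.tile_px
    # per-tile tissue pixel counts, then window sums over k x k tiles
    h_crop, w_crop = grid.n_rows * t, grid.n_cols * t
    per_tile = (
        tissue_mask[:h_crop, :w_crop]
        .reshape(grid.n_rows, t, grid.n_cols, t)
        .sum(axis=(1, 3))
    )
    if grid.n_rows < k or grid.n_cols < k:
        raise ValueError("image holds no complete ROI window")
    from numpy.lib.stride_tricks import sliding_window_view

    win = sliding_window_view(per_tile, (k, k)).sum(axis=(2, 3))
    frac = win / float((k * t) ** 2)

    order = sorted(
        ((r, c) for r in range(win.shape[0]) for c in range(win.shape[1])
         if frac[r, c] >= min_tissue_fraction),
        key=lambda rc: (-frac[rc[0], rc[1]], rc[0], rc[1]),
    )
    chosen: list[Roi] = []
    for r, c in order:
        if all(abs(r - q.row) >= k or abs(c - q.col) >= k for q in chosen):
            chosen.append(Roi(r, c))

    if len(chosen) < n_rois:
        warnings.warn(
            f"only {len(chosen)} qualifying ROI windows (requested {n_rois})",
            stacklevel=2,
        )
        rois, shortfall = chosen, True
    else:
        rng = np.random.default_rng(seed)
        idx = sorted(rng.choice(len(chosen), size=n_rois, replace=False))
        rois, shortfall = [chosen[i] for i in idx], False
    rois = sorted(rois, key=lambda q: (q.row, q.col))
    return RoiSet(
        rois=rois,
        tiles_per_roi_side=k,
        tile_um=grid.tile_um,
        shortfall=shortfall,
    )
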