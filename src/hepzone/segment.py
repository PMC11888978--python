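"""Otsu-threshold tissue/collagen masks and tissue-cavity ("hollow") detection.

The TPEF autofluorescence channel shows hepatocyte cytoplasm as bright signal;
lumens, lipid vacuoles, vessels, and tissue cracks emit nothing and appear as
dark hollows. The SHG channel shows fibrillar collagen. Both channels are
segmented with Otsu's 256-bin histogram threshold; SHG signal outside the
tissue and sub-fibril residual specks are treated as noise and removed.

Intensities are quantized to 8 bit before thresholding so the threshold search
is an exact, enumerable 256-level problem.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology

__all__ = [
    "DegenerateHistogramError",
    "quantize_u8",
    "otsu_threshold",
    "tissue_mask",
    "section_support",
    "collagen_mask",
    "TissueMasks",
    "CavityObject",
    "detect_cavities",
]


class DegenerateHistogramError(ValueError):
    """Histogram has fewer than two populated bins; no threshold separates it."""


def quantize_u8(raster: np.ndarray) -> np.ndarray:
    """Quantize an intensity raster to uint8 (8-bit, 256 levels).

    uint8 input is passed through; integer input already within [0, 255] is
    cast; anything else is min-max rescaled onto [0, 255].
    """
    arr = np.asarray(raster)
    if arr.dtype == np.uint8:
        return arr
    if np.issubdtype(arr.dtype, np.integer) and arr.min() >= 0 and arr.max() <= 255:
        return arr.astype(np.uint8)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    return np.round((arr - lo) * (255.0 / (hi - lo))).astype(np.uint8)


def otsu_threshold(histogram: np.ndarray) -> int:
    """Otsu threshold on a 256-bin histogram.

    Returns the level ``t`` maximizing the between-class variance of the split
    ``{< t}`` (background) vs ``{>= t}`` (foreground); ties are broken by the
    lowest qualifying level.
    """
    h = np.asarray(histogram, dtype=np.int64)
    if h.shape != (256,):
        raise ValueError("histogram must have exactly 256 bins")
    if h.min() < 0:
        raise ValueError("histogram counts must be non-negative")
    if np.count_nonzero(h) < 2:
        raise DegenerateHistogramError("histogram has fewer than two populated bins")

    levels = np.arange(256, dtype=np.float64)
    c = np.cumsum(h).astype(np.float64)  # counts below each split, exact in float64
    m = np.cumsum(h * levels)
    n_total, m_total = c[-1], m[-1]

    t = np.arange(1, 256)
    n0 = c[t - 1]
    valid = (n0 > 0) & (n0 < n_total)
    n0 = n0[valid]
    t = t[valid]
    mu0 = m[t - 1] / n0
    mu1 = (m_total - m[t - 1]) / (n_total - n0)
    var_b = (n0 / n_total) * (1.0 - n0 / n_total) * (mu0 - mu1) ** 2
    return int(t[int(np.argmax(var_b))])


def _otsu_of(raster: np.ndarray) -> tuple[np.ndarray, int]:
    u8 = quantize_u8(raster)
    hist = np.bincount(u8.ravel(), minlength=256)
    return u8, otsu_threshold(hist)


def _otsu_effectiveness(u8: np.ndarray, t: int) -> float:
    """Otsu's separability measure eta = sigma_between^2 / sigma_total^2.

    Near 1 for well-separated classes; ~0.5-0.6 when the threshold merely
    bisects a unimodal noise distribution.
    """
    x = u8.astype(np.float64)
    total = x.var()
    if total == 0:
        return 0.0
    fg = x >= t
    w = fg.mean()
    if w in (0.0, 1.0):
        return 0.0
    return float(w * (1.0 - w) * (x[fg].mean() - x[~fg].mean()) ** 2 / total)


@dataclass
class TissueMasks:
    """Tissue (TPEF) and collagen (SHG, restricted to tissue) binary masks."""

    tissue: np.ndarray
    collagen: np.ndarray
    thresholds: tuple[int, int]  # (t_tpef, t_shg)

    def __post_init__(self) -> None:
        if self.tissue.shape != self.collagen.shape:
            raise ValueError("tissue and collagen masks must share dimensions")
        if np.any(self.collagen & ~self.tissue):
            raise ValueError("collagen mask must be a subset of the tissue mask")


def tissue_mask(
    tpef: np.ndarray,
    pixel_size_um: float,
    max_hole_um2: float = 400.0,
    min_tissue_um2: float = 10_000.0,
) -> np.ndarray:
    """Tissue mask from the TPEF channel.

    Otsu foreground, with holes smaller than ``max_hole_um2`` filled (holes
    that small are intracellular and must not erase vacuoles from the cavity
    complement) and connected components smaller than ``min_tissue_um2``
    removed. Idempotent under re-application.
    """
    if not pixel_size_um > 0:
        raise ValueError("pixel_size_um must be positive")
    u8, t = _otsu_of(tpef)
    fg = u8 >= t
    px_area = pixel_size_um**2
    fg = morphology.remove_small_objects(
        fg, max_size=max(0, math.ceil(min_tissue_um2 / px_area) - 1), connectivity=2
    )
    fg = morphology.remove_small_holes(
        fg, max_size=max(1, math.ceil(max_hole_um2 / px_area))
    )
    return fg


def section_support(
    tissue: np.ndarray,
    pixel_size_um: float | None = None,
    seal_um: float = 6.0,
) -> np.ndarray:
    """Section support: tissue with every enclosed cavity filled.

    Lumens, vessels, and vacuoles are interior holes of the specimen; the
    support is the footprint over which zones partition and per-area readouts
    (foci per mm^2, hepatocyte-occupiable area) are normalized. When a pixel
    size is given, thin fissures open to the section edge (cracks) are first
    sealed by a Euclidean closing of radius ``seal_um`` so they count as part
    of the footprint instead of leaking into the background.
    """
    t = np.asarray(tissue, dtype=bool)
    if pixel_size_um is not None:
        r = seal_um / pixel_size_um
        dilated = ndi.distance_transform_edt(~t) <= r
        closed = ndi.distance_transform_edt(dilated) > r  # erosion of the dilation
        t = t | closed
    return ndi.binary_fill_holes(t)


def collagen_mask(
    shg: np.ndarray,
    tissue: np.ndarray,
    pixel_size_um: float,
    min_fibril_um2: float = 5.0,
    min_separability: float = 0.62,
) -> np.ndarray:
    """Collagen mask from the SHG channel, restricted to tissue.

    SHG signal outside the specimen and connected components smaller than
    ``min_fibril_um2`` (residual specks) are treated as noise and removed.
    A collagen-free channel contains only detector noise, which Otsu would
    bisect; such unimodal histograms are recognized by a low separability
    measure (below ``min_separability``) and yield an empty mask.
    """
    if not pixel_size_um > 0:
        raise ValueError("pixel_size_um must be positive")
    tissue = np.asarray(tissue, dtype=bool)
    u8, t = _otsu_of(shg)
    if _otsu_effectiveness(u8, t) < min_separability:
        return np.zeros(u8.shape, dtype=bool)
    fg = (u8 >= t) & tissue
    min_px = max(2, math.ceil(min_fibril_um2 / pixel_size_um**2))
    return morphology.remove_small_objects(fg, max_size=min_px - 1, connectivity=2)


@dataclass
class CavityObject:
    """A detected tissue cavity (dark TPEF hollow) with morphological features.

    ``collagen_ring_fraction`` is the fraction of a thin (default 5 um) outer
    annulus covered by collagen -- the discriminator between lipid vacuoles
    (bare) and vessels/portal lumens (collagen-sheathed).
    """

    id: int
    bbox: tuple[slice, slice]
    mask: np.ndarray  # boolean crop within bbox
    centroid_um: tuple[float, float]  # (x, y)
    area_um2: float
    equivalent_diameter_um: float
    circularity: float  # 4*pi*A / P^2, capped at 1.05 for discretization
    solidity: float
    collagen_ring_fraction: float
    border: bool  # touches the section border (never classed as vacuole)
    label: str | None = None

    def feature(self, name: str) -> float:
        value = getattr(self, name)
        return float(value)

    def with_label(self, label: str) -> "CavityObject":
        return replace(self, label=label)


def detect_cavities(
    tpef: np.ndarray,
    tissue: np.ndarray,
    collagen: np.ndarray,
    pixel_size_um: float,
    min_cavity_um2: float = 15.0,
    ring_um: float = 5.0,
) -> list[CavityObject]:
    """Detect dark cavities enclosed by tissue and compute their features.

    Works on the complement of the raw (pre-hole-fill) Otsu foreground within
    the section support, so intracellular vacuoles survive. Objects touching
    the section border are flagged (cracks and cut artefacts; excluded from
    vacuole calls downstream).
    """
    if not pixel_size_um > 0:
        raise ValueError("pixel_size_um must be positive")
    tissue = np.asarray(tissue, dtype=bool)
    collagen = np.asarray(collagen, dtype=bool)
    support = section_support(tissue, pixel_size_um)
    u8, t = _otsu_of(tpef)
    dark = support & (u8 < t)
    if not dark.any():
        return []

    ps2 = pixel_size_um**2
    min_px = max(1, math.ceil(min_cavity_um2 / ps2))
    ring_px = max(1, round(ring_um / pixel_size_um))
    selem = morphology.disk(ring_px)
    # section border layer: support pixels adjacent to non-support or image edge
    edge = support & ~ndi.binary_erosion(support, border_value=0)

    labels = measure.label(dark, connectivity=2)
    objects: list[CavityObject] = []
    h, w = dark.shape
    for rp in measure.regionprops(labels):
        if rp.area < min_px:
            continue
        rs, cs, re, ce = rp.bbox
        # expand bbox to fit the ring annulus
        ers, ecs = max(0, rs - ring_px - 1), max(0, cs - ring_px - 1)
        ere, ece = min(h, re + ring_px + 1), min(w, ce + ring_px + 1)
        sl = (slice(ers, ere), slice(ecs, ece))
        obj = labels[sl] == rp.label
        ann = ndi.binary_dilation(obj, structure=selem) & ~dark[sl] & support[sl]
        ring_fraction = float(collagen[sl][ann].mean()) if ann.any() else 0.0
        perim = rp.perimeter_crofton
        circ = 4.0 * math.pi * rp.area / perim**2 if perim > 0 else 1.0
        cy, cx = rp.centroid
        objects.append(
            CavityObject(
                id=int(rp.label),
                bbox=(slice(rs, re), slice(cs, ce)),
                mask=(labels[rs:re, cs:ce] == rp.label),
                centroid_um=(cx * pixel_size_um, cy * pixel_size_um),
                area_um2=rp.area * ps2,
                equivalent_diameter_um=rp.equivalent_diameter_area * pixel_size_um,
                circularity=min(circ, 1.05),
                solidity=float(rp.solidity),
                collagen_ring_fraction=ring_fraction,
                border=bool(edge[rs:re, cs:ce][labels[rs:re, cs:ce] == rp.label].any()),
            )
        )
    return objects
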