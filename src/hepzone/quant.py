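"""Zone-wise collagen quantification, steatosis, and PT/CV foci density."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .segment import CavityObject, section_support
from .zonation import ZONE_BACKGROUND, ZONE_NAMES, ZoneMap

__all__ = [
    "ZoneCollagenProfile",
    "SteatosisResult",
    "FociDensity",
    "collagen_by_zone",
    "collagen_ratio",
    "steatosis",
    "foci_density",
]


@dataclass
class ZoneCollagenProfile:
    """Collagen distribution over the five acinar zones.

    ``shares`` is the fraction of all collagen pixels falling in each zone
    (the headline readout: "percentage of total collagen in each area");
    ``densities`` is collagen pixels / zone pixels, the within-zone areal
    density. ``shares_defined`` is False when the section holds no collagen.
    """

    shares: dict[str, float]
    densities: dict[str, float]
    total_areal_fraction: float  # collagen pixels / tissue pixels
    collagen_px: int
    tissue_px: int
    shares_defined: bool = True


def collagen_by_zone(collagen: np.ndarray, zone_map: ZoneMap) -> ZoneCollagenProfile:
    """Exact pixel-count collagen shares and densities per zone."""
    collagen = np.asarray(collagen, dtype=bool)
    labels = zone_map.labels
    if collagen.shape != labels.shape:
        raise ValueError(
            f"collagen mask {collagen.shape} and zone map {labels.shape} differ"
        )
    zones = [name for code, name in ZONE_NAMES.items() if code != ZONE_BACKGROUND]
    counts = {
        name: int(np.count_nonzero(collagen & (labels == code)))
        for code, name in ZONE_NAMES.items()
        if code != ZONE_BACKGROUND
    }
    zone_px = {
        name: int(np.count_nonzero(labels == code))
        for code, name in ZONE_NAMES.items()
        if code != ZONE_BACKGROUND
    }
    total = sum(counts.values())
    tissue_px = sum(zone_px.values())
    defined = total > 0
    shares = {
        z: (counts[z] / total if defined else 0.0) for z in zones
    }
    densities = {
        z: (counts[z] / zone_px[z] if zone_px[z] else 0.0) for z in zones
    }
    return ZoneCollagenProfile(
        shares=shares,
        densities=densities,
        total_areal_fraction=(total / tissue_px if tissue_px else 0.0),
        collagen_px=total,
        tissue_px=tissue_px,
        shares_defined=defined,
    )


def collagen_ratio(
    group_a: Sequence[ZoneCollagenProfile],
    group_b: Sequence[ZoneCollagenProfile],
    zone: str | None = None,
) -> float:
    """Ratio of mean collagen areal fraction, group a over group b.

    With ``zone=None`` the total collagen areal fraction is compared; with a
    zone name, that zone's within-zone density.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")

    def _value(p: ZoneCollagenProfile) -> float:
        return p.total_areal_fraction if zone is None else p.densities[zone]

    mean_b = float(np.mean([_value(p) for p in group_b]))
    if mean_b <= 0:
        raise ZeroDivisionError("denominator group has zero mean collagen")
    return float(np.mean([_value(p) for p in group_a])) / mean_b


@dataclass
class SteatosisResult:
    """Steatotic-hepatocyte proportion and vacuole size statistics."""

    steatotic_fraction: float
    vacuole_count: int
    total_hepatocytes: float
    median_diameter_um: float
    iqr_diameter_um: tuple[float, float]


def steatosis(
    labeled_cavities: Sequence[CavityObject],
    tissue: np.ndarray,
    pixel_size_um: float,
    nominal_cell_area_um2: float = 450.0,
) -> SteatosisResult:
    """Steatotic hepatocytes as a proportion of total hepatocytes.

    One vacuole-class object counts as one steatotic hepatocyte (adjacent
    vacuoles merged by connectivity count once). The hepatocyte denominator is
    the hepatocyte-occupiable area -- section support minus all cavity pixels
    -- divided by the nominal cell area; this area quotient slightly exceeds
    the true cell count when cells pack looser than the nominal footprint, a
    bias documented in the methods note.
    """
    if not nominal_cell_area_um2 > 0:
        raise ValueError("nominal_cell_area_um2 must be positive")
    support = section_support(tissue, pixel_size_um)
    support_um2 = float(np.count_nonzero(support)) * pixel_size_um**2
    cavity_um2 = float(sum(obj.area_um2 for obj in labeled_cavities))
    total_hep = max(0.0, support_um2 - cavity_um2) / nominal_cell_area_um2
    vacuoles = [obj for obj in labeled_cavities if obj.label == "vacuole"]
    frac = min(1.0, len(vacuoles) / total_hep) if total_hep > 0 else 0.0
    diam = np.array([v.equivalent_diameter_um for v in vacuoles])
    if diam.size:
        med = float(np.median(diam))
        iqr = (float(np.percentile(diam, 25)), float(np.percentile(diam, 75)))
    else:
        med, iqr = float("nan"), (float("nan"), float("nan"))
    return SteatosisResult(
        steatotic_fraction=frac,
        vacuole_count=len(vacuoles),
        total_hepatocytes=total_hep,
        median_diameter_um=med,
        iqr_diameter_um=iqr,
    )


@dataclass
class FociDensity:
    pt_per_mm2: float
    cv_per_mm2: float
    tissue_area_mm2: float


def _object_class(obj) -> str | None:
    # accepts classified CavityObject (.label) or planted Landmark (.cls)
    return getattr(obj, "label", None) or getattr(obj, "cls", None)


def foci_density(labeled_objects: Sequence, tissue_area_mm2: float) -> FociDensity:
    """PT- and CV-class object counts per mm^2 of section area."""
    if not tissue_area_mm2 > 0:
        raise ValueError("tissue_area_mm2 must be positive")
    classes = [_object_class(o) for o in labeled_objects]
    return FociDensity(
        pt_per_mm2=classes.count("PT") / tissue_area_mm2,
        cv_per_mm2=classes.count("CV") / tissue_area_mm2,
        tissue_area_mm2=tissue_area_mm2,
    )
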