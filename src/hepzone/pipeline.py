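"""End-to-end analysis of one calibrated two-channel section.

Chains the stages: Otsu tissue/collagen masks -> cavity detection ->
decision-tree classification -> zone map from the detected PT/CV landmarks ->
zone-wise collagen, steatosis, and foci-density readouts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import quant, segment, zonation
from .imgio import ChannelImage

__all__ = ["AnalysisResult", "analyze_section"]


@dataclass
class AnalysisResult:
    tissue: np.ndarray
    support: np.ndarray
    collagen: np.ndarray
    cavities: list[segment.CavityObject]  # classified
    zone_map: zonation.ZoneMap
    collagen_profile: quant.ZoneCollagenProfile
    steatosis: quant.SteatosisResult
    foci: quant.FociDensity

    @property
    def tissue_area_mm2(self) -> float:
        return self.foci.tissue_area_mm2


def analyze_section(
    image: ChannelImage,
    tree: zonation.ObjectClassTree | None = None,
    band_um: float = 100.0,
    nominal_cell_area_um2: float = 450.0,
    **segment_kwargs,
) -> AnalysisResult:
    """Run the full quantification pipeline on one section.

    ``segment_kwargs`` are forwarded to the segmentation stage
    (``max_hole_um2``, ``min_tissue_um2``, ``min_fibril_um2``,
    ``min_cavity_um2``).
    """
    ps = image.pixel_size_um
    seg_names = {"max_hole_um2", "min_tissue_um2"}
    tissue_kwargs = {k: v for k, v in segment_kwargs.items() if k in seg_names}
    tissue = segment.tissue_mask(image.tpef, ps, **tissue_kwargs)
    support = segment.section_support(tissue, ps)
    collagen = segment.collagen_mask(
        image.shg, support, ps,
        **{k: v for k, v in segment_kwargs.items() if k == "min_fibril_um2"},
    )
    cavities = segment.detect_cavities(
        image.tpef, tissue, collagen, ps,
        **{k: v for k, v in segment_kwargs.items() if k == "min_cavity_um2"},
    )
    labeled = zonation.classify_objects(cavities, tree)
    pt_mask, cv_mask = zonation.cavities_to_landmark_masks(labeled, image.shape)
    zone_map = zonation.build_zone_map(
        support, pt_mask, cv_mask, ps, band_um,
        landmarks=[o for o in labeled if o.label in ("PT", "CV")],
    )
    collagen_profile = quant.collagen_by_zone(collagen, zone_map)
    steat = quant.steatosis(labeled, tissue, ps, nominal_cell_area_um2)
    area_mm2 = float(np.count_nonzero(support)) * ps**2 / 1e6
    foci = quant.foci_density(labeled, area_mm2)
    return AnalysisResult(
        tissue=tissue,
        support=support,
        collagen=collagen,
        cavities=labeled,
        zone_map=zone_map,
        collagen_profile=collagen_profile,
        steatosis=steat,
        foci=foci,
    )
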