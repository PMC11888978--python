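"""Synthetic two-channel liver-section generator with full ground truth.

Renders a calibrated SHG/TPEF image pair emulating an unstained regenerating
mouse liver section:

* TPEF: bright, textured hepatocyte cytoplasm over the whole section, with
  dark hollows for portal-tract (PT) and central-vein (CV) lumens, small
  vessels/bile ducts, tissue cracks, and lipid vacuoles. Vacuoles occupy a
  Bernoulli fraction of hepatocyte lattice sites equal to the profile's
  steatotic fraction.
* SHG: collagen fibrils whose areal density per acinar zone follows the
  profile's zonal map over the *true* zone map (computed from the planted
  landmarks with the same 100 um band routine the analysis uses). PT lumens
  and small vessels get a dense collagen annulus; CV lumens and vacuoles stay
  bare, giving the classifier its learnable contrast.

Every random draw comes from one seeded generator passed explicitly; identical
(profile, dims, seed) produce bit-identical images and ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage import draw as skdraw

from .imgio import ChannelImage, write_section
from .profiles import ConditionProfile
from .zonation import (
    ZONE_NAMES,
    ZONE_PP,
    ZONE_TS,
    ZONE_PC,
    ZoneMap,
    build_zone_map,
    rasterize_landmarks,
)

__all__ = [
    "Landmark",
    "GroundTruth",
    "PlacementInfeasibleError",
    "plant_landmarks",
    "generate_section",
    "save_synthetic_section",
]

#: Native calibration: a 512 px tile spans 200 um.
DEFAULT_PIXEL_SIZE_UM = 200.0 / 512.0


class PlacementInfeasibleError(RuntimeError):
    """Requested landmark count cannot be placed at the minimum separation."""


@dataclass(frozen=True)
class Landmark:
    """A circular PT or CV landmark (center and radius in microns)."""

    cls: str  # "PT" | "CV"
    x_um: float
    y_um: float
    radius_um: float


@dataclass
class GroundTruth:
    """Everything the generator planted, for parameter-recovery testing."""

    landmark_list: list[Landmark]
    vacuole_mask: np.ndarray
    collagen_mask: np.ndarray
    zone_map_true: ZoneMap
    planted_params: dict

    @property
    def pt_count(self) -> int:
        return sum(1 for lm in self.landmark_list if lm.cls == "PT")

    @property
    def cv_count(self) -> int:
        return sum(1 for lm in self.landmark_list if lm.cls == "CV")


def plant_landmarks(
    area_mm2: float,
    pt_count: int,
    cv_count: int,
    min_sep_um: float,
    seed: int,
    pt_radius_um: float = 25.0,
    cv_radius_um: float = 40.0,
    edge_margin_um: float = 10.0,
) -> list[Landmark]:
    """Place non-overlapping circular landmarks in a square field by rejection
    sampling; deterministic given the seed.

    Raises :class:`PlacementInfeasibleError` after a bounded number of
    attempts when the requested counts cannot be honored at the minimum
    center separation.
    """
    if area_mm2 <= 0:
        raise ValueError("area_mm2 must be positive")
    side = math.sqrt(area_mm2) * 1000.0
    rng = np.random.default_rng(seed)
    return _plant(side, side, pt_count, cv_count, min_sep_um, rng,
                  pt_radius_um, cv_radius_um, edge_margin_um)


def _plant(
    width_um: float,
    height_um: float,
    pt_count: int,
    cv_count: int,
    min_sep_um: float,
    rng: np.random.Generator,
    pt_radius_um: float,
    cv_radius_um: float,
    edge_margin_um: float,
    max_attempts_per_landmark: int = 5000,
) -> list[Landmark]:
    if pt_count < 0 or cv_count < 0:
        raise ValueError("landmark counts must be non-negative")
    if min_sep_um <= 0:
        raise ValueError("min_sep_um must be positive")
    specs = [("PT", pt_radius_um)] * pt_count + [("CV", cv_radius_um)] * cv_count
    placed: list[Landmark] = []
    for cls, r in specs:
        margin = r + edge_margin_um
        if width_um - 2 * margin <= 0 or height_um - 2 * margin <= 0:
            raise PlacementInfeasibleError(
                f"field too small for a radius-{r} um landmark"
            )
        for _ in range(max_attempts_per_landmark):
            x = rng.uniform(margin, width_um - margin)
            y = rng.uniform(margin, height_um - margin)
            if all(
                (x - q.x_um) ** 2 + (y - q.y_um) ** 2 >= min_sep_um**2
                for q in placed
            ):
                placed.append(Landmark(cls, x, y, r))
                break
        else:
            raise PlacementInfeasibleError(
                f"could not place landmark {len(placed) + 1}/{len(specs)} at "
                f"min separation {min_sep_um} um"
            )
    return placed


def _realize_count(density_per_mm2: float, area_mm2: float,
                   rng: np.random.Generator) -> int:
    """Expected-count-preserving integerization: floor plus a Bernoulli on the
    fractional part."""
    expected = density_per_mm2 * area_mm2
    base = int(math.floor(expected))
    return base + int(rng.random() < (expected - base))


def _disc_indices(shape, cx, cy, r):
    h, w = shape
    r0, r1 = max(0, int(cy - r) - 1), min(h, int(cy + r) + 2)
    c0, c1 = max(0, int(cx - r) - 1), min(w, int(cx + r) + 2)
    if r0 >= r1 or c0 >= c1:
        return None
    yy, xx = np.ogrid[r0:r1, c0:c1]
    return (slice(r0, r1), slice(c0, c1)), (
        (yy + 0.5 - cy) ** 2 + (xx + 0.5 - cx) ** 2 <= r**2
    )


def _paint(mask, cx, cy, r, value=True):
    hit = _disc_indices(mask.shape, cx, cy, r)
    if hit is not None:
        sl, disc = hit
        mask[sl][disc] = value


def _annulus(shape, cx, cy, r0, r1):
    hit = _disc_indices(shape, cx, cy, r1)
    if hit is None:
        return None
    sl, outer = hit
    yy, xx = np.ogrid[sl[0], sl[1]]
    inner = (yy + 0.5 - cy) ** 2 + (xx + 0.5 - cx) ** 2 <= r0**2
    return sl, outer & ~inner


def _truncated_lognormal(rng, median, sigma_log, lo, hi, size):
    vals = rng.lognormal(math.log(median), sigma_log, size)
    bad = (vals < lo) | (vals > hi)
    while bad.any():
        vals[bad] = rng.lognormal(math.log(median), sigma_log, int(bad.sum()))
        bad = (vals < lo) | (vals > hi)
    return vals


def _hex_sites(width_px, height_px, spacing_px, jitter_px, rng):
    """Jittered hexagonal lattice of hepatocyte site centers, in pixel coords."""
    dy = spacing_px * math.sqrt(3.0) / 2.0
    rows = np.arange(spacing_px / 2.0, height_px, dy)
    xs_list, ys_list = [], []
    for i, y in enumerate(rows):
        offset = spacing_px / 2.0 if i % 2 else 0.0
        xs = np.arange(spacing_px / 2.0 + offset, width_px, spacing_px)
        xs_list.append(xs)
        ys_list.append(np.full(xs.shape, y))
    xs = np.concatenate(xs_list)
    ys = np.concatenate(ys_list)
    xs = xs + rng.normal(0.0, jitter_px, xs.shape)
    ys = ys + rng.normal(0.0, jitter_px, ys.shape)
    keep = (xs >= 1) & (xs < width_px - 1) & (ys >= 1) & (ys < height_px - 1)
    return xs[keep], ys[keep]


def _draw_fibril(mask, cy, cx, length_px, theta, thick2: bool):
    h, w = mask.shape
    dy, dx = math.sin(theta) * length_px / 2, math.cos(theta) * length_px / 2
    r0, c0 = int(round(cy - dy)), int(round(cx - dx))
    r1, c1 = int(round(cy + dy)), int(round(cx + dx))
    rr, cc = skdraw.line(r0, c0, r1, c1)
    ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    rr, cc = rr[ok], cc[ok]
    mask[rr, cc] = True
    if thick2:  # ~2 px thick at fine calibration
        rr2 = np.clip(rr + 1, 0, h - 1)
        mask[rr2, cc] = True


def generate_section(
    profile: ConditionProfile,
    width_mm: float = 1.0,
    height_mm: float = 1.0,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    seed: int = 0,
    *,
    margin_um: float = 0.0,
    cell_diameter_um: float = 24.0,
    cell_jitter_um: float = 2.0,
    vacuole_median_um: float = 12.0,
    vacuole_sigma_log: float = 0.35,
    vacuole_range_um: tuple[float, float] = (5.0, 40.0),
    pt_radius_um: float = 25.0,
    cv_radius_um: float = 40.0,
    min_sep_um: float = 150.0,
    pt_count: int | None = None,
    cv_count: int | None = None,
    vessels_per_mm2: float = 8.0,
    vessel_radius_um: tuple[float, float] = (5.0, 8.5),
    n_cracks: int = 1,
    noise_sigma: float = 5.0,
    band_um: float = 100.0,
) -> tuple[ChannelImage, GroundTruth]:
    """Generate one synthetic section plus its ground truth.

    Landmark counts default to the profile's foci densities times the field
    area (expected-count-preserving integerization); ``pt_count``/``cv_count``
    override them for controlled-planting experiments.
    """
    if width_mm <= 0 or height_mm <= 0:
        raise ValueError("section dimensions must be positive")
    if not pixel_size_um > 0:
        raise ValueError("pixel_size_um must be positive")
    if pixel_size_um > vacuole_range_um[0]:
        raise ValueError(
            "pixel size exceeds the smallest structure (minimum vacuole diameter)"
        )
    ps = pixel_size_um
    H = round(height_mm * 1000.0 / ps)
    W = round(width_mm * 1000.0 / ps)
    width_um, height_um = W * ps, H * ps
    area_mm2 = width_um * height_um / 1e6
    rng = np.random.default_rng(seed)

    # --- section support -------------------------------------------------
    support = np.zeros((H, W), dtype=bool)
    m = round(margin_um / ps)
    support[m: H - m if m else H, m: W - m if m else W] = True
    tis_w, tis_h = width_um - 2 * margin_um, height_um - 2 * margin_um

    # --- landmarks --------------------------------------------------------
    n_pt = pt_count if pt_count is not None else _realize_count(
        profile.pt_foci_density, area_mm2, rng)
    n_cv = cv_count if cv_count is not None else _realize_count(
        profile.cv_foci_density, area_mm2, rng)
    landmarks = _plant(tis_w, tis_h, n_pt, n_cv, min_sep_um, rng,
                       pt_radius_um, cv_radius_um, edge_margin_um=10.0)
    if margin_um:
        landmarks = [
            Landmark(lm.cls, lm.x_um + margin_um, lm.y_um + margin_um, lm.radius_um)
            for lm in landmarks
        ]
    pt_mask, cv_mask = rasterize_landmarks(landmarks, (H, W), ps)

    # --- confounder vessels / bile ducts ---------------------------------
    n_vessels = rng.poisson(vessels_per_mm2 * area_mm2)
    vessels: list[tuple[float, float, float]] = []  # (x_um, y_um, r_um)
    attempts = 0
    while len(vessels) < n_vessels and attempts < 200 * max(1, n_vessels):
        attempts += 1
        r = rng.uniform(*vessel_radius_um)
        x = rng.uniform(margin_um + 15, width_um - margin_um - 15)
        y = rng.uniform(margin_um + 15, height_um - margin_um - 15)
        if any((x - lm.x_um) ** 2 + (y - lm.y_um) ** 2 < (lm.radius_um + 25) ** 2
               for lm in landmarks):
            continue
        if any((x - vx) ** 2 + (y - vy) ** 2 < 30.0**2 for vx, vy, _ in vessels):
            continue
        vessels.append((x, y, r))
    vessel_mask = np.zeros((H, W), dtype=bool)
    for x, y, r in vessels:
        _paint(vessel_mask, x / ps, y / ps, r / ps)

    # --- cracks (border-anchored, routed around landmarks) ----------------
    crack_mask = np.zeros((H, W), dtype=bool)
    crack_line = np.zeros((H, W), dtype=bool)
    for _ in range(n_cracks):
        side = rng.integers(0, 4)
        if side == 0:
            x, y, heading = rng.uniform(0.1, 0.9) * width_um, margin_um, math.pi / 2
        elif side == 1:
            x, y, heading = rng.uniform(0.1, 0.9) * width_um, height_um - margin_um, -math.pi / 2
        elif side == 2:
            x, y, heading = margin_um, rng.uniform(0.1, 0.9) * height_um, 0.0
        else:
            x, y, heading = width_um - margin_um, rng.uniform(0.1, 0.9) * height_um, math.pi
        length = rng.uniform(0.3, 0.6) * min(width_um, height_um)
        step = 10.0
        pts = [(x, y)]
        for _ in range(int(length / step)):
            heading += rng.normal(0.0, 0.35)
            nx, ny = x + step * math.cos(heading), y + step * math.sin(heading)
            if not (0 <= nx < width_um and 0 <= ny < height_um):
                break
            if any((nx - lm.x_um) ** 2 + (ny - lm.y_um) ** 2
                   < (lm.radius_um + 15) ** 2 for lm in landmarks):
                break  # cracks deflect around rigid structures; stop here
            pts.append((nx, ny))
            x, y = nx, ny
        for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
            rr, cc = skdraw.line(int(y0 / ps), int(x0 / ps),
                                 int(y1 / ps), int(x1 / ps))
            ok = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
            crack_line[rr[ok], cc[ok]] = True
    crack_dist_um = None
    if crack_line.any():
        crack_dist_um = ndi.distance_transform_edt(~crack_line) * ps
        crack_mask = (crack_dist_um <= 3.0) & ~pt_mask & ~cv_mask

    # --- true zone map (shared geometry routine) --------------------------
    zone_true = build_zone_map(support, pt_mask, cv_mask, ps, band_um,
                               landmarks=list(landmarks))

    # --- hepatocyte sites and vacuoles ------------------------------------
    spacing_px = cell_diameter_um / ps
    xs, ys = _hex_sites(W, H, spacing_px, cell_jitter_um / ps, rng)
    ix, iy = xs.astype(int), ys.astype(int)
    keep = support[iy, ix]
    # exclude sites inside or hugging a cavity structure (analytic distances)
    xu, yu = xs * ps, ys * ps
    for lm in landmarks:
        keep &= (xu - lm.x_um) ** 2 + (yu - lm.y_um) ** 2 > (lm.radius_um + 4.0) ** 2
    for vx, vy, vr in vessels:
        keep &= (xu - vx) ** 2 + (yu - vy) ** 2 > (vr + 6.0) ** 2
    if crack_dist_um is not None:
        keep &= crack_dist_um[iy, ix] > 9.0
    xs, ys = xs[keep], ys[keep]
    n_sites = xs.size

    is_vac = rng.random(n_sites) < profile.steatotic_fraction
    n_vac = int(is_vac.sum())
    vac_diam = _truncated_lognormal(
        rng, vacuole_median_um, vacuole_sigma_log, *vacuole_range_um, size=n_vac
    )
    vacuole_mask = np.zeros((H, W), dtype=bool)
    for x, y, d in zip(xs[is_vac], ys[is_vac], vac_diam):
        # vacuoles shrink against neighboring rigid structures so cavities
        # stay separable (peri-structural hepatocytes are smaller)
        xu_i, yu_i = x * ps, y * ps
        gap = math.inf
        for lm in landmarks:
            gap = min(gap, math.hypot(xu_i - lm.x_um, yu_i - lm.y_um) - lm.radius_um)
        for vx, vy, vr in vessels:
            gap = min(gap, math.hypot(xu_i - vx, yu_i - vy) - vr)
        if crack_dist_um is not None:
            gap = min(gap, float(crack_dist_um[int(y), int(x)]) - 3.0)
        r_um = min(d / 2.0, max(2.5, gap - 2.0))
        _paint(vacuole_mask, x, y, r_um / ps)
    vacuole_mask &= support

    cavity_mask = pt_mask | cv_mask | vessel_mask | crack_mask | vacuole_mask

    # --- collagen ----------------------------------------------------------
    coll_draw = np.zeros((H, W), dtype=bool)
    ring_px = 5.0 / ps
    for lm in landmarks:
        if lm.cls != "PT":
            continue
        hit = _annulus((H, W), lm.x_um / ps, lm.y_um / ps,
                       lm.radius_um / ps, lm.radius_um / ps + ring_px)
        if hit is not None:
            sl, ann = hit
            coll_draw[sl] |= ann & (rng.random(ann.shape) < 0.85)
    for x, y, r in vessels:
        hit = _annulus((H, W), x / ps, y / ps, r / ps, (r + 4.0) / ps)
        if hit is not None:
            sl, ann = hit
            coll_draw[sl] |= ann & (rng.random(ann.shape) < 0.8)

    # keep the CV periphery collagen-poor: a 5 um exclusion collar
    cv_collar = np.zeros((H, W), dtype=bool)
    for lm in landmarks:
        if lm.cls != "CV":
            continue
        hit = _annulus((H, W), lm.x_um / ps, lm.y_um / ps,
                       lm.radius_um / ps, lm.radius_um / ps + ring_px)
        if hit is not None:
            sl, ann = hit
            cv_collar[sl] |= ann

    allowed = support & ~cavity_mask & ~cv_collar
    thick2 = ps < 0.6
    zone_labels = zone_true.labels
    for zone_code in (ZONE_PP, ZONE_TS, ZONE_PC):
        density = profile.zonal_collagen_density.get(ZONE_NAMES[zone_code], 0.0)
        if density <= 0:
            continue
        zone_px = int(np.count_nonzero(zone_labels == zone_code))
        if zone_px == 0:
            continue
        target = density * zone_px
        valid = (zone_labels == zone_code) & allowed
        idx = np.flatnonzero(valid)
        if idx.size == 0:
            continue
        mean_len_px = 27.5 / ps  # fibril length ~ U(15, 40) um
        est_px = mean_len_px * (2.0 if thick2 else 1.0) * 0.9  # overlap discount
        scratch = np.zeros((H, W), dtype=bool)
        for _ in range(10):
            current = np.count_nonzero(coll_draw & valid)
            deficit = target - current
            if deficit < est_px / 2:
                break
            n_fib = max(1, min(4000, int(deficit / est_px)))
            centers = idx[rng.integers(0, idx.size, n_fib)]
            cys, cxs = np.unravel_index(centers, (H, W))
            lengths = rng.uniform(15.0, 40.0, n_fib) / ps
            thetas = rng.uniform(0.0, math.pi, n_fib)
            scratch[:] = False
            for cy, cx, L, th in zip(cys, cxs, lengths, thetas):
                _draw_fibril(scratch, cy, cx, L, th, thick2)
            coll_draw |= scratch & valid  # fibrils stay within their zone
    collagen = coll_draw & support & ~cavity_mask & ~cv_collar

    # --- render TPEF --------------------------------------------------------
    # texture sd kept well below the cavity/cytoplasm contrast so the
    # threshold always lands in the gap, even on near-featureless sections
    texture = ndi.gaussian_filter(rng.standard_normal((H, W)), 2.0)
    texture /= texture.std() or 1.0
    tpef = np.clip(170.0 + 8.0 * texture, 135.0, 210.0)
    tpef[~support] = 8.0
    tpef[cavity_mask] = 18.0

    # --- render SHG ----------------------------------------------------------
    shg = np.full((H, W), 8.0)
    shg[collagen] = 160.0
    # salt specks: outside-tissue noise plus isolated in-tissue residuals
    outside = np.flatnonzero(~support)
    if outside.size:
        k = min(200, outside.size)
        pick = outside[rng.integers(0, outside.size, k)]
        shg.ravel()[pick] = 210.0
    inside = np.flatnonzero(support & ~collagen)
    pick = inside[rng.integers(0, inside.size, 40)]
    shg.ravel()[pick] = 210.0

    tpef = np.clip(tpef + rng.normal(0.0, noise_sigma, (H, W)), 0, 255)
    shg = np.clip(shg + rng.normal(0.0, noise_sigma, (H, W)), 0, 255)
    image = ChannelImage(
        shg=shg.astype(np.uint8), tpef=tpef.astype(np.uint8), pixel_size_um=ps
    )

    zone_px_counts = {
        name: int(np.count_nonzero(zone_labels == code))
        for code, name in ZONE_NAMES.items()
    }
    realized_zone_coll = {
        name: (
            float(np.count_nonzero(collagen & (zone_labels == code)))
            / zone_px_counts[name]
            if zone_px_counts[name]
            else 0.0
        )
        for code, name in ZONE_NAMES.items()
        if name != "background"
    }
    gt = GroundTruth(
        landmark_list=list(landmarks),
        vacuole_mask=vacuole_mask,
        collagen_mask=collagen,
        zone_map_true=zone_true,
        planted_params={
            "group": profile.group,
            "day": profile.day,
            "seed": int(seed),
            "pixel_size_um": ps,
            "realized_pt_count": n_pt,
            "realized_cv_count": n_cv,
            "n_vessels": len(vessels),
            "n_hepatocyte_sites": int(n_sites),
            "n_vacuoles": n_vac,
            "realized_steatotic_fraction": (n_vac / n_sites) if n_sites else 0.0,
            "target_steatotic_fraction": profile.steatotic_fraction,
            "realized_zonal_collagen_density": realized_zone_coll,
            "total_collagen_fraction": float(
                np.count_nonzero(collagen) / np.count_nonzero(support)
            ),
        },
    )
    return image, gt


def save_synthetic_section(
    out_dir: str | Path, image: ChannelImage, gt: GroundTruth, stem: str = "section"
) -> dict[str, str]:
    """Write a section, its ground-truth masks, and a JSON sidecar to a directory.

    Masks go out as single-page 8-bit TIFF label rasters; the sidecar records
    calibration, planted parameters, and the ground-truth file paths.
    """
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    section_path = out / f"{stem}.tif"
    write_section(image, section_path)
    paths = {"section": str(section_path)}
    for name, mask in [
        ("vacuole_mask", gt.vacuole_mask),
        ("collagen_mask", gt.collagen_mask),
    ]:
        p = out / f"{stem}_{name}.tif"
        tifffile.imwrite(p, (mask.astype(np.uint8) * 255))
        paths[name] = str(p)
    p = out / f"{stem}_zone_map.tif"
    tifffile.imwrite(p, gt.zone_map_true.labels)
    paths["zone_map"] = str(p)
    meta = {
        "pixel_size_um": image.pixel_size_um,
        "zone_legend": {str(k): v for k, v in ZONE_NAMES.items()},
        "planted_params": gt.planted_params,
        "landmarks": [asdict(lm) for lm in gt.landmark_list],
        "paths": paths,
    }
    (out / f"{stem}_ground_truth.json").write_text(json.dumps(meta, indent=1))
    return paths
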