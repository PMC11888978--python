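"""Condition profiles: ground-truth parameter sets per experimental group and day.

A :class:`ConditionProfile` bundles everything the synthetic-section generator and
the cohort simulator need for one (group, day) cell of the hepatectomy/glutamine
study design: the steatotic-hepatocyte fraction, portal-tract (PT) and central-vein
(CV) foci densities, per-zone collagen areal densities, and the longitudinal
endpoint means (remnant liver weight / body weight, transaminases, albumin,
PCNA-positive hepatocyte percentage) as mean +/- SEM with a group size.

Profiles for the published group x day cells carry the printed means; cells the
figures do not print (baseline foci densities, absolute collagen densities, some
endpoint days) are smooth, physiologically plausible interpolations chosen once and
documented in docs/methods.md. The day-2 and day-4 collagen density maps are
constructed so that the group ratio of total collagen areal fraction reproduces the
reported 1.2x (day 2) and 4.9x (day 4) glutamine effects under the default landmark
geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from types import MappingProxyType
from typing import Mapping

__all__ = [
    "GROUPS",
    "ZONES",
    "ENDPOINTS",
    "EndpointStat",
    "ConditionProfile",
    "builtin_profiles",
    "get_profile",
]

#: Experimental arms: sham or 70% partial hepatectomy, with/without glutamine water.
GROUPS = ("sham+Gln", "sham-Gln", "PHx+Gln", "PHx-Gln")

#: Acinar zones used for collagen density maps (PT/CV are the lumen label classes).
ZONES = ("PT", "PP", "TS", "PC", "CV")

#: Longitudinal endpoints simulated by :mod:`hepzone.cohort`.
ENDPOINTS = ("rlw_bw_pct", "ast_UL", "alt_UL", "albumin", "pcna_pct")


@dataclass(frozen=True)
class EndpointStat:
    """Mean +/- SEM of one endpoint in one group at one day, with group size n."""

    mean: float
    sem: float
    n: int = 6

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise ValueError("SEM must be non-negative")
        if self.n < 1:
            raise ValueError("group size n must be >= 1")

    @property
    def sd(self) -> float:
        """Per-animal standard deviation implied by the SEM (sem * sqrt(n))."""
        return self.sem * self.n**0.5


@dataclass(frozen=True)
class ConditionProfile:
    group: str
    day: int
    steatotic_fraction: float
    pt_foci_density: float  # per mm^2
    cv_foci_density: float  # per mm^2
    zonal_collagen_density: Mapping[str, float]  # zone -> areal fraction in [0, 1]
    endpoint_means: Mapping[str, EndpointStat]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if not 0 <= self.day <= 6:
            raise ValueError("day must be in 0..6")
        if not 0.0 <= self.steatotic_fraction <= 1.0:
            raise ValueError("steatotic_fraction must be in [0, 1]")
        if self.pt_foci_density < 0 or self.cv_foci_density < 0:
            raise ValueError("foci densities must be >= 0")
        for zone, dens in self.zonal_collagen_density.items():
            if zone not in ZONES:
                raise ValueError(f"unknown zone {zone!r}")
            if not 0.0 <= dens <= 1.0:
                raise ValueError(f"collagen density for {zone} outside [0, 1]")
        # freeze the mappings so profiles are safely shareable
        object.__setattr__(
            self, "zonal_collagen_density",
            MappingProxyType(dict(self.zonal_collagen_density)),
        )
        object.__setattr__(
            self, "endpoint_means", MappingProxyType(dict(self.endpoint_means))
        )

    def with_(self, **changes) -> "ConditionProfile":
        """Return a copy with fields replaced (mappings are re-validated)."""
        return replace(
            self,
            **{
                k: (dict(v) if isinstance(v, MappingProxyType) else v)
                for k, v in changes.items()
            },
        )


def _coll(pp: float, ts: float, pc: float) -> dict[str, float]:
    # PT and CV zone labels are the lumen pixels themselves; no collagen inside.
    return {"PT": 0.0, "PP": pp, "TS": ts, "PC": pc, "CV": 0.0}


def _ep(rlw, ast, alt, alb, pcna) -> dict[str, EndpointStat]:
    return {
        "rlw_bw_pct": EndpointStat(*rlw),
        "ast_UL": EndpointStat(*ast),
        "alt_UL": EndpointStat(*alt),
        "albumin": EndpointStat(*alb),
        "pcna_pct": EndpointStat(*pcna),
    }


_BASELINE_COLL = _coll(0.020, 0.0040, 0.0060)

# (group, day) -> field tuples. Anchor cells carry the reported group means
# (liver weight, transaminases, PCNA, steatosis percentages, collagen ratios, foci
# densities); the remaining cells are declared interpolations.
_TABLE: dict[tuple[str, int], dict] = {
    # ---- PHx + Gln -------------------------------------------------------
    ("PHx+Gln", 0): dict(
        steatotic_fraction=0.0, pt=3.0, cv=2.0, coll=_BASELINE_COLL,
        ep=_ep((1.4, 0.10), (100, 15), (55, 10), (3.0, 0.1), (1.0, 0.3)),
    ),
    ("PHx+Gln", 1): dict(
        steatotic_fraction=0.103, pt=5.0, cv=2.0, coll=_coll(0.022, 0.0045, 0.0065),
        ep=_ep((1.7, 0.15), (11393, 367), (9478, 564), (2.7, 0.1), (9.6, 1.5)),
    ),
    ("PHx+Gln", 2): dict(
        steatotic_fraction=0.333, pt=7.7, cv=2.0, coll=_coll(0.020, 0.0043, 0.0070),
        ep=_ep((3.0, 0.2), (4000, 500), (3000, 400), (2.8, 0.1), (34.3, 4.8)),
    ),
    ("PHx+Gln", 4): dict(
        steatotic_fraction=0.057, pt=5.0, cv=2.0, coll=_coll(0.145, 0.0180, 0.0080),
        ep=_ep((3.7, 0.4), (800, 150), (500, 100), (2.9, 0.1), (24.2, 3.3)),
    ),
    ("PHx+Gln", 6): dict(
        steatotic_fraction=0.010, pt=3.5, cv=2.0, coll=_coll(0.030, 0.0060, 0.0070),
        ep=_ep((4.2, 0.3), (150, 30), (80, 15), (3.0, 0.1), (5.0, 1.0)),
    ),
    # ---- PHx - Gln -------------------------------------------------------
    ("PHx-Gln", 0): dict(
        steatotic_fraction=0.0, pt=3.0, cv=2.0, coll=_BASELINE_COLL,
        ep=_ep((1.4, 0.10), (100, 15), (55, 10), (3.0, 0.1), (1.0, 0.3)),
    ),
    ("PHx-Gln", 1): dict(
        steatotic_fraction=0.044, pt=3.0, cv=2.0, coll=_coll(0.024, 0.0050, 0.0065),
        ep=_ep((1.6, 0.10), (7600, 873), (5704, 588), (2.7, 0.1), (9.1, 3.9)),
    ),
    ("PHx-Gln", 2): dict(
        steatotic_fraction=0.162, pt=3.2, cv=2.0, coll=_coll(0.025, 0.0050, 0.0070),
        ep=_ep((2.0, 0.1), (3000, 400), (2200, 350), (2.8, 0.1), (15.5, 1.4)),
    ),
    ("PHx-Gln", 4): dict(
        steatotic_fraction=0.011, pt=2.5, cv=2.0, coll=_coll(0.030, 0.0060, 0.0080),
        ep=_ep((2.7, 0.3), (700, 150), (450, 90), (2.9, 0.1), (13.6, 0.8)),
    ),
    ("PHx-Gln", 6): dict(
        steatotic_fraction=0.005, pt=3.0, cv=2.0, coll=_coll(0.028, 0.0055, 0.0070),
        ep=_ep((3.8, 0.3), (150, 30), (80, 15), (3.0, 0.1), (4.0, 1.0)),
    ),
    # ---- sham + Gln ------------------------------------------------------
    ("sham+Gln", 0): dict(
        steatotic_fraction=0.0, pt=3.0, cv=2.0, coll=_BASELINE_COLL,
        ep=_ep((4.4, 0.2), (120, 20), (60, 10), (3.1, 0.1), (1.2, 0.3)),
    ),
    ("sham+Gln", 2): dict(
        steatotic_fraction=0.0, pt=3.0, cv=2.0, coll=_BASELINE_COLL,
        ep=_ep((4.3, 0.2), (120, 20), (60, 10), (3.1, 0.1), (1.5, 0.4)),
    ),
    ("sham+Gln", 6): dict(
        steatotic_fraction=0.0, pt=3.0, cv=2.0, coll=_BASELINE_COLL,
        ep=_ep((4.3, 0.2), (120, 20), (60, 10), (3.1, 0.1), (1.2, 0.3)),
    ),
    # ---- sham - Gln ------------------------------------------------------
    ("sham-Gln", 0): dict(
        steatotic_fraction=0.0, pt=3.0, cv=2.0, coll=_BASELINE_COLL,
        ep=_ep((4.4, 0.2), (120, 20), (60, 10), (3.1, 0.1), (1.2, 0.3)),
    ),
    ("sham-Gln", 2): dict(
        steatotic_fraction=0.0, pt=3.0, cv=2.0, coll=_BASELINE_COLL,
        ep=_ep((4.1, 0.4), (120, 20), (60, 10), (3.1, 0.1), (1.4, 0.4)),
    ),
    ("sham-Gln", 6): dict(
        steatotic_fraction=0.0, pt=3.0, cv=2.0, coll=_BASELINE_COLL,
        ep=_ep((4.7, 0.1), (120, 20), (60, 10), (3.1, 0.1), (1.2, 0.3)),
    ),
}


def builtin_profiles() -> dict[tuple[str, int], ConditionProfile]:
    """All built-in condition profiles, keyed by (group, day).

    One profile exists per (group, day) combination reported in the study's
    results figures; sham arms carry baseline values on the sampled days.
    """
    out: dict[tuple[str, int], ConditionProfile] = {}
    for (group, day), row in _TABLE.items():
        out[(group, day)] = ConditionProfile(
            group=group,
            day=day,
            steatotic_fraction=row["steatotic_fraction"],
            pt_foci_density=row["pt"],
            cv_foci_density=row["cv"],
            zonal_collagen_density=row["coll"],
            endpoint_means=row["ep"],
        )
    return out


def get_profile(group: str, day: int) -> ConditionProfile:
    """Look up one built-in profile; raises ``KeyError`` for unsampled cells."""
    profiles = builtin_profiles()
    try:
        return profiles[(group, day)]
    except KeyError:
        raise KeyError(
            f"no built-in profile for group={group!r}, day={day}; "
            f"available: {sorted(profiles)}"
        ) from None
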