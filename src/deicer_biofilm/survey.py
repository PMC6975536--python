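"""Standardized biofilm volumes from rapid periphyton-style field surveys.

Each reach visit records ~50 survey points (5 transects x 10 points); every
point is assigned one of four operational biofilm classes — soft algae,
transition, heterotrophs, diatoms — or none, plus a biofilm thickness in mm.
Per-class volumes are standardized to a 50 m^2 reach:

    V = (F * 50) * T

where ``F`` is the fraction of survey points in the class and ``T`` is the
median thickness (mm) among points of the class.  With thickness in mm and
area in m^2 the volume unit is liters per standardized reach.  A class absent
from the survey has F = 0 and hence V = 0 exactly; for log-transformation
zeros are replaced by half the minimum non-zero volume of the analysis set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "CLASSES",
    "STANDARD_REACH_M2",
    "SurveyPoint",
    "BiofilmVolumeRecord",
    "compute_class_volume",
    "compute_visit_volumes",
    "substitute_zeros_for_log",
    "season_contrast",
]

#: Closed operational class vocabulary (plus "none" for bare points).
CLASSES: tuple[str, ...] = ("soft algae", "transition", "heterotrophs", "diatoms")

#: Standardized reach area, m^2.
STANDARD_REACH_M2: float = 50.0


@dataclass(frozen=True)
class SurveyPoint:
    """A single transect-point observation."""

    site: str
    visit: pd.Timestamp
    transect: int
    point: int
    biofilm_class: str  # one of CLASSES or "none"
    thickness_mm: float | None = None

    def __post_init__(self) -> None:
        if self.biofilm_class not in CLASSES and self.biofilm_class != "none":
            raise ValueError(f"unknown biofilm class {self.biofilm_class!r}")
        if self.biofilm_class != "none":
            if self.thickness_mm is None:
                raise ValueError("thickness required when a biofilm class is present")
            if self.thickness_mm < 0:
                raise ValueError("thickness must be non-negative")


@dataclass(frozen=True)
class BiofilmVolumeRecord:
    """Per-class standardized volume for one site visit.

    ``volume_l`` is liters per standardized 50 m^2 reach
    (fraction x m^2 x mm = L).
    """

    site: str
    visit: pd.Timestamp
    biofilm_class: str
    fraction: float
    median_thickness_mm: float
    volume_l: float
    substituted: bool = False


def compute_class_volume(
    points: Sequence[SurveyPoint], biofilm_class: str
) -> BiofilmVolumeRecord:
    """Standardized volume of one biofilm class from a visit's survey points.

    ``F`` counts points of the class over *all* surveyed points (bare "none"
    points count in the denominator).  ``T`` is the median thickness among
    points of the class; the median of an even count is the mean of the two
    central values.  When the class is absent, F = 0 and V = 0 by definition.
    """
    if not points:
        raise ValueError("empty survey: at least one point required")
    if biofilm_class not in CLASSES:
        raise ValueError(f"unknown biofilm class {biofilm_class!r}")
    in_class = [p for p in points if p.biofilm_class == biofilm_class]
    fraction = len(in_class) / len(points)
    if in_class:
        median_t = float(np.median([p.thickness_mm for p in in_class]))
    else:
        median_t = 0.0
    volume = fraction * STANDARD_REACH_M2 * median_t
    p0 = points[0]
    return BiofilmVolumeRecord(
        site=p0.site,
        visit=p0.visit,
        biofilm_class=biofilm_class,
        fraction=fraction,
        median_thickness_mm=median_t,
        volume_l=volume,
    )


def compute_visit_volumes(points: Sequence[SurveyPoint]) -> pd.DataFrame:
    """All four class volumes for one visit, as a tidy frame."""
    recs = [compute_class_volume(points, c) for c in CLASSES]
    return pd.DataFrame(
        {
            "site": [r.site for r in recs],
            "visit": [r.visit for r in recs],
            "biofilm_class": [r.biofilm_class for r in recs],
            "fraction": [r.fraction for r in recs],
            "median_thickness_mm": [r.median_thickness_mm for r in recs],
            "volume_l": [r.volume_l for r in recs],
        }
    )


def substitute_zeros_for_log(volumes: Iterable[float]) -> tuple[np.ndarray, np.ndarray]:
    """Replace zero volumes by half the minimum non-zero volume.

    The floor is computed over the whole collection passed in — i.e. over the
    full analysis dataset entering a regression, not per site.  Returns the
    substituted values and a boolean flag array marking substituted entries.
    Raises when every volume is zero (the floor is then undefined).
    """
    v = np.asarray(list(volumes), dtype=float)
    if np.any(v < 0):
        raise ValueError("volumes must be non-negative")
    nonzero = v[v > 0]
    zeros = v == 0
    if not zeros.any():
        return v.copy(), zeros
    if nonzero.size == 0:
        raise ValueError("all volumes are zero; substitution floor undefined")
    out = v.copy()
    out[zeros] = 0.5 * nonzero.min()
    return out, zeros


def season_contrast(
    volumes: pd.DataFrame,
    *,
    deicer_months: frozenset[int] = frozenset({12, 1, 2, 3, 4, 5}),
    value_col: str = "volume_l",
    date_col: str = "visit",
) -> tuple[float, float]:
    """Kruskal-Wallis contrast of volumes between deicer and non-deicer months.

    Visits in December-May are deicer influenced; June-November are not.
    Returns ``(H, p)``; raises when either seasonal group has fewer than two
    observations.
    """
    months = pd.to_datetime(volumes[date_col]).dt.month
    in_season = months.isin(deicer_months)
    a = volumes.loc[in_season, value_col].to_numpy(float)
    b = volumes.loc[~in_season, value_col].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 observations in each seasonal group")
    h, p = scipy.stats.kruskal(a, b)
    return float(h), float(p)
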