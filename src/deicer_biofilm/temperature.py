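"""Between-site temperature gap-filling and antecedent statistics.

Water temperature at the two ungaged sites is recorded by paired thermocouples
with occasional gaps; continuous records exist at the two nearby gages.  Gaps
at an ungaged site are filled from an ordinary-least-squares affine relation
fitted between contemporaneous ungaged and gaged observations, and antecedent
summary statistics (mean, max, min, median, SD) are computed over a ladder of
look-back windows preceding each biofilm site visit.

A temperature frame has columns ``timestamp``, ``value`` (deg C, NaN when
missing) and, after filling, ``estimated`` (bool provenance flag).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .config import TEMPERATURE_WINDOWS_WEEKS

__all__ = [
    "PairRelation",
    "fit_pair_relation",
    "fill_gaps",
    "antecedent_temperature_stats",
    "average_dual_sensors",
    "despike",
]


@dataclass(frozen=True)
class PairRelation:
    """Fitted affine relation of an ungaged on a gaged temperature record."""

    slope: float
    intercept: float
    r2: float
    n: int

    def predict(self, gaged: float | np.ndarray) -> float | np.ndarray:
        return self.slope * np.asarray(gaged, dtype=float) + self.intercept


def fit_pair_relation(
    ungaged: pd.DataFrame, gaged: pd.DataFrame, *, min_pairs: int = 10
) -> PairRelation:
    """OLS of contemporaneous ungaged on gaged temperature.

    Records are matched on exact timestamps; pairs with either value missing
    are dropped.  Raises when fewer than ``min_pairs`` pairs remain or the
    gaged series is constant (degenerate fit).
    """
    merged = pd.merge(
        ungaged[["timestamp", "value"]],
        gaged[["timestamp", "value"]],
        on="timestamp",
        suffixes=("_u", "_g"),
    ).dropna()
    if len(merged) < min_pairs:
        raise ValueError(
            f"only {len(merged)} contemporaneous pairs; need >= {min_pairs}"
        )
    x = merged["value_g"].to_numpy(float)
    y = merged["value_u"].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("gaged series is constant; pair relation undefined")
    res = scipy.stats.linregress(x, y)
    return PairRelation(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        n=len(merged),
    )


def fill_gaps(
    ungaged: pd.DataFrame, gaged: pd.DataFrame, relation: PairRelation
) -> pd.DataFrame:
    """Fill missing ungaged values from the gaged record via ``relation``.

    Observed values are untouched; filled values are flagged ``estimated``.
    A gap where the gaged record is also missing stays missing.
    """
    out = ungaged.copy()
    gaged_at = gaged.set_index("timestamp")["value"]
    missing = out["value"].isna()
    donor = out.loc[missing, "timestamp"].map(gaged_at)
    out["estimated"] = False
    filled = relation.slope * donor + relation.intercept
    out.loc[missing, "value"] = filled
    out.loc[missing, "estimated"] = filled.notna().to_numpy()
    return out


def average_dual_sensors(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Average two co-located thermocouple records on their timestamp union.

    Where only one sensor reports, its value is used alone; where neither
    does, the result is missing.
    """
    merged = pd.merge(
        a[["timestamp", "value"]],
        b[["timestamp", "value"]],
        on="timestamp",
        how="outer",
        suffixes=("_a", "_b"),
    ).sort_values("timestamp", ignore_index=True)
    merged["value"] = merged[["value_a", "value_b"]].mean(axis=1)
    return merged[["timestamp", "value"]]


def despike(
    series: pd.DataFrame,
    *,
    lower_c: float = -1.0,
    upper_c: float = 35.0,
    max_step_c: float = 5.0,
) -> pd.DataFrame:
    """Mask physically implausible readings as missing.

    A simple stand-in for agency record QA: values outside ``[lower, upper]``
    deg C, or jumping more than ``max_step_c`` from the previous retained
    value, are set missing.
    """
    out = series.copy()
    v = out["value"].to_numpy(float).copy()
    bad = (v < lower_c) | (v > upper_c)
    v[bad] = np.nan
    prev = np.nan
    for i in range(len(v)):
        if np.isnan(v[i]):
            continue
        if not np.isnan(prev) and abs(v[i] - prev) > max_step_c:
            v[i] = np.nan
        else:
            prev = v[i]
    out["value"] = v
    return out


_STATS = ("mean", "max", "min", "median", "sd")


def antecedent_temperature_stats(
    series: pd.DataFrame,
    visit: pd.Timestamp,
    windows_weeks: Sequence[float] = TEMPERATURE_WINDOWS_WEEKS,
) -> pd.DataFrame:
    """Antecedent temperature statistics over look-back windows before a visit.

    For each window ``w`` the mean, max, min, median and sample (n-1) SD are
    computed over non-missing values with timestamps in ``(visit - w, visit]``.
    The returned frame has one row per window with a ``completeness`` column
    (fraction of expected 15-minute records present) and an
    ``estimated_fraction`` column when the series carries a provenance flag.
    An empty window yields missing statistics.
    """
    visit = pd.Timestamp(visit)
    ts = pd.to_datetime(series["timestamp"])
    vals = series["value"].to_numpy(float)
    est = (
        series["estimated"].to_numpy(bool)
        if "estimated" in series.columns
        else np.zeros(len(series), bool)
    )
    rows = []
    for w in windows_weeks:
        lo = visit - pd.Timedelta(weeks=w)
        in_win = (ts > lo) & (ts <= visit)
        v = vals[in_win]
        ok = ~np.isnan(v)
        expected = pd.Timedelta(weeks=w) / pd.Timedelta(minutes=15)
        row: dict[str, object] = {
            "window_weeks": w,
            "n": int(ok.sum()),
            "completeness": float(ok.sum() / expected),
            "estimated_fraction": (
                float(est[in_win][ok].mean()) if ok.any() else np.nan
            ),
        }
        if ok.any():
            vv = v[ok]
            row.update(
                mean=float(np.mean(vv)),
                max=float(np.max(vv)),
                min=float(np.min(vv)),
                median=float(np.median(vv)),
                sd=float(np.std(vv, ddof=1)) if ok.sum() > 1 else 0.0,
            )
        else:
            row.update({s: np.nan for s in _STATS})
        rows.append(row)
    return pd.DataFrame(rows)
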