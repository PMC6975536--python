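"""qPCR relative abundance of *Sphaerotilus* and environmental screening.

The taxon-specific marker is *sthA*, a sheath-biosynthesis glycosyltransferase
gene.  The custom primers amplify four products distinguishable by melting
temperature (80, 86, 88, 90 deg C), of which only the 80 and 90 deg C
amplicons are on-target; raw genomic copy numbers are corrected by the
proportion of signal in those two classes.  The ratio of corrected *sthA*
copies to 16S rDNA copies measures *Sphaerotilus* abundance relative to the
total bacterial population, and is screened against environmental measures by
tie-corrected Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "ON_TARGET_TM_C",
    "QpcrSample",
    "correct_on_target",
    "relative_abundance",
    "spearman_screen",
    "AUTOTROPH_CLASSES",
]

#: Melting-temperature classes (deg C) whose amplicons are sthA-specific.
ON_TARGET_TM_C: tuple[int, ...] = (80, 90)

#: Biofilm classes whose volumes sum to the aggregated autotrophic volume.
AUTOTROPH_CLASSES: tuple[str, ...] = ("soft algae", "transition", "diatoms")

#: Tolerance on the sum of per-amplicon signal fractions.
_FRACTION_TOL = 1e-6


@dataclass(frozen=True)
class QpcrSample:
    """One biofilm sample's qPCR result.

    ``signal_fractions`` maps melting-temperature class (deg C) to the
    fraction of total qPCR signal in that amplicon; fractions must be
    non-negative and sum to one within tolerance.
    """

    site: str
    visit: pd.Timestamp
    stha_copies: float
    r16s_copies: float
    signal_fractions: Mapping[int, float]

    def __post_init__(self) -> None:
        if self.stha_copies < 0 or self.r16s_copies < 0:
            raise ValueError("copy numbers must be non-negative")
        fr = dict(self.signal_fractions)
        if any(f < 0 for f in fr.values()):
            raise ValueError("signal fractions must be non-negative")
        total = sum(fr.values())
        if abs(total - 1.0) > 1e-3:
            raise ValueError(
                f"signal fractions sum to {total:.4f}; expected 1 within tolerance"
            )


def correct_on_target(sample: QpcrSample) -> float:
    """sthA copies corrected for off-target amplification.

    Multiplies the raw copy number by the proportion of signal in the
    on-target melt classes (80 and 90 deg C), the minimal interpretation of
    an adjustment "for the proportion of on-target amplicons".  The corrected
    count never exceeds the raw count.
    """
    on = sum(sample.signal_fractions.get(tm, 0.0) for tm in ON_TARGET_TM_C)
    return sample.stha_copies * on


def relative_abundance(sample: QpcrSample) -> float:
    """Corrected sthA : 16S copy ratio (dimensionless relative abundance)."""
    if sample.r16s_copies <= 0:
        raise ValueError("relative abundance undefined: 16S copies must be > 0")
    return correct_on_target(sample) / sample.r16s_copies


def spearman_screen(
    ratios: Sequence[float] | np.ndarray,
    features: pd.DataFrame,
    *,
    min_pairs: int = 5,
) -> pd.DataFrame:
    """Tie-corrected Spearman correlation of the sthA:16S ratio per feature.

    Each column of ``features`` is screened against ``ratios`` over rows where
    both are present.  Returns a frame with columns ``feature``, ``rho``,
    ``n`` and ``p`` (t-approximation; reported for context, not used for any
    screening decision), sorted by descending |rho|.  Features with fewer
    than ``min_pairs`` complete pairs, or that are constant over them, get a
    missing rho.
    """
    r = np.asarray(ratios, dtype=float)
    if len(r) != len(features):
        raise ValueError("ratios and feature table must have equal length")
    rows = []
    for name in features.columns:
        x = features[name].to_numpy(float)
        ok = np.isfinite(r) & np.isfinite(x)
        n = int(ok.sum())
        if n < min_pairs or np.ptp(x[ok]) == 0 or np.ptp(r[ok]) == 0:
            rows.append({"feature": name, "rho": np.nan, "n": n, "p": np.nan})
            continue
        rho, p = scipy.stats.spearmanr(r[ok], x[ok])
        rows.append({"feature": name, "rho": float(rho), "n": n, "p": float(p)})
    out = pd.DataFrame(rows)
    return out.reindex(
        out["rho"].abs().sort_values(ascending=False, na_position="last").index
    ).reset_index(drop=True)
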