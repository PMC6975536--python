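"""Regression modelling: stepwise-BIC multiple OLS and log-log surrogates.

Two multiple linear models are central: a log10 heterotrophic-biofilm-volume
model and a dissolved-oxygen model, both selected from a candidate suite of
antecedent exposure, temperature, nutrient and site-indicator predictors by
stepwise ordinary least squares with forward and backward moves, minimizing
the Bayesian Information Criterion.  Simple log10-log10 regressions relate
COD to total deicer concentration and grab to flow-composite COD.

BIC convention used throughout (Gaussian profile likelihood, constants
dropped)::

    BIC = n * ln(RSS / n) + k * ln(n)

with ``k`` counting the intercept.  Additive constants do not affect the
selection ordering, but the convention is fixed so reported values are
comparable across fits.

Left-censored measurements enter every regression at their reporting level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "Predictor",
    "ModelSpec",
    "RegressionResult",
    "stepwise_bic",
    "fit_loglog",
    "substitute_censored",
    "ols_bic",
]

Transform = Literal["identity", "log10"]


@dataclass(frozen=True)
class Predictor:
    """A candidate model term: a data column with its transform."""

    name: str
    transform: Transform = "identity"
    indicator: bool = False

    @property
    def label(self) -> str:
        return f"log10({self.name})" if self.transform == "log10" else self.name


@dataclass(frozen=True)
class ModelSpec:
    """Response definition plus the candidate predictor suite."""

    response: str
    response_transform: Transform = "identity"
    candidates: Sequence[Predictor] = ()
    #: Pairwise |r| above which the later-listed candidate is dropped.
    collinearity_threshold: float = 0.98


@dataclass
class RegressionResult:
    """A fitted (selected) OLS model."""

    terms: list[str]
    coefficients: dict[str, float]
    intercept: float
    r2: float
    bic: float
    n: int
    residual_sd: float
    #: (move, term, BIC) records of the stepwise search.
    trace: list[tuple[str, str, float]] = field(default_factory=list)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        out = np.full(len(X), self.intercept, dtype=float)
        for t in self.terms:
            out += self.coefficients[t] * X[t].to_numpy(float)
        return out


def _apply_transform(x: np.ndarray, transform: Transform, name: str) -> np.ndarray:
    if transform == "log10":
        if np.any(x <= 0):
            bad = int(np.argmax(x <= 0))
            raise ValueError(
                f"non-positive value in {name!r} at row {bad}; cannot log10-transform"
            )
        return np.log10(x)
    return x


def ols_bic(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Least-squares fit of y on [1, X]; returns (beta, RSS, BIC)."""
    n = len(y)
    design = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    rss = float(resid @ resid)
    k = design.shape[1]
    # guard: a saturated/perfect fit has RSS ~ 0; clamp for the log
    bic = n * np.log(max(rss, 1e-300) / n) + k * np.log(n)
    return beta, rss, float(bic)


def _drop_collinear(
    cols: dict[str, np.ndarray], threshold: float
) -> dict[str, np.ndarray]:
    names = list(cols)
    keep = list(names)
    for i, a in enumerate(names):
        if a not in keep:
            continue
        for b in names[i + 1:]:
            if b not in keep:
                continue
            xa, xb = cols[a], cols[b]
            if np.std(xa) == 0 or np.std(xb) == 0:
                continue
            r = np.corrcoef(xa, xb)[0, 1]
            if abs(r) >= threshold:
                warnings.warn(
                    f"candidates {a!r} and {b!r} nearly collinear (|r|={abs(r):.3f}); "
                    f"dropping later-listed {b!r}",
                    stacklevel=3,
                )
                keep.remove(b)
    return {k: cols[k] for k in keep}


def stepwise_bic(data: pd.DataFrame, spec: ModelSpec) -> RegressionResult:
    """Stepwise OLS with forward and backward selection under BIC.

    Starting from the intercept-only model, the search alternates a forward
    step (add the single candidate whose inclusion most lowers BIC) with a
    backward sweep (repeatedly remove the term whose exclusion most lowers
    BIC) until no single add or drop improves the criterion.  Ties are broken
    toward the smaller model: an add must *strictly* lower BIC, a drop is
    taken when it does not raise it.  The returned model is therefore locally
    BIC-optimal in its one-term neighborhood.

    Rows with any missing value among the response and surviving candidates
    are dropped (complete-case analysis after censoring substitution, which
    is the caller's responsibility).  Nearly collinear candidate pairs are
    reduced deterministically to the earlier-listed member.
    """
    if data.empty:
        raise ValueError("empty data")
    used_cols = [spec.response] + [c.name for c in spec.candidates]
    frame = data[list(dict.fromkeys(used_cols))].dropna()
    if frame.empty:
        raise ValueError("no complete-case rows")
    n = len(frame)
    if n <= len(spec.candidates) + 2:
        raise ValueError(
            f"n={n} too small for {len(spec.candidates)} candidates"
        )
    y = _apply_transform(
        frame[spec.response].to_numpy(float), spec.response_transform, spec.response
    )
    cols = {
        c.label: _apply_transform(frame[c.name].to_numpy(float), c.transform, c.name)
        for c in spec.candidates
    }
    cols = _drop_collinear(cols, spec.collinearity_threshold)

    selected: list[str] = []
    _, _, current_bic = ols_bic(y, np.empty((n, 0)))
    trace: list[tuple[str, str, float]] = [("start", "(intercept)", current_bic)]

    def bic_for(terms: list[str]) -> float:
        X = np.column_stack([cols[t] for t in terms]) if terms else np.empty((n, 0))
        return ols_bic(y, X)[2]

    improved = True
    while improved:
        improved = False
        # forward: best strict improvement
        remaining = [t for t in cols if t not in selected]
        if remaining:
            adds = [(bic_for(selected + [t]), t) for t in remaining]
            best_bic, best_t = min(adds)
            if best_bic < current_bic:
                selected.append(best_t)
                current_bic = best_bic
                trace.append(("add", best_t, current_bic))
                improved = True
        # backward sweep: drop while it does not raise BIC
        dropping = True
        while dropping and selected:
            drops = [
                (bic_for([t for t in selected if t != d]), d) for d in selected
            ]
            best_bic, best_d = min(drops)
            if best_bic <= current_bic:
                selected.remove(best_d)
                current_bic = best_bic
                trace.append(("drop", best_d, current_bic))
                improved = True
            else:
                dropping = False

    X = np.column_stack([cols[t] for t in selected]) if selected else np.empty((n, 0))
    beta, rss, bic = ols_bic(y, X)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    dof = max(n - len(selected) - 1, 1)
    return RegressionResult(
        terms=selected,
        coefficients={t: float(b) for t, b in zip(selected, beta[1:])},
        intercept=float(beta[0]),
        r2=r2,
        bic=bic,
        n=n,
        residual_sd=float(np.sqrt(rss / dof)),
        trace=trace,
    )


def fit_loglog(
    x: Sequence[float] | np.ndarray, y: Sequence[float] | np.ndarray
) -> tuple[float, float, float]:
    """OLS of log10(y) on log10(x); returns (slope, intercept, R2).

    Both series must be strictly positive (apply censoring substitution
    first); a non-positive value raises with the offending record index.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    lx = _apply_transform(x, "log10", "x")
    ly = _apply_transform(y, "log10", "y")
    res = scipy.stats.linregress(lx, ly)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def substitute_censored(
    values: Sequence[float] | np.ndarray,
    censored: Sequence[bool] | np.ndarray,
    reporting_levels: Sequence[float] | np.ndarray | float,
) -> np.ndarray:
    """Replace left-censored entries by their reporting level.

    ``reporting_levels`` may be a scalar applied to all censored entries or a
    per-record sequence; a censored record whose reporting level is missing
    raises.  Uncensored values pass through unchanged.
    """
    v = np.array(values, dtype=float)
    c = np.asarray(censored, dtype=bool)
    if v.shape != c.shape:
        raise ValueError("values and censor flags must have equal length")
    rl = np.broadcast_to(np.asarray(reporting_levels, dtype=float), v.shape)
    if np.any(c & ~np.isfinite(rl)):
        bad = int(np.argmax(c & ~np.isfinite(rl)))
        raise ValueError(f"censored record {bad} lacks a reporting level")
    v[c] = rl[c]
    return v
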