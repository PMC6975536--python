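"""Synthetic two-season study generator with known ground truth.

Generates every input the analysis pipeline consumes — gage hydrographs,
15-minute temperature records with sensor gaps, weekly flow-composite COD
with paired total-deicer samples, grab water chemistry, biofilm survey
points, dissolved-oxygen observations, and qPCR records — from a
:class:`~deicer_biofilm.config.ScenarioConfig` whose coefficient sets default
to the study's fitted relations.  The random seed fully determines all
output, and every generated quantity is recoverable by the downstream
pipeline stages, which is what the parameter-recovery test suite exercises.

Residual noise everywhere is calibrated from a target coefficient of
determination given the realized spread of the signal
(:func:`~deicer_biofilm.config.noise_sd_for_r2`), since the study reports
R-squared values rather than noise magnitudes.  Rank dependence of the
sthA:16S ratio on biofilm volume and dissolved oxygen is produced by a
Gaussian copula whose Pearson parameters come from the target Spearman
correlations via the sine transform ``r = 2 sin(pi * rho / 6)``.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .config import AffineRelation, ScenarioConfig, noise_sd_for_r2

logger = logging.getLogger(__name__)

__all__ = [
    "stage_rng",
    "generate_hydrographs",
    "generate_temperature",
    "simulate_temperature_pair",
    "generate_cod_and_deicer",
    "generate_surveys_do_qpcr",
    "visit_schedule",
    "simulate_loglog_pairs",
    "simulate_biofilm_dataset",
    "simulate_do_dataset",
    "rank_coupled_ratio",
    "spearman_to_pearson",
]

# fixed stage keys so each generator stage draws an independent stream
_STAGE_KEYS = {
    "hydrograph": 11,
    "temperature": 23,
    "cod": 37,
    "survey": 53,
    "do": 67,
    "qpcr": 79,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from the scenario seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, _STAGE_KEYS[stage]]))


def spearman_to_pearson(rho_s: float) -> float:
    """Pearson copula parameter reproducing a target Spearman rho.

    For a bivariate Gaussian copula, ``rho_s = (6/pi) * arcsin(r/2)``; the
    inverse is the sine transform ``r = 2 sin(pi * rho_s / 6)``.
    """
    if not -1.0 <= rho_s <= 1.0:
        raise ValueError("Spearman rho must lie in [-1, 1]")
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


# ---------------------------------------------------------------------------
# hydrographs


def generate_hydrographs(config: ScenarioConfig) -> dict[str, pd.DataFrame]:
    """Baseflow-plus-storm-pulse flow series at each gage.

    Storm timing is shared between the gages (the watersheds overlap) while
    baseflow and pulse amplitude scale with drainage area.  Returns
    ``{gage_name: DataFrame(timestamp, flow)}`` with strictly positive flow;
    gage names are ``"<site>-gage"`` for each gaged site.
    """
    hc = config.hydrograph
    if hc.baseflow <= 0:
        raise ValueError("baseflow must be positive")
    rng = stage_rng(config.seed, "hydrograph")
    t = pd.date_range(
        config.start, config.end, freq=pd.Timedelta(hours=hc.time_step_h)
    )
    hours = (t - t[0]) / pd.Timedelta(hours=1)
    hours = hours.to_numpy(float)
    years = hours[-1] / (365.25 * 24)
    n_events = int(round(hc.events_per_year * years))
    event_starts = np.sort(rng.uniform(0, hours[-1], size=n_events))
    event_scales = rng.lognormal(mean=0.0, sigma=0.5, size=n_events)

    da_ref = max(s.drainage_area_km2 for s in config.gaged_sites)
    out: dict[str, pd.DataFrame] = {}
    for site in config.gaged_sites:
        ratio = site.drainage_area_km2 / da_ref
        flow = np.full(len(hours), hc.baseflow * ratio)
        for t0, s in zip(event_starts, event_scales):
            dt = hours - t0
            mask = dt >= 0
            flow[mask] += (
                hc.event_amplitude * ratio * s * np.exp(-dt[mask] / hc.event_duration_h)
            )
        out[f"{site.name}-gage"] = pd.DataFrame({"timestamp": t, "flow": flow})
    return out


# ---------------------------------------------------------------------------
# temperature


def _seasonal_temperature(
    timestamps: pd.DatetimeIndex, config: ScenarioConfig, rng: np.random.Generator
) -> np.ndarray:
    """Seasonal + diurnal water temperature signal with weather noise."""
    tc = config.temperature
    doy = timestamps.dayofyear.to_numpy(float)
    hour = timestamps.hour.to_numpy(float) + timestamps.minute.to_numpy(float) / 60
    seasonal = tc.annual_mean_c + tc.annual_amplitude_c * np.cos(
        2 * np.pi * (doy - 207) / 365.25
    )
    diurnal = tc.diurnal_amplitude_c * np.cos(2 * np.pi * (hour - 16) / 24)
    # slow synoptic wander: smoothed white noise
    raw = rng.normal(0.0, 1.0, size=len(timestamps))
    kernel = np.exp(-np.arange(0, 4 * 96) / 96.0)
    kernel /= kernel.sum()
    synoptic = 1.5 * np.convolve(raw, kernel, mode="same")
    return np.maximum(seasonal + diurnal + synoptic, 0.0)


def _mask_gaps(
    values: np.ndarray, gap_fraction: float, rng: np.random.Generator,
    block: int = 96,
) -> np.ndarray:
    """Mask ~``gap_fraction`` of values missing in contiguous blocks."""
    out = values.copy()
    if gap_fraction <= 0:
        return out
    n = len(values)
    n_blocks = max(int(round(gap_fraction * n / block)), 1)
    starts = rng.integers(0, max(n - block, 1), size=n_blocks)
    for s in starts:
        out[s : s + block] = np.nan
    return out


def generate_temperature(config: ScenarioConfig) -> dict[str, pd.DataFrame]:
    """15-minute temperature at every site, with gaps at the ungaged sites.

    Gaged records (``<site>-gage``) are complete.  Each ungaged site is an
    affine image of its paired gage record plus Gaussian noise whose SD is
    calibrated so the population R-squared of the pair equals the configured
    target; a configured fraction of its values is masked as sensor gaps.
    """
    rng = stage_rng(config.seed, "temperature")
    t = pd.date_range(config.start, config.end, freq="15min")
    gaged_series: dict[str, np.ndarray] = {}
    out: dict[str, pd.DataFrame] = {}
    for site in config.gaged_sites:
        vals = _seasonal_temperature(t, config, rng)
        gaged_series[f"{site.name}-gage"] = vals
        out[f"{site.name}-gage"] = pd.DataFrame({"timestamp": t, "value": vals})
    for key, rel in config.temperature_relations.items():
        ungaged_name, gage_name = key.split("~")
        if gage_name not in gaged_series:
            raise ValueError(f"pair relation {key!r} references unknown gage")
        g = gaged_series[gage_name]
        signal_sd = abs(rel.slope) * float(np.std(g))
        sd = noise_sd_for_r2(signal_sd, rel.r2)
        vals = rel.slope * g + rel.intercept + rng.normal(0.0, sd, size=len(g))
        vals = _mask_gaps(vals, config.temperature.gap_fraction, rng)
        out[ungaged_name] = pd.DataFrame({"timestamp": t, "value": vals})
    return out


def simulate_temperature_pair(
    relation: AffineRelation,
    n: int,
    rng: np.random.Generator,
    config: ScenarioConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Contemporaneous (gaged, ungaged) 15-minute pairs from one relation.

    A fast path for recovery experiments: ``n`` consecutive 15-minute steps
    of the seasonal gage signal, with the ungaged series generated from the
    affine relation and R-squared-calibrated noise.
    """
    config = config or ScenarioConfig()
    t = pd.date_range(config.start, periods=n, freq="15min")
    gaged = _seasonal_temperature(t, config, rng)
    signal_sd = abs(relation.slope) * float(np.std(gaged))
    sd = noise_sd_for_r2(signal_sd, relation.r2)
    ungaged = relation.slope * gaged + relation.intercept + rng.normal(0, sd, n)
    return gaged, ungaged


# ---------------------------------------------------------------------------
# COD composites, deicer pairs, grab chemistry


def visit_schedule(config: ScenarioConfig) -> pd.DataFrame:
    """Site-visit calendar: monthly visits through both deicing seasons.

    Approximately monthly visits (day 15) December-June of each season plus
    a November pre-deicing visit in the second season and extra mid-spring
    visits (day 1 of May), at every site.
    """
    months: list[pd.Timestamp] = []
    cur = pd.Timestamp(config.start).normalize().replace(day=1)
    end = pd.Timestamp(config.end)
    while cur <= end:
        # deicing-season months plus June and a November pre-deicing trip
        if cur.month in config.deicer_months or cur.month in (6, 11):
            months.append(cur)
        cur = cur + pd.DateOffset(months=1)
    visits: list[pd.Timestamp] = []
    for m in months:
        visits.append(m + pd.Timedelta(days=14, hours=10))
        if m.month == 5:  # twice-monthly in spring
            visits.append(m + pd.Timedelta(hours=10))
    visits = sorted(v for v in visits if pd.Timestamp(config.start) <= v <= end)
    rows = [
        {"site": s.name, "timestamp": v} for v in visits for s in config.sites
    ]
    return pd.DataFrame(rows)


def generate_cod_and_deicer(
    config: ScenarioConfig, hydrographs: dict[str, pd.DataFrame] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Weekly composites at the upstream gage, deicer pairs, and grab COD.

    Returns ``(composites, deicer_pairs, grabs)``:

    * ``composites`` — weekly flow-composite COD at the gage nearest the
      deicing operations, with event volume integrated from its hydrograph
      and seasonal lognormal concentrations (elevated December-May);
    * ``deicer_pairs`` — an intermittent subset with total-deicer
      concentration generated from the configured log10-log10 relation;
    * ``grabs`` — per site-visit grab chemistry (COD, nutrients, SC, pH) with
      grab COD tied to the nearest composite through the grab/composite
      relation and attenuated with distance downstream; upstream grabs sit
      at background.  Values below the reporting level carry a censor flag
      and the reporting level as working value.
    """
    from .hydro import event_volume_from_flow

    cc = config.cod
    rng = stage_rng(config.seed, "cod")
    hydrographs = hydrographs or generate_hydrographs(config)
    source_gage = f"{config.gaged_sites[0].name}-gage"
    flow = hydrographs[source_gage]

    starts = pd.date_range(config.start, config.end - pd.Timedelta(weeks=1), freq="7D")
    comp_rows = []
    for s in starts:
        e = s + pd.Timedelta(days=7)
        mid = s + pd.Timedelta(days=3, hours=12)
        gm = cc.deicer_season_gm if mid.month in config.deicer_months else cc.off_season_gm
        conc = 10 ** rng.normal(np.log10(gm), cc.log10_sd)
        censored = conc < cc.reporting_level_mg_l
        comp_rows.append(
            {
                "site": source_gage,
                "start": s,
                "end": e,
                "volume": event_volume_from_flow(flow, s, e),
                "concentration": max(conc, cc.reporting_level_mg_l) if censored else conc,
                "censored": censored,
                "reporting_level": cc.reporting_level_mg_l,
            }
        )
    composites = pd.DataFrame(comp_rows)

    # intermittent paired total-deicer samples (log10-log10 relation)
    rel = config.cod_deicer_relation
    pair_idx = np.arange(0, len(composites), 6)
    log_cod = np.log10(composites.loc[pair_idx, "concentration"].to_numpy(float))
    sd = noise_sd_for_r2(abs(rel.slope) * float(np.std(log_cod)), rel.r2)
    log_deicer = rel.slope * log_cod + rel.intercept + rng.normal(0, sd, len(log_cod))
    deicer_pairs = pd.DataFrame(
        {
            "start": composites.loc[pair_idx, "start"].to_numpy(),
            "cod_mg_l": composites.loc[pair_idx, "concentration"].to_numpy(float),
            "total_deicer_mg_l": 10**log_deicer,
        }
    )

    # grab chemistry at each site visit
    grel = config.grab_composite_relation
    visits = visit_schedule(config)
    mids = composites["start"] + (composites["end"] - composites["start"]) / 2
    log_comp_all = np.log10(composites["concentration"].to_numpy(float))
    gsd = noise_sd_for_r2(abs(grel.slope) * float(np.std(log_comp_all)), grel.r2)
    max_rank = max(s.downstream_rank for s in config.sites)
    grab_rows = []
    for _, v in visits.iterrows():
        site = config.site(v["site"])
        when = pd.Timestamp(v["timestamp"])
        nearest = int((mids - when).abs().idxmin())
        log_comp = log_comp_all[nearest]
        if site.downstream_rank == 0:
            cod = 10 ** rng.normal(np.log10(cc.upstream_gm), cc.log10_sd)
        else:
            # dilution with distance downstream from the outfall
            atten = 0.12 * (site.downstream_rank - 1) / max(max_rank - 1, 1)
            log_grab = grel.slope * log_comp + grel.intercept - atten
            cod = 10 ** (log_grab + rng.normal(0, gsd))
        censored = cod < cc.reporting_level_mg_l
        winter = when.month in config.deicer_months
        no23 = 10 ** rng.normal(np.log10(0.6 if winter else 0.4), 0.25)
        grab_rows.append(
            {
                "site": site.name,
                "timestamp": when,
                "cod_mg_l": cc.reporting_level_mg_l if censored else cod,
                "cod_censored": censored,
                "cod_reporting_level": cc.reporting_level_mg_l,
                "no23_mg_l": no23,
                "tkn_mg_l": 10 ** rng.normal(np.log10(0.9), 0.2),
                "tp_mg_l": 10 ** rng.normal(np.log10(0.08), 0.25),
                "sc_us_cm": 10 ** rng.normal(np.log10(900 if winter else 600), 0.12),
                "ph": rng.normal(7.8, 0.2),
            }
        )
    grabs = pd.DataFrame(grab_rows)
    return composites, deicer_pairs, grabs


# ---------------------------------------------------------------------------
# surveys, dissolved oxygen, qPCR


#: Smallest heterotroph volume (L) a 50-point survey records; thinner or
#: patchier growth is field-recorded as absent (F = 0), which downstream
#: becomes a zero volume subject to the half-minimum substitution rule.
SURVEY_DETECTION_FLOOR_L = 0.005


def _points_for_volume(
    volume_l: float, n_points: int, rng: np.random.Generator
) -> tuple[int, float]:
    """Choose a (point count, per-point thickness) pair realizing a volume.

    With all class points sharing one thickness ``T`` (mm) the standardized
    volume is ``count * T`` liters, so ``T = V / count``; thickness is
    recorded to 0.01 mm, bounding the aggregation error by 0.005 mm x count.
    Volumes below the survey detection floor yield no points at all.
    """
    if volume_l < SURVEY_DETECTION_FLOOR_L:
        return 0, 0.0
    count = int(np.clip(round(float(np.sqrt(volume_l) * 2)), 1, n_points - 1))
    thickness = max(round(volume_l / count, 2), 0.01)
    return count, thickness


def generate_surveys_do_qpcr(
    config: ScenarioConfig, antecedent: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Survey points, DO observations, qPCR records, and a truth sidecar.

    ``antecedent`` must hold one row per planned site-visit with columns
    ``site``, ``timestamp``, ``cod_fwmc_2wk``, ``cod_fwmc_8wk`` and
    ``temp_max_2wk``.  Downstream visits missing exposure features are
    skipped with a logged warning; the upstream reference site (downstream
    rank 0) legitimately has no composite-event exposure and is generated at
    the minimal-biofilm floor instead.

    True heterotroph volume follows the configured log-linear model with
    site effects and lognormal noise; survey points are constructed so the
    standard volume aggregation returns the true volume up to the 0.1 mm
    thickness discretization.  DO follows its linear model with Gaussian
    noise.  The sthA:16S ratio is rank-coupled to heterotroph volume
    (positive) and DO (negative) through a Gaussian copula.

    Returns ``(survey_points, do_obs, qpcr, truth)``.
    """
    bm = config.biofilm_model
    dm = config.do_model
    rng_s = stage_rng(config.seed, "survey")
    rng_d = stage_rng(config.seed, "do")
    rng_q = stage_rng(config.seed, "qpcr")
    n_points = config.transects_per_reach * config.points_per_transect

    rows = []
    for _, r in antecedent.iterrows():
        site = config.site(r["site"])
        cod2, cod8 = r.get("cod_fwmc_2wk"), r.get("cod_fwmc_8wk")
        tmax2 = r.get("temp_max_2wk")
        upstream = site.downstream_rank == 0
        if (pd.isna(cod2) or pd.isna(cod8) or pd.isna(tmax2)) and not upstream:
            logger.warning(
                "skipping visit %s @ %s: antecedent features missing",
                r["site"], r["timestamp"],
            )
            continue
        rows.append(
            {
                "site": site.name,
                "timestamp": pd.Timestamp(r["timestamp"]),
                "upstream": upstream,
                "cod_fwmc_2wk": np.nan if upstream else float(cod2),
                "cod_fwmc_8wk": np.nan if upstream else float(cod8),
                "temp_max_2wk": float(tmax2) if pd.notna(tmax2) else np.nan,
            }
        )
    if not rows:
        raise ValueError("no usable site-visits in the antecedent table")
    table = pd.DataFrame(rows)

    # --- true heterotroph volumes (log-linear model, noise from target R2)
    down = ~table["upstream"]
    linpred = np.full(len(table), np.nan)
    linpred[down.to_numpy()] = (
        bm.cod_slope * np.log10(table.loc[down, "cod_fwmc_2wk"].to_numpy(float))
        + table.loc[down, "site"].map(lambda s: bm.site_effects.get(s, 0.0)).to_numpy(float)
        + bm.intercept
    )
    lp = linpred[down.to_numpy()]
    sd_b = noise_sd_for_r2(float(np.std(lp)), bm.r2) if len(lp) > 1 else 0.0
    log_v = np.where(down, linpred + rng_s.normal(0, sd_b, len(table)), np.nan)
    true_v = np.where(down, 10**log_v, 0.0)  # upstream at the zero floor
    table["true_heterotroph_volume_l"] = true_v

    # --- survey points realizing the true volumes
    point_rows = []
    for i, r in table.iterrows():
        v = float(r["true_heterotroph_volume_l"])
        h_count, h_thick = _points_for_volume(v, n_points, rng_s)
        # autotrophic classes: modest spring growth, stronger upstream
        month = pd.Timestamp(r["timestamp"]).month
        spring = 1.0 if month in (3, 4, 5, 6) else 0.3
        base = 3.0 if r["upstream"] else 1.0
        auto_counts = {}
        budget = n_points - h_count
        for cls, share in (("soft algae", 0.5), ("diatoms", 0.3), ("transition", 0.2)):
            lam = base * spring * 4 * share
            auto_counts[cls] = min(int(rng_s.poisson(lam)), budget)
            budget -= auto_counts[cls]
        labels = (
            ["heterotrophs"] * h_count
            + sum([[c] * k for c, k in auto_counts.items()], [])
        )
        labels += ["none"] * (n_points - len(labels))
        order = rng_s.permutation(n_points)
        for j, pos in enumerate(order):
            cls = labels[pos]
            if cls == "heterotrophs":
                thick = h_thick
            elif cls == "none":
                thick = None
            else:
                thick = round(float(rng_s.lognormal(0.0, 0.4)), 2) or 0.01
            point_rows.append(
                {
                    "site": r["site"],
                    "timestamp": r["timestamp"],
                    "transect": j // config.points_per_transect + 1,
                    "point": j % config.points_per_transect + 1,
                    "biofilm_class": cls,
                    "thickness_mm": thick,
                }
            )
    survey_points = pd.DataFrame(point_rows)

    # --- dissolved oxygen from its linear model
    from .survey import substitute_zeros_for_log

    v_sub, _ = substitute_zeros_for_log(table["true_heterotroph_volume_l"])
    log_v_sub = np.log10(v_sub)
    cod8 = table["cod_fwmc_8wk"].to_numpy(float)
    cod8 = np.where(np.isnan(cod8), config.cod.upstream_gm, cod8)
    tmax = table["temp_max_2wk"].to_numpy(float)
    tmax = np.where(np.isnan(tmax), 12.0, tmax)
    do_lin = (
        dm.volume_slope * log_v_sub
        + dm.temp_slope * tmax
        + dm.cod_slope * np.log10(cod8)
        + dm.intercept
    )
    sd_do = noise_sd_for_r2(float(np.std(do_lin)), dm.r2)
    do_vals = np.maximum(do_lin + rng_d.normal(0, sd_do, len(table)), 0.2)
    do_obs = pd.DataFrame(
        {"site": table["site"], "timestamp": table["timestamp"], "do_mg_l": do_vals}
    )
    table["do_mg_l"] = do_vals

    # --- qPCR rank-coupled ratio
    ratio = rank_coupled_ratio(
        table["true_heterotroph_volume_l"].to_numpy(float),
        do_vals,
        config.qpcr.rho_volume,
        config.qpcr.rho_do,
        rng_q,
    )
    qc = config.qpcr
    a = qc.on_target_mean * qc.on_target_concentration
    b = (1 - qc.on_target_mean) * qc.on_target_concentration
    on_frac = rng_q.beta(a, b, size=len(table))
    r16s = 10 ** rng_q.normal(8.0, 0.4, size=len(table))
    corrected = ratio * r16s
    raw_stha = corrected / on_frac
    qpcr = pd.DataFrame(
        {
            "site": table["site"],
            "timestamp": table["timestamp"],
            "stha_copies": raw_stha,
            "r16s_copies": r16s,
            "frac_tm80": on_frac * 0.6,
            "frac_tm90": on_frac * 0.4,
            "frac_tm86": (1 - on_frac) * 0.55,
            "frac_tm88": (1 - on_frac) * 0.45,
        }
    )

    truth = table[
        [
            "site",
            "timestamp",
            "true_heterotroph_volume_l",
            "do_mg_l",
            "cod_fwmc_2wk",
            "cod_fwmc_8wk",
            "temp_max_2wk",
        ]
    ].copy()
    truth["true_ratio"] = ratio
    return survey_points, do_obs, qpcr, truth


def rank_coupled_ratio(
    volume: np.ndarray,
    do: np.ndarray,
    rho_volume: float,
    rho_do: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """sthA:16S ratio with target Spearman coupling to volume and DO.

    Both variables are mapped to normal scores of their ranks; a latent
    normal for the ratio is constructed as a linear combination of the two
    scores plus independent noise, with weights solved so its Pearson
    correlation with each score equals the sine-transformed target
    (``r = 2 sin(pi rho / 6)``), given the realized correlation between the
    scores.  The ratio is a lognormal monotone map of the latent normal, so
    rank correlations carry through.  Raises when the requested pair of
    couplings is infeasible for the realized volume-DO dependence.
    """
    n = len(volume)
    if n != len(do):
        raise ValueError("volume and DO must have equal length")

    def scores(x: np.ndarray) -> np.ndarray:
        ranks = scipy.stats.rankdata(x, method="average")
        return scipy.stats.norm.ppf(ranks / (n + 1))

    z_v, z_d = scores(volume), scores(do)
    r_v = spearman_to_pearson(rho_volume)
    r_d = spearman_to_pearson(rho_do)
    if n > 2 and np.std(z_v) > 0 and np.std(z_d) > 0:
        rho_vd = float(np.corrcoef(z_v, z_d)[0, 1])
    else:
        rho_vd = 0.0
    # solve [[1, rho], [rho, 1]] @ [a, b] = [r_v, r_d]
    det = 1.0 - rho_vd**2
    if det <= 1e-12:
        raise ValueError("volume and DO ranks are collinear; coupling infeasible")
    a = (r_v - rho_vd * r_d) / det
    b = (r_d - rho_vd * r_v) / det
    var_sys = a**2 + b**2 + 2 * a * b * rho_vd
    if var_sys > 1.0 + 1e-9:
        raise ValueError(
            f"requested couplings ({rho_volume}, {rho_do}) infeasible given the "
            f"realized volume-DO rank correlation {rho_vd:.3f}"
        )
    sv = z_v / max(np.std(z_v), 1e-12)
    sd_ = z_d / max(np.std(z_d), 1e-12)
    eps = rng.normal(0.0, 1.0, size=n)
    z_r = a * sv + b * sd_ + np.sqrt(max(1.0 - var_sys, 0.0)) * eps
    return 10 ** (-3.0 + 0.8 * z_r)


# ---------------------------------------------------------------------------
# fast recovery-experiment paths


def simulate_loglog_pairs(
    relation: AffineRelation,
    n: int,
    rng: np.random.Generator,
    *,
    log10_x_mean: float = np.log10(60.0),
    log10_x_sd: float = 0.45,
) -> tuple[np.ndarray, np.ndarray]:
    """(x, y) pairs with ``log10 y = slope log10 x + intercept + noise``.

    Noise SD is calibrated from the relation's target R-squared and the
    realized spread of the predictor.
    """
    log_x = rng.normal(log10_x_mean, log10_x_sd, size=n)
    sd = noise_sd_for_r2(abs(relation.slope) * float(np.std(log_x)), relation.r2)
    log_y = relation.slope * log_x + relation.intercept + rng.normal(0, sd, n)
    return 10**log_x, 10**log_y


def _correlated_windows(
    base_log: np.ndarray, rng: np.random.Generator, corr: float = 0.75
) -> np.ndarray:
    """A companion antecedent window, rank-correlated with the base window."""
    sd = float(np.std(base_log))
    mix = corr * (base_log - base_log.mean()) + np.sqrt(1 - corr**2) * rng.normal(
        0, sd, len(base_log)
    )
    return base_log.mean() + mix


def simulate_biofilm_dataset(
    config: ScenarioConfig, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Site-visit table drawn from the configured biofilm-volume model.

    ``n`` visits are assigned round-robin to the downstream sites; the
    2-week flow-weighted COD predictor is lognormal, companion windows (4
    and 8 weeks) and temperature statistics are correlated distractors, and
    log10 volume follows the configured model with noise calibrated to its
    target R-squared.  Columns are ready for the stepwise-regression stage.
    """
    bm = config.biofilm_model
    sites = [s.name for s in config.sites if s.downstream_rank > 0]
    site_col = np.array([sites[i % len(sites)] for i in range(n)])
    log_cod2 = rng.normal(np.log10(60.0), 0.45, size=n)
    log_cod4 = _correlated_windows(log_cod2, rng)
    log_cod8 = _correlated_windows(log_cod2, rng)
    temp_max2 = np.clip(rng.normal(11.0, 6.0, size=n), 0.1, None)
    temp_mean2 = np.clip(temp_max2 - np.abs(rng.normal(2.0, 1.0, n)), 0.1, None)
    tp = 10 ** rng.normal(np.log10(0.08), 0.25, size=n)
    linpred = (
        bm.cod_slope * log_cod2
        + np.array([bm.site_effects.get(s, 0.0) for s in site_col])
        + bm.intercept
    )
    sd = noise_sd_for_r2(float(np.std(linpred)), bm.r2)
    log_v = linpred + rng.normal(0, sd, n)
    frame = pd.DataFrame(
        {
            "site": site_col,
            "volume_l": 10**log_v,
            "cod_fwmc_2wk": 10**log_cod2,
            "cod_fwmc_4wk": 10**log_cod4,
            "cod_fwmc_8wk": 10**log_cod8,
            "temp_max_2wk": temp_max2,
            "temp_mean_2wk": temp_mean2,
            "tp_mg_l": tp,
        }
    )
    for s in sites:
        frame[f"is_{s}"] = (site_col == s).astype(float)
    return frame


def simulate_do_dataset(
    config: ScenarioConfig, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Site-visit table drawn from the configured dissolved-oxygen model.

    Builds on :func:`simulate_biofilm_dataset` (so biofilm volume carries its
    own model structure) and adds DO from the configured linear model with
    R-squared-calibrated Gaussian noise.
    """
    dm = config.do_model
    frame = simulate_biofilm_dataset(config, n, rng)
    linpred = (
        dm.volume_slope * np.log10(frame["volume_l"].to_numpy(float))
        + dm.temp_slope * frame["temp_max_2wk"].to_numpy(float)
        + dm.cod_slope * np.log10(frame["cod_fwmc_8wk"].to_numpy(float))
        + dm.intercept
    )
    sd = noise_sd_for_r2(float(np.std(linpred)), dm.r2)
    frame["do_mg_l"] = linpred + rng.normal(0, sd, n)
    return frame
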