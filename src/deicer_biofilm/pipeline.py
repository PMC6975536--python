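"""Pipeline orchestration: generate -> exposure -> temperature -> survey ->
merge -> model -> correlate, over documented CSV schemas.

Each stage reads and writes only CSV files in the run directory, so stages
are independently runnable and testable.  Timestamps are ISO-8601 in a fixed
local standard time (no DST); censored concentrations travel as a
``(value, censored, reporting_level)`` column triple.  A run manifest (JSON)
records the configuration hash, seed, and per-stage outputs with row counts;
rerunning with the same configuration and seed reproduces byte-identical
stage outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import ScenarioConfig
from .hydro import (
    CompositeEvent,
    antecedent_features,
    align_event_to_site,
    event_volume_from_flow,
    propagate_concentration,
    scale_by_drainage_area,
)
from .models import ModelSpec, Predictor, RegressionResult, stepwise_bic
from .qpcr import AUTOTROPH_CLASSES, QpcrSample, relative_abundance, spearman_screen
from .survey import CLASSES, SurveyPoint, compute_visit_volumes, substitute_zeros_for_log
from .synthetic import (
    generate_cod_and_deicer,
    generate_hydrographs,
    generate_surveys_do_qpcr,
    generate_temperature,
    visit_schedule,
)
from .temperature import antecedent_temperature_stats, fill_gaps, fit_pair_relation

logger = logging.getLogger(__name__)

__all__ = [
    "run_pipeline",
    "run_generate",
    "run_exposure",
    "run_temperature",
    "run_survey",
    "run_merge",
    "run_model",
    "run_correlate",
    "merge_features",
    "events_from_frame",
]

_TEMP_STATS = ("mean", "max", "min", "median", "sd")


def _write(df: pd.DataFrame, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def _read(path: Path, parse: tuple[str, ...] = ()) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"required stage input missing: {path}")
    df = pd.read_csv(path)
    for col in parse:
        if col in df.columns:
            df[col] = pd.to_datetime(df[col])
    return df


def events_from_frame(frame: pd.DataFrame) -> list[CompositeEvent]:
    """Composite events from their CSV representation."""
    out = []
    for _, r in frame.iterrows():
        out.append(
            CompositeEvent(
                start=pd.Timestamp(r["start"]),
                end=pd.Timestamp(r["end"]),
                site=str(r["site"]),
                volume=float(r["volume"]),
                concentration=float(r["concentration"]),
                censored=bool(r["censored"]),
                reporting_level=(
                    float(r["reporting_level"])
                    if pd.notna(r.get("reporting_level"))
                    else None
                ),
            )
        )
    return out


# ---------------------------------------------------------------------------
# stage: generate


def run_generate(config: ScenarioConfig, outdir: Path) -> dict[str, Path]:
    """Generate every synthetic input CSV plus the ground-truth sidecar.

    Survey, DO, and qPCR generation needs antecedent exposure and temperature
    features, so this stage computes them internally (the downstream
    exposure/temperature stages recompute the same features from the written
    CSVs; recovery tests compare the two paths).
    """
    outdir = Path(outdir)
    hydro = generate_hydrographs(config)
    temps = generate_temperature(config)
    composites, deicer, grabs = generate_cod_and_deicer(config, hydro)
    visits = visit_schedule(config)

    paths: dict[str, Path] = {}
    for name, df in hydro.items():
        paths[f"flow_{name}"] = _write(df, outdir / f"flow_{name}.csv")
    for name, df in temps.items():
        paths[f"temperature_{name}"] = _write(df, outdir / f"temperature_{name}.csv")
    paths["composites"] = _write(composites, outdir / "composites.csv")
    paths["deicer_pairs"] = _write(deicer, outdir / "deicer_pairs.csv")
    paths["grabs"] = _write(grabs, outdir / "grabs.csv")
    paths["visits"] = _write(visits, outdir / "visits.csv")

    site_events = _propagate_events(config, composites, hydro)
    ante = _antecedent_wide(config, site_events, visits)
    tstats = _temperature_wide(config, temps, visits)
    features = ante.merge(tstats, on=["site", "timestamp"], how="outer")
    points, do_obs, qpcr, truth = generate_surveys_do_qpcr(config, features)
    paths["survey_points"] = _write(points, outdir / "survey_points.csv")
    paths["do_observations"] = _write(do_obs, outdir / "do_observations.csv")
    paths["qpcr"] = _write(qpcr, outdir / "qpcr.csv")
    paths["truth"] = _write(truth, outdir / "truth_sidecar.csv")
    return paths


# ---------------------------------------------------------------------------
# stage: exposure


def _propagate_events(
    config: ScenarioConfig,
    composites: pd.DataFrame,
    hydro: dict[str, pd.DataFrame],
) -> dict[str, list[CompositeEvent]]:
    """Composite events at each downstream site from the source-gage events.

    The source events are shifted by the gage-to-gage travel time (evaluated
    at the downstream-gage flow nearest each unshifted midpoint), downstream
    event volumes are integrated from the gage records (drainage-area scaled
    at the ungaged site), and concentrations follow by load conservation.
    Shift-then-window order throughout.
    """
    gages = [f"{s.name}-gage" for s in config.gaged_sites]
    up_gage, down_gage = gages[0], gages[-1]
    up_site = config.gaged_sites[0]
    down_site = config.gaged_sites[-1]
    down_flow = hydro[down_gage]
    source = events_from_frame(composites)

    sites_down = sorted(
        (s for s in config.sites if s.downstream_rank > 0),
        key=lambda s: s.downstream_rank,
    )
    out: dict[str, list[CompositeEvent]] = {s.name: [] for s in sites_down}
    for ev in source:
        out[up_site.name].append(
            CompositeEvent(
                start=ev.start, end=ev.end, site=up_site.name, volume=ev.volume,
                concentration=ev.working_concentration, censored=ev.censored,
                reporting_level=ev.reporting_level,
            )
        )
        try:
            shifted = align_event_to_site(ev, down_flow, config.travel_time)
            if config.shift_before_volume:
                v_down = event_volume_from_flow(down_flow, shifted.start, shifted.end)
            else:
                v_down = event_volume_from_flow(down_flow, ev.start, ev.end)
        except ValueError:
            logger.warning("event at %s could not be aligned downstream", ev.midpoint)
            continue
        for site in sites_down:
            if site.name == up_site.name:
                continue
            if site.gaged:
                v_site = v_down
            else:
                v_site = scale_by_drainage_area(
                    ev.volume,
                    v_down,
                    up_site.drainage_area_km2,
                    down_site.drainage_area_km2,
                    site.drainage_area_km2,
                )
            conc = propagate_concentration(ev, v_site)
            out[site.name].append(
                CompositeEvent(
                    start=shifted.start, end=shifted.end, site=site.name,
                    volume=v_site, concentration=conc,
                )
            )
    return out


def _antecedent_wide(
    config: ScenarioConfig,
    site_events: dict[str, list[CompositeEvent]],
    visits: pd.DataFrame,
) -> pd.DataFrame:
    """Pivot the long antecedent table to one row per site-visit."""
    long = antecedent_features(
        site_events, visits, config.cod_windows_weeks, min_completeness=0.5
    )
    wide_rows = {}
    for _, r in long.iterrows():
        key = (r["site"], r["timestamp"])
        row = wide_rows.setdefault(key, {"site": key[0], "timestamp": key[1]})
        w = r["window_weeks"]
        tag = f"{w:g}wk"
        row[f"cod_fwmc_{tag}"] = r["flow_weighted_mean_cod"]
        row[f"cod_load_{tag}"] = r["total_load"]
        row[f"cod_completeness_{tag}"] = r["completeness"]
    return pd.DataFrame(list(wide_rows.values()))


def run_exposure(config: ScenarioConfig, outdir: Path) -> Path:
    """Propagate composites downstream and write the antecedent-COD matrix."""
    outdir = Path(outdir)
    composites = _read(outdir / "composites.csv", parse=("start", "end"))
    hydro = {
        f"{s.name}-gage": _read(
            outdir / f"flow_{s.name}-gage.csv", parse=("timestamp",)
        )
        for s in config.gaged_sites
    }
    visits = _read(outdir / "visits.csv", parse=("timestamp",))
    site_events = _propagate_events(config, composites, hydro)
    events_long = pd.DataFrame(
        [
            {
                "site": e.site, "start": e.start, "end": e.end,
                "volume": e.volume, "concentration": e.working_concentration,
                "censored": e.censored, "reporting_level": e.reporting_level,
            }
            for evs in site_events.values()
            for e in evs
        ]
    )
    _write(events_long, outdir / "site_events.csv")
    long = antecedent_features(
        site_events, visits, config.cod_windows_weeks, min_completeness=0.5
    )
    _write(long, outdir / "antecedent_cod_long.csv")
    wide = _antecedent_wide(config, site_events, visits)
    return _write(wide, outdir / "antecedent_cod.csv")


# ---------------------------------------------------------------------------
# stage: temperature


def _temperature_wide(
    config: ScenarioConfig,
    temps: dict[str, pd.DataFrame],
    visits: pd.DataFrame,
) -> pd.DataFrame:
    """Gap-fill ungaged records and pivot antecedent stats per site-visit."""
    filled: dict[str, pd.DataFrame] = {}
    for site in config.sites:
        if site.gaged:
            filled[site.name] = temps[f"{site.name}-gage"].assign(estimated=False)
    for key in config.temperature_relations:
        ungaged_name, gage_name = key.split("~")
        relation = fit_pair_relation(temps[ungaged_name], temps[gage_name])
        filled[ungaged_name] = fill_gaps(temps[ungaged_name], temps[gage_name], relation)
    rows = []
    for _, v in visits.iterrows():
        series = filled.get(v["site"])
        if series is None:
            continue
        stats = antecedent_temperature_stats(
            series, v["timestamp"], config.temperature_windows_weeks
        )
        row: dict[str, object] = {"site": v["site"], "timestamp": v["timestamp"]}
        for _, s in stats.iterrows():
            tag = f"{s['window_weeks']:g}wk"
            for stat in _TEMP_STATS:
                row[f"temp_{stat}_{tag}"] = s[stat]
        rows.append(row)
    return pd.DataFrame(rows)


def run_temperature(config: ScenarioConfig, outdir: Path) -> Path:
    """Fit pair relations, fill gaps, and write antecedent temperature stats."""
    outdir = Path(outdir)
    temps: dict[str, pd.DataFrame] = {}
    for site in config.sites:
        name = f"{site.name}-gage" if site.gaged else site.name
        temps[name] = _read(outdir / f"temperature_{name}.csv", parse=("timestamp",))
    visits = _read(outdir / "visits.csv", parse=("timestamp",))
    wide = _temperature_wide(config, temps, visits)
    return _write(wide, outdir / "antecedent_temperature.csv")


# ---------------------------------------------------------------------------
# stage: survey


def run_survey(config: ScenarioConfig, outdir: Path) -> Path:
    """Aggregate survey points to standardized per-class volumes."""
    outdir = Path(outdir)
    points = _read(outdir / "survey_points.csv", parse=("timestamp",))
    frames = []
    for (site, visit), grp in points.groupby(["site", "timestamp"], sort=True):
        pts = [
            SurveyPoint(
                site=site,
                visit=visit,
                transect=int(r["transect"]),
                point=int(r["point"]),
                biofilm_class=str(r["biofilm_class"]),
                thickness_mm=(
                    float(r["thickness_mm"]) if pd.notna(r["thickness_mm"]) else None
                ),
            )
            for _, r in grp.iterrows()
        ]
        frames.append(compute_visit_volumes(pts))
    volumes = pd.concat(frames, ignore_index=True)
    return _write(volumes, outdir / "biofilm_volumes.csv")


# ---------------------------------------------------------------------------
# stage: merge


def merge_features(
    volumes: pd.DataFrame,
    antecedent_cod: pd.DataFrame,
    antecedent_temp: pd.DataFrame,
    grabs: pd.DataFrame,
    qpcr: pd.DataFrame,
    do_obs: pd.DataFrame | None = None,
    *,
    tolerance_days: float = 1.0,
) -> pd.DataFrame:
    """One analysis row per site-visit, joining all feature families.

    Tables are keyed by ``(site, timestamp)``; a feature row joins a visit
    when its timestamp is within ``tolerance_days`` of the visit timestamp.
    Missing features stay missing (never imputed).  Duplicate keys within a
    table raise.
    """
    vol_wide = volumes.pivot_table(
        index=["site", "visit"], columns="biofilm_class", values="volume_l",
        aggfunc="first",
    ).reset_index()
    vol_wide.columns.name = None
    rename = {c: f"volume_{c.replace(' ', '_')}" for c in CLASSES}
    vol_wide = vol_wide.rename(columns=rename).rename(columns={"visit": "timestamp"})
    vol_wide["volume_autotroph_total"] = sum(
        vol_wide[f"volume_{c.replace(' ', '_')}"] for c in AUTOTROPH_CLASSES
    )

    base = vol_wide
    if base.duplicated(["site", "timestamp"]).any():
        raise ValueError("duplicate (site, visit) keys in survey volumes")

    def join(left: pd.DataFrame, right: pd.DataFrame, label: str) -> pd.DataFrame:
        right = right.copy()
        if right.duplicated(["site", "timestamp"]).any():
            raise ValueError(f"duplicate (site, timestamp) keys in {label}")
        if left.empty or right.empty:
            return left
        tol = pd.Timedelta(days=tolerance_days)
        out_rows = []
        for _, lrow in left.iterrows():
            row = dict(lrow)
            cand = right[right["site"] == lrow["site"]]
            if not cand.empty:
                d = (pd.to_datetime(cand["timestamp"]) - lrow["timestamp"]).abs()
                i = d.idxmin()
                if d.loc[i] <= tol:
                    for c in right.columns:
                        if c not in ("site", "timestamp"):
                            row[c] = cand.loc[i, c]
            out_rows.append(row)
        return pd.DataFrame(out_rows)

    merged = join(base, antecedent_cod, "antecedent COD")
    merged = join(merged, antecedent_temp, "antecedent temperature")
    merged = join(merged, grabs, "grab samples")
    if do_obs is not None:
        merged = join(merged, do_obs, "DO observations")

    if not qpcr.empty:
        samples = []
        for _, r in qpcr.iterrows():
            s = QpcrSample(
                site=str(r["site"]),
                visit=pd.Timestamp(r["timestamp"]),
                stha_copies=float(r["stha_copies"]),
                r16s_copies=float(r["r16s_copies"]),
                signal_fractions={
                    80: float(r["frac_tm80"]),
                    86: float(r["frac_tm86"]),
                    88: float(r["frac_tm88"]),
                    90: float(r["frac_tm90"]),
                },
            )
            samples.append(
                {
                    "site": s.site, "timestamp": s.visit,
                    "stha_16s_ratio": relative_abundance(s),
                }
            )
        merged = join(merged, pd.DataFrame(samples), "qPCR")

    if merged.empty:
        logger.warning("merged feature table is empty (disjoint site sets?)")
    return merged


def run_merge(config: ScenarioConfig, outdir: Path) -> Path:
    outdir = Path(outdir)
    merged = merge_features(
        _read(outdir / "biofilm_volumes.csv", parse=("visit",)).rename(
            columns={"visit": "visit"}
        ).assign(visit=lambda d: pd.to_datetime(d["visit"])),
        _read(outdir / "antecedent_cod.csv", parse=("timestamp",)),
        _read(outdir / "antecedent_temperature.csv", parse=("timestamp",)),
        _read(outdir / "grabs.csv", parse=("timestamp",)),
        _read(outdir / "qpcr.csv", parse=("timestamp",)),
        _read(outdir / "do_observations.csv", parse=("timestamp",)),
    )
    return _write(merged, outdir / "analysis_table.csv")


# ---------------------------------------------------------------------------
# stage: model


def default_biofilm_spec(config: ScenarioConfig) -> ModelSpec:
    """Candidate suite for the biofilm-volume regression.

    Flow-weighted COD means for every antecedent window, key temperature
    statistics, nutrients, SC, pH and downstream site indicators.  DO is
    excluded by construction (biofilms may themselves drive DO).
    """
    cands = [
        Predictor(f"cod_fwmc_{w:g}wk", "log10")
        for w in config.cod_windows_weeks
    ]
    cands += [
        Predictor("temp_max_2wk"),
        Predictor("temp_mean_2wk"),
        Predictor("no23_mg_l", "log10"),
        Predictor("tp_mg_l", "log10"),
        Predictor("sc_us_cm", "log10"),
        Predictor("ph"),
    ]
    cands += [
        Predictor(f"is_{s.name}", indicator=True)
        for s in config.sites
        if 0 < s.downstream_rank < max(x.downstream_rank for x in config.sites)
    ]
    return ModelSpec(
        response="volume_for_log", response_transform="log10", candidates=cands
    )


def default_do_spec(config: ScenarioConfig) -> ModelSpec:
    cands = [
        Predictor("volume_for_log", "log10"),
        Predictor(f"cod_fwmc_2wk", "log10"),
        Predictor(f"cod_fwmc_8wk", "log10"),
        Predictor("temp_max_2wk"),
        Predictor("temp_mean_2wk"),
        Predictor("no23_mg_l", "log10"),
        Predictor("tp_mg_l", "log10"),
    ]
    return ModelSpec(response="do_mg_l", candidates=cands)


def _prepare_model_table(config: ScenarioConfig, table: pd.DataFrame) -> pd.DataFrame:
    """Add log-ready volume and site-indicator columns to the merged table."""
    out = table.copy()
    vols = out["volume_heterotrophs"].to_numpy(float)
    ok = np.isfinite(vols)
    sub = vols.copy()
    sub[ok], _ = substitute_zeros_for_log(vols[ok])
    out["volume_for_log"] = sub
    for s in config.sites:
        out[f"is_{s.name}"] = (out["site"] == s.name).astype(float)
    return out


def format_model_report(name: str, res: RegressionResult) -> str:
    lines = [f"model: {name}", f"n = {res.n}", f"R2 = {res.r2:.3f}",
             f"BIC = {res.bic:.2f}", f"residual SD = {res.residual_sd:.3f}",
             f"intercept = {res.intercept:.4g}"]
    for t in res.terms:
        lines.append(f"  {t}: {res.coefficients[t]:.4g}")
    lines.append("selection trace:")
    for move, term, bic in res.trace:
        lines.append(f"  {move:5s} {term:32s} BIC={bic:.2f}")
    return "\n".join(lines) + "\n"


def run_model(config: ScenarioConfig, outdir: Path) -> dict[str, Path]:
    """Fit both stepwise-BIC models and write text + CSV reports."""
    outdir = Path(outdir)
    table = _read(outdir / "analysis_table.csv", parse=("timestamp",))
    table = _prepare_model_table(config, table)
    # the regressions use downstream sites (exposure features exist there)
    down = table[table["site"] != config.sites[0].name]
    results: dict[str, Path] = {}
    for name, spec in (
        ("biofilm_volume", default_biofilm_spec(config)),
        ("dissolved_oxygen", default_do_spec(config)),
    ):
        res = stepwise_bic(down, spec)
        (outdir / f"model_{name}.txt").write_text(format_model_report(name, res))
        coef = pd.DataFrame(
            {
                "term": ["(intercept)"] + res.terms,
                "coefficient": [res.intercept]
                + [res.coefficients[t] for t in res.terms],
            }
        )
        coef["r2"], coef["bic"], coef["n"] = res.r2, res.bic, res.n
        results[name] = _write(coef, outdir / f"model_{name}.csv")
    return results


# ---------------------------------------------------------------------------
# stage: correlate


def run_correlate(config: ScenarioConfig, outdir: Path) -> Path:
    """Spearman screen of the sthA:16S ratio against environmental measures."""
    outdir = Path(outdir)
    table = _read(outdir / "analysis_table.csv", parse=("timestamp",))
    feature_cols = [
        "volume_heterotrophs",
        "volume_autotroph_total",
        "do_mg_l",
        "tp_mg_l",
        "no23_mg_l",
        "tkn_mg_l",
    ] + [f"cod_fwmc_{w:g}wk" for w in config.cod_windows_weeks] + [
        "temp_max_2wk",
        "temp_mean_2wk",
    ]
    present = [c for c in feature_cols if c in table.columns]
    screen = spearman_screen(
        table["stha_16s_ratio"].to_numpy(float), table[present]
    )
    return _write(screen, outdir / "spearman_screen.csv")


# ---------------------------------------------------------------------------
# whole pipeline


def _config_hash(config: ScenarioConfig) -> str:
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: ScenarioConfig, outdir: Path) -> dict:
    """Execute all stages in order and write ``manifest.json``.

    A stage failure leaves a ``FAILED`` marker naming the stage and
    re-raises, preserving partial outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = [
        ("generate", lambda: run_generate(config, outdir)),
        ("exposure", lambda: run_exposure(config, outdir)),
        ("temperature", lambda: run_temperature(config, outdir)),
        ("survey", lambda: run_survey(config, outdir)),
        ("merge", lambda: run_merge(config, outdir)),
        ("model", lambda: run_model(config, outdir)),
        ("correlate", lambda: run_correlate(config, outdir)),
    ]
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "stages": [],
    }
    for name, fn in stages:
        logger.info("stage=%s seed=%d starting", name, config.seed)
        try:
            result = fn()
        except Exception as exc:
            (outdir / "FAILED").write_text(f"stage {name}: {exc}\n")
            raise
        paths = (
            list(result.values())
            if isinstance(result, dict)
            else [result]
        )
        entry = {"stage": name, "outputs": []}
        for p in paths:
            p = Path(p)
            n_rows = sum(1 for _ in open(p)) - 1 if p.suffix == ".csv" else None
            entry["outputs"].append({"path": p.name, "rows": n_rows})
        manifest["stages"].append(entry)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
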