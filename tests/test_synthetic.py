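"""Generator behavior: determinism, calibration targets, recoverability."""

import numpy as np
import pandas as pd
import pytest
import scipy.signal
import scipy.stats

from deicer_biofilm.config import (
    AffineRelation,
    HydrographConfig,
    ScenarioConfig,
    TemperatureConfig,
    noise_sd_for_r2,
)
from deicer_biofilm.models import fit_loglog
from deicer_biofilm.survey import SurveyPoint, compute_class_volume, season_contrast
from deicer_biofilm.synthetic import (
    generate_cod_and_deicer,
    generate_hydrographs,
    generate_surveys_do_qpcr,
    generate_temperature,
    simulate_biofilm_dataset,
    simulate_do_dataset,
    simulate_temperature_pair,
    visit_schedule,
)


def _feature_table(config, n=40, cod_lo=20.0, cod_hi=400.0, seed=3):
    """Hand-built antecedent table covering all sites and both seasons."""
    rng = np.random.default_rng(seed)
    rows = []
    dates = pd.date_range("2010-01-15", periods=n // 4, freq="30D")
    for d in dates:
        for s in config.sites:
            rows.append(
                {
                    "site": s.name,
                    "timestamp": d,
                    "cod_fwmc_2wk": float(rng.uniform(cod_lo, cod_hi)),
                    "cod_fwmc_8wk": float(rng.uniform(cod_lo, cod_hi)),
                    "temp_max_2wk": float(rng.uniform(2, 20)),
                }
            )
    return pd.DataFrame(rows)


class TestNoiseCalibration:
    def test_formula(self):
        # R2 = s^2 / (s^2 + sd^2) inverted
        sd = noise_sd_for_r2(2.0, 0.5)
        assert 4.0 / (4.0 + sd**2) == pytest.approx(0.5)

    def test_r2_one_returns_zero_noise(self):
        assert noise_sd_for_r2(2.0, 1.0) == 0.0

    @pytest.mark.parametrize("bad", [0.0, 1.5, -0.2])
    def test_invalid_target_rejected(self, bad):
        with pytest.raises(ValueError):
            noise_sd_for_r2(2.0, bad)


class TestHydrographs:
    def test_seeded_determinism(self, small_config):
        a = generate_hydrographs(small_config)
        b = generate_hydrographs(small_config)
        for k in a:
            pd.testing.assert_frame_equal(a[k], b[k])

    def test_zero_amplitude_constant_baseflow(self, small_config):
        cfg = small_config.model_copy(
            update={"hydrograph": HydrographConfig(event_amplitude=0.0)}
        )
        out = generate_hydrographs(cfg)
        for df in out.values():
            assert np.ptp(df["flow"].to_numpy()) == pytest.approx(0.0)

    def test_flows_positive(self, small_config):
        for df in generate_hydrographs(small_config).values():
            assert (df["flow"] > 0).all()

    def test_configured_event_count_yields_detectable_pulses(self, small_config):
        # well-separated large pulses: count peaks above baseflow
        cfg = small_config.model_copy(
            update={
                "hydrograph": HydrographConfig(
                    baseflow=4.0, events_per_year=10, event_amplitude=80.0,
                    event_duration_h=6.0,
                ),
                "seed": 42,
            }
        )
        flow = generate_hydrographs(cfg)[f"{cfg.gaged_sites[-1].name}-gage"]
        years = (flow["timestamp"].iloc[-1] - flow["timestamp"].iloc[0]) / pd.Timedelta(
            days=365.25
        )
        expected = int(round(10 * years))
        v = flow["flow"].to_numpy()
        peaks, _ = scipy.signal.find_peaks(v, height=4.0 * 3, distance=12)
        # pulses may overlap by chance; most must be individually detectable
        assert expected * 0.6 <= len(peaks) <= expected


class TestTemperature:
    def test_zero_noise_exact_affine_image(self, small_config):
        rels = {
            k: AffineRelation(slope=r.slope, intercept=r.intercept, r2=1.0)
            for k, r in small_config.temperature_relations.items()
        }
        cfg = small_config.model_copy(
            update={
                "temperature_relations": rels,
                "temperature": TemperatureConfig(gap_fraction=0.0),
            }
        )
        out = generate_temperature(cfg)
        g = out["DS1-gage"]["value"].to_numpy()
        u = out["US1"]["value"].to_numpy()
        assert np.allclose(u, 1.13 * g - 1.71)

    def test_zero_gap_fraction_no_missing(self, small_config):
        cfg = small_config.model_copy(
            update={"temperature": TemperatureConfig(gap_fraction=0.0)}
        )
        for df in generate_temperature(cfg).values():
            assert df["value"].notna().all()

    def test_gap_fraction_masks_values(self, small_config):
        out = generate_temperature(small_config)
        frac = out["US1"]["value"].isna().mean()
        assert 0.02 < frac < 0.25

    def test_sample_r2_matches_configured_target(self):
        # population R2 calibration: sample R2 near target over many seeds
        rel = AffineRelation(slope=1.13, intercept=-1.71, r2=0.85)
        cfg = ScenarioConfig()
        r2s = []
        for seed in range(20):
            g, u = simulate_temperature_pair(rel, 2000, np.random.default_rng(seed), cfg)
            r2s.append(scipy.stats.linregress(g, u).rvalue ** 2)
        assert np.mean(r2s) == pytest.approx(0.85, abs=0.02)


class TestCodAndDeicer:
    def test_off_season_near_background(self, config):
        comps, _, _ = generate_cod_and_deicer(config)
        mid = comps["start"] + (comps["end"] - comps["start"]) / 2
        season = mid.dt.month.isin(config.deicer_months)
        gm_on = 10 ** np.log10(comps.loc[season, "concentration"]).mean()
        gm_off = 10 ** np.log10(comps.loc[~season, "concentration"]).mean()
        assert gm_on > 4 * gm_off
        assert gm_off == pytest.approx(config.cod.off_season_gm, rel=0.5)

    def test_censoring_threshold_above_all_values_flags_everything(self, small_config):
        cc = small_config.cod.model_copy(update={"reporting_level_mg_l": 1e6})
        cfg = small_config.model_copy(update={"cod": cc})
        comps, _, grabs = generate_cod_and_deicer(cfg)
        assert comps["censored"].all()
        assert grabs["cod_censored"].all()
        # working values sit at the reporting level
        assert (comps["concentration"] == 1e6).all()

    def test_deicer_slope_recovered_by_ols(self, config):
        slopes = []
        for seed in range(20):
            cfg = config.model_copy(update={"seed": seed})
            comps, pairs, _ = generate_cod_and_deicer(cfg)
            slopes.append(
                fit_loglog(pairs["cod_mg_l"], pairs["total_deicer_mg_l"])[0]
            )
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert np.mean(slopes) == pytest.approx(1.03, abs=3 * se + 0.02)

    def test_composite_volumes_positive_and_weekly(self, small_config):
        comps, _, _ = generate_cod_and_deicer(small_config)
        assert (comps["volume"] > 0).all()
        assert ((comps["end"] - comps["start"]) == pd.Timedelta(days=7)).all()


class TestSurveysDoQpcr:
    def test_zero_noise_survey_roundtrip(self, small_config):
        # with zero model noise, aggregating the generated points returns the
        # model-predicted volume up to the thickness discretization
        bm = small_config.biofilm_model.model_copy(update={"r2": 1.0})
        cfg = small_config.model_copy(update={"biofilm_model": bm})
        feats = _feature_table(cfg)
        points, _, _, truth = generate_surveys_do_qpcr(cfg, feats)
        for (site, ts), grp in points.groupby(["site", "timestamp"]):
            pts = [
                SurveyPoint(site, ts, int(r["transect"]), int(r["point"]),
                            r["biofilm_class"],
                            None if pd.isna(r["thickness_mm"]) else float(r["thickness_mm"]))
                for _, r in grp.iterrows()
            ]
            vol = compute_class_volume(pts, "heterotrophs").volume_l
            true = truth.set_index(["site", "timestamp"]).loc[
                (site, ts), "true_heterotroph_volume_l"
            ]
            if true >= 0.005:
                # count <= 49 points at 0.005 mm rounding error each
                assert vol == pytest.approx(true, abs=0.25, rel=0.02)
            else:
                assert vol == 0.0

    def test_upstream_site_stays_at_floor(self, small_config):
        feats = _feature_table(small_config)
        _, _, _, truth = generate_surveys_do_qpcr(small_config, feats)
        up = truth[truth["site"] == "US1"]
        assert (up["true_heterotroph_volume_l"] == 0).all()

    def test_missing_features_skip_with_warning(self, small_config, caplog):
        feats = _feature_table(small_config)
        feats.loc[feats.index[5], "cod_fwmc_2wk"] = np.nan
        import logging

        with caplog.at_level(logging.WARNING):
            _, _, _, truth = generate_surveys_do_qpcr(small_config, feats)
        assert "skipping visit" in caplog.text
        assert len(truth) == len(feats) - 1

    def test_deicer_season_volumes_dominate_downstream(self, config):
        # generated downstream heterotroph volumes are stochastically larger
        # in deicer months; the seasonal contrast detects this
        hits = 0
        for seed in range(10):
            cfg = config.model_copy(update={"seed": seed})
            feats = _feature_table(cfg, seed=seed)
            # impose the seasonal exposure pattern on the features
            winter = pd.to_datetime(feats["timestamp"]).dt.month.isin(
                cfg.deicer_months
            )
            feats.loc[~winter, ["cod_fwmc_2wk", "cod_fwmc_8wk"]] = 15.0
            _, _, _, truth = generate_surveys_do_qpcr(cfg, feats)
            down = truth[truth["site"] != "US1"].rename(
                columns={"timestamp": "visit", "true_heterotroph_volume_l": "volume_l"}
            )
            _, p = season_contrast(down)
            hits += p < 0.05
        assert hits >= 9

    def test_qpcr_fractions_sum_to_one(self, small_config):
        feats = _feature_table(small_config)
        _, _, qpcr, _ = generate_surveys_do_qpcr(small_config, feats)
        total = qpcr[["frac_tm80", "frac_tm86", "frac_tm88", "frac_tm90"]].sum(axis=1)
        assert np.allclose(total, 1.0)


class TestFastPaths:
    def test_biofilm_dataset_r2_calibration(self, config):
        r2s = []
        for seed in range(20):
            f = simulate_biofilm_dataset(config, 500, np.random.default_rng(seed))
            y = np.log10(f["volume_l"])
            X = np.column_stack(
                [np.log10(f["cod_fwmc_2wk"]), f["is_DS1"], f["is_DS2"]]
            )
            beta, *_ = np.linalg.lstsq(
                np.column_stack([np.ones(len(y)), X]), y, rcond=None
            )
            resid = y - np.column_stack([np.ones(len(y)), X]) @ beta
            r2s.append(1 - resid @ resid / ((y - y.mean()) @ (y - y.mean())))
        assert np.mean(r2s) == pytest.approx(0.62, abs=0.03)

    def test_do_dataset_contains_model_signal(self, config):
        f = simulate_do_dataset(config, 400, np.random.default_rng(1))
        r = np.corrcoef(np.log10(f["volume_l"]), f["do_mg_l"])[0, 1]
        assert r < -0.3  # volume depresses DO


def test_visit_schedule_covers_both_seasons(config):
    v = visit_schedule(config)
    months = pd.to_datetime(v["timestamp"]).dt.to_period("M").unique()
    assert pd.Period("2010-01") in months
    assert pd.Period("2011-01") in months
    # off-season months are not visited (except June/November comparisons)
    assert pd.Period("2010-08") not in months
    assert set(v["site"]) == {s.name for s in config.sites}
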