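"""Scenario configuration for the deicer-runoff biofilm study system.

The configuration describes a small urban stream network around an airport:
one upstream reference site (``US1``) and three sites at increasing distance
downstream from the deicing operations (``DS1``, ``DS2``, ``DS3``), with
continuous stream gages near DS1 and DS3.  All ground-truth coefficient sets
default to the fitted relations of the field study this package models
(temperature pair relations, the log-linear biofilm-volume model, the
dissolved-oxygen model, the COD/total-deicer and grab/composite surrogate
regressions), so that synthetic data generated from a default configuration
carry a known, recoverable truth.

Residual noise magnitudes are never stated directly; instead each relation
carries a target coefficient of determination, and generators calibrate the
noise standard deviation as::

    sd_noise = sd(signal) * sqrt((1 - R2) / R2)

which makes the population R-squared of the generated data equal the target.
"""

from __future__ import annotations

import datetime as _dt
from pydantic import BaseModel, Field, field_validator, model_validator

#: Months (1-12) in which stream chemistry is considered deicer influenced.
DEICER_MONTHS: frozenset[int] = frozenset({12, 1, 2, 3, 4, 5})

#: Antecedent look-back windows, in weeks, for flow-weighted COD statistics.
COD_WINDOWS_WEEKS: tuple[float, ...] = (2, 4, 6, 8, 12, 16, 20)

#: Antecedent look-back windows, in weeks, for temperature statistics.
TEMPERATURE_WINDOWS_WEEKS: tuple[float, ...] = (0.5, 1, 2, 4, 6, 8, 12, 16, 20)


class Site(BaseModel):
    """A monitoring site on the stream network."""

    name: str
    drainage_area_km2: float = Field(gt=0)
    gaged: bool = False
    #: Rank order along the flow path; 0 is the upstream reference site.
    downstream_rank: int = Field(ge=0)


class AffineRelation(BaseModel):
    """An affine ground-truth relation ``y = slope * x + intercept`` with a
    target population coefficient of determination used for noise calibration."""

    slope: float
    intercept: float
    r2: float = Field(gt=0.0, le=1.0)


class TravelTimeLaw(BaseModel):
    """Power-law travel time between the two gages: ``T = c * Q**(-e)`` hours.

    The coefficients are empirical constants from dye-tracer calibration and
    are bound to the flow unit declared in :attr:`flow_unit`; the functions
    that evaluate the law refuse inputs declared in any other unit.
    """

    coefficient: float = 29.35
    exponent: float = 0.62
    flow_unit: str = "cfs"


class BiofilmVolumeModel(BaseModel):
    """Log-linear model for heterotrophic biofilm volume.

    ``log10(V) = cod_slope * log10(cod_2wk) + site_effects[site] + intercept``
    with lognormal noise calibrated to ``r2``.
    """

    cod_slope: float = 0.79
    site_effects: dict[str, float] = Field(
        default_factory=lambda: {"DS1": 1.1, "DS2": 0.61}
    )
    intercept: float = -3.9
    r2: float = 0.62


class DissolvedOxygenModel(BaseModel):
    """Linear model for dissolved oxygen (mg/L).

    ``DO = volume_slope * log10(V) + temp_slope * maxT_2wk
    + cod_slope * log10(cod_8wk) + intercept`` with Gaussian noise
    calibrated to ``r2``.
    """

    volume_slope: float = -2.2
    temp_slope: float = -0.35
    cod_slope: float = -4.4
    intercept: float = 20.0
    r2: float = 0.74


class QpcrCoupling(BaseModel):
    """Rank-dependence parameters for the sthA:16S relative-abundance ratio.

    The ratio is coupled to heterotrophic biofilm volume (positive) and
    dissolved oxygen (negative) through a Gaussian copula whose Pearson
    parameters are set from the target Spearman correlations by the sine
    transform ``r = 2 sin(pi * rho / 6)``.
    """

    rho_volume: float = Field(default=0.73, ge=-1.0, le=1.0)
    rho_do: float = Field(default=-0.77, ge=-1.0, le=1.0)
    #: Mean proportion of qPCR signal in the on-target melt classes (80/90 C).
    on_target_mean: float = Field(default=0.6, gt=0.0, le=1.0)
    #: Beta-distribution concentration for sample-to-sample on-target spread.
    on_target_concentration: float = Field(default=40.0, gt=0.0)


class HydrographConfig(BaseModel):
    """Baseflow plus randomly timed storm pulses at each gage."""

    baseflow: float = Field(default=4.0, gt=0)
    #: Storm events per simulated year.
    events_per_year: float = Field(default=40.0, ge=0.0)
    event_amplitude: float = Field(default=25.0, ge=0.0)
    #: Exponential recession time constant of a pulse, hours.
    event_duration_h: float = Field(default=18.0, gt=0.0)
    time_step_h: float = Field(default=1.0, gt=0.0)


class TemperatureConfig(BaseModel):
    """Seasonal 15-minute water temperature with sensor gaps at ungaged sites."""

    annual_mean_c: float = 10.0
    annual_amplitude_c: float = 9.5
    diurnal_amplitude_c: float = 0.6
    gap_fraction: float = Field(default=0.08, ge=0.0, lt=1.0)


class CodConfig(BaseModel):
    """Weekly flow-composite COD at the upstream gage plus grab samples."""

    #: Geometric-mean composite COD during deicer months, mg/L.
    deicer_season_gm: float = Field(default=120.0, gt=0)
    #: Geometric-mean composite COD outside deicer months, mg/L.
    off_season_gm: float = Field(default=14.0, gt=0)
    #: Lognormal spread (SD of log10 concentration) within season.
    log10_sd: float = Field(default=0.35, ge=0)
    #: Upstream-site grab COD geometric mean, mg/L (background).
    upstream_gm: float = Field(default=15.0, gt=0)
    reporting_level_mg_l: float = Field(default=8.0, gt=0)


class ScenarioConfig(BaseModel):
    """Full specification of a synthetic two-season study scenario.

    The random ``seed`` fully determines every generated record; generating
    twice from an identical configuration yields byte-identical CSV output.
    """

    sites: list[Site] = Field(
        default_factory=lambda: [
            Site(name="US1", drainage_area_km2=2.1, gaged=False, downstream_rank=0),
            Site(name="DS1", drainage_area_km2=18.3, gaged=True, downstream_rank=1),
            Site(name="DS2", drainage_area_km2=24.9, gaged=False, downstream_rank=2),
            Site(name="DS3", drainage_area_km2=30.6, gaged=True, downstream_rank=3),
        ]
    )
    start: _dt.date = _dt.date(2009, 12, 1)
    end: _dt.date = _dt.date(2011, 6, 30)
    seed: int = 0

    travel_time: TravelTimeLaw = Field(default_factory=TravelTimeLaw)
    hydrograph: HydrographConfig = Field(default_factory=HydrographConfig)
    temperature: TemperatureConfig = Field(default_factory=TemperatureConfig)
    cod: CodConfig = Field(default_factory=CodConfig)

    #: Ungaged-on-gaged temperature relations, keyed ``(ungaged, gaged)`` site.
    temperature_relations: dict[str, AffineRelation] = Field(
        default_factory=lambda: {
            "US1~DS1-gage": AffineRelation(slope=1.13, intercept=-1.71, r2=0.85),
            "DS2~DS3-gage": AffineRelation(slope=1.01, intercept=0.16, r2=0.98),
        }
    )
    #: log10 total deicer on log10 COD.
    cod_deicer_relation: AffineRelation = Field(
        default_factory=lambda: AffineRelation(slope=1.03, intercept=-0.47, r2=0.93)
    )
    #: log10 grab COD on log10 flow-composite COD.
    grab_composite_relation: AffineRelation = Field(
        default_factory=lambda: AffineRelation(slope=0.97, intercept=0.04, r2=0.86)
    )
    biofilm_model: BiofilmVolumeModel = Field(default_factory=BiofilmVolumeModel)
    do_model: DissolvedOxygenModel = Field(default_factory=DissolvedOxygenModel)
    qpcr: QpcrCoupling = Field(default_factory=QpcrCoupling)

    #: Survey discretization: points per transect and transects per reach.
    transects_per_reach: int = Field(default=5, gt=0)
    points_per_transect: int = Field(default=10, gt=0)

    #: Order of the downstream exposure calculation: shift composite
    #: intervals by the travel time before integrating downstream event
    #: volumes (default) or integrate over the unshifted interval first and
    #: shift afterwards.  The source never states the order; both are exact
    #: mass-conserving variants.
    shift_before_volume: bool = True

    cod_windows_weeks: tuple[float, ...] = COD_WINDOWS_WEEKS
    temperature_windows_weeks: tuple[float, ...] = TEMPERATURE_WINDOWS_WEEKS
    deicer_months: frozenset[int] = DEICER_MONTHS

    @field_validator("sites")
    @classmethod
    def _at_least_two_gaged(cls, v: list[Site]) -> list[Site]:
        if sum(s.gaged for s in v) < 2:
            raise ValueError("scenario requires two gaged sites for scaling")
        names = [s.name for s in v]
        if len(set(names)) != len(names):
            raise ValueError("site names must be unique")
        return v

    @model_validator(mode="after")
    def _check_period(self) -> "ScenarioConfig":
        if self.end <= self.start:
            raise ValueError("end date must follow start date")
        return self

    def site(self, name: str) -> Site:
        for s in self.sites:
            if s.name == name:
                return s
        raise KeyError(f"unknown site {name!r}")

    @property
    def gaged_sites(self) -> list[Site]:
        return [s for s in self.sites if s.gaged]


def noise_sd_for_r2(signal_sd: float, r2: float) -> float:
    """Residual SD that makes the population R-squared equal ``r2``.

    For ``y = f(x) + e`` with ``Var f = s**2`` and independent noise,
    ``R2 = s**2 / (s**2 + sd**2)``, hence ``sd = s * sqrt((1-R2)/R2)``.

    Raises ``ValueError`` when the calibration is impossible (``r2`` outside
    (0, 1] or a target of 1 requested together with nonzero signal spread —
    the only attainable noise there is exactly zero, which is returned).
    """
    if not 0.0 < r2 <= 1.0:
        raise ValueError(f"target R2 must be in (0, 1], got {r2}")
    if signal_sd < 0:
        raise ValueError("signal SD must be non-negative")
    return signal_sd * ((1.0 - r2) / r2) ** 0.5
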