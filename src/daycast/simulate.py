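"""Synthetic multi-environment trials with marker-encoded photoperiod
sensitivity.

The generator is mechanistic rather than statistical: each genotype
carries a base development rate r_i (1/days) and a short-day photoperiod
sensitivity s_i (1/hours), both scaled linear combinations of its
standardized marker dosages plus a marker-free residual sized to the
target heritability.  In environment j, daily development accrues as

    d_t = r_i * max(0, 1 - s_i * max(0, DL_jt - critical_dl))

and heading occurs on the first day the accumulated development reaches 1;
observation noise (rounded Gaussian, floored at day 1) is then added to
the day count.  Because heading is driven through the day-length curve,
the genotype-specific relationship between DL-at-heading and DTH that the
curve-intersection method relies on *emerges* from the mechanism instead
of being baked in — which is what makes recovery tests on this generator
meaningful.

Defaults emulate a temperate japonica rice MET: 31-40 degrees N, April to
June plantings, DTH broadly in the 60-140 day range, with genotype spread
driven mostly by the sensitivity parameter.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

from .daylength import DayLengthSeries, series_for_environment
from .exceptions import ValidationError
from .io_model import Environment, MarkerMatrix, MetDataset, PhenotypeRecord

__all__ = ["SimConfig", "TrueParams", "simulate_met", "build_series",
           "fig4_fixture"]

#: coefficient of variation of the base rate / sensitivity across genotypes
CV_BASE_RATE = 0.08
CV_SENSITIVITY = 0.25
#: accrual horizon; records not heading within it are dropped
MAX_DAYS = 366


@dataclass
class SimConfig:
    """Conditions of a synthetic MET.

    `heritability` is the fraction of variance in each genetic parameter
    (r and s) explained by markers; `noise_sd` is the observation error on
    DTH in days; `critical_dl` is the day-length threshold (hours) above
    which development slows for sensitive genotypes.
    """

    n_genotypes: int = 100
    n_markers: int = 500
    n_environments: int = 20
    latitude_range: tuple[float, float] = (35.5, 36.5)
    planting_doy_range: tuple[int, int] = (134, 196)  # mid-May - mid-July
    base_rate_mean: float = 0.016
    sensitivity_mean: float = 0.25
    heritability: float = 0.8
    noise_sd: float = 1.0
    critical_dl: float = 12.5
    seed: int = 0
    year: int = 2016  # leap year, exercises day-of-year handling

    def __post_init__(self) -> None:
        if min(self.n_genotypes, self.n_markers, self.n_environments) < 2:
            raise ValidationError("all counts must be >= 2")
        if not 0.0 < self.heritability <= 1.0:
            raise ValidationError("heritability must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass
class TrueParams:
    """Ground truth behind one simulated MET."""

    base_rate: np.ndarray        # r_i, per genotype (1/days)
    sensitivity: np.ndarray      # s_i, per genotype (1/hours)
    marker_effects_rate: np.ndarray
    marker_effects_sensitivity: np.ndarray
    true_dth: np.ndarray = field(repr=False)  # genotype x env, before noise (NaN = dropped)
    genotype_ids: list[str] = field(default_factory=list)
    env_ids: list[str] = field(default_factory=list)
    n_dropped: int = 0

    def genetic_values(self) -> np.ndarray:
        """Centered genotype main effects of noise-free DTH (mean over
        environments, overall mean removed) — the target the genomic BLUPs
        should recover."""
        means = np.nanmean(self.true_dth, axis=1)
        return means - means.mean()


def _scaled_trait(X: np.ndarray, effects: np.ndarray, resid: np.ndarray,
                  mean: float, cv: float, h2: float) -> np.ndarray:
    """mean * (1 + cv * z) with z a unit-variance blend of a marker score
    (weight h2) and a marker-free residual (weight 1 - h2)."""
    score = X @ effects
    sd = score.std()
    score = score / sd if sd > 0 else score
    z = np.sqrt(h2) * score + np.sqrt(1.0 - h2) * resid
    return mean * (1.0 + cv * z)


def simulate_met(config: SimConfig) -> tuple[MetDataset, TrueParams]:
    """Generate one synthetic MET and its ground truth.

    Fully reproducible from `config.seed`; a record whose accumulated
    development never reaches 1 within a year is dropped with a count
    (kept in `TrueParams.n_dropped`).
    """
    rng = np.random.default_rng(config.seed)
    n_g, n_m, n_e = (config.n_genotypes, config.n_markers,
                     config.n_environments)
    genotype_ids = [f"G{i + 1:03d}" for i in range(n_g)]
    env_ids = [f"E{j + 1:02d}" for j in range(n_e)]

    # independent biallelic markers, allele frequency U(0.1, 0.9)
    freqs = rng.uniform(0.1, 0.9, size=n_m)
    calls = rng.binomial(2, freqs, size=(n_g, n_m)).astype(float)
    markers = MarkerMatrix(genotype_ids, [f"M{k + 1:04d}" for k in range(n_m)],
                           calls)
    # standardize with whatever polymorphism came out; fixed markers get
    # zero weight rather than blowing up
    sd = calls.std(axis=0)
    X = np.where(sd > 0, (calls - calls.mean(axis=0)) / np.where(sd > 0, sd, 1.0),
                 0.0)

    w_r = rng.normal(size=n_m)
    w_s = rng.normal(size=n_m)
    resid_r = rng.normal(size=n_g)
    resid_s = rng.normal(size=n_g)
    r = _scaled_trait(X, w_r, resid_r, config.base_rate_mean, CV_BASE_RATE,
                      config.heritability)
    s = _scaled_trait(X, w_s, resid_s, config.sensitivity_mean,
                      CV_SENSITIVITY, config.heritability)
    r = np.maximum(r, 1e-4)
    s = np.maximum(s, 0.0)

    lat_lo, lat_hi = config.latitude_range
    doy_lo, doy_hi = config.planting_doy_range
    latitudes = rng.uniform(lat_lo, lat_hi, size=n_e)
    doys = rng.integers(doy_lo, doy_hi + 1, size=n_e)
    environments = [
        Environment(env_ids[j], float(latitudes[j]),
                    dt.date(config.year, 1, 1) + dt.timedelta(int(doys[j]) - 1),
                    label=f"synthetic lat {latitudes[j]:.1f} doy {doys[j]}")
        for j in range(n_e)]

    true_dth = np.full((n_g, n_e), np.nan)
    records: list[PhenotypeRecord] = []
    n_dropped = 0
    for j, env in enumerate(environments):
        series = series_for_environment(env, MAX_DAYS)
        excess = np.maximum(series.values - config.critical_dl, 0.0)
        # genotype x day development increments
        rate = r[:, None] * np.maximum(1.0 - s[:, None] * excess[None, :], 0.0)
        cum = np.cumsum(rate, axis=1)
        reached = cum >= 1.0
        for i in range(n_g):
            if not reached[i].any():
                n_dropped += 1
                continue
            day = int(np.argmax(reached[i])) + 1  # 1-based day index
            true_dth[i, j] = day
            noisy = day
            if config.noise_sd > 0:
                noisy = int(round(day + rng.normal(0.0, config.noise_sd)))
            records.append(PhenotypeRecord(genotype_ids[i], env.env_id,
                                           max(1, noisy)))
    dataset = MetDataset(environments, records, markers)
    truth = TrueParams(base_rate=r, sensitivity=s,
                       marker_effects_rate=w_r, marker_effects_sensitivity=w_s,
                       true_dth=true_dth, genotype_ids=genotype_ids,
                       env_ids=env_ids, n_dropped=n_dropped)
    return dataset, truth


def build_series(dataset: MetDataset,
                 n_days: int = MAX_DAYS) -> dict[str, DayLengthSeries]:
    """Day-length series for every environment of a dataset."""
    return {env.env_id: series_for_environment(env, n_days)
            for env in dataset.environments}


@dataclass(frozen=True)
class ToyExample:
    """The five-genotype, four-environment walkthrough of the CB method.

    Four tested genotypes get C-method estimates in the unobserved
    environment E4; their mean is the predicted E-mean; the untested
    fifth genotype's prediction is that E-mean plus its genomic BLUP.
    """

    training_estimates: tuple[float, ...] = (104.0, 105.0, 110.0, 114.0)
    training_genotypes: tuple[str, ...] = ("G1", "G2", "G3", "G4")
    untested_genotype: str = "G5"
    target_env: str = "E4"
    blup: float = -2.3
    #: expected E-mean at full precision and as presented (1 decimal)
    e_mean: float = 108.25
    e_mean_presented: float = 108.3
    #: expected CB prediction at full precision and as presented (integer)
    cb_prediction: float = 105.95
    cb_prediction_presented: float = 106.0


def fig4_fixture() -> ToyExample:
    """The worked toy example used by the test suite and documentation."""
    return ToyExample()
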