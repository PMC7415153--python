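"""Cross-validation schemes, the CB and GS predictors, and the metrics.

Two schemes mimic the decisions a breeder faces before planting:

* CV0 — predict an already *tested* genotype in an *unobserved*
  environment: every record of the target environment is removed from
  training.  Served by the C method (curve intersection, no markers).
* CV00 — predict an *untested* genotype in an *unobserved* environment:
  the target environment's records AND every record of the target
  genotype, in all environments, are removed.  Served by either

  - CB: predicted environmental mean (average of C-method estimates over
    the training genotypes) plus the untested genotype's genomic BLUP, or
  - GS: the conventional genomic-selection baseline mu_hat + g_hat, whose
    predicted environmental mean is by construction the same overall mean
    for every unobserved environment.

Metrics follow the usual within/across-environment decomposition: RMSE,
Pearson correlation, and the environmental-mean difference
EMD = mean(predicted) - mean(observed) per environment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from . import gblup
from .curves import CMethodConfig, CMethodEstimate, c_method_predict
from .daylength import DayLengthSeries, cumulative_day_length
from .exceptions import FitError, UnderdeterminedError, ValidationError
from .io_model import MetDataset
from .markers import GenomicRelationship

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionTask", "PredictionResult", "MetricsReport",
    "enumerate_tasks", "predict_cv0_c", "estimate_e_mean",
    "mean_of_estimates", "predict_cv00_cb", "predict_cv00_gs",
    "evaluate", "cdl_diagnostic", "run_cv0_c", "run_cv00", "format_days",
]


def format_days(value: float, decimals: int = 1) -> float:
    """Round a day count for presentation, half away from zero (so an
    E-mean of 108.25 presents as 108.3 and a prediction of 105.95 as 106
    at integer precision); full precision is kept everywhere internally."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum,
                                               rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PredictionTask:
    """One (scheme, method, genotype, environment) prediction problem."""

    scheme: str  # cv0 | cv00
    method: str  # c | cb | gs
    target_genotype_id: str
    target_env_id: str

    def __post_init__(self) -> None:
        if self.scheme not in ("cv0", "cv00"):
            raise ValidationError(f"unknown scheme {self.scheme!r}")
        if self.method not in ("c", "cb", "gs"):
            raise ValidationError(f"unknown method {self.method!r}")

    def training_view(self, dataset: MetDataset) -> MetDataset:
        """The dataset this task is allowed to train on: cv0 drops the
        target environment; cv00 additionally drops the target genotype
        everywhere."""
        if self.scheme == "cv0":
            return dataset.exclude(env_id=self.target_env_id)
        return dataset.exclude(env_id=self.target_env_id,
                               genotype_id=self.target_genotype_id)


@dataclass
class PredictionResult:
    """A predicted DTH with its provenance."""

    task: PredictionTask
    predicted_dth: float
    observed_dth: float | None = None
    e_mean_used: float | None = None  # CB/GS only
    blup_used: float | None = None    # CB/GS only
    root_status: str | None = None    # C method only

    @property
    def genotype_id(self) -> str:
        return self.task.target_genotype_id

    @property
    def env_id(self) -> str:
        return self.task.target_env_id

    @property
    def scheme(self) -> str:
        return self.task.scheme

    @property
    def method(self) -> str:
        return self.task.method


@dataclass
class MetricsReport:
    """Within- and across-environment prediction accuracy."""

    per_env: dict[str, dict[str, float]]
    across_env: dict[str, float]
    averages: dict[str, float]
    emd_range: tuple[float, float]
    n_undefined_pearson: int = 0

    def to_dict(self) -> dict:
        return {"per_env": self.per_env, "across_env": self.across_env,
                "averages": self.averages, "emd_range": list(self.emd_range),
                "n_undefined_pearson": self.n_undefined_pearson}


# ---------------------------------------------------------------------------
# task enumeration

def enumerate_tasks(dataset: MetDataset, scheme: str,
                    method: str | None = None) -> list[PredictionTask]:
    """All prediction tasks for a scheme.

    cv0 yields one task per *observed* (genotype, environment) record;
    cv00 yields one per cell of the full genotype x environment grid, so a
    5-genotype x 6-environment trial gives 30 tasks.
    """
    if method is None:
        method = "c" if scheme == "cv0" else "cb"
    if scheme == "cv0":
        return [PredictionTask(scheme, method, r.genotype_id, r.env_id)
                for r in dataset.phenotypes]
    if scheme == "cv00":
        return [PredictionTask(scheme, method, g, e)
                for g in dataset.genotype_ids for e in dataset.env_ids]
    raise ValidationError(f"unknown scheme {scheme!r}")


# ---------------------------------------------------------------------------
# CV0 / C method

def predict_cv0_c(dataset: MetDataset,
                  series_by_env: dict[str, DayLengthSeries],
                  task: PredictionTask,
                  config: CMethodConfig | None = None) -> PredictionResult:
    """C-method prediction of a tested genotype in an unobserved
    environment (the target environment's records never enter training)."""
    if task.scheme != "cv0" or task.method != "c":
        raise ValidationError("predict_cv0_c expects a (cv0, c) task")
    training = task.training_view(dataset)
    est = c_method_predict(training, series_by_env, task.target_genotype_id,
                           task.target_env_id, config)
    return PredictionResult(
        task, est.dth_estimate,
        observed_dth=dataset.observed_dth(task.target_genotype_id,
                                          task.target_env_id),
        root_status=est.root_status)


# ---------------------------------------------------------------------------
# CV00 / CB and GS methods

def mean_of_estimates(estimates: list[float]) -> float:
    """Arithmetic mean of per-genotype C-method estimates — the predicted
    environmental mean (E-mean) of the target environment."""
    if not estimates:
        raise FitError("no C-method estimates to average")
    return float(np.mean(estimates))


def _c_estimates_for_env(dataset: MetDataset,
                         series_by_env: dict[str, DayLengthSeries],
                         target_env_id: str,
                         config: CMethodConfig | None,
                         ) -> tuple[dict[str, float], int]:
    """C-method estimate in `target_env_id` for every genotype with enough
    records elsewhere; returns ({genotype: estimate}, n_skipped)."""
    training = dataset.exclude(env_id=target_env_id)
    estimates: dict[str, float] = {}
    skipped = 0
    for g in dataset.genotype_ids:
        try:
            est = c_method_predict(training, series_by_env, g,
                                   target_env_id, config)
        except UnderdeterminedError:
            skipped += 1
            continue
        estimates[g] = est.dth_estimate
    if skipped:
        logger.info("E-mean for %s: skipped %d genotypes with too few "
                    "records", target_env_id, skipped)
    return estimates, skipped


def estimate_e_mean(dataset: MetDataset,
                    series_by_env: dict[str, DayLengthSeries],
                    target_env_id: str,
                    excluded_genotype_id: str | None = None,
                    config: CMethodConfig | None = None) -> float:
    """Predicted environmental mean of an unobserved environment: the mean
    of C-method estimates over all eligible training genotypes.

    `excluded_genotype_id` (the genotype being predicted under cv00) never
    contributes; genotypes failing the C-method preconditions are skipped
    with a logged count.
    """
    estimates, _ = _c_estimates_for_env(dataset, series_by_env,
                                        target_env_id, config)
    estimates.pop(excluded_genotype_id, None)
    if not estimates:
        raise FitError(
            f"no eligible training genotypes for E-mean of {target_env_id}")
    return mean_of_estimates(list(estimates.values()))


def predict_cv00_cb(dataset: MetDataset,
                    series_by_env: dict[str, DayLengthSeries],
                    grmat: GenomicRelationship,
                    task: PredictionTask,
                    fit: gblup.GblupFit | None = None,
                    config: CMethodConfig | None = None) -> PredictionResult:
    """CB prediction of an untested genotype in an unobserved environment:
    predicted E-mean (from the C method on training genotypes) plus the
    genotype's projected genomic BLUP.

    `fit` may carry a GBLUP fit already trained on this task's training
    view; otherwise the model is refitted here (exact per-task refit).
    """
    if task.scheme != "cv00" or task.method != "cb":
        raise ValidationError("predict_cv00_cb expects a (cv00, cb) task")
    e_mean = estimate_e_mean(dataset, series_by_env, task.target_env_id,
                             task.target_genotype_id, config)
    if fit is None:
        fit = gblup.fit(task.training_view(dataset), grmat)
    blup = gblup.blup_for_untested(fit, grmat, [task.target_genotype_id])
    g_hat = blup[task.target_genotype_id]
    return PredictionResult(
        task, e_mean + g_hat,
        observed_dth=dataset.observed_dth(task.target_genotype_id,
                                          task.target_env_id),
        e_mean_used=e_mean, blup_used=g_hat)


def predict_cv00_gs(dataset: MetDataset,
                    grmat: GenomicRelationship,
                    task: PredictionTask,
                    fit: gblup.GblupFit | None = None) -> PredictionResult:
    """Conventional GS baseline under cv00: mu_hat + projected BLUP.  The
    implied environmental mean is mu_hat for every unobserved
    environment."""
    if task.scheme != "cv00" or task.method != "gs":
        raise ValidationError("predict_cv00_gs expects a (cv00, gs) task")
    if fit is None:
        fit = gblup.fit(task.training_view(dataset), grmat)
    predicted = gblup.predict_gs(fit, task.target_genotype_id,
                                 task.target_env_id, "cv00", grmat)
    return PredictionResult(
        task, predicted,
        observed_dth=dataset.observed_dth(task.target_genotype_id,
                                          task.target_env_id),
        e_mean_used=fit.mu, blup_used=predicted - fit.mu)


# ---------------------------------------------------------------------------
# batch runners (shared refits; results identical to the per-task calls)

def run_cv0_c(dataset: MetDataset,
              series_by_env: dict[str, DayLengthSeries],
              config: CMethodConfig | None = None,
              ) -> tuple[list[PredictionResult], int]:
    """C-method predictions for every observed record (cv0); genotypes
    with too few training records are skipped with a count."""
    results, skipped = [], 0
    for task in enumerate_tasks(dataset, "cv0", "c"):
        try:
            results.append(predict_cv0_c(dataset, series_by_env, task,
                                         config))
        except UnderdeterminedError:
            skipped += 1
    if skipped:
        logger.info("cv0/C: skipped %d tasks with too few records", skipped)
    return results, skipped


def run_cv00(dataset: MetDataset,
             series_by_env: dict[str, DayLengthSeries],
             grmat: GenomicRelationship,
             methods: tuple[str, ...] = ("cb", "gs"),
             config: CMethodConfig | None = None,
             ) -> dict[str, list[PredictionResult]]:
    """CB and/or GS predictions for the full genotype x environment grid
    under cv00, with one exact GBLUP refit per task shared between the two
    methods and per-environment caching of the C-method estimates.

    Numerically identical to calling predict_cv00_cb / predict_cv00_gs
    task by task, just without redoing shared work.
    """
    need_cb = "cb" in methods
    results: dict[str, list[PredictionResult]] = {m: [] for m in methods}
    env_estimates: dict[str, dict[str, float]] = {}
    if need_cb:
        for env_id in dataset.env_ids:
            env_estimates[env_id], _ = _c_estimates_for_env(
                dataset, series_by_env, env_id, config)
    for env_id in dataset.env_ids:
        for genotype_id in dataset.genotype_ids:
            training = dataset.exclude(env_id=env_id,
                                       genotype_id=genotype_id)
            fit = gblup.fit(training, grmat)
            observed = dataset.observed_dth(genotype_id, env_id)
            g_hat = gblup.blup_for_untested(fit, grmat,
                                            [genotype_id])[genotype_id]
            if need_cb:
                pool = {g: v for g, v in env_estimates[env_id].items()
                        if g != genotype_id}
                if not pool:
                    raise FitError(f"no training genotypes for E-mean of "
                                   f"{env_id}")
                e_mean = mean_of_estimates(list(pool.values()))
                task = PredictionTask("cv00", "cb", genotype_id, env_id)
                results["cb"].append(PredictionResult(
                    task, e_mean + g_hat, observed_dth=observed,
                    e_mean_used=e_mean, blup_used=g_hat))
            if "gs" in methods:
                task = PredictionTask("cv00", "gs", genotype_id, env_id)
                results["gs"].append(PredictionResult(
                    task, fit.mu + g_hat, observed_dth=observed,
                    e_mean_used=fit.mu, blup_used=g_hat))
    return results


# ---------------------------------------------------------------------------
# metrics

def _rmse(pred: np.ndarray, obs: np.ndarray) -> float:
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def _pearson(pred: np.ndarray, obs: np.ndarray) -> float:
    if len(pred) < 2 or np.std(pred) == 0 or np.std(obs) == 0:
        return float("nan")
    return float(np.corrcoef(pred, obs)[0, 1])


def evaluate(results: list[PredictionResult]) -> MetricsReport:
    """RMSE, Pearson correlation and EMD, within and across environments.

    Across-environment metrics pool all (predicted, observed) pairs;
    within-environment metrics are computed per environment and averaged.
    An environment whose observed values have zero variance (or fewer than
    two results) gets an undefined Pearson entry, excluded from the
    average with a count.
    """
    rows = [(r.env_id, r.predicted_dth, r.observed_dth) for r in results]
    if any(obs is None for _, _, obs in rows):
        raise ValidationError("evaluate requires observed_dth on every "
                              "result")
    df = pd.DataFrame(rows, columns=["env_id", "pred", "obs"])
    per_env: dict[str, dict[str, float]] = {}
    n_undefined = 0
    for env_id, sub in df.groupby("env_id", sort=True):
        pred, obs = sub["pred"].to_numpy(), sub["obs"].to_numpy(dtype=float)
        pc = _pearson(pred, obs)
        if np.isnan(pc):
            n_undefined += 1
        per_env[env_id] = {
            "rmse": _rmse(pred, obs),
            "pearson": pc,
            "emd": float(pred.mean() - obs.mean()),
            "n": int(len(sub)),
        }
    pred_all = df["pred"].to_numpy()
    obs_all = df["obs"].to_numpy(dtype=float)
    across = {"rmse": _rmse(pred_all, obs_all),
              "pearson": _pearson(pred_all, obs_all),
              "n": int(len(df))}
    rmses = [m["rmse"] for m in per_env.values()]
    pcs = [m["pearson"] for m in per_env.values()
           if not np.isnan(m["pearson"])]
    emds = [m["emd"] for m in per_env.values()]
    averages = {"rmse": float(np.mean(rmses)),
                "pearson": float(np.mean(pcs)) if pcs else float("nan")}
    return MetricsReport(per_env=per_env, across_env=across,
                         averages=averages,
                         emd_range=(float(min(emds)), float(max(emds))),
                         n_undefined_pearson=n_undefined)


# ---------------------------------------------------------------------------
# diagnostics

def cdl_diagnostic(dataset: MetDataset,
                   series_by_env: dict[str, DayLengthSeries]) -> dict:
    """Pooled OLS of DTH on cumulative day length at heading (CDL).

    A near-unity R-squared shows how tightly accumulated daylight tracks
    heading, motivating day length as a predictor; CDL itself cannot be
    used for prediction because computing it requires knowing DTH.
    """
    cdl, dth = [], []
    for rec in dataset.phenotypes:
        series = series_by_env[rec.env_id]
        cdl.append(cumulative_day_length(series, rec.dth))
        dth.append(float(rec.dth))
    reg = stats.linregress(cdl, dth)
    return {"slope": float(reg.slope), "intercept": float(reg.intercept),
            "r_squared": float(reg.rvalue ** 2), "n": len(dth)}
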