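"""The C method: day-length curves and their intersection.

A photoperiod-sensitive genotype heads when the seasonal day-length (DL)
trajectory satisfies its internal requirement, so across environments the
DL observed *on the heading day* traces a smooth, genotype-specific curve
when plotted against days-to-heading (DTH).  The C method exploits this:

1. For the target genotype, fit a third-degree polynomial of DL-at-heading
   on DTH across its training environments (curve C1).
2. For the target environment, fit a third-degree polynomial to its daily
   DL series against days since planting (curve C2) — computable in
   advance from latitude and planting date alone.
3. The abscissa where the two curves intersect is the estimated DTH of
   that genotype in that environment.

Both curves live in the (days-since-planting, day-length) plane, and the
intersection is found from the real roots of the difference polynomial via
its companion matrix, with a data-driven search window and an anchor
(the genotype's mean training DTH) to break ties when the cubics cross
more than once.  When no root falls in the window the nearest-approach
minimizer on a fine grid is returned and flagged, so cross-validation
loops complete rather than abort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .daylength import DayLengthSeries
from .exceptions import DegenerateSystemError, DomainError, UnderdeterminedError
from .io_model import MetDataset

__all__ = ["CubicCurve", "CMethodEstimate", "CMethodConfig",
           "fit_genotype_curve", "fit_environment_curve", "intersect",
           "c_method_predict"]

#: all four difference coefficients below this -> curves considered identical
_DEGENERACY_TOL = 1e-10
#: imaginary part below this (relative) -> companion-matrix root counts as real
_REAL_TOL = 1e-8


@dataclass
class CubicCurve:
    """Third-degree polynomial dl(t) = b0 + b1 t + b2 t^2 + b3 t^3.

    Coefficients are in ascending order; `fit_domain` records the abscissa
    range the curve was fitted on, `residual_sd` the OLS residual scale.
    """

    coefficients: tuple[float, float, float, float]
    fit_domain: tuple[float, float]
    residual_sd: float
    n_points: int

    def __post_init__(self) -> None:
        if len(self.coefficients) != 4:
            raise DomainError("a cubic has exactly four coefficients")
        lo, hi = self.fit_domain
        if not lo < hi:
            raise DomainError(f"degenerate fit domain [{lo}, {hi}]")

    def __call__(self, t):
        b0, b1, b2, b3 = self.coefficients
        t = np.asarray(t, dtype=float)
        out = b0 + t * (b1 + t * (b2 + t * b3))
        return float(out) if out.ndim == 0 else out


@dataclass
class CMethodEstimate:
    """One C-method DTH estimate with its root-selection provenance."""

    genotype_id: str
    env_id: str
    dth_estimate: float
    root_status: str  # unique_in_window | tie_broken | fallback_nearest_approach
    candidates: list[float] = field(default_factory=list)


@dataclass
class CMethodConfig:
    """Tunable knobs of the C method.

    The search window for the intersection is [lo_mult * min training DTH,
    hi_mult * max training DTH]; the environment curve is fitted over
    `env_window` days from planting (day 1); `grid_step` is the resolution
    of the nearest-approach fallback and of any grid diagnostics.
    """

    window_lo_mult: float = 0.8
    window_hi_mult: float = 1.2
    env_window: tuple[int, int] = (1, 160)
    grid_step: float = 0.01


def _fit_cubic(t: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """OLS cubic of y on t; returns ascending coefficients and residual sd
    (divisor n - 4; zero when n == 4, a perfect interpolant)."""
    V = np.vander(t, 4, increasing=True)
    coef, _, rank, _ = np.linalg.lstsq(V, y, rcond=None)
    if rank < 4:
        raise UnderdeterminedError(
            "rank-deficient cubic design (need >= 4 distinct abscissae)")
    resid = y - V @ coef
    dof = len(t) - 4
    residual_sd = float(np.sqrt(resid @ resid / dof)) if dof > 0 else 0.0
    return coef, residual_sd


def fit_genotype_curve(records: list[tuple[float, float]]) -> CubicCurve:
    """Fit the genotype curve C1: DL at heading as a cubic in DTH.

    `records` are (dth, dl_at_heading) pairs from the genotype's training
    environments; at least four pairs with four distinct DTH values are
    required for the cubic to be determined.
    """
    if len(records) < 4:
        raise UnderdeterminedError(
            f"genotype curve needs >= 4 records, got {len(records)}")
    t = np.asarray([r[0] for r in records], dtype=float)
    y = np.asarray([r[1] for r in records], dtype=float)
    if len(np.unique(t)) < 4:
        raise UnderdeterminedError(
            "genotype curve needs >= 4 distinct DTH values")
    coef, residual_sd = _fit_cubic(t, y)
    return CubicCurve(tuple(coef), (float(t.min()), float(t.max())),
                      residual_sd, len(records))


def fit_environment_curve(series: DayLengthSeries,
                          window: tuple[int, int]) -> CubicCurve:
    """Fit the environment curve C2: daily DL as a cubic in days since
    planting, over `window` (1-based day indices, inclusive)."""
    lo, hi = int(window[0]), int(window[1])
    if lo < 1 or hi > len(series):
        raise DomainError(
            f"window [{lo}, {hi}] outside series of length {len(series)}")
    if hi - lo + 1 < 4:
        raise UnderdeterminedError("environment window must span >= 4 days")
    t = np.arange(lo, hi + 1, dtype=float)
    y = series.values[lo - 1:hi]
    coef, residual_sd = _fit_cubic(t, y)
    return CubicCurve(tuple(coef), (float(lo), float(hi)),
                      residual_sd, hi - lo + 1)


def _real_roots(diff: np.ndarray) -> list[float]:
    """Real roots of a polynomial with ascending coefficients `diff`,
    via companion-matrix eigenvalues (numpy.roots)."""
    coeffs = np.trim_zeros(diff[::-1], "f")  # descending, leading zeros cut
    if coeffs.size <= 1:
        return []
    roots = np.roots(coeffs)
    scale = np.maximum(1.0, np.abs(roots.real))
    real = roots[np.abs(roots.imag) <= _REAL_TOL * scale].real
    return sorted(float(r) for r in real)


def intersect(genotype_curve: CubicCurve, env_curve: CubicCurve,
              search_window: tuple[float, float], anchor: float,
              genotype_id: str = "", env_id: str = "",
              grid_step: float = 0.01) -> CMethodEstimate:
    """Solve C1(t) = C2(t) for t inside `search_window`.

    A single root in the window is returned as-is; with several, the one
    nearest `anchor` (the genotype's mean training DTH) wins and the
    estimate is flagged `tie_broken`; with none, the window is scanned at
    `grid_step` resolution for the nearest approach of the two curves and
    the estimate is flagged `fallback_nearest_approach`.
    """
    t_lo, t_hi = float(search_window[0]), float(search_window[1])
    if not 0 < t_lo < t_hi:
        raise DomainError(f"search window [{t_lo}, {t_hi}] must be positive "
                          "and non-degenerate")
    diff = (np.asarray(genotype_curve.coefficients)
            - np.asarray(env_curve.coefficients))
    if np.all(np.abs(diff) < _DEGENERACY_TOL):
        raise DegenerateSystemError(
            "genotype and environment curves coincide; intersection "
            "undefined")
    candidates = _real_roots(diff)
    in_window = [r for r in candidates if t_lo <= r <= t_hi]
    if len(in_window) == 1:
        est, status = in_window[0], "unique_in_window"
    elif len(in_window) > 1:
        est = min(in_window, key=lambda r: (abs(r - anchor), r))
        status = "tie_broken"
    else:
        grid = np.arange(t_lo, t_hi + grid_step / 2, grid_step)
        gap = np.abs(np.polynomial.polynomial.polyval(grid, diff))
        est, status = float(grid[np.argmin(gap)]), "fallback_nearest_approach"
    return CMethodEstimate(genotype_id, env_id, float(est), status,
                           candidates)


def c_method_predict(dataset: MetDataset,
                     series_by_env: dict[str, DayLengthSeries],
                     genotype_id: str, target_env_id: str,
                     config: CMethodConfig | None = None) -> CMethodEstimate:
    """Estimate DTH of `genotype_id` in `target_env_id` by the C method.

    Training pairs are (dth, dl at that day) built from the genotype's
    records in every *other* environment, each evaluated on that
    environment's own day-length series at the integer heading day.  The
    target environment contributes only its (pre-computable) daily DL
    series.
    """
    config = config or CMethodConfig()
    pairs: list[tuple[float, float]] = []
    for rec in dataset.records_for_genotype(genotype_id):
        if rec.env_id == target_env_id:
            continue
        series = series_by_env.get(rec.env_id)
        if series is None:
            raise DomainError(f"no day-length series for {rec.env_id}")
        pairs.append((float(rec.dth), series.value_at(rec.dth)))
    if len(pairs) < 4:
        raise UnderdeterminedError(
            f"genotype {genotype_id}: only {len(pairs)} training records "
            "outside the target environment (need >= 4)")
    c1 = fit_genotype_curve(pairs)

    target_series = series_by_env.get(target_env_id)
    if target_series is None:
        raise DomainError(f"no day-length series for {target_env_id}")
    lo, hi = config.env_window
    hi = min(int(hi), len(target_series))
    c2 = fit_environment_curve(target_series, (int(lo), hi))

    dths = [p[0] for p in pairs]
    window = (config.window_lo_mult * min(dths),
              config.window_hi_mult * max(dths))
    anchor = float(np.mean(dths))
    return intersect(c1, c2, window, anchor, genotype_id, target_env_id,
                     config.grid_step)
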