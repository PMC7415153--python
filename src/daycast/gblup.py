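"""Genomic BLUP (GBLUP) for multi-environment trial phenotypes.

Model: Y_ij = mu + E_j + g_i + e_ij, with environment effects
E ~ N(0, I sigma2_E), genomic effects g ~ N(0, G sigma2_g) for a genomic
relationship matrix G, and residuals e ~ N(0, I sigma2_e).  In a MET the
environmental component usually dominates the phenotypic variability, and
both random effects are centered on zero — which is exactly why a
conventional genomic-selection prediction for an *unobserved* environment
collapses onto the overall mean plus a small genomic deviation.

Fitting is deterministic REML: the restricted likelihood is profiled over
the residual variance, leaving a two-parameter surface in the variance
ratios (sigma2_E/sigma2_e, sigma2_g/sigma2_e) that is scanned on a
log-spaced grid and polished with Nelder-Mead.  Each evaluation solves
Henderson's mixed-model equations, whose order is 1 + n_envs + n_genotypes
regardless of the number of records, so per-fit cost stays small even when
cross-validation refits the model thousands of times.

BLUPs of genotypes without phenotype records come from the conditional-
expectation projection g_hat_u = G[u,T] G[T,T]^-1 g_hat_T, which equals the
joint mixed-model solution that carries the recordless genotype in G.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .exceptions import FitError, ValidationError
from .io_model import MetDataset
from .markers import GenomicRelationship

__all__ = ["GblupFit", "fit", "blup_for_untested", "predict_gs"]

#: ridge added to G before any inversion
G_JITTER = 1e-8
#: bounds for log variance ratios during optimization
_LOG_RATIO_BOUND = 30.0


@dataclass
class GblupFit:
    """Fitted GBLUP model: point estimates and variance components."""

    mu: float
    env_effects: dict[str, float]
    genomic_blups: dict[str, float]
    var_E: float
    var_g: float
    var_e: float
    converged: bool
    n_iterations: int
    #: REML log-likelihood up to a constant (-0.5 * profiled deviance)
    loglik: float = field(default=np.nan, repr=False)

    @property
    def trained_genotypes(self) -> list[str]:
        return list(self.genomic_blups)


class _RemlProblem:
    """Cross-products and MME assembly for one training set."""

    def __init__(self, dataset: MetDataset, grmat: GenomicRelationship):
        records = dataset.phenotypes
        if not records:
            raise FitError("no phenotype records to fit")
        self.env_ids = sorted({r.env_id for r in records})
        geno_in_data = {r.genotype_id for r in records}
        # genotype order follows the GRM for reproducible indexing
        self.geno_ids = [g for g in grmat.genotype_ids if g in geno_in_data]
        missing = geno_in_data - set(self.geno_ids)
        if missing:
            raise ValidationError(
                f"phenotyped genotypes not in GRM: {sorted(missing)[:5]}")
        if len(self.env_ids) < 1 or len(self.geno_ids) < 2:
            raise FitError("need >= 2 genotypes with records")
        e_index = {e: i for i, e in enumerate(self.env_ids)}
        g_index = {g: i for i, g in enumerate(self.geno_ids)}
        self.n = len(records)
        self.J = len(self.env_ids)
        self.I = len(self.geno_ids)
        y = np.array([r.dth for r in records], dtype=float)
        ei = np.array([e_index[r.env_id] for r in records])
        gi = np.array([g_index[r.genotype_id] for r in records])

        self.yty = float(y @ y)
        env_counts = np.bincount(ei, minlength=self.J).astype(float)
        geno_counts = np.bincount(gi, minlength=self.I).astype(float)
        # (genotype, env) incidence cross-counts
        N = np.zeros((self.J, self.I))
        np.add.at(N, (ei, gi), 1.0)

        q = 1 + self.J + self.I
        C0 = np.zeros((q, q))
        C0[0, 0] = self.n
        C0[0, 1:1 + self.J] = env_counts
        C0[1:1 + self.J, 0] = env_counts
        C0[0, 1 + self.J:] = geno_counts
        C0[1 + self.J:, 0] = geno_counts
        C0[1:1 + self.J, 1:1 + self.J] = np.diag(env_counts)
        C0[1:1 + self.J, 1 + self.J:] = N
        C0[1 + self.J:, 1:1 + self.J] = N.T
        C0[1 + self.J:, 1 + self.J:] = np.diag(geno_counts)
        self.C0 = C0

        rhs = np.empty(q)
        rhs[0] = y.sum()
        rhs[1:1 + self.J] = np.bincount(ei, weights=y, minlength=self.J)
        rhs[1 + self.J:] = np.bincount(gi, weights=y, minlength=self.I)
        self.rhs = rhs

        G = grmat.subset(self.geno_ids) + G_JITTER * np.eye(self.I)
        try:
            self.G_chol = linalg.cho_factor(G, lower=True)
        except linalg.LinAlgError:
            raise FitError("genomic relationship matrix is not positive "
                           "definite even after jitter") from None
        self.Ginv = linalg.cho_solve(self.G_chol, np.eye(self.I))
        self.logdetG = 2.0 * float(
            np.sum(np.log(np.diag(self.G_chol[0]))))

    def deviance(self, log_lam: np.ndarray) -> float:
        """-2 * profiled restricted log-likelihood (up to a constant)."""
        out = self._solve(log_lam)
        return out["deviance"]

    def _solve(self, log_lam: np.ndarray) -> dict:
        lam_E = float(np.exp(np.clip(log_lam[0], -_LOG_RATIO_BOUND,
                                     _LOG_RATIO_BOUND)))
        lam_g = float(np.exp(np.clip(log_lam[1], -_LOG_RATIO_BOUND,
                                     _LOG_RATIO_BOUND)))
        C = self.C0.copy()
        idx = np.arange(1, 1 + self.J)
        C[idx, idx] += 1.0 / lam_E
        C[1 + self.J:, 1 + self.J:] += self.Ginv / lam_g
        try:
            cf = linalg.cho_factor(C, lower=True)
        except linalg.LinAlgError:
            return {"deviance": np.inf}
        sol = linalg.cho_solve(cf, self.rhs)
        logdetC = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        yPy = max(self.yty - float(self.rhs @ sol), 0.0)
        s2e = max(yPy / (self.n - 1), 1e-12)
        dev = ((self.n - 1) * np.log(s2e)
               + self.J * np.log(lam_E) + self.I * np.log(lam_g)
               + self.logdetG + logdetC)
        return {"deviance": dev, "sol": sol, "s2e": s2e,
                "lam_E": lam_E, "lam_g": lam_g}


def fit(dataset: MetDataset, grmat: GenomicRelationship,
        fixed_ratios: tuple[float, float] | None = None,
        max_iter: int = 200) -> GblupFit:
    """REML fit of the GBLUP model on a MET dataset.

    Parameters
    ----------
    dataset : MetDataset
        Training records; every phenotyped genotype must be in `grmat`.
    grmat : GenomicRelationship
        Genomic relationship matrix covering the training genotypes.
    fixed_ratios : (float, float), optional
        Hold the variance ratios (sigma2_E/sigma2_e, sigma2_g/sigma2_e)
        fixed instead of estimating them; the residual variance is still
        profiled.  Used for oracle comparisons and fast approximations.
    max_iter : int
        Iteration cap for the Nelder-Mead refinement.
    """
    prob = _RemlProblem(dataset, grmat)

    if fixed_ratios is not None:
        log_lam = np.log(np.asarray(fixed_ratios, dtype=float))
        out = prob._solve(log_lam)
        converged, n_iter = True, 0
    else:
        grid = np.log(10.0 ** np.linspace(-4.0, 4.0, 9))
        best, best_val = None, np.inf
        for a in grid:
            for b in grid:
                val = prob.deviance(np.array([a, b]))
                if val < best_val:
                    best, best_val = np.array([a, b]), val
        res = optimize.minimize(
            prob.deviance, best, method="Nelder-Mead",
            options={"maxiter": max_iter, "xatol": 1e-6, "fatol": 1e-8})
        out = prob._solve(res.x)
        converged, n_iter = bool(res.success), int(res.nit)

    if "sol" not in out:
        raise FitError("mixed-model equations are singular")
    sol, s2e = out["sol"], out["s2e"]
    mu = float(sol[0])
    env_effects = {e: float(v) for e, v in
                   zip(prob.env_ids, sol[1:1 + prob.J])}
    blups = {g: float(v) for g, v in
             zip(prob.geno_ids, sol[1 + prob.J:])}
    return GblupFit(
        mu=mu, env_effects=env_effects, genomic_blups=blups,
        var_E=out["lam_E"] * s2e, var_g=out["lam_g"] * s2e, var_e=s2e,
        converged=converged, n_iterations=n_iter,
        loglik=-0.5 * out["deviance"])


def blup_for_untested(fit: GblupFit, grmat: GenomicRelationship,
                      target_ids: list[str]) -> dict[str, float]:
    """Genomic BLUPs for genotypes with no phenotype records.

    Projects the trained BLUPs through the relationship matrix:
    g_hat_target = G[target, trained] G[trained, trained]^-1 g_hat_trained.
    A target genotype with zero covariance to every trained genotype gets
    exactly 0 (the prior mean).
    """
    trained = fit.trained_genotypes
    overlap = set(target_ids) & set(trained)
    if overlap:
        raise ValidationError(
            f"target genotypes already phenotyped in the fit: "
            f"{sorted(overlap)[:5]}")
    g_hat = np.array([fit.genomic_blups[g] for g in trained])
    GTT = grmat.subset(trained) + G_JITTER * np.eye(len(trained))
    try:
        w = linalg.cho_factor(GTT, lower=True)
        alpha = linalg.cho_solve(w, g_hat)
    except linalg.LinAlgError:
        raise FitError("G[trained, trained] singular after jitter") from None
    cross = grmat.cross(list(target_ids), trained)
    proj = cross @ alpha
    return {t: float(v) for t, v in zip(target_ids, proj)}


def predict_gs(fit: GblupFit, genotype_id: str, env_id: str,
               scheme: str = "cv00",
               grmat: GenomicRelationship | None = None) -> float:
    """Conventional genomic-selection prediction for an unobserved
    environment: mu_hat + g_hat_i, with the environment effect at its
    prior mean of zero.

    The fit must have been trained without the target environment; under
    cv00 the target genotype must also be absent (its BLUP then comes from
    the relationship-matrix projection, which needs `grmat`).
    """
    if env_id in fit.env_effects:
        raise ValidationError(
            f"environment {env_id} was in the training set; refit without it")
    if genotype_id in fit.genomic_blups:
        if scheme == "cv00":
            raise ValidationError(
                f"genotype {genotype_id} was phenotyped in the training set; "
                "cv00 requires it excluded")
        g_hat = fit.genomic_blups[genotype_id]
    else:
        if grmat is None:
            raise ValidationError(
                f"genotype {genotype_id} has no BLUP and no GRM was given "
                "for projection")
        g_hat = blup_for_untested(fit, grmat, [genotype_id])[genotype_id]
    return float(fit.mu + g_hat)
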