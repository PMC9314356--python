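"""Logistic-regression association testing and variance-explained measures.

Fits use Newton/IRLS (max 100 iterations, coefficient-change tolerance 1e-8);
complete separation is flagged when any coefficient diverges past |beta| > 20.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GenotypeStudy
from .stratify import StratifiedCohort

log = logging.getLogger(__name__)

MAX_ITER = 100
TOL = 1e-8
SEPARATION_BOUND = 20.0


@dataclass
class LogisticFit:
    """One fitted logistic model plus its covariate-only null."""

    params: pd.Series           # coefficient per term (incl. "const")
    bse: pd.Series              # standard errors
    zvalues: pd.Series
    pvalues: pd.Series
    llf: float                  # log-likelihood, full model
    llnull: float               # log-likelihood, covariate-only model
    nobs: int
    n_events: int               # samples with y = 1 (the "resilient" group)
    converged: bool

    def term(self, name: str) -> tuple[float, float, float]:
        """(beta, se, p) for one term."""
        return float(self.params[name]), float(self.bse[name]), float(self.pvalues[name])


@dataclass
class VarianceExplained:
    """Observed- and liability-scale variance explained by a score."""

    nagelkerke_r2: float
    liability_r2: float
    prevalence_k: float
    case_proportion_p: float


class SeparationError(RuntimeError):
    pass


class ConvergenceError(RuntimeError):
    pass


def _irls(X: np.ndarray, y: np.ndarray, max_iter: int = MAX_ITER,
          tol: float = TOL) -> tuple[np.ndarray, np.ndarray, float]:
    """Newton-Raphson logistic fit; returns (beta, se, log-likelihood)."""
    from scipy.special import expit

    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        XtW = X.T * w
        H = XtW @ X
        grad = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as err:
            raise ConvergenceError(f"singular information matrix: {err}") from err
        beta_new = beta + step
        if np.max(np.abs(beta_new)) > SEPARATION_BOUND:
            raise SeparationError("coefficients diverging (complete separation?)")
        done = np.max(np.abs(beta_new - beta)) < tol
        beta = beta_new
        if done:
            break
    else:
        raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations")
    eta = X @ beta
    mu = expit(eta)
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    cov = np.linalg.inv((X.T * w) @ X)
    se = np.sqrt(np.diag(cov))
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    return beta, se, ll


def fit_logistic(X: pd.DataFrame, y: np.ndarray,
                 null_columns: Optional[Sequence[str]] = None) -> LogisticFit:
    """Fit ``y ~ X`` by IRLS, plus the covariate-only null for pseudo-R2.

    ``X`` must already contain an intercept column ``const``; ``null_columns``
    names the terms of the null model (default: every column except the first
    non-const one, i.e. all covariates).
    """
    names = list(X.columns)
    Xm = X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    beta, se, ll = _irls(Xm, y)
    if null_columns is None:
        score_terms = [c for c in names if c != "const"][:1]
        null_columns = [c for c in names if c not in score_terms]
    Xn = X[list(null_columns)].to_numpy(dtype=float)
    _, _, llnull = _irls(Xn, y)
    z = beta / se
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    return LogisticFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(se, index=names),
        zvalues=pd.Series(z, index=names),
        pvalues=pd.Series(pvals, index=names),
        llf=ll,
        llnull=llnull,
        nobs=len(y),
        n_events=int(y.sum()),
        converged=True,
    )


def _analysis_frame(study: GenotypeStudy, cohort: StratifiedCohort,
                    covariates: Sequence[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Subset the study to the stratified groups.

    Returns (sample row indices, y, covariate matrix).  ``y`` is 1 for the
    resilient group, 0 for risk-matched cases.
    """
    ids = study.samples["sample_id"]
    pos = pd.Series(np.arange(study.n_samples), index=ids)
    res = pos.reindex(cohort.resilient_ids).dropna().astype(int).to_numpy()
    mat = pos.reindex(cohort.risk_matched_case_ids).dropna().astype(int).to_numpy()
    idx = np.concatenate([res, mat])
    y = np.concatenate([np.ones(len(res)), np.zeros(len(mat))])
    for c in covariates:
        if c not in study.samples.columns:
            raise KeyError(f"covariate {c!r} missing from study {study.study_id}")
    C = study.samples.iloc[idx][list(covariates)].to_numpy(dtype=float)
    return idx, y, C


def run_resilience_gwas(study: GenotypeStudy, cohort: StratifiedCohort,
                        covariates: Sequence[str] = ()) -> pd.DataFrame:
    """Per-variant logistic GWAS of resilient (1) vs risk-matched case (0).

    Monomorphic variants within the analysis subset are skipped, as are
    variants whose fit separates or fails to converge (all logged).  Output
    columns follow the summary-statistics convention (beta = log OR per
    effect allele).
    """
    if cohort.n_resilient < 2 or cohort.n_risk_matched < 2:
        raise ValueError("need at least two samples per group")
    idx, y, C = _analysis_frame(study, cohort, covariates)
    n = len(y)
    X = np.empty((n, 2 + C.shape[1]))
    X[:, 0] = 1.0
    X[:, 2:] = C
    dos = study.dosages[idx]
    skipped = {"monomorphic": 0, "separated": 0, "nonconverged": 0}
    out = []
    for j in range(study.n_variants):
        g = dos[:, j]
        if np.ptp(g) == 0:
            skipped["monomorphic"] += 1
            continue
        X[:, 1] = g
        try:
            beta, se, _ = _irls(X, y)
        except SeparationError:
            skipped["separated"] += 1
            continue
        except ConvergenceError:
            skipped["nonconverged"] += 1
            continue
        out.append((j, beta[1], se[1]))
    if any(skipped.values()):
        log.info("resilience GWAS[%s]: skipped %s", study.study_id, skipped)
    if not out:
        raise ValueError(f"no variant could be tested in {study.study_id}")
    jj, bb, ss = map(np.asarray, zip(*out))
    v = study.variants.iloc[jj.astype(int)].reset_index(drop=True)
    zz = bb / ss
    return pd.DataFrame({
        "snp_id": v["snp_id"], "chrom": v["chrom"], "pos": v["pos"],
        "effect_allele": v["effect_allele"], "other_allele": v["other_allele"],
        "beta": bb, "se": ss,
        "p": np.clip(2.0 * sps.norm.sf(np.abs(zz)), 1e-300, 1.0),
    })


def evaluate_score(study: GenotypeStudy, cohort: StratifiedCohort,
                   scores: pd.Series,
                   covariates: Sequence[str] = ()) -> LogisticFit:
    """Regress resilient-group inclusion on a standardized polygenic score.

    ``scores`` is indexed by sample_id (raw scale); it is standardized to
    mean 0 / SD 1 over the analyzed subset so the reported lnOR is per score
    SD.  Zero score variance is fatal for the study.
    """
    idx, y, C = _analysis_frame(study, cohort, covariates)
    s = scores.reindex(study.samples["sample_id"].iloc[idx]).to_numpy(dtype=float)
    if np.isnan(s).any():
        raise ValueError("score missing for some analyzed samples")
    sd = s.std(ddof=0)
    if sd == 0:
        raise ValueError(f"zero score variance in study {study.study_id}")
    s = (s - s.mean()) / sd
    X = pd.DataFrame({"const": 1.0, "score": s})
    for k, c in enumerate(covariates):
        X[c] = C[:, k]
    return fit_logistic(X, y, null_columns=["const", *covariates])


def nagelkerke_r2(fit: LogisticFit) -> float:
    """Nagelkerke pseudo-R2 of the full model against its covariate-only null:

        R2 = [1 - exp(2 (LL0 - LL1) / n)] / [1 - exp(2 LL0 / n)]
    """
    if fit.nobs == 0:
        raise ValueError("empty fit")
    n = fit.nobs
    cox_snell = 1.0 - np.exp(2.0 * (fit.llnull - fit.llf) / n)
    denom = 1.0 - np.exp(2.0 * fit.llnull / n)
    if denom == 0:
        return 0.0
    return float(cox_snell / denom)


def liability_scale_r2(obs_r2: float, K: float, P: float,
                       ascertainment_correction: bool = True) -> float:
    """Convert observed-scale R2 to the liability scale.

    Uses the threshold-model conversion with conversion factor
    ``C = K(1-K)/z^2 * K(1-K)/(P(1-P))`` where ``z`` is the standard-normal
    density at the ``(1-K)`` quantile.  With ``ascertainment_correction``
    (the default) the case-enrichment second-order term is applied:

        R2_liab = C R2 / (1 + C theta R2),
        theta = m (P-K)/(1-K) * (m (P-K)/(1-K) - t),

    with ``t`` the liability threshold and ``m = z/K`` the mean case
    liability.
    """
    if not (0 < K < 1 and 0 < P < 1):
        raise ValueError("K and P must be in (0, 1)")
    t = sps.norm.isf(K)
    z = sps.norm.pdf(t)
    C = K * (1 - K) / z**2 * K * (1 - K) / (P * (1 - P))
    if not ascertainment_correction:
        return float(C * obs_r2)
    m = z / K
    theta = m * (P - K) / (1 - K) * (m * (P - K) / (1 - K) - t)
    return float(C * obs_r2 / (1.0 + C * theta * obs_r2))


def variance_explained(fit: LogisticFit, K: float,
                       ascertainment_correction: bool = True) -> VarianceExplained:
    """Bundle Nagelkerke and liability-scale R2 for one evaluation fit."""
    r2 = nagelkerke_r2(fit)
    P = fit.n_events / fit.nobs
    return VarianceExplained(
        nagelkerke_r2=r2,
        liability_r2=liability_scale_r2(r2, K, P, ascertainment_correction),
        prevalence_k=K,
        case_proportion_p=P,
    )
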