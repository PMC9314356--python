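"""Resilience-score derivation at multiple P thresholds, replication-cohort
evaluation, risk/resilience correlation contrast, and the end-to-end driver.

The driver wires together: simulation -> risk PRS -> stratification (designs
1/2) -> per-study resilience GWAS -> genomic-control random-effects meta ->
risk-variant exclusion -> LD clumping -> threshold score weights -> scoring
and evaluation on held-out replication studies -> risk/resilience
correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import assoc, ld, meta as meta_mod, prs as prs_mod, stratify
from .io import GenotypeStudy, Region, ScoreWeights
from .simulate import (MAJOR_LOCUS_ID, SimulationConfig, make_prior_risk_gwas,
                       simulate_cohorts, simulate_reference_panel)

log = logging.getLogger(__name__)

#: default escalating P-value threshold series (10 values)
DEFAULT_THRESHOLDS = (5e-8, 1e-5, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.2, 0.3, 0.5)

APOE_REGION = Region("19", 44_400_000, 46_500_000)


@dataclass
class ThresholdResult:
    """Evaluation outcome for one P-value threshold."""

    threshold: float
    weights: ScoreWeights
    meta: Optional[meta_mod.MetaResult] = None
    pooled_nagelkerke_r2: Optional[float] = None
    pooled_liability_r2: Optional[float] = None
    per_study: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_variants(self) -> int:
        return len(self.weights)


@dataclass
class ThresholdSeries:
    """Ordered, nested score-weight sets across escalating P thresholds."""

    thresholds: tuple
    results: dict  # threshold -> ThresholdResult

    def __post_init__(self):
        ts = list(self.thresholds)
        if ts != sorted(ts) or len(set(ts)) != len(ts):
            raise ValueError("thresholds must be strictly increasing")

    def weights(self, t: float) -> ScoreWeights:
        return self.results[t].weights

    def summary(self) -> pd.DataFrame:
        rows = []
        for t in self.thresholds:
            r = self.results[t]
            row = {"threshold": t, "n_variants": r.n_variants}
            if r.meta is not None:
                row.update(OR=r.meta.odds_ratio, ci_low=r.meta.or_ci[0],
                           ci_high=r.meta.or_ci[1], p=r.meta.p, k=r.meta.k,
                           tau2=r.meta.tau2,
                           nagelkerke_r2=r.pooled_nagelkerke_r2,
                           liability_r2=r.pooled_liability_r2)
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class CorrelationContrast:
    """Pearson correlation of PRS vs resilience score, controls vs cases."""

    r_controls: float
    ci_controls: tuple
    p_controls: float
    n_controls: int
    r_cases: float
    ci_cases: tuple
    p_cases: float
    n_cases: int
    z_diff: float
    p_one_tailed: float
    n_trimmed_cases: int = 0
    n_trimmed_controls: int = 0


def build_resilience_weights(marginal: pd.DataFrame,
                             thresholds: Sequence[float] = DEFAULT_THRESHOLDS
                             ) -> ThresholdSeries:
    """Per threshold ``t``, weights = {(snp, effect allele, lnOR): P < t}.

    Empty sets are allowed (and logged); all-empty is fatal.
    """
    results = {}
    any_nonempty = False
    for t in thresholds:
        table = marginal.loc[marginal["p"] < t,
                             ["snp_id", "effect_allele", "beta"]]
        table = table.rename(columns={"beta": "weight"}).reset_index(drop=True)
        if table.empty:
            log.info("threshold %g: empty weight set", t)
        else:
            any_nonempty = True
        results[t] = ThresholdResult(
            threshold=t,
            weights=ScoreWeights(table=table, p_threshold=t,
                                 provenance="resilience"),
        )
    if not any_nonempty:
        raise ValueError("every threshold produced an empty weight set")
    return ThresholdSeries(thresholds=tuple(thresholds), results=results)


def score_and_evaluate(replication_studies: Sequence[GenotypeStudy],
                       labels: dict, series: ThresholdSeries,
                       covariates: Sequence[str] = (),
                       prevalence_k: Optional[float] = None,
                       ascertainment_correction: bool = True) -> ThresholdSeries:
    """Score replication studies at each threshold and meta-analyze.

    ``labels`` maps study_id -> StratifiedCohort (replication-stage labels of
    the same design the weights came from).  Per threshold: scores are
    computed, standardized within study, regressed on group, pooled by
    DerSimonian-Laird, and per-study Nagelkerke/liability R2 pooled with the
    meta weights.  Studies without overlapping variants at a threshold are
    excluded from that threshold's meta (logged).
    """
    if prevalence_k is None:
        n_res = sum(c.n_resilient for c in labels.values())
        n_all = sum(c.n_resilient + c.n_risk_matched for c in labels.values())
        prevalence_k = n_res / n_all if n_all else 0.5
    for t in series.thresholds:
        result = series.results[t]
        if len(result.weights) == 0:
            continue
        rows = []
        for study in replication_studies:
            cohort = labels.get(study.study_id)
            if cohort is None:
                continue
            try:
                scored = prs_mod.compute_prs(study, result.weights)
                fit = assoc.evaluate_score(
                    study, cohort,
                    scored.table.set_index("sample_id")["score"],
                    covariates=covariates,
                )
            except ValueError as err:
                log.warning("threshold %g: study %s excluded (%s)",
                            t, study.study_id, err)
                continue
            beta, se, p = fit.term("score")
            ve = assoc.variance_explained(fit, prevalence_k,
                                          ascertainment_correction)
            rows.append({
                "study_id": study.study_id, "beta": beta, "se": se, "p": p,
                "n": fit.nobs, "n_resilient": fit.n_events,
                "nagelkerke_r2": ve.nagelkerke_r2,
                "liability_r2": ve.liability_r2,
            })
        if not rows:
            log.warning("threshold %g: no study could be evaluated", t)
            continue
        per_study = pd.DataFrame(rows)
        pooled = meta_mod.meta_random(per_study["beta"], per_study["se"])
        result.meta = pooled
        result.per_study = per_study
        result.pooled_nagelkerke_r2 = meta_mod.pool_r2(
            per_study["nagelkerke_r2"], pooled.weights)
        result.pooled_liability_r2 = meta_mod.pool_r2(
            per_study["liability_r2"], pooled.weights)
    return series


def _fisher_ci(r: float, n: int, alpha: float = 0.05) -> tuple:
    z = np.arctanh(r)
    half = sps.norm.isf(alpha / 2) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def correlate_risk_resilience(prs_scores: pd.Series, res_scores: pd.Series,
                              is_case: pd.Series,
                              trim: bool = True) -> CorrelationContrast:
    """Contrast the PRS/resilience-score correlation in controls vs cases.

    Inputs are pooled, sample-indexed series over the full cohorts (not just
    stratified subsets).  With ``trim``, ultra-high-risk cases (PRS above the
    control maximum) and ultra-low-risk controls (PRS below the case minimum)
    are excluded first.  The one-tailed comparison tests r_controls >
    r_cases via independent Fisher z.
    """
    df = pd.DataFrame({"prs": prs_scores, "res": res_scores,
                       "is_case": is_case}).dropna()
    cases = df[df["is_case"]]
    controls = df[~df["is_case"]]
    n_tc = n_tk = 0
    if trim and len(cases) and len(controls):
        max_ctrl = controls["prs"].max()
        min_case = cases["prs"].min()
        n_tc = int((cases["prs"] > max_ctrl).sum())
        n_tk = int((controls["prs"] < min_case).sum())
        cases = cases[cases["prs"] <= max_ctrl]
        controls = controls[controls["prs"] >= min_case]
        if n_tc or n_tk:
            log.info("correlation trim: excluded %d ultra-high-risk cases, "
                     "%d ultra-low-risk controls", n_tc, n_tk)
    if len(cases) < 4 or len(controls) < 4:
        raise ValueError("need at least 4 cases and 4 controls for the contrast")
    r1, p1 = sps.pearsonr(controls["prs"], controls["res"])
    r2, p2 = sps.pearsonr(cases["prs"], cases["res"])
    n1, n2 = len(controls), len(cases)
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    return CorrelationContrast(
        r_controls=float(r1), ci_controls=_fisher_ci(r1, n1), p_controls=float(p1),
        n_controls=n1,
        r_cases=float(r2), ci_cases=_fisher_ci(r2, n2), p_cases=float(p2),
        n_cases=n2,
        z_diff=float(z), p_one_tailed=float(sps.norm.sf(z)),
        n_trimmed_cases=n_tc, n_trimmed_controls=n_tk,
    )


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything needed for one simulated end-to-end run."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    n_discovery_studies: int = 2
    designs: tuple = (1,)
    risk_p_threshold: float = 0.5
    design1_percentile: float = 90.0
    design2_percentile: float = 80.0
    excluded_region: Region = APOE_REGION
    min_age: float = 60.0
    thresholds: tuple = DEFAULT_THRESHOLDS
    r2_max: float = ld.DEFAULT_R2_MAX
    window_bp: int = ld.DEFAULT_WINDOW_BP
    genomic_control: bool = True
    use_age_sex_covariates: bool = True
    n_pcs_covariates: Optional[int] = None   # None = all simulated PCs
    n_effective_prior: int = 300_000
    prevalence_k: Optional[float] = None
    trim_correlation: bool = True
    correlation_threshold: float = 0.1

    def __post_init__(self):
        if not 0 < self.n_discovery_studies < self.sim.n_studies:
            raise ValueError(
                "n_discovery_studies must leave at least one replication study"
            )
        for d in self.designs:
            if d not in (1, 2):
                raise ValueError(f"unknown design {d}")

    def covariate_names(self, study: GenotypeStudy) -> list[str]:
        names = ["age", "sex"] if self.use_age_sex_covariates else []
        pcs = study.pc_columns
        if self.n_pcs_covariates is not None:
            pcs = pcs[: self.n_pcs_covariates]
        return names + pcs


@dataclass
class DesignReport:
    """All artifacts of one design within a pipeline run."""

    design: int
    discovery_cohorts: dict
    replication_cohorts: dict
    discovery_accounting: pd.DataFrame
    replication_accounting: pd.DataFrame
    gc_lambdas: dict
    resilience_meta: pd.DataFrame
    marginal: pd.DataFrame
    series: ThresholdSeries

    def summary(self) -> pd.DataFrame:
        return self.series.summary()


@dataclass
class PipelineReport:
    config: PipelineConfig
    designs: dict                     # design number -> DesignReport
    correlation: Optional[CorrelationContrast]
    discovery_ids: list
    replication_ids: list


def run_pipeline(cfg: PipelineConfig) -> PipelineReport:
    """Execute the full workflow on simulated cohorts.

    The first ``n_discovery_studies`` simulated studies form the discovery
    set; the rest are held out for replication (the split is disjoint by
    construction).  The risk-orthogonality certificate is asserted on every
    run.
    """
    studies, truth = simulate_cohorts(cfg.sim)
    panel = simulate_reference_panel(cfg.sim)
    prior = make_prior_risk_gwas(panel, truth, cfg.n_effective_prior)

    studies = [stratify.filter_age(s, cfg.min_age) for s in studies]
    discovery = studies[: cfg.n_discovery_studies]
    replication = studies[cfg.n_discovery_studies:]
    ld_panel = ld.LDPanel.from_studies(discovery, window_bp=cfg.window_bp)

    weights_full = prs_mod.build_risk_weights(
        prior, cfg.risk_p_threshold, None, provenance="risk-full")
    weights_no_region = prs_mod.build_risk_weights(
        prior, cfg.risk_p_threshold, cfg.excluded_region,
        provenance="risk-excised")

    reports = {}
    for design in cfg.designs:
        disc_cohorts, rep_cohorts = {}, {}
        for study in studies:
            if design == 1:
                scored = prs_mod.compute_prs(study, weights_full)
                cohort = stratify.select_design1(
                    study, scored, cfg.design1_percentile)
            else:
                scored = prs_mod.compute_prs(study, weights_no_region)
                carrier = stratify.major_allele_carriers(study, MAJOR_LOCUS_ID)
                cohort = stratify.select_design2(
                    study, scored, carrier, cfg.design2_percentile)
            if cohort is None:
                continue
            target = (disc_cohorts if study in discovery else rep_cohorts)
            target[study.study_id] = cohort

        if not disc_cohorts or not rep_cohorts:
            raise RuntimeError(
                f"design {design}: no viable discovery or replication study"
            )

        per_study_stats, lambdas = [], {}
        for study in discovery:
            cohort = disc_cohorts.get(study.study_id)
            if cohort is None:
                continue
            stats_ = assoc.run_resilience_gwas(
                study, cohort, covariates=cfg.covariate_names(study))
            _, lam = meta_mod.genomic_control(stats_)
            lambdas[study.study_id] = lam
            per_study_stats.append(stats_)
        meta_stats = meta_mod.meta_gwas(per_study_stats, gc=cfg.genomic_control)

        survivors = ld.exclude_risk_variants(
            meta_stats, prior, ld_panel, risk_p=cfg.risk_p_threshold,
            r2_max=cfg.r2_max, window_bp=cfg.window_bp)
        marginal = ld.clump(survivors, ld_panel, r2_max=cfg.r2_max,
                            window_bp=cfg.window_bp)
        ld.risk_orthogonality_certificate(
            marginal, prior, ld_panel, risk_p=cfg.risk_p_threshold,
            r2_max=cfg.r2_max, window_bp=cfg.window_bp)

        series = build_resilience_weights(marginal, cfg.thresholds)
        series = score_and_evaluate(
            replication, rep_cohorts, series,
            covariates=cfg.covariate_names(replication[0]),
            prevalence_k=cfg.prevalence_k)

        reports[design] = DesignReport(
            design=design,
            discovery_cohorts=disc_cohorts,
            replication_cohorts=rep_cohorts,
            discovery_accounting=stratify.accounting_table(disc_cohorts.values()),
            replication_accounting=stratify.accounting_table(rep_cohorts.values()),
            gc_lambdas=lambdas,
            resilience_meta=meta_stats,
            marginal=marginal,
            series=series,
        )

    correlation = None
    if 1 in reports:
        series = reports[1].series
        t = cfg.correlation_threshold
        if t in series.results and len(series.results[t].weights):
            res_weights = series.results[t].weights
            frames = []
            for study in replication:
                prs_scores = prs_mod.compute_prs(study, weights_full)
                res_scores = prs_mod.compute_prs(study, res_weights)
                f = pd.DataFrame({
                    "sample_id": study.samples["sample_id"],
                    "prs": _standardize(prs_scores.table["score"].to_numpy()),
                    "res": _standardize(res_scores.table["score"].to_numpy()),
                    "is_case": study.is_case,
                })
                frames.append(f)
            pooled = pd.concat(frames, ignore_index=True).set_index("sample_id")
            try:
                correlation = correlate_risk_resilience(
                    pooled["prs"], pooled["res"], pooled["is_case"],
                    trim=cfg.trim_correlation)
            except ValueError as err:
                log.warning("correlation contrast skipped: %s", err)

    return PipelineReport(
        config=cfg,
        designs=reports,
        correlation=correlation,
        discovery_ids=[s.study_id for s in discovery],
        replication_ids=[s.study_id for s in replication],
    )


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()
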