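"""Genomic control and inverse-variance meta-analysis (fixed / DerSimonian-Laird).

Per-variant GWAS results are combined across studies with per-study genomic
control followed by random-effects pooling; the same machinery pools the
per-study score-evaluation lnORs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

CHI2_MEDIAN_1DF = float(sps.chi2.ppf(0.5, df=1))  # 0.4549...
CI_MULTIPLIER = 1.96


@dataclass
class MetaResult:
    """Pooled effect on the log scale plus heterogeneity diagnostics."""

    effect: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    tau2: float
    q: float
    i2: float
    k: int
    method: str                       # "fixed" | "random"
    study_effects: np.ndarray = field(default_factory=lambda: np.empty(0))
    study_ses: np.ndarray = field(default_factory=lambda: np.empty(0))
    weights: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.effect))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))


def genomic_control(stats: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Apply genomic-control inflation correction to one study's statistics.

    ``lambda = median(z^2) / 0.4549``; when ``lambda > 1`` all SEs are
    multiplied by ``sqrt(lambda)`` and P-values recomputed; otherwise the
    input is returned unchanged.
    """
    if len(stats) == 0:
        raise ValueError("no variants for genomic control")
    z2 = (stats["beta"].to_numpy() / stats["se"].to_numpy()) ** 2
    lam = float(np.median(z2) / CHI2_MEDIAN_1DF)
    if lam <= 1.0:
        return stats, lam
    out = stats.copy()
    out["se"] = out["se"] * np.sqrt(lam)
    z = out["beta"].to_numpy() / out["se"].to_numpy()
    out["p"] = np.clip(2.0 * sps.norm.sf(np.abs(z)), 1e-300, 1.0)
    log.info("genomic control: lambda = %.4f, SEs inflated", lam)
    return out, lam


def _pooled(effects: np.ndarray, ses: np.ndarray, tau2: float, q: float,
            method: str) -> MetaResult:
    w = 1.0 / (ses**2 + tau2)
    eff = float(np.sum(w * effects) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = eff / se
    k = len(effects)
    i2 = float(max(0.0, (q - (k - 1)) / q) * 100.0) if q > 0 else 0.0
    return MetaResult(
        effect=eff, se=se,
        ci_low=eff - CI_MULTIPLIER * se, ci_high=eff + CI_MULTIPLIER * se,
        p=float(np.clip(2.0 * sps.norm.sf(abs(z)), 1e-300, 1.0)),
        tau2=tau2, q=q, i2=i2, k=k, method=method,
        study_effects=effects, study_ses=ses, weights=w,
    )


def _check(effects, ses) -> tuple[np.ndarray, np.ndarray]:
    effects = np.asarray(effects, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if effects.size == 0 or effects.shape != ses.shape:
        raise ValueError("effects and ses must be equal-length and non-empty")
    if (ses <= 0).any():
        raise ValueError("standard errors must be positive")
    return effects, ses


def meta_fixed(effects: Sequence[float], ses: Sequence[float]) -> MetaResult:
    """Inverse-variance fixed-effect pooling; Q computed on the same weights."""
    effects, ses = _check(effects, ses)
    w = 1.0 / ses**2
    pooled = np.sum(w * effects) / np.sum(w)
    q = float(np.sum(w * (effects - pooled) ** 2))
    return _pooled(effects, ses, 0.0, q, "fixed")


def meta_random(effects: Sequence[float], ses: Sequence[float]) -> MetaResult:
    """DerSimonian-Laird random-effects pooling.

    ``tau2 = max(0, (Q - (k-1)) / (sum(w) - sum(w^2)/sum(w)))`` with fixed
    weights ``w = 1/se^2``; a single study passes through with tau2 = 0.
    """
    effects, ses = _check(effects, ses)
    k = len(effects)
    if k == 1:
        log.info("meta_random: single study, returning it unchanged")
        res = _pooled(effects, ses, 0.0, 0.0, "random")
        return res
    w = 1.0 / ses**2
    fixed = np.sum(w * effects) / np.sum(w)
    q = float(np.sum(w * (effects - fixed) ** 2))
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
    return _pooled(effects, ses, tau2, q, "random")


def _align_to_reference(stats: pd.DataFrame, ref: pd.DataFrame) -> pd.DataFrame:
    """Flip one study's betas onto the reference allele orientation.

    Irreconcilable allele pairs are dropped with a logged count.
    """
    m = stats.merge(ref, on="snp_id", suffixes=("", "_ref"))
    same = (m["effect_allele"] == m["effect_allele_ref"]) & (
        m["other_allele"] == m["other_allele_ref"])
    flip = (m["effect_allele"] == m["other_allele_ref"]) & (
        m["other_allele"] == m["effect_allele_ref"])
    bad = int((~(same | flip)).sum())
    if bad:
        log.warning("meta_gwas: dropped %d variants with irreconcilable alleles", bad)
    m = m.loc[same | flip].copy()
    f = flip.loc[m.index].to_numpy()
    m.loc[f, "beta"] = -m.loc[f, "beta"]
    m["effect_allele"] = m["effect_allele_ref"]
    m["other_allele"] = m["other_allele_ref"]
    return m[["snp_id", "beta", "se"]]


def meta_gwas(per_study_stats: Sequence[pd.DataFrame], gc: bool = True) -> pd.DataFrame:
    """Per-variant random-effects meta-analysis across studies.

    Each study is genomic-control corrected first (when ``gc``); alleles are
    harmonized to the orientation of the first study carrying each variant;
    variants present in any study are analyzed (union policy) and the number
    of contributing studies plus a +/- direction string are recorded.
    """
    if not per_study_stats:
        raise ValueError("no input studies")
    corrected = []
    for stats_ in per_study_stats:
        if gc:
            stats_, _ = genomic_control(stats_)
        corrected.append(stats_)
    # reference orientation: first occurrence of each variant
    ref = (
        pd.concat([s[["snp_id", "chrom", "pos", "effect_allele", "other_allele"]]
                   for s in corrected])
        .drop_duplicates("snp_id").reset_index(drop=True)
    )
    aligned = [_align_to_reference(s, ref) for s in corrected]
    n_snps = len(ref)
    order = pd.Series(np.arange(n_snps), index=ref["snp_id"])
    B = np.full((n_snps, len(aligned)), np.nan)
    S = np.full((n_snps, len(aligned)), np.nan)
    for j, s in enumerate(aligned):
        rows = order.loc[s["snp_id"]].to_numpy()
        B[rows, j] = s["beta"].to_numpy()
        S[rows, j] = s["se"].to_numpy()
    eff, se, tau2, q, kk = _dl_rowwise(B, S)
    z = eff / se
    direction = np.array([
        "".join("?" if not np.isfinite(b) else ("+" if b >= 0 else "-")
                for b in row)
        for row in B
    ])
    out = ref.copy()
    out["beta"] = eff
    out["se"] = se
    out["p"] = np.clip(2.0 * sps.norm.sf(np.abs(z)), 1e-300, 1.0)
    out["n_studies"] = kk
    out["direction"] = direction
    out["tau2"] = tau2
    out["q"] = q
    return out


def _dl_rowwise(B: np.ndarray, S: np.ndarray):
    """Vectorized DerSimonian-Laird across rows with missingness (NaN) support."""
    mask = np.isfinite(B) & np.isfinite(S)
    w = np.where(mask, 1.0 / np.where(mask, S, 1.0) ** 2, 0.0)
    k = mask.sum(axis=1)
    if (k == 0).any():
        raise ValueError("variant with no contributing study")
    sw = w.sum(axis=1)
    fixed = np.where(mask, w * B, 0.0).sum(axis=1) / sw
    q = np.where(mask, w * (np.where(mask, B, 0.0) - fixed[:, None]) ** 2, 0.0).sum(axis=1)
    c = sw - (w**2).sum(axis=1) / sw
    with np.errstate(invalid="ignore", divide="ignore"):
        tau2 = np.where((k > 1) & (c > 0), np.maximum(0.0, (q - (k - 1)) / c), 0.0)
    wr = np.where(mask, 1.0 / (np.where(mask, S, 1.0) ** 2 + tau2[:, None]), 0.0)
    swr = wr.sum(axis=1)
    eff = np.where(mask, wr * B, 0.0).sum(axis=1) / swr
    se = 1.0 / np.sqrt(swr)
    return eff, se, tau2, q, k


def pool_r2(r2_values: Sequence[float], meta_weights: Sequence[float]) -> float:
    """Weighted mean of per-study R2 using the random-effects meta weights."""
    r2 = np.asarray(r2_values, dtype=float)
    w = np.asarray(meta_weights, dtype=float)
    if r2.size == 0 or r2.shape != w.shape:
        raise ValueError("r2 values and weights must align")
    return float(np.sum(w * r2) / np.sum(w))
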