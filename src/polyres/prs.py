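"""Polygenic risk scoring: threshold weight selection, scoring, and
within-study percentile ranking."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import GenotypeStudy, Region, ScoreWeights

log = logging.getLogger(__name__)


@dataclass
class PRSResult:
    """Per-sample polygenic scores with optional within-study percentiles.

    ``table`` columns: ``sample_id, score`` and, after ranking,
    ``percentile`` (in ``[0, 100]``, strictly-below convention, ties share).
    """

    study_id: str
    table: pd.DataFrame
    p_threshold: Optional[float] = None
    excluded_region: Optional[Region] = None
    n_variants_used: int = 0

    def scores_for(self, sample_ids) -> np.ndarray:
        return (
            self.table.set_index("sample_id")["score"].reindex(sample_ids).to_numpy()
        )


def build_risk_weights(stats: pd.DataFrame, p_threshold: float,
                       excluded_region: Optional[Region] = None,
                       provenance: str = "risk") -> ScoreWeights:
    """Retain variants with ``p < p_threshold`` outside ``excluded_region``;
    the weight is the beta toward the effect allele."""
    keep = stats["p"].to_numpy() < p_threshold
    if excluded_region is not None:
        inside = excluded_region.contains(stats["chrom"], stats["pos"])
        keep &= ~inside
    table = stats.loc[keep, ["snp_id", "effect_allele", "beta"]].rename(
        columns={"beta": "weight"})
    if table.empty:
        raise ValueError(
            f"no variants survive p<{p_threshold} with region {excluded_region}"
        )
    log.info("built %s weights: %d of %d variants (p<%g, region=%s)",
             provenance, len(table), len(stats), p_threshold, excluded_region)
    return ScoreWeights(table=table.reset_index(drop=True),
                        p_threshold=p_threshold,
                        excluded_region=excluded_region,
                        provenance=provenance)


def compute_prs(study: GenotypeStudy, weights: ScoreWeights) -> PRSResult:
    """Score each sample as the weighted sum of effect-allele dosages.

    Weight effect alleles are aligned to the study's: a weight whose effect
    allele equals the study's *other* allele contributes via the complementary
    dosage ``2 - d`` (equivalently a sign flip plus constant).  Variants in
    the weight set absent from the study (or with irreconcilable alleles) are
    skipped with a logged count.
    """
    merged = weights.table.merge(
        study.variants[["snp_id", "effect_allele", "other_allele"]],
        on="snp_id", how="inner", suffixes=("_w", ""),
    )
    same = merged["effect_allele_w"] == merged["effect_allele"]
    flip = merged["effect_allele_w"] == merged["other_allele"]
    usable = merged.loc[same | flip]
    n_skipped = len(weights) - len(usable)
    if n_skipped:
        log.info("compute_prs[%s]: %d of %d weight variants absent or mismatched",
                 study.study_id, n_skipped, len(weights))
    if usable.empty:
        raise ValueError(
            f"no overlap between weights and study {study.study_id}"
        )
    indexer = study.variant_indexer()
    cols = indexer.loc[usable["snp_id"]].to_numpy()
    w = usable["weight"].to_numpy(dtype=float)
    flip_mask = flip.loc[usable.index].to_numpy()
    d = study.dosages[:, cols].astype(np.float64, copy=True)
    if flip_mask.any():
        d[:, flip_mask] = 2.0 - d[:, flip_mask]
    scores = d @ w
    table = pd.DataFrame({"sample_id": study.samples["sample_id"], "score": scores})
    return PRSResult(study_id=study.study_id, table=table,
                     p_threshold=weights.p_threshold,
                     excluded_region=weights.excluded_region,
                     n_variants_used=len(usable))


def percentile_of(scores, population_scores) -> np.ndarray:
    """Percentile of each score against a ranking population.

    ``percentile(s) = 100 * #{p in population : p < s} / |population|`` —
    tied scores share the same percentile.
    """
    pop = np.sort(np.asarray(population_scores, dtype=float))
    if pop.size == 0:
        raise ValueError("ranking population is empty")
    below = np.searchsorted(pop, np.asarray(scores, dtype=float), side="left")
    return 100.0 * below / pop.size


def rank_within_study(prs: PRSResult, population_ids: Sequence) -> PRSResult:
    """Attach percentiles ranked against the scores of ``population_ids``.

    Percentiles for *all* scored samples are computed relative to that
    population (e.g. cases can be placed on the control score distribution).
    """
    pop_scores = prs.scores_for(population_ids)
    if np.isnan(pop_scores).any():
        raise ValueError("ranking population contains unscored samples")
    table = prs.table.copy()
    table["percentile"] = percentile_of(table["score"].to_numpy(), pop_scores)
    return PRSResult(study_id=prs.study_id, table=table,
                     p_threshold=prs.p_threshold,
                     excluded_region=prs.excluded_region,
                     n_variants_used=prs.n_variants_used)
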