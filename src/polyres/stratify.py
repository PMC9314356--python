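"""Selection of resilient high-risk controls and risk-matched cases.

Design 1: controls at or above the 90th within-control PRS percentile are
"resilient"; cases whose PRS falls between the selection cutoff and the
maximum control PRS are "risk-matched".  Design 2 restricts both groups to
carriers of at least one major-effect (epsilon-4-like) allele, uses a PRS
with the chr19 exclusion region excised, and an 80th-percentile cutoff
computed within carrier controls.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .io import GenotypeStudy
from .prs import PRSResult, percentile_of

log = logging.getLogger(__name__)

MIN_GROUP_SIZE = 2  # per-study minimum for a viable resilience GWAS


@dataclass
class StratifiedCohort:
    """Per-study resilient/risk-matched labels and the cutoffs behind them."""

    study_id: str
    design: int
    resilient_ids: list
    risk_matched_case_ids: list
    control_cutoff_score: float
    control_max_score: float
    n_controls_total: int
    n_cases_total: int

    @property
    def n_resilient(self) -> int:
        return len(self.resilient_ids)

    @property
    def n_risk_matched(self) -> int:
        return len(self.risk_matched_case_ids)

    def counts(self) -> dict:
        return {
            "study": self.study_id,
            "n_high_risk": self.n_resilient,
            "n_controls": self.n_controls_total,
            "n_risk_matched": self.n_risk_matched,
            "n_cases": self.n_cases_total,
        }

    def labels(self) -> pd.DataFrame:
        """Long-format label table (sample_id, study_id, group)."""
        rows = [(s, self.study_id, "resilient") for s in self.resilient_ids]
        rows += [(s, self.study_id, "risk_matched") for s in self.risk_matched_case_ids]
        return pd.DataFrame(rows, columns=["sample_id", "study_id", "group"])


def filter_age(study: GenotypeStudy, min_age: float = 60.0) -> GenotypeStudy:
    """Retain cases with age-at-onset and controls with age-at-last-exam
    at or above ``min_age``."""
    keep = study.samples["age"].to_numpy() >= min_age
    n_removed = int((~keep).sum())
    if n_removed:
        log.info("filter_age[%s]: removed %d of %d samples below %g",
                 study.study_id, n_removed, study.n_samples, min_age)
    if not keep.any():
        raise ValueError(f"age filter removed every sample in {study.study_id}")
    if keep.all():
        return study
    return study.subset_samples(keep)


def _select(study_id: str, sample_table: pd.DataFrame, scores: np.ndarray,
            design: int, control_percentile: float) -> Optional[StratifiedCohort]:
    is_case = sample_table["status"].to_numpy() == 2
    ctrl_scores = scores[~is_case]
    case_scores = scores[is_case]
    n_controls, n_cases = int((~is_case).sum()), int(is_case.sum())
    if n_controls < MIN_GROUP_SIZE or n_cases < MIN_GROUP_SIZE:
        log.warning("%s dropped: %d controls / %d cases available",
                    study_id, n_controls, n_cases)
        return None
    pct = percentile_of(ctrl_scores, ctrl_scores)
    resilient_mask = pct >= control_percentile
    if resilient_mask.sum() < MIN_GROUP_SIZE:
        log.warning("%s dropped: only %d resilient controls",
                    study_id, int(resilient_mask.sum()))
        return None
    cutoff = float(ctrl_scores[resilient_mask].min())
    ctrl_max = float(ctrl_scores.max())
    matched_mask = (case_scores >= cutoff) & (case_scores <= ctrl_max)
    if matched_mask.sum() < MIN_GROUP_SIZE:
        log.warning("%s dropped: only %d risk-matched cases",
                    study_id, int(matched_mask.sum()))
        return None
    ids = sample_table["sample_id"]
    return StratifiedCohort(
        study_id=study_id,
        design=design,
        resilient_ids=ids[~is_case][resilient_mask].tolist(),
        risk_matched_case_ids=ids[is_case][matched_mask].tolist(),
        control_cutoff_score=cutoff,
        control_max_score=ctrl_max,
        n_controls_total=n_controls,
        n_cases_total=n_cases,
    )


def select_design1(study: GenotypeStudy, prs: PRSResult,
                   control_percentile: float = 90.0) -> Optional[StratifiedCohort]:
    """Design-1 stratification on the full-genome risk PRS.

    Returns ``None`` (with a logged reason) when either group would fall
    below the per-study minimum — such studies are dropped from the GWAS.
    """
    scores = prs.scores_for(study.samples["sample_id"])
    if np.isnan(scores).any():
        raise ValueError("PRS missing for some samples")
    return _select(study.study_id, study.samples, scores, 1, control_percentile)


def select_design2(study: GenotypeStudy, prs_no_apoe: PRSResult,
                   carrier: np.ndarray,
                   control_percentile: float = 80.0) -> Optional[StratifiedCohort]:
    """Design-2 stratification: major-allele carriers only, region-excised PRS.

    ``carrier`` is a per-sample boolean flag (aligned with ``study.samples``)
    for harboring at least one major-effect allele; percentiles are computed
    within carrier controls.
    """
    carrier = np.asarray(carrier, dtype=bool)
    if carrier.shape[0] != study.n_samples:
        raise ValueError("carrier flag length does not match study samples")
    if carrier.sum() < 2 * MIN_GROUP_SIZE:
        log.warning("%s dropped: only %d carriers", study.study_id, int(carrier.sum()))
        return None
    sub = study.samples.loc[carrier].reset_index(drop=True)
    scores = prs_no_apoe.scores_for(sub["sample_id"])
    if np.isnan(scores).any():
        raise ValueError("PRS missing for some carrier samples")
    return _select(study.study_id, sub, scores, 2, control_percentile)


def major_allele_carriers(study: GenotypeStudy, snp_id: str) -> np.ndarray:
    """Carrier flag from a dosage column (dosage >= 1 counts as carrying)."""
    idx = study.variant_indexer()
    if snp_id not in idx.index:
        raise KeyError(f"{snp_id} not present in study {study.study_id}")
    return study.dosages[:, int(idx[snp_id])] >= 1.0


# ---------------------------------------------------------------------------
# accounting
# ---------------------------------------------------------------------------

def _pct(numer: float, denom: float) -> float:
    """Percent retained, half-up to one decimal (0 when the denominator is 0)."""
    if denom == 0:
        return 0.0
    return float(np.floor(1000.0 * numer / denom + 0.5) / 10.0)


def accounting_table(cohorts: Iterable) -> pd.DataFrame:
    """Per-study and total retention accounting.

    Accepts ``StratifiedCohort`` objects or plain dicts with keys
    ``study, n_high_risk, n_controls, n_risk_matched, n_cases``.  Percentages
    are reported to one decimal; the total row recomputes them from summed
    counts.
    """
    rows = []
    for c in cohorts:
        rec = c.counts() if isinstance(c, StratifiedCohort) else dict(c)
        rows.append(rec)
    cols = ["study", "n_high_risk", "n_controls", "pct_controls_retained",
            "n_risk_matched", "n_cases", "pct_cases_retained"]
    if not rows:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(rows)
    df["pct_controls_retained"] = [
        _pct(a, b) for a, b in zip(df["n_high_risk"], df["n_controls"])
    ]
    df["pct_cases_retained"] = [
        _pct(a, b) for a, b in zip(df["n_risk_matched"], df["n_cases"])
    ]
    total = {
        "study": "Total",
        "n_high_risk": int(df["n_high_risk"].sum()),
        "n_controls": int(df["n_controls"].sum()),
        "n_risk_matched": int(df["n_risk_matched"].sum()),
        "n_cases": int(df["n_cases"].sum()),
    }
    total["pct_controls_retained"] = _pct(total["n_high_risk"], total["n_controls"])
    total["pct_cases_retained"] = _pct(total["n_risk_matched"], total["n_cases"])
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)[cols]


def load_reference_counts() -> pd.DataFrame:
    """Bundled per-study stratification counts from a published multi-study
    resilience analysis, used as accounting fixtures."""
    with importlib.resources.files("polyres.data").joinpath(
        "cohort_counts.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def reference_counts_records(stage: str, design: int,
                             counts: Optional[pd.DataFrame] = None) -> list[dict]:
    """Turn one stage/design slice of the bundled counts into accounting records."""
    df = counts if counts is not None else load_reference_counts()
    df = df[df["stage"] == stage]
    d = f"d{design}"
    return [
        {
            "study": r["study"],
            "n_high_risk": int(r[f"{d}_n_high_risk"]),
            "n_controls": int(r[f"{d}_n_controls"]),
            "n_risk_matched": int(r[f"{d}_n_risk_matched"]),
            "n_cases": int(r[f"{d}_n_cases"]),
        }
        for _, r in df.iterrows()
    ]
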