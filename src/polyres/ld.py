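"""LD-based risk-variant exclusion and greedy clumping.

LD is the squared Pearson correlation of dosage vectors (composite r2) in a
reference panel; pairs on different chromosomes or farther apart than the
window are treated as r2 = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .io import GenotypeStudy

log = logging.getLogger(__name__)

DEFAULT_R2_MAX = 0.2
DEFAULT_WINDOW_BP = 1_000_000


@dataclass
class LDPanel:
    """Reference dosages with coordinates for windowed r2 queries."""

    variants: pd.DataFrame          # snp_id, chrom, pos (panel column order)
    dosages: np.ndarray             # samples x variants
    window_bp: int = DEFAULT_WINDOW_BP
    _z: np.ndarray = field(init=False, repr=False)
    _ok: np.ndarray = field(init=False, repr=False)
    _index: pd.Series = field(init=False, repr=False)

    def __post_init__(self):
        d = np.asarray(self.dosages)
        if not np.issubdtype(d.dtype, np.floating):
            d = d.astype(np.float64)
        mu = d.mean(axis=0, dtype=np.float64)
        sd = d.std(axis=0, dtype=np.float64)
        self._ok = sd > 0
        n_bad = int((~self._ok).sum())
        if n_bad:
            log.info("LD panel: %d zero-variance variants excluded from r2", n_bad)
        safe_sd = np.where(self._ok, sd, 1.0)
        # standardized so z_i . z_j = r_ij; kept in the input dtype to bound memory
        z = d - mu.astype(d.dtype)
        z /= safe_sd.astype(d.dtype)
        z /= np.asarray(np.sqrt(d.shape[0]), dtype=d.dtype)
        self._z = z
        self.variants = self.variants.reset_index(drop=True)
        self._index = pd.Series(np.arange(len(self.variants)),
                                index=self.variants["snp_id"])

    @classmethod
    def from_study(cls, study: GenotypeStudy,
                   window_bp: int = DEFAULT_WINDOW_BP) -> "LDPanel":
        return cls(variants=study.variants[["snp_id", "chrom", "pos"]].copy(),
                   dosages=study.dosages, window_bp=window_bp)

    @classmethod
    def from_studies(cls, studies, window_bp: int = DEFAULT_WINDOW_BP) -> "LDPanel":
        """Union of several studies' samples sharing one variant map."""
        first = studies[0]
        for s in studies[1:]:
            if not first.variants["snp_id"].equals(s.variants["snp_id"]):
                raise ValueError("studies do not share a variant map")
        return cls(
            variants=first.variants[["snp_id", "chrom", "pos"]].copy(),
            dosages=np.vstack([s.dosages for s in studies]),
            window_bp=window_bp,
        )

    def col(self, snp_id: str) -> int:
        return int(self._index[snp_id])

    def r2(self, snp_a: str, snp_b: str) -> float:
        """Windowless pairwise r2 (NaN if either variant is zero-variance)."""
        i, j = self.col(snp_a), self.col(snp_b)
        if not (self._ok[i] and self._ok[j]):
            return float("nan")
        r = float(self._z[:, i] @ self._z[:, j])
        return r * r

    def r2_profile(self, target_col: int, other_cols: np.ndarray) -> np.ndarray:
        """r2 of one variant against a set of columns (zero-variance -> 0)."""
        r = self._z[:, other_cols].T @ self._z[:, target_col]
        r2 = r * r
        r2[~self._ok[other_cols]] = 0.0
        if not self._ok[target_col]:
            r2[:] = 0.0
        return r2

    def window_mates(self, col: int, candidate_cols: np.ndarray) -> np.ndarray:
        """Subset of ``candidate_cols`` on the same chromosome within the window."""
        chrom = self.variants["chrom"].to_numpy()
        pos = self.variants["pos"].to_numpy()
        near = (chrom[candidate_cols] == chrom[col]) & (
            np.abs(pos[candidate_cols] - pos[col]) <= self.window_bp
        )
        return candidate_cols[near]


def ld_r2(panel: LDPanel, snp_a: str, snp_b: str) -> float:
    return panel.r2(snp_a, snp_b)


def exclude_risk_variants(candidates: pd.DataFrame, risk: pd.DataFrame,
                          panel: LDPanel, risk_p: float = 0.5,
                          r2_max: float = DEFAULT_R2_MAX,
                          window_bp: Optional[int] = None) -> pd.DataFrame:
    """Remove risk-associated variants and their LD partners from candidates.

    Rule (a): drop every candidate whose risk-GWAS P is below ``risk_p``.
    Rule (b): drop every remaining candidate with r2 >= ``r2_max`` to any
    rule-(a) risk variant within the window on the same chromosome.
    Candidates absent from the risk GWAS are retained by rule (a) but remain
    subject to rule (b); counts removed by each rule are logged.
    """
    if window_bp is None:
        window_bp = panel.window_bp
    risk_p_by_id = risk.set_index("snp_id")["p"]
    cand_risk_p = candidates["snp_id"].map(risk_p_by_id)
    n_unknown = int(cand_risk_p.isna().sum())
    rule_a = (cand_risk_p < risk_p).fillna(False).to_numpy()

    # risk-associated set for rule (b): every risk-GWAS variant with P < risk_p
    # that the panel can place
    risk_ids = risk.loc[risk["p"] < risk_p, "snp_id"]
    risk_cols = panel._index.reindex(risk_ids).dropna().astype(int).to_numpy()

    survivors = candidates.loc[~rule_a]
    rule_b = np.zeros(len(survivors), dtype=bool)
    chrom = panel.variants["chrom"].to_numpy()
    pos = panel.variants["pos"].to_numpy()
    risk_by_chrom = {
        c: risk_cols[chrom[risk_cols] == c] for c in np.unique(chrom[risk_cols])
    } if risk_cols.size else {}
    for c, cols in risk_by_chrom.items():
        cols = cols[np.argsort(pos[cols])]
        risk_by_chrom[c] = cols
    for i, snp in enumerate(survivors["snp_id"]):
        if snp not in panel._index.index:
            continue  # not placeable; cannot test LD
        col = panel.col(snp)
        near = risk_by_chrom.get(chrom[col])
        if near is None or near.size == 0:
            continue
        lo = np.searchsorted(pos[near], pos[col] - window_bp, side="left")
        hi = np.searchsorted(pos[near], pos[col] + window_bp, side="right")
        window_cols = near[lo:hi]
        window_cols = window_cols[window_cols != col]
        if window_cols.size and (panel.r2_profile(col, window_cols) >= r2_max).any():
            rule_b[i] = True
    out = survivors.loc[~rule_b].reset_index(drop=True)
    log.info(
        "exclude_risk_variants: %d removed by risk P<%g, %d by LD (r2>=%g, %d bp); "
        "%d candidates with unknown risk P retained under rule (a); %d survive",
        int(rule_a.sum()), risk_p, int(rule_b.sum()), r2_max, window_bp,
        n_unknown, len(out),
    )
    if out.empty:
        raise ValueError(
            f"no candidate survives risk exclusion (risk_p={risk_p}, r2_max={r2_max}): "
            f"{int(rule_a.sum())} removed by rule (a), {int(rule_b.sum())} by rule (b)"
        )
    return out


def clump(candidates: pd.DataFrame, panel: LDPanel,
          r2_max: float = DEFAULT_R2_MAX,
          window_bp: Optional[int] = None) -> pd.DataFrame:
    """Greedy LD clumping by ascending P.

    Repeatedly takes the unclaimed variant with the smallest P (ties broken
    by chromosome then position) as an index and claims every unclaimed
    variant with r2 >= ``r2_max`` within the window; the index variants form
    the output, in input order.
    """
    if window_bp is None:
        window_bp = panel.window_bp
    df = candidates.reset_index(drop=True)
    order = df.sort_values(
        ["p", "chrom", "pos"], kind="mergesort"
    ).index.to_numpy()
    in_panel = df["snp_id"].isin(panel._index.index)
    if not in_panel.all():
        raise KeyError("clump: candidates missing from the LD panel")
    cols = panel._index.loc[df["snp_id"]].to_numpy()
    claimed = np.zeros(len(df), dtype=bool)
    is_index = np.zeros(len(df), dtype=bool)
    for i in order:
        if claimed[i]:
            continue
        claimed[i] = True
        is_index[i] = True
        free = np.flatnonzero(~claimed)
        if free.size == 0:
            break
        mates_cols = panel.window_mates(cols[i], cols[free])
        if mates_cols.size == 0:
            continue
        r2 = panel.r2_profile(cols[i], mates_cols)
        hit_cols = set(mates_cols[r2 >= r2_max].tolist())
        for j in free:
            if cols[j] in hit_cols:
                claimed[j] = True
    out = df.loc[is_index].reset_index(drop=True)
    log.info("clump: %d index variants from %d candidates (r2>=%g, %d bp)",
             len(out), len(df), r2_max, window_bp)
    return out


def risk_orthogonality_certificate(scored: pd.DataFrame, risk: pd.DataFrame,
                                   panel: LDPanel, risk_p: float = 0.5,
                                   r2_max: float = DEFAULT_R2_MAX,
                                   window_bp: Optional[int] = None) -> None:
    """Assert that no scored variant is risk-associated or in LD with one.

    Raises ``AssertionError`` with the offending variant otherwise; intended
    as a post-hoc hard check on any pipeline run.
    """
    if window_bp is None:
        window_bp = panel.window_bp
    risk_p_by_id = risk.set_index("snp_id")["p"]
    chrom = panel.variants["chrom"].to_numpy()
    pos = panel.variants["pos"].to_numpy()
    risk_ids = risk.loc[risk["p"] < risk_p, "snp_id"]
    risk_cols = panel._index.reindex(risk_ids).dropna().astype(int).to_numpy()
    for snp in scored["snp_id"]:
        rp = risk_p_by_id.get(snp, np.nan)
        if np.isfinite(rp) and rp < risk_p:
            raise AssertionError(f"scored variant {snp} has risk P = {rp:.3g} < {risk_p}")
        if snp not in panel._index.index:
            continue
        col = panel.col(snp)
        near = risk_cols[(chrom[risk_cols] == chrom[col])
                         & (np.abs(pos[risk_cols] - pos[col]) <= window_bp)]
        near = near[near != col]
        if near.size:
            r2 = panel.r2_profile(col, near)
            if (r2 >= r2_max).any():
                bad = panel.variants["snp_id"].iloc[near[int(np.argmax(r2))]]
                raise AssertionError(
                    f"scored variant {snp} has r2 = {r2.max():.3f} >= {r2_max} "
                    f"with risk variant {bad} within {window_bp} bp"
                )
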