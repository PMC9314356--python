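"""Synthetic multi-study case-control cohorts under a liability-threshold model.

The generative model: each sample's liability is

    L = sum_i beta_i * g_i  +  beta_M * g_M  +  eps,     eps ~ N(0, 1)

where ``g_i`` are additive risk-SNP dosages and ``g_M`` is a single
major-effect biallelic locus (an epsilon-4-like allele placed inside the
chr19 exclusion region so region excision is exercisable).  Resilience SNPs
subtract from liability only for samples whose genetic risk exceeds a
population quantile:

    affected  <=>  L - I[risk > q] * sum_j gamma_j * g_j  >  T

with ``T`` calibrated by Monte Carlo so the pre-resilience affection rate
equals the configured prevalence.  This is the minimal construction under
which resilience effects are statistically independent of risk effects.

Genotypes are drawn in Hardy-Weinberg proportions; local LD can be induced
by generating variants in correlated blocks (Gaussian copula with
compound-symmetric within-block correlation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GenotypeStudy

log = logging.getLogger(__name__)

MAJOR_LOCUS_ID = "chr19_major"
MAJOR_LOCUS_CHROM = "19"
MAJOR_LOCUS_POS = 45_000_000  # inside the chr19:44.4-46.5 Mb exclusion region

# rng stream tags, so every operation draws from an independent,
# config-determined stream
_STREAM_CALIBRATION = 101
_STREAM_PANEL = 202
_STREAM_PRIOR_GWAS = 303
_STREAM_STUDY_BASE = 1000


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic-cohort generator."""

    n_studies: int = 4
    n_cases_per_study: int = 500
    n_controls_per_study: int = 500
    n_variants: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_risk_snps: int = 100
    risk_beta_sd: float = 0.10
    major_locus_beta: float = 1.0
    major_locus_freq: float = 0.15
    n_resilience_snps: int = 20
    resilience_gamma: float = 0.0
    risk_quantile_for_resilience: float = 0.8
    disease_prevalence: float = 0.2
    age_range: tuple[float, float] = (60.0, 90.0)
    sex_ratio: float = 0.5
    n_pcs: int = 4
    seed: int = 0
    ld_block_size: int = 1
    ld_block_rho: float = 0.0
    n_reference: int = 2000
    max_rejection_factor: int = 1000

    def __post_init__(self):
        for name in ("n_studies", "n_cases_per_study", "n_controls_per_study",
                     "n_variants", "n_reference"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0 < self.disease_prevalence < 1:
            raise ValueError("disease_prevalence must be in (0, 1)")
        if not 0 < self.risk_quantile_for_resilience < 1:
            raise ValueError("risk_quantile_for_resilience must be in (0, 1)")
        if self.n_risk_snps + self.n_resilience_snps > self.n_variants:
            raise ValueError("risk + resilience SNPs exceed n_variants")
        if not 0 < self.major_locus_freq < 1:
            raise ValueError("major_locus_freq must be in (0, 1)")
        if self.ld_block_size < 1 or not 0 <= self.ld_block_rho < 1:
            raise ValueError("bad LD block parameters")


@dataclass
class TruthSet:
    """Ground truth of one simulation: causal variants and thresholds."""

    config: SimulationConfig
    variants: pd.DataFrame          # snp_id, chrom, pos, effect_allele, other_allele, freq, block
    risk_betas: pd.Series           # snp_id -> liability-scale beta (incl. major locus)
    resilience_gammas: pd.Series    # snp_id -> per-allele liability reduction
    liability_threshold: float
    risk_cutoff: float              # genetic-risk quantile above which resilience acts
    components: dict = field(default_factory=dict)  # study_id -> per-sample liability parts

    @property
    def risk_snp_ids(self) -> list[str]:
        return [s for s in self.risk_betas.index if s != MAJOR_LOCUS_ID]

    @property
    def resilience_snp_ids(self) -> list[str]:
        return list(self.resilience_gammas.index)

    def to_frame(self) -> pd.DataFrame:
        df = self.variants.copy()
        df["risk_beta"] = df["snp_id"].map(self.risk_betas).fillna(0.0)
        df["resilience_gamma"] = df["snp_id"].map(self.resilience_gammas).fillna(0.0)
        df["liability_threshold"] = self.liability_threshold
        df["risk_cutoff"] = self.risk_cutoff
        return df


# ---------------------------------------------------------------------------
# variant map and genotype drawing
# ---------------------------------------------------------------------------

def _variant_map(cfg: SimulationConfig) -> pd.DataFrame:
    """Lay background variants in LD blocks over chromosomes 1-22 and append
    the major locus on chr19 inside the exclusion region."""
    n = cfg.n_variants
    block = np.arange(n) // cfg.ld_block_size
    n_blocks = int(block.max()) + 1
    chroms = np.array([str(b % 22 + 1) for b in range(n_blocks)])
    block_rank = np.arange(n_blocks) // 22           # per-chromosome block index
    block_start = 1_000_000 + block_rank * 400_000
    within = np.arange(n) % cfg.ld_block_size
    pos = block_start[block] + within * 1_000
    df = pd.DataFrame({
        "snp_id": [f"rs{i + 1}" for i in range(n)],
        "chrom": chroms[block],
        "pos": pos.astype(int),
        "effect_allele": "A",
        "other_allele": "G",
        "block": block,
    })
    major = pd.DataFrame({
        "snp_id": [MAJOR_LOCUS_ID], "chrom": [MAJOR_LOCUS_CHROM],
        "pos": [MAJOR_LOCUS_POS], "effect_allele": ["A"], "other_allele": ["G"],
        "block": [n_blocks],
    })
    return pd.concat([df, major], ignore_index=True)


def _draw_freqs(cfg: SimulationConfig, n_background: int) -> np.ndarray:
    rng = np.random.default_rng([cfg.seed, 7])
    lo, hi = cfg.maf_range
    freqs = rng.uniform(lo, hi, size=n_background)
    return np.append(freqs, cfg.major_locus_freq)


def _draw_genotypes(rng, n: int, cfg: SimulationConfig, freqs: np.ndarray,
                    blocks: np.ndarray, cols: Optional[np.ndarray] = None) -> np.ndarray:
    """Draw an ``n x len(cols)`` dosage matrix in HWE with block LD.

    ``cols`` restricts generation to a variant subset; whole blocks touching
    the subset are drawn so within-block LD is preserved.  Vectorized over
    all blocks (Gaussian copula, float32 latents).
    """
    if cols is None:
        cols = np.arange(len(freqs))
    cols = np.asarray(cols)
    wanted = np.unique(blocks[cols])
    members = np.flatnonzero(np.isin(blocks, wanted))
    # members are sorted and blocks is non-decreasing, so per-block runs are
    # contiguous and the shared factor can be expanded with a cheap repeat
    _, counts = np.unique(blocks[members], return_counts=True)
    thr = sps.norm.ppf(freqs[members]).astype(np.float32)
    rho = cfg.ld_block_rho
    dos = np.zeros((n, len(members)), dtype=np.float32)
    sq_rho = np.float32(np.sqrt(rho))
    sq_1mrho = np.float32(np.sqrt(1.0 - rho))
    for _hap in range(2):
        latent = rng.standard_normal((n, len(members)), dtype=np.float32)
        if rho > 0:
            shared = rng.standard_normal((n, len(counts)), dtype=np.float32)
            latent *= sq_1mrho
            latent += sq_rho * np.repeat(shared, counts, axis=1)
        dos += latent < thr
    member_pos = np.full(len(freqs), -1)
    member_pos[members] = np.arange(len(members))
    return dos[:, member_pos[cols]]


# ---------------------------------------------------------------------------
# truth construction and calibration
# ---------------------------------------------------------------------------

def _build_truth(cfg: SimulationConfig) -> tuple[TruthSet, np.ndarray, np.ndarray]:
    variants = _variant_map(cfg)
    freqs = _draw_freqs(cfg, cfg.n_variants)
    rng = np.random.default_rng([cfg.seed, 11])
    causal = rng.choice(cfg.n_variants, size=cfg.n_risk_snps + cfg.n_resilience_snps,
                        replace=False)
    risk_idx = np.sort(causal[: cfg.n_risk_snps])
    resil_idx = np.sort(causal[cfg.n_risk_snps:])
    betas = rng.normal(0.0, cfg.risk_beta_sd, size=cfg.n_risk_snps)
    ids = variants["snp_id"].to_numpy()
    risk_betas = pd.Series(betas, index=ids[risk_idx], dtype=float)
    risk_betas[MAJOR_LOCUS_ID] = cfg.major_locus_beta
    gammas = pd.Series(np.full(cfg.n_resilience_snps, cfg.resilience_gamma),
                       index=ids[resil_idx], dtype=float)

    # Monte-Carlo calibration of the liability threshold and the genetic-risk
    # gating quantile on a large reference draw.
    cal_rng = np.random.default_rng([cfg.seed, _STREAM_CALIBRATION])
    n_cal = 50_000
    blocks = variants["block"].to_numpy()
    beta_cols = np.append(risk_idx, cfg.n_variants)  # background risk + major
    beta_vec = np.append(betas, cfg.major_locus_beta)
    g = _draw_genotypes(cal_rng, n_cal, cfg, freqs, blocks, cols=beta_cols)
    risk_score = g @ beta_vec
    liab = risk_score + cal_rng.standard_normal(n_cal)
    threshold = float(np.quantile(liab, 1 - cfg.disease_prevalence))
    risk_cutoff = float(np.quantile(risk_score, cfg.risk_quantile_for_resilience))

    truth = TruthSet(
        config=cfg,
        variants=variants.assign(freq=freqs),
        risk_betas=risk_betas,
        resilience_gammas=gammas,
        liability_threshold=threshold,
        risk_cutoff=risk_cutoff,
    )
    return truth, freqs, blocks


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def simulate_reference_panel(cfg: SimulationConfig,
                             n_reference: Optional[int] = None) -> GenotypeStudy:
    """Draw a panel of unrelated genotypes for allele-frequency and LD use.

    Samples are phenotype-free stand-ins (coded as controls, age fixed) since
    the panel only supplies genotypes.
    """
    n = n_reference if n_reference is not None else cfg.n_reference
    if n <= 0:
        raise ValueError("reference panel size must be positive")
    variants = _variant_map(cfg)
    freqs = _draw_freqs(cfg, cfg.n_variants)
    rng = np.random.default_rng([cfg.seed, _STREAM_PANEL])
    dosages = _draw_genotypes(rng, n, cfg, freqs, variants["block"].to_numpy())
    samples = pd.DataFrame({
        "sample_id": [f"ref_{i:05d}" for i in range(n)],
        "status": 1, "sex": 1, "age": 70.0,
    })
    return GenotypeStudy(
        study_id="reference",
        variants=variants.drop(columns="block"),
        dosages=dosages,
        samples=samples,
    )


def simulate_cohorts(cfg: SimulationConfig) -> tuple[list[GenotypeStudy], TruthSet]:
    """Simulate ``cfg.n_studies`` case-control studies with fixed group sizes.

    Case/control quotas are filled by rejection sampling; a study failing to
    fill its quota within ``max_rejection_factor`` times the requested size
    raises ``RuntimeError``.
    """
    truth, freqs, blocks = _build_truth(cfg)
    variants = truth.variants
    ids = variants["snp_id"].to_numpy()
    beta_cols = np.flatnonzero(pd.Index(ids).isin(truth.risk_betas.index))
    beta_vec = truth.risk_betas.reindex(ids[beta_cols]).to_numpy()
    gamma_cols = np.flatnonzero(pd.Index(ids).isin(truth.resilience_gammas.index))
    gamma_vec = truth.resilience_gammas.reindex(ids[gamma_cols]).to_numpy()

    studies = []
    for s in range(cfg.n_studies):
        study_id = f"study{s + 1}"
        rng = np.random.default_rng([cfg.seed, _STREAM_STUDY_BASE + s])
        need = {True: cfg.n_cases_per_study, False: cfg.n_controls_per_study}
        kept_g, kept_parts = [], []
        total = cfg.n_cases_per_study + cfg.n_controls_per_study
        max_draws = cfg.max_rejection_factor * total
        drawn = 0
        while (need[True] > 0 or need[False] > 0):
            if drawn >= max_draws:
                raise RuntimeError(
                    f"{study_id}: could not fill case/control quota within "
                    f"{max_draws} draws (prevalence too extreme for requested n)"
                )
            # size batches by the expected acceptance rate of the scarcer group
            k = cfg.disease_prevalence
            est = max(need[True] / k, need[False] / (1.0 - k))
            batch = int(np.clip(1.3 * est, 512, 8192))
            m = min(batch, max_draws - drawn)
            drawn += m
            g = _draw_genotypes(rng, m, cfg, freqs, blocks)
            eps = rng.standard_normal(m)
            risk_score = g[:, beta_cols] @ beta_vec if len(beta_cols) else np.zeros(m)
            gate = risk_score > truth.risk_cutoff
            resil = g[:, gamma_cols] @ gamma_vec if len(gamma_cols) else np.zeros(m)
            liab = risk_score + eps - gate * resil
            affected = liab > truth.liability_threshold
            for is_case in (True, False):
                if need[is_case] <= 0:
                    continue
                take = np.flatnonzero(affected == is_case)[: need[is_case]]
                if take.size:
                    kept_g.append(g[take])
                    kept_parts.append(pd.DataFrame({
                        "is_case": is_case,
                        "risk_liability": risk_score[take],
                        "gated": gate[take],
                        "resilience_sum": resil[take],
                        "epsilon": eps[take],
                    }))
                    need[is_case] -= take.size
        dosages = np.vstack(kept_g)
        parts = pd.concat(kept_parts, ignore_index=True)
        n = len(parts)
        samples = pd.DataFrame({
            "sample_id": [f"{study_id}_{i:05d}" for i in range(n)],
            "status": np.where(parts["is_case"], 2, 1),
            "sex": np.where(rng.uniform(size=n) < cfg.sex_ratio, 1, 2),
            "age": rng.uniform(*cfg.age_range, size=n).round(1),
        })
        for k in range(cfg.n_pcs):
            samples[f"PC{k + 1}"] = rng.standard_normal(n)
        parts.insert(0, "sample_id", samples["sample_id"])
        truth.components[study_id] = parts
        studies.append(GenotypeStudy(
            study_id=study_id,
            variants=variants.drop(columns=["block", "freq"]),
            dosages=dosages,
            samples=samples,
        ))
        log.info("%s: %d cases + %d controls from %d draws", study_id,
                 cfg.n_cases_per_study, cfg.n_controls_per_study, drawn)
    return studies, truth


def make_prior_risk_gwas(panel: GenotypeStudy, truth: TruthSet,
                         n_effective: int, seed: Optional[int] = None) -> pd.DataFrame:
    """Emulate an external risk-GWAS summary-statistics file.

    Per variant: ``beta_hat = beta_true + N(0, se^2)`` with
    ``se = 1 / sqrt(2 p (1-p) n_effective)`` on the standardized-liability
    scale (``p`` = panel effect-allele frequency), and a Wald P-value.  Null
    variants have ``beta_true = 0``.  Zero-variance variants are excluded
    with a logged warning.
    """
    if n_effective <= 0:
        raise ValueError("n_effective must be positive")
    rng = np.random.default_rng(
        [truth.config.seed, _STREAM_PRIOR_GWAS] if seed is None else seed
    )
    p_hat = panel.dosages.mean(axis=0) / 2.0
    ok = (p_hat > 0) & (p_hat < 1)
    if not ok.all():
        log.warning("excluding %d zero-variance variants from prior risk GWAS",
                    int((~ok).sum()))
    variants = panel.variants.loc[ok].reset_index(drop=True)
    p_hat = p_hat[ok]
    beta_true = variants["snp_id"].map(truth.risk_betas).fillna(0.0).to_numpy()
    se = 1.0 / np.sqrt(2.0 * p_hat * (1.0 - p_hat) * n_effective)
    beta = beta_true + rng.normal(0.0, se)
    z = beta / se
    pval = np.clip(2.0 * sps.norm.sf(np.abs(z)), 1e-300, 1.0)
    return pd.DataFrame({
        "snp_id": variants["snp_id"],
        "chrom": variants["chrom"],
        "pos": variants["pos"],
        "effect_allele": variants["effect_allele"],
        "other_allele": variants["other_allele"],
        "beta": beta,
        "se": se,
        "p": pval,
    })
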