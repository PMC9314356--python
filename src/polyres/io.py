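"""Readers, writers and validation for on-disk artifacts.

Genotypes travel as VCF v4.2 (uncompressed; ``DS`` dosage or ``GT`` field)
plus a tab-separated sample table; association statistics, score weights and
stratification labels travel as TSV.  All coordinates are 1-based and region
intervals are closed, matching VCF conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: canonical summary-statistics column order
SUMSTATS_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "se", "p",
]

#: complementary bases, used to detect strand-ambiguous (palindromic) pairs
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class Region(NamedTuple):
    """A closed 1-based chromosome interval ``[start, end]``."""

    chrom: str
    start: int
    end: int

    def contains(self, chrom, pos) -> bool:
        return (np.asarray(chrom, dtype=str) == str(self.chrom)) & (
            (np.asarray(pos) >= self.start) & (np.asarray(pos) <= self.end)
        )

    @classmethod
    def parse(cls, text: str) -> "Region":
        """Parse ``chr19:44400000-46500000`` (an optional ``chr`` prefix is kept)."""
        chrom, _, span = text.partition(":")
        start, _, end = span.partition("-")
        region = cls(chrom.removeprefix("chr"), int(start), int(end))
        if region.start >= region.end:
            raise ValueError(f"malformed region {text!r}: start must precede end")
        return region


@dataclass
class GenotypeStudy:
    """One study's dosage matrix with per-sample phenotype and covariates.

    Attributes
    ----------
    study_id : str
    variants : pandas.DataFrame
        Columns ``snp_id, chrom, pos, effect_allele, other_allele``; one row
        per variant, ``snp_id`` unique.
    dosages : numpy.ndarray
        Effect-allele dosages in ``[0, 2]``, shape ``(n_samples, n_variants)``.
    samples : pandas.DataFrame
        Columns ``sample_id, status, sex, age`` plus covariates (``PC1``...).
        ``status`` is 1 for controls, 2 for cases; ``age`` is the age at onset
        for cases and the age at last examination for controls.
    """

    study_id: str
    variants: pd.DataFrame
    dosages: np.ndarray
    samples: pd.DataFrame

    def __post_init__(self):
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        arr = np.asarray(self.dosages)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float64)  # float32 is preserved to bound memory
        self.dosages = arr
        validate_genotype_study(self)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def is_case(self) -> np.ndarray:
        return self.samples["status"].to_numpy() == 2

    @property
    def pc_columns(self) -> list[str]:
        return [c for c in self.samples.columns if c.startswith("PC")]

    def subset_samples(self, mask_or_ids) -> "GenotypeStudy":
        """Return a copy restricted to a boolean mask or a list of sample IDs."""
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            wanted = set(mask_or_ids)
            idx = np.flatnonzero(self.samples["sample_id"].isin(wanted).to_numpy())
        return GenotypeStudy(
            study_id=self.study_id,
            variants=self.variants,
            dosages=self.dosages[idx],
            samples=self.samples.iloc[idx],
        )

    def variant_indexer(self) -> pd.Series:
        """Map snp_id -> column index into ``dosages``."""
        return pd.Series(np.arange(self.n_variants), index=self.variants["snp_id"])


def validate_genotype_study(study: GenotypeStudy) -> None:
    if study.dosages.shape != (len(study.samples), len(study.variants)):
        raise ValueError(
            f"dosage matrix shape {study.dosages.shape} does not match "
            f"{len(study.samples)} samples x {len(study.variants)} variants"
        )
    if study.variants["snp_id"].duplicated().any():
        dup = study.variants.loc[study.variants["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise ValueError(f"duplicate variant ID {dup!r} in study {study.study_id}")
    if study.dosages.size and (
        np.nanmin(study.dosages) < -1e-9 or np.nanmax(study.dosages) > 2 + 1e-9
    ):
        raise ValueError("dosages outside [0, 2]")
    if study.samples["status"].isna().any() or study.samples["age"].isna().any():
        raise ValueError("every sample needs a non-missing status and age")
    if not study.samples["status"].isin([1, 2]).all():
        raise ValueError("status must be coded 1 (control) / 2 (case)")


@dataclass
class ScoreWeights:
    """A variant -> weight map defining a polygenic score.

    ``table`` has columns ``snp_id, effect_allele, weight`` (log-odds toward
    the effect allele).  Metadata records how the set was built.
    """

    table: pd.DataFrame
    p_threshold: Optional[float] = None
    excluded_region: Optional[Region] = None
    provenance: str = ""

    def __post_init__(self):
        self.table = self.table.reset_index(drop=True)
        if self.table["snp_id"].duplicated().any():
            raise ValueError("duplicate snp_id in score weights")
        if not np.isfinite(self.table["weight"].to_numpy(dtype=float)).all():
            raise ValueError("non-finite weight")
        if self.excluded_region is not None and not (
            self.excluded_region.start < self.excluded_region.end
        ):
            raise ValueError("excluded_region start must precede end")

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def validate_summary_stats(stats: pd.DataFrame, max_reject_frac: float = 0.10) -> pd.DataFrame:
    """Validate and type a summary-statistics frame.

    Rows violating row-level invariants (non-positive SE, P outside ``(0, 1]``,
    non-finite beta) are dropped with a logged count; if more than
    ``max_reject_frac`` of rows are rejected the input is considered corrupt.
    """
    missing = [c for c in SUMSTATS_COLUMNS if c not in stats.columns]
    if missing:
        raise ValueError(f"summary statistics missing columns {missing}")
    out = stats.copy()
    out["chrom"] = out["chrom"].astype(str)
    out["pos"] = out["pos"].astype(int)
    for col in ("beta", "se", "p"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    ok = (
        np.isfinite(out["beta"])
        & np.isfinite(out["se"]) & (out["se"] > 0)
        & np.isfinite(out["p"]) & (out["p"] > 0) & (out["p"] <= 1)
    )
    n_bad = int((~ok).sum())
    if n_bad:
        log.warning("rejected %d/%d summary-statistic rows failing validation", n_bad, len(out))
        if n_bad > max_reject_frac * len(out):
            raise ValueError(
                f"{n_bad}/{len(out)} summary-statistic rows invalid "
                f"(> {max_reject_frac:.0%} threshold)"
            )
    out = out.loc[ok].reset_index(drop=True)
    if out["snp_id"].duplicated().any():
        raise ValueError("duplicate snp_id in summary statistics")
    return out


def read_summary_stats(path, column_map: Optional[dict] = None) -> pd.DataFrame:
    """Read a summary-statistics TSV, optionally renaming columns first.

    ``column_map`` maps *file* column names to canonical names, e.g.
    ``{"P-value": "p"}``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if column_map:
        df = df.rename(columns=column_map)
    return validate_summary_stats(df)


def write_summary_stats(stats: pd.DataFrame, path) -> None:
    cols = SUMSTATS_COLUMNS + [c for c in stats.columns if c not in SUMSTATS_COLUMNS]
    stats.to_csv(path, sep="\t", index=False, columns=cols)


def read_score_weights(path) -> ScoreWeights:
    df = pd.read_csv(path, sep="\t")
    return ScoreWeights(table=df[["snp_id", "effect_allele", "weight"]])


def write_score_weights(weights: ScoreWeights, path) -> None:
    weights.table.to_csv(path, sep="\t", index=False)


def is_palindromic(a1, a2) -> np.ndarray:
    """True where the allele pair is strand-ambiguous (A/T or C/G)."""
    a1 = np.char.upper(np.asarray(a1, dtype=str))
    a2 = np.char.upper(np.asarray(a2, dtype=str))
    comp = np.array([_COMPLEMENT.get(x, "?") for x in a1])
    return comp == a2


def harmonize_alleles(stats: pd.DataFrame, study: GenotypeStudy) -> tuple[pd.DataFrame, dict]:
    """Orient summary statistics to a study's effect alleles.

    For each variant shared by ``stats`` and ``study``: if the study effect
    allele equals the stats effect allele the beta is kept; if it equals the
    stats other allele the beta is negated and the alleles swapped.
    Strand-ambiguous palindromic pairs (A/T, C/G) and irreconcilable allele
    pairs are dropped.  Returns the harmonized frame (study allele
    orientation) and a drop-accounting dict.
    """
    merged = stats.merge(
        study.variants[["snp_id", "effect_allele", "other_allele"]],
        on="snp_id",
        suffixes=("", "_study"),
    )
    if merged.empty:
        raise ValueError(
            f"no overlapping variants between summary statistics and study {study.study_id}"
        )
    palin = is_palindromic(merged["effect_allele"], merged["other_allele"])
    same = (merged["effect_allele"] == merged["effect_allele_study"]) & (
        merged["other_allele"] == merged["other_allele_study"]
    )
    flipped = (merged["effect_allele"] == merged["other_allele_study"]) & (
        merged["other_allele"] == merged["effect_allele_study"]
    )
    keep = ~palin & (same | flipped)
    report = {
        "n_shared": len(merged),
        "n_palindromic_dropped": int(palin.sum()),
        "n_mismatched_dropped": int((~palin & ~(same | flipped)).sum()),
        "n_flipped": int((flipped & keep).sum()),
    }
    if report["n_palindromic_dropped"] or report["n_mismatched_dropped"]:
        log.info(
            "harmonize_alleles[%s]: dropped %d palindromic, %d mismatched of %d shared",
            study.study_id, report["n_palindromic_dropped"],
            report["n_mismatched_dropped"], report["n_shared"],
        )
    out = merged.loc[keep].copy()
    flip = flipped.loc[keep].to_numpy()
    out.loc[flip, "beta"] = -out.loc[flip, "beta"]
    out["effect_allele"] = out["effect_allele_study"]
    out["other_allele"] = out["other_allele_study"]
    out = out.drop(columns=["effect_allele_study", "other_allele_study"])
    return out.reset_index(drop=True), report


# ---------------------------------------------------------------------------
# genotype I/O
# ---------------------------------------------------------------------------

def write_genotype_study(study: GenotypeStudy, vcf_path, sample_table_path,
                         dosage_field: str = "DS") -> None:
    """Write a study as an uncompressed VCF 4.2 plus a sample-table TSV.

    ``dosage_field`` selects the FORMAT used: ``DS`` writes fractional dosages
    (lossless for simulated data); ``GT`` writes hard genotypes and is only
    exact for integer dosages.
    """
    if dosage_field not in ("DS", "GT"):
        raise ValueError("dosage_field must be 'DS' or 'GT'")
    ids = study.samples["sample_id"].astype(str).tolist()
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=polyres\n##polyres_study_id={study.study_id}\n")
        if dosage_field == "DS":
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                     'Description="Effect (ALT) allele dosage">\n')
        else:
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ids) + "\n")
        v = study.variants
        for j in range(study.n_variants):
            row = v.iloc[j]
            if dosage_field == "DS":
                cells = [format(d, ".6g") for d in study.dosages[:, j]]
            else:
                gt = {0: "0/0", 1: "0/1", 2: "1/1"}
                cells = [gt[int(round(d))] for d in study.dosages[:, j]]
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.other_allele}\t"
                f"{row.effect_allele}\t.\t.\t.\t{dosage_field}\t" + "\t".join(cells) + "\n"
            )
    out = study.samples.copy()
    out.insert(1, "study_id", study.study_id)
    out.to_csv(sample_table_path, sep="\t", index=False)


def read_genotype_study(vcf_path, sample_table_path) -> GenotypeStudy:
    """Read a genotype study back from VCF + sample table.

    Dosages come from ``DS`` when present, else from ``GT`` as the effect
    (ALT) allele count.  Multi-allelic sites are fatal.  Missing genotypes are
    imputed to twice the effect-allele frequency with a logged count.
    """
    from cyvcf2 import VCF

    table = pd.read_csv(sample_table_path, sep="\t")
    vcf = VCF(str(vcf_path))
    vcf_ids = list(vcf.samples)
    if set(vcf_ids) != set(table["sample_id"].astype(str)):
        raise ValueError(
            f"sample IDs in {vcf_path} do not match sample table {sample_table_path}"
        )
    # align table to VCF sample order
    table = (
        table.assign(sample_id=table["sample_id"].astype(str))
        .set_index("sample_id").loc[vcf_ids].reset_index()
    )
    study_ids = table["study_id"].unique() if "study_id" in table else ["study"]
    if len(study_ids) != 1:
        raise ValueError("sample table mixes multiple study IDs")

    records, columns = [], []
    n_imputed = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ValueError(f"multi-allelic variant {variant.ID} is not supported")
        records.append((variant.ID, str(variant.CHROM).removeprefix("chr"),
                        variant.POS, variant.ALT[0], variant.REF))
        try:
            ds = variant.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
        else:
            # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            gt = variant.gt_types
            col = np.where(gt == 3, 2.0, np.where(gt == 1, 1.0, 0.0))
            col[gt == 2] = np.nan
        miss = ~np.isfinite(col)
        if miss.any():
            n_imputed += int(miss.sum())
            freq = np.nanmean(col) / 2.0 if np.isfinite(col).any() else 0.0
            col[miss] = 2.0 * freq
        columns.append(col)
    if n_imputed:
        log.warning("imputed %d missing genotypes to 2 x allele frequency", n_imputed)
    variants = pd.DataFrame(
        records, columns=["snp_id", "chrom", "pos", "effect_allele", "other_allele"]
    )
    dosages = (
        np.column_stack(columns) if columns else np.empty((len(table), 0))
    )
    drop = [c for c in ("study_id",) if c in table]
    return GenotypeStudy(
        study_id=str(study_ids[0]),
        variants=variants,
        dosages=dosages,
        samples=table.drop(columns=drop),
    )


def write_labels(labels: pd.DataFrame, path) -> None:
    labels.to_csv(path, sep="\t", index=False)


def read_labels(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
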