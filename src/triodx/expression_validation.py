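"""Blood-RNA dosage validation of candidate CNVs and SNVs.

A CNV that changes gene copy number should shift the blood expression of the
genes it spans: duplications up, deletions down. The validation statistic
compares the mean per-gene cohort z-score (and log2 fold change) of in-CNV
genes in the carrier against (a) all expressed genes on the same chromosome
(background) and (b) three random same-size sets of expressed out-CNV genes on
that chromosome (negative controls). A protein-truncating SNV is checked for
reduced expression of the mutant gene relative to the cohort mean, the
expectation under nonsense-mediated decay.

All statistics operate on a size-factor-normalized genes x samples matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .variant_triage import CnvCall, CnvType, overlap_bp


class NormalizationError(ValueError):
    """Raised when size factors cannot be computed."""


class SamplingError(ValueError):
    """Raised when the out-CNV gene pool is too small for a random set."""


class NotEvaluableError(ValueError):
    """Raised when a dosage result without expressed genes is interrogated."""


@dataclass
class ExpressionMatrix:
    """Gene-level expression, genes x samples, with a normalization flag.

    ``values`` is a pandas DataFrame indexed by gene id with sample-id columns.
    Entries must be non-negative and ids unique.
    """

    values: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("non-numeric expression values")
        if (arr < 0).any():
            raise ValueError("negative expression values")
        if self.normalized and (arr.sum(axis=0) == 0).any():
            raise ValueError("normalized matrix has an all-zero sample")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.normalized == other.normalized and self.values.equals(other.values)


@dataclass
class DosageValidationResult:
    """Per-CNV dosage statistics: background, in-CNV, and random-set means."""

    cnv_key: str
    gene_in_cnv: int
    rna_in_cnv: int
    status: str  # "evaluable" | "not_expressed"
    zscore_chr: Optional[float] = None
    zscore_cnv: Optional[float] = None
    zscore_random: Optional[tuple] = None
    log2fc_chr: Optional[float] = None
    log2fc_cnv: Optional[float] = None
    log2fc_random: Optional[tuple] = None


@dataclass
class SnvExpressionResult:
    gene: str
    expressed_in_blood: bool
    patient_level: Optional[float] = None
    cohort_mean_level: Optional[float] = None
    reduced: Optional[bool] = None


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_counts(raw: ExpressionMatrix) -> ExpressionMatrix:
    """Median-of-ratios size-factor normalization.

    For genes with a strictly positive geometric mean across samples, each
    sample's size factor is the median of value/geometric-mean ratios; the
    sample's column is divided by its factor.
    """
    if raw.values.shape[1] < 2:
        raise NormalizationError("need at least 2 samples to normalize")
    arr = raw.values.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise NormalizationError("no gene is nonzero in every sample")
    log_geo = np.log(arr[positive]).mean(axis=1, keepdims=True)
    ratios = arr[positive] / np.exp(log_geo)
    size_factors = np.median(ratios, axis=0)
    out = raw.values / size_factors
    return ExpressionMatrix(out, normalized=True)


# ---------------------------------------------------------------------------
# Per-gene statistics
# ---------------------------------------------------------------------------

def expressed_in_blood(m: ExpressionMatrix, gene: str, min_mean: float = 1.0) -> bool:
    """A gene counts as blood-expressed iff its cohort mean is >= ``min_mean``.

    A gene absent from the matrix is simply not expressed (no error).
    """
    if gene not in m.genes:
        return False
    return float(m.values.loc[gene].mean()) >= min_mean


def gene_zscore(m: ExpressionMatrix, gene: str, patient: str) -> float:
    """Patient's expression standardized against the cohort (population sd).

    Returns 0 for a gene constant across the cohort.
    """
    row = m.values.loc[gene].to_numpy(dtype=float)
    sd = row.std(ddof=0)
    if sd == 0:
        return 0.0
    x = float(m.values.at[gene, patient])
    return (x - row.mean()) / sd


def gene_log2fc(
    m: ExpressionMatrix, gene: str, patient: str, pseudocount: float = 1.0
) -> float:
    """log2 of (patient + pseudocount) over (cohort mean + pseudocount)."""
    row = m.values.loc[gene].to_numpy(dtype=float)
    x = float(m.values.at[gene, patient])
    return float(np.log2((x + pseudocount) / (row.mean() + pseudocount)))


# ---------------------------------------------------------------------------
# CNV dosage validation
# ---------------------------------------------------------------------------

def genes_in_interval(genes: Iterable, chrom: str, start: int, end: int) -> list:
    """Gene models overlapping a 1-based inclusive interval by >= 1 bp."""
    return [
        g for g in genes
        if g.chrom == chrom and overlap_bp(start, end, g.start, g.end) > 0
    ]


def cnv_dosage_validation(
    m: ExpressionMatrix,
    cnv: CnvCall,
    genes: Sequence,
    n_random_sets: int = 3,
    seed: int = 0,
    min_mean: float = 1.0,
) -> DosageValidationResult:
    """Dosage statistics for one CNV carrier against the cohort.

    in-CNV genes are those overlapping the CNV span by >= 1 bp; only the
    blood-expressed subset contributes statistics. Background means run over
    all expressed genes on the CNV's chromosome; each random set draws
    ``rna_in_cnv`` expressed out-CNV genes on that chromosome uniformly
    without replacement (sets mutually independent, seeded).
    """
    if cnv.sample_id not in m.samples:
        raise KeyError(f"sample {cnv.sample_id!r} not in expression matrix")
    key = f"{cnv.sample_id}:{cnv.chrom}:{cnv.start}-{cnv.end}"
    chrom_genes = [g for g in genes if g.chrom == cnv.chrom]
    in_cnv = {g.gene_id for g in genes_in_interval(chrom_genes, cnv.chrom, cnv.start, cnv.end)}
    expressed = [
        g.gene_id for g in chrom_genes if expressed_in_blood(m, g.gene_id, min_mean)
    ]
    in_expr = [g for g in expressed if g in in_cnv]
    out_expr = [g for g in expressed if g not in in_cnv]

    if not in_expr:
        return DosageValidationResult(
            cnv_key=key, gene_in_cnv=len(in_cnv), rna_in_cnv=0, status="not_expressed"
        )

    def set_means(gene_ids: Sequence[str]) -> tuple:
        zs = [gene_zscore(m, g, cnv.sample_id) for g in gene_ids]
        fcs = [gene_log2fc(m, g, cnv.sample_id) for g in gene_ids]
        return float(np.mean(zs)), float(np.mean(fcs))

    z_cnv, fc_cnv = set_means(in_expr)
    z_chr, fc_chr = set_means(expressed)

    if len(out_expr) < len(in_expr):
        raise SamplingError(
            f"only {len(out_expr)} expressed out-CNV genes on {cnv.chrom} but "
            f"{len(in_expr)} needed per random set; enlarge the gene universe"
        )
    rng = np.random.default_rng(seed)
    z_rand, fc_rand = [], []
    for _ in range(n_random_sets):
        pick = rng.choice(len(out_expr), size=len(in_expr), replace=False)
        z, fc = set_means([out_expr[i] for i in pick])
        z_rand.append(z)
        fc_rand.append(fc)

    return DosageValidationResult(
        cnv_key=key, gene_in_cnv=len(in_cnv), rna_in_cnv=len(in_expr),
        status="evaluable",
        zscore_chr=z_chr, zscore_cnv=z_cnv, zscore_random=tuple(z_rand),
        log2fc_chr=fc_chr, log2fc_cnv=fc_cnv, log2fc_random=tuple(fc_rand),
    )


def direction_consistent(r: DosageValidationResult, cnv_type: CnvType) -> bool:
    """Does the dosage shift point the way the copy-number change predicts?

    Duplications must exceed every random-set mean on both statistics;
    deletions must fall below every random-set minimum on both.
    """
    if r.status != "evaluable":
        raise NotEvaluableError(f"{r.cnv_key}: no blood-expressed in-CNV genes")
    if cnv_type is CnvType.DUPLICATION:
        return (r.zscore_cnv > max(r.zscore_random)
                and r.log2fc_cnv > max(r.log2fc_random))
    return (r.zscore_cnv < min(r.zscore_random)
            and r.log2fc_cnv < min(r.log2fc_random))


# ---------------------------------------------------------------------------
# SNV expression check
# ---------------------------------------------------------------------------

def snv_expression_check(
    m: ExpressionMatrix,
    gene: str,
    patient: str,
    min_mean: float = 1.0,
    include_index: bool = True,
) -> SnvExpressionResult:
    """Is the mutant gene's expression reduced in the carrier?

    The control is the cohort mean of the gene; by default the index patient
    is included in that mean (``include_index=False`` excludes it).
    ``reduced`` is a strict comparison: patient < control.
    """
    if patient not in m.samples:
        raise KeyError(f"sample {patient!r} not in expression matrix")
    if not expressed_in_blood(m, gene, min_mean):
        return SnvExpressionResult(gene=gene, expressed_in_blood=False)
    row = m.values.loc[gene]
    level = float(row[patient])
    control = float(row.mean()) if include_index else float(row.drop(patient).mean())
    return SnvExpressionResult(
        gene=gene, expressed_in_blood=True, patient_level=level,
        cohort_mean_level=control, reduced=level < control,
    )
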