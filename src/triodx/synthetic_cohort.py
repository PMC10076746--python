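"""Synthetic trio-cohort generator.

Produces every input the pipeline consumes — pedigree, annotated trio VCF,
per-member CNV calls, a raw gene-level expression matrix, qPCR plates and
paired FASTQ — with the statistical structure the analysis assumes:

* a minority of probands carry multi-gene CNVs that multiply the blood
  expression of in-CNV genes by a copy ratio (1.5 for a heterozygous
  duplication, 0.5 for a deletion), or de novo protein-truncating SNVs that
  reduce the mutant gene's expression (partial nonsense-mediated decay);
* a blood-expression mask under which a fraction of genes are silent in
  peripheral blood, so some causal genes cannot be validated by RNA;
* multiplicative lognormal expression noise on a lognormal baseline;
* triplicate qPCR Cq values generated from the true copy ratio and the
  amplification efficiency E.

Every component draws from its own seeded RNG stream, so identical seeds give
identical outputs. A :func:`study_config` factory plants the reference study
conditions: 354 trios (279 male / 75 female probands), 9 catalog-matching
CNVs (6 duplications / 3 deletions; 5 de novo / 4 inherited) and 10 de novo
PTV SNVs in listed genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .expression_validation import ExpressionMatrix
from .io_formats import (
    GeneModel,
    Individual,
    Pedigree,
    Read,
    ReadPair,
    SnvRecord,
    write_cnv_calls,
    write_expression_matrix,
    write_fastq_pairs,
    write_gene_models,
    write_pedigree,
    write_snv_calls,
)
from .qpcr_quant import QpcrPlate, Well
from .variant_triage import (
    CnvCall,
    CnvType,
    Consequence,
    GeneList,
    Genotype,
    KnownRegion,
    Origin,
)


class ConfigError(ValueError):
    """Raised for simulation configurations that cannot be realized."""


@dataclass(frozen=True)
class PlantedCnv:
    carrier: int  # trio index
    chrom: str
    start: int
    end: int
    cnv_type: CnvType
    copy_ratio: float
    origin: Origin = Origin.DE_NOVO
    in_catalog: bool = True

    def __post_init__(self) -> None:
        if self.copy_ratio <= 0:
            raise ConfigError("copy_ratio must be positive")


@dataclass(frozen=True)
class PlantedSnv:
    carrier: int
    gene: str
    consequence: Consequence = Consequence.NONSENSE
    expression_ratio: float = 0.6  # partial nonsense-mediated decay
    origin: Origin = Origin.DE_NOVO

    def __post_init__(self) -> None:
        if not 0 < self.expression_ratio <= 1:
            raise ConfigError("expression_ratio must be in (0, 1]")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_trios: int = 354
    male_fraction: float = 279 / 354
    n_chromosomes: int = 4
    genes_per_chromosome: int = 120
    chromosome_length: int = 50_000_000
    min_gene_length: int = 5_000
    max_gene_length: int = 50_000
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 2.0
    noise_sd_log2: float = 0.2
    blood_expressed_fraction: float = 0.7
    integer_counts: bool = True
    include_decoys: bool = True
    planted_cnvs: Tuple[PlantedCnv, ...] = ()
    planted_snvs: Tuple[PlantedSnv, ...] = ()
    qpcr_noise_sd: float = 0.15

    def __post_init__(self) -> None:
        for pv in list(self.planted_cnvs) + list(self.planted_snvs):
            if pv.carrier >= self.n_trios:
                raise ConfigError(f"carrier index {pv.carrier} >= n_trios {self.n_trios}")


def _rng(cfg_seed: int, component: int) -> np.random.Generator:
    # one integer-stable stream per component
    return np.random.default_rng([cfg_seed, component])


_GENOME, _SEX, _MASK, _BASELINE, _NOISE, _VCF, _QPCR, _FASTQ = range(8)


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def generate_genome(cfg: SimulationConfig) -> List[GeneModel]:
    """Non-overlapping gene spans on ``n_chromosomes`` chromosomes.

    Each chromosome is divided into equal slots, one gene per slot with a
    jittered start and length, so spans never overlap and the layout is
    deterministic under the seed.
    """
    if cfg.genes_per_chromosome == 0:
        return []
    slot = cfg.chromosome_length // cfg.genes_per_chromosome
    if slot <= cfg.max_gene_length:
        raise ConfigError(
            f"{cfg.genes_per_chromosome} genes of up to {cfg.max_gene_length} bp "
            f"do not fit on a {cfg.chromosome_length} bp chromosome"
        )
    rng = _rng(cfg.seed, _GENOME)
    genes: List[GeneModel] = []
    for c in range(1, cfg.n_chromosomes + 1):
        chrom = f"chr{c}"
        for i in range(cfg.genes_per_chromosome):
            length = int(rng.integers(cfg.min_gene_length, cfg.max_gene_length + 1))
            start = i * slot + int(rng.integers(0, slot - length)) + 1
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"{chrom}_g{i:04d}", chrom, start, start + length - 1, strand))
    return genes


def span_of_genes(genes: Sequence[GeneModel], chrom: str, first: int, count: int) -> Tuple[int, int]:
    """1-based inclusive span covering ``count`` consecutive genes of a chromosome."""
    chrom_genes = sorted((g for g in genes if g.chrom == chrom), key=lambda g: g.start)
    block = chrom_genes[first:first + count]
    if len(block) < count:
        raise ConfigError(f"not enough genes on {chrom} for a {count}-gene span")
    return block[0].start, block[-1].end


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortData:
    pedigree: Pedigree
    snv_records: List[SnvRecord]
    cnv_calls: Dict[str, List[CnvCall]]
    expression: ExpressionMatrix  # raw counts, probands as samples
    truth: pd.DataFrame
    genes: List[GeneModel]
    gene_list: GeneList
    catalog: List[KnownRegion]

    def proband_ids(self) -> List[str]:
        return [t.proband for t in self.pedigree.trios()]


def _trio_ids(i: int) -> Tuple[str, str, str, str]:
    fam = f"FAM{i:04d}"
    proband = f"ASD{i:04d}"
    return fam, proband, proband + "_fa", proband + "_mo"


def _origin_genotypes(origin: Origin) -> Tuple[Genotype, Genotype, Genotype]:
    table = {
        Origin.DE_NOVO: (Genotype.HET, Genotype.HOM_REF, Genotype.HOM_REF),
        Origin.PATERNAL: (Genotype.HET, Genotype.HET, Genotype.HOM_REF),
        Origin.MATERNAL: (Genotype.HET, Genotype.HOM_REF, Genotype.HET),
        Origin.INHERITED_BOTH: (Genotype.HET, Genotype.HET, Genotype.HET),
    }
    if origin not in table:
        raise ConfigError(f"cannot plant origin {origin}")
    return table[origin]


def _hgvs_for(consequence: Consequence, pos_in_gene: int) -> Tuple[str, Optional[str]]:
    if consequence is Consequence.NONSENSE:
        return f"c.{pos_in_gene}C>T", f"p.Arg{max(1, pos_in_gene // 3)}*"
    if consequence is Consequence.FRAMESHIFT:
        return f"c.{pos_in_gene}del", f"p.Leu{max(1, pos_in_gene // 3)}fs"
    if consequence is Consequence.SPLICE_DONOR:
        return f"c.{pos_in_gene}+1G>A", None
    if consequence is Consequence.SPLICE_ACCEPTOR:
        return f"c.{pos_in_gene}-2A>G", None
    if consequence is Consequence.MISSENSE:
        return f"c.{pos_in_gene}G>A", f"p.Gly{max(1, pos_in_gene // 3)}Ser"
    return f"c.{pos_in_gene}A>G", None


def generate_cohort(cfg: SimulationConfig, genes: Sequence[GeneModel]) -> CohortData:
    """Generate pedigree, variant calls, expression and ground truth.

    Trio genotypes are consistent with each planted origin; the carrier's
    blood-expressed in-CNV genes are multiplied by the copy ratio and PTV
    genes by the expression ratio before multiplicative noise. Genes outside
    the blood-expression mask get near-zero counts for everyone.
    """
    genes = list(genes)
    by_id = {g.gene_id: g for g in genes}
    for ps in cfg.planted_snvs:
        if ps.gene not in by_id:
            raise ConfigError(f"planted SNV gene {ps.gene!r} not in genome")
    for pc in cfg.planted_cnvs:
        if not any(g.chrom == pc.chrom for g in genes):
            raise ConfigError(f"planted CNV chromosome {pc.chrom!r} not in genome")

    # --- pedigree with sex metadata -------------------------------------
    n_male = int(round(cfg.n_trios * cfg.male_fraction))
    sexes = np.array(["male"] * n_male + ["female"] * (cfg.n_trios - n_male))
    _rng(cfg.seed, _SEX).shuffle(sexes)
    individuals: List[Individual] = []
    for i in range(cfg.n_trios):
        fam, proband, father, mother = _trio_ids(i)
        individuals.append(Individual(fam, father, "0", "0", "male", False))
        individuals.append(Individual(fam, mother, "0", "0", "female", False))
        individuals.append(Individual(fam, proband, father, mother, str(sexes[i]), True))
    pedigree = Pedigree(individuals)
    probands = [_trio_ids(i)[1] for i in range(cfg.n_trios)]

    # --- expression matrix ----------------------------------------------
    mask_rng = _rng(cfg.seed, _MASK)
    expressed = mask_rng.random(len(genes)) < cfg.blood_expressed_fraction
    base_rng = _rng(cfg.seed, _BASELINE)
    baseline = np.where(
        expressed,
        np.exp2(base_rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, len(genes))),
        0.0,
    )
    effect = np.ones((len(genes), cfg.n_trios))
    gene_index = {g.gene_id: k for k, g in enumerate(genes)}
    for pc in cfg.planted_cnvs:
        for k, g in enumerate(genes):
            if g.chrom == pc.chrom and g.start <= pc.end and g.end >= pc.start:
                effect[k, pc.carrier] *= pc.copy_ratio
    for ps in cfg.planted_snvs:
        effect[gene_index[ps.gene], ps.carrier] *= ps.expression_ratio

    noise_rng = _rng(cfg.seed, _NOISE)
    noise = (
        np.exp2(noise_rng.normal(0.0, cfg.noise_sd_log2, effect.shape))
        if cfg.noise_sd_log2 > 0 else 1.0
    )
    values = baseline[:, None] * effect * noise
    # silent genes get sparse low counts rather than exact zeros
    silent = ~expressed
    if silent.any():
        values[silent] = noise_rng.poisson(0.05, (int(silent.sum()), cfg.n_trios))
    if cfg.integer_counts:
        values = np.rint(values)
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=[g.gene_id for g in genes], columns=probands),
        normalized=False,
    )

    # --- SNV records (VCF rows) ------------------------------------------
    vcf_rng = _rng(cfg.seed, _VCF)
    all_samples = [ind.sample_id for ind in individuals]
    snv_records: List[SnvRecord] = []
    listed_genes: set = set()

    def plant_snv(trio_index: int, gene_id: str, consequence: Consequence,
                  origin: Origin) -> SnvRecord:
        g = by_id[gene_id]
        pos = g.start + int(vcf_rng.integers(0, g.length))
        pos_in_gene = pos - g.start + 1
        hgvs_c, hgvs_p = _hgvs_for(consequence, pos_in_gene)
        p_gt, f_gt, m_gt = _origin_genotypes(origin)
        fam, proband, father, mother = _trio_ids(trio_index)
        gts = []
        for s in all_samples:
            if s == proband:
                gts.append((s, p_gt))
            elif s == father:
                gts.append((s, f_gt))
            elif s == mother:
                gts.append((s, m_gt))
            else:
                gts.append((s, Genotype.HOM_REF))
        return SnvRecord(
            chrom=g.chrom, pos=pos, ref="C", alt="T", gene=gene_id,
            consequence=consequence, hgvs_c=hgvs_c, hgvs_p=hgvs_p,
            genotypes=tuple(gts),
        )

    truth_rows = []
    for ps in cfg.planted_snvs:
        rec = plant_snv(ps.carrier, ps.gene, ps.consequence, ps.origin)
        snv_records.append(rec)
        listed_genes.add(ps.gene)
        truth_rows.append({
            "carrier": _trio_ids(ps.carrier)[1], "kind": "snv",
            "variant_key": rec.key, "gene": ps.gene,
            "origin": ps.origin.value,
            "expected_direction": "down" if ps.expression_ratio < 1 else "none",
        })

    if cfg.include_decoys and genes:
        # non-qualifying variants that must survive no filter:
        # de novo missense in a listed gene, inherited PTV in a listed gene,
        # de novo synonymous elsewhere.
        decoy_trios = [int(vcf_rng.integers(0, cfg.n_trios)) for _ in range(3)]
        decoy_gene = genes[int(vcf_rng.integers(0, len(genes)))].gene_id
        if listed_genes:
            some_listed = sorted(listed_genes)[0]
            snv_records.append(plant_snv(decoy_trios[0], some_listed,
                                         Consequence.MISSENSE, Origin.DE_NOVO))
            snv_records.append(plant_snv(decoy_trios[1], some_listed,
                                         Consequence.FRAMESHIFT, Origin.PATERNAL))
        snv_records.append(plant_snv(decoy_trios[2], decoy_gene,
                                     Consequence.SYNONYMOUS, Origin.DE_NOVO))

    # --- CNV calls --------------------------------------------------------
    cnv_calls: Dict[str, List[CnvCall]] = {}
    catalog: List[KnownRegion] = []
    for j, pc in enumerate(cfg.planted_cnvs):
        fam, proband, father, mother = _trio_ids(pc.carrier)
        call = CnvCall(proband, pc.chrom, pc.start, pc.end, pc.cnv_type)
        cnv_calls.setdefault(proband, []).append(call)
        carriers = {
            Origin.DE_NOVO: (), Origin.PATERNAL: (father,),
            Origin.MATERNAL: (mother,), Origin.INHERITED_BOTH: (father, mother),
        }[pc.origin]
        for parent in carriers:
            cnv_calls.setdefault(parent, []).append(
                CnvCall(parent, pc.chrom, pc.start, pc.end, pc.cnv_type)
            )
        if pc.in_catalog:
            catalog.append(KnownRegion(
                name=f"region_{j:02d}_{pc.chrom}", chrom=pc.chrom,
                start=pc.start, end=pc.end,
                syndrome=f"synthetic {pc.cnv_type.value} syndrome",
            ))
        truth_rows.append({
            "carrier": proband, "kind": "cnv",
            "variant_key": f"{pc.chrom}:{pc.start}-{pc.end}:{pc.cnv_type.value}",
            "gene": "", "origin": pc.origin.value,
            "expected_direction": "up" if pc.cnv_type is CnvType.DUPLICATION else "down",
        })

    truth = pd.DataFrame(
        truth_rows,
        columns=["carrier", "kind", "variant_key", "gene", "origin", "expected_direction"],
    )
    gene_list = GeneList(frozenset(listed_genes))
    return CohortData(pedigree, snv_records, cnv_calls, matrix, truth,
                      genes, gene_list, catalog)


# ---------------------------------------------------------------------------
# Study conditions
# ---------------------------------------------------------------------------

def study_config(seed: int = 0) -> SimulationConfig:
    """Simulation mirroring the reference cohort's structure.

    354 trios; 9 catalog-matching multi-gene CNVs (6 duplications at copy
    ratio 1.5, 3 deletions at 0.5; 5 de novo, 2 maternal, 2 paternal) and 10
    de novo PTV SNVs (4 frameshift, 3 nonsense, 2 splice, 1 more frameshift)
    in listed genes, one per carrier, all carriers distinct.
    """
    cfg = SimulationConfig(seed=seed, n_trios=354, n_chromosomes=9,
                           genes_per_chromosome=120)
    genes = generate_genome(cfg)
    cnv_specs = [
        # (chrom index, first gene, n genes, type, origin)
        (1, 20, 12, CnvType.DUPLICATION, Origin.DE_NOVO),
        (2, 40, 16, CnvType.DUPLICATION, Origin.DE_NOVO),
        (3, 10, 10, CnvType.DELETION, Origin.PATERNAL),
        (4, 60, 14, CnvType.DUPLICATION, Origin.MATERNAL),
        (5, 30, 20, CnvType.DUPLICATION, Origin.MATERNAL),
        (6, 50, 8, CnvType.DELETION, Origin.DE_NOVO),
        (7, 70, 18, CnvType.DELETION, Origin.DE_NOVO),
        (8, 15, 22, CnvType.DUPLICATION, Origin.DE_NOVO),
        (9, 80, 15, CnvType.DUPLICATION, Origin.MATERNAL),
    ]
    planted_cnvs = []
    for i, (ci, first, count, ctype, origin) in enumerate(cnv_specs):
        chrom = f"chr{ci}"
        start, end = span_of_genes(genes, chrom, first, count)
        ratio = 1.5 if ctype is CnvType.DUPLICATION else 0.5
        planted_cnvs.append(PlantedCnv(
            carrier=i, chrom=chrom, start=start, end=end, cnv_type=ctype,
            copy_ratio=ratio, origin=origin,
        ))
    snv_consequences = [
        Consequence.FRAMESHIFT, Consequence.NONSENSE, Consequence.FRAMESHIFT,
        Consequence.NONSENSE, Consequence.FRAMESHIFT, Consequence.SPLICE_ACCEPTOR,
        Consequence.FRAMESHIFT, Consequence.SPLICE_DONOR, Consequence.FRAMESHIFT,
        Consequence.NONSENSE,
    ]
    planted_snvs = tuple(
        PlantedSnv(carrier=9 + i, gene=f"chr{(i % 9) + 1}_g{100 + (i // 9):04d}",
                   consequence=cons)
        for i, cons in enumerate(snv_consequences)
    )
    return SimulationConfig(
        seed=seed, n_trios=354, n_chromosomes=9, genes_per_chromosome=120,
        planted_cnvs=tuple(planted_cnvs), planted_snvs=planted_snvs,
    )


# ---------------------------------------------------------------------------
# qPCR plate
# ---------------------------------------------------------------------------

def generate_qpcr_plate(
    copy_ratio: float,
    efficiency: float = 2.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_id: str = "case",
    calibrator_id: str = "control",
    target_gene: str = "CNV_target",
    reference_gene: str = "GAPDH",
    n_replicates: int = 3,
    base_cq_target: float = 25.0,
    base_cq_reference: float = 20.0,
) -> QpcrPlate:
    """Triplicate plate from a true copy ratio.

    The case sample's target Cq is shifted by -log_E(ratio) relative to the
    calibrator; the reference gene is flat. Gaussian noise of ``noise_sd``
    cycles is added per case well, modelling measurement noise around the
    calibrator baseline (Cq_sample = Cq_calibrator - log_E(ratio) + noise).
    """
    if copy_ratio <= 0:
        raise ConfigError("copy ratio must be positive")
    rng = _rng(seed, _QPCR)
    shift = math.log(copy_ratio, efficiency)
    wells = []
    layout = [
        (calibrator_id, target_gene, "target", True, base_cq_target),
        (calibrator_id, reference_gene, "reference", True, base_cq_reference),
        (sample_id, target_gene, "target", False, base_cq_target - shift),
        (sample_id, reference_gene, "reference", False, base_cq_reference),
    ]
    for sid, gene, role, is_cal, cq in layout:
        for rep in range(1, n_replicates + 1):
            noisy = cq
            if noise_sd > 0 and not is_cal:
                noisy += rng.normal(0.0, noise_sd)
            wells.append(Well(sid, gene, role, is_cal, rep, noisy, efficiency))
    return QpcrPlate(wells)


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

@dataclass
class FastqTruth:
    n_rich_ids: set
    lowq_ids: set
    adapter_ids: set


def generate_fastq_pairs(
    n_pairs: int,
    n_rich_rate: float = 0.0,
    lowq_rate: float = 0.0,
    adapter_rate: float = 0.0,
    seed: int = 0,
    read_length: int = 150,
) -> Tuple[List[ReadPair], FastqTruth]:
    """Read pairs with planted QC violations.

    Planted counts are round(rate * n_pairs) per category, assigned to
    disjoint pair subsets: N-rich mates carry 5 N bases (> 3), low-quality
    mates have 25% of bases at Phred 2 (> 20% below 5), adapter pairs are
    flagged. All other pairs are clean.
    """
    for rate in (n_rich_rate, lowq_rate, adapter_rate):
        if not 0 <= rate <= 1:
            raise ConfigError("contamination rates must be in [0, 1]")
    rng = _rng(seed, _FASTQ)
    n_n = round(n_rich_rate * n_pairs)
    n_q = round(lowq_rate * n_pairs)
    n_a = round(adapter_rate * n_pairs)
    if n_n + n_q + n_a > n_pairs:
        raise ConfigError("contamination rates exceed the number of pairs")
    order = rng.permutation(n_pairs)
    n_set = set(order[:n_n])
    q_set = set(order[n_n:n_n + n_q])
    a_set = set(order[n_n + n_q:n_n + n_q + n_a])

    bases = np.array(list("ACGT"))
    pairs, truth = [], FastqTruth(set(), set(), set())
    for i in range(n_pairs):
        rid = f"read{i:06d}"
        mates = []
        for mate in (1, 2):
            seq = list(rng.choice(bases, size=read_length))
            qual = [int(q) for q in rng.integers(30, 41, size=read_length)]
            if i in n_set and mate == 1:
                for j in rng.choice(read_length, size=5, replace=False):
                    seq[j] = "N"
            if i in q_set and mate == 2:
                n_low = int(read_length * 0.25)
                for j in rng.choice(read_length, size=n_low, replace=False):
                    qual[j] = 2
            mates.append(Read(f"{rid}/{mate}", "".join(seq), tuple(qual)))
        pairs.append(ReadPair(mates[0], mates[1], adapters_detected=i in a_set))
        if i in n_set:
            truth.n_rich_ids.add(rid)
        elif i in q_set:
            truth.lowq_ids.add(rid)
        elif i in a_set:
            truth.adapter_ids.add(rid)
    return pairs, truth


# ---------------------------------------------------------------------------
# Writing a cohort to disk
# ---------------------------------------------------------------------------

def write_cohort(cohort: CohortData, outdir) -> Dict[str, Path]:
    """Write every pipeline input file plus the truth table; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": outdir / "cohort.ped",
        "snvs": outdir / "snvs.vcf",
        "cnvs": outdir / "cnvs.tsv",
        "expression": outdir / "expression.tsv",
        "genes": outdir / "genes.tsv",
        "gene_list": outdir / "gene_list.tsv",
        "catalog": outdir / "catalog.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_pedigree(cohort.pedigree, paths["pedigree"])
    contigs = sorted({g.chrom for g in cohort.genes})
    write_snv_calls(cohort.snv_records, paths["snvs"], contigs=contigs)
    all_cnvs = [c for calls in cohort.cnv_calls.values() for c in calls]
    write_cnv_calls(sorted(all_cnvs, key=lambda c: (c.sample_id, c.chrom, c.start)),
                    paths["cnvs"])
    write_expression_matrix(cohort.expression, paths["expression"])
    write_gene_models(cohort.genes, paths["genes"])
    with open(paths["gene_list"], "w") as fh:
        fh.write("symbol\thaploinsufficient\n")
        for sym in sorted(cohort.gene_list.symbols):
            flag = "1" if sym in cohort.gene_list.haploinsufficient else "0"
            fh.write(f"{sym}\t{flag}\n")
    with open(paths["catalog"], "w") as fh:
        fh.write("name\tchrom\tstart\tend\tsyndrome\tkey_genes\n")
        for r in cohort.catalog:
            fh.write(f"{r.name}\t{r.chrom}\t{r.start}\t{r.end}\t{r.syndrome}\t"
                     + ";".join(r.key_genes) + "\n")
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
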