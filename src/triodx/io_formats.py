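"""Readers/writers for the pipeline's external formats, plus the read-pair QC filter.

Formats: paired FASTQ (Phred+33), BED3+ gene models (converted to the internal
1-based inclusive convention at the boundary), CNV TSV (1-based inclusive),
VCF 4.2 trio small variants (pysam), 6-column PED, genes x samples expression
TSV, and long-format qPCR CSV plates.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .expression_validation import ExpressionMatrix
from .qpcr_quant import QpcrPlate, Well
from .variant_triage import (
    CnvCall,
    CnvType,
    Consequence,
    GeneList,
    Genotype,
    KnownRegion,
    Origin,
    SnvCall,
    TrioGenotypes,
)


class ParseError(ValueError):
    """Malformed input file; message carries the file and line context."""


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A gene span. Coordinates are 1-based inclusive on both ends."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("empty chromosome name")
        if self.end < self.start:
            raise ValueError(f"{self.gene_id}: end {self.end} < start {self.start}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def read_gene_models(path) -> List[GeneModel]:
    """Read gene models from BED (0-based half-open) or headered TSV (1-based).

    BED is detected by the ``.bed`` suffix; coordinates are converted to the
    internal 1-based inclusive convention. Duplicate gene ids are rejected.
    """
    path = Path(path)
    is_bed = path.suffix.lower() == ".bed"
    genes: List[GeneModel] = []
    seen: set = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if is_bed:
                    chrom, start, end = fields[0], int(fields[1]) + 1, int(fields[2])
                    gene_id = fields[3] if len(fields) > 3 else f"feature_{lineno}"
                    strand = fields[5] if len(fields) > 5 else "+"
                else:
                    if lineno == 1 and fields[0] == "gene_id":
                        continue
                    gene_id, chrom = fields[0], fields[1]
                    start, end = int(fields[2]), int(fields[3])
                    strand = fields[4] if len(fields) > 4 else "+"
                gene = GeneModel(gene_id, chrom, start, end, strand)
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if gene.gene_id in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene id {gene.gene_id!r}")
            seen.add(gene.gene_id)
            genes.append(gene)
    return genes


def write_gene_models(genes: Iterable[GeneModel], path) -> None:
    """Write gene models; ``.bed`` suffix emits BED6, anything else headered TSV."""
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix.lower() == ".bed":
            for g in genes:
                fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
        else:
            fh.write("gene_id\tchrom\tstart\tend\tstrand\n")
            for g in genes:
                fh.write(f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\n")


# ---------------------------------------------------------------------------
# FASTQ read pairs and QC
# ---------------------------------------------------------------------------

ADAPTER_TOKEN = "adapter"


@dataclass(frozen=True)
class Read:
    read_id: str
    sequence: str
    qualities: Tuple[int, ...]  # Phred scores, same length as sequence

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ParseError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )


@dataclass(frozen=True)
class ReadPair:
    read1: Read
    read2: Read
    adapters_detected: bool = False


@dataclass
class QcReport:
    n_input_pairs: int = 0
    n_removed_n: int = 0
    n_removed_lowq: int = 0
    n_removed_adapter: int = 0
    n_clean: int = 0


def _n_rich(read: Read, max_n: int) -> bool:
    return read.sequence.upper().count("N") > max_n


def _low_quality(read: Read, threshold: int, fraction: float) -> bool:
    n_low = sum(1 for q in read.qualities if q < threshold)
    return n_low / len(read.qualities) > fraction


def qc_filter_read_pairs(
    pairs: Iterable[ReadPair],
    max_n: int = 3,
    lowq_threshold: int = 5,
    lowq_fraction: float = 0.20,
) -> Tuple[List[ReadPair], QcReport]:
    """Remove read pairs failing any of three rules, in either mate.

    A pair is removed iff (strictly more than ``max_n`` N bases) or (the
    fraction of bases with Phred quality below ``lowq_threshold`` strictly
    exceeds ``lowq_fraction``) or adapter sequence was detected. Boundary
    values pass. Each removal is reported under the first matching rule in the
    order N -> low-quality -> adapter.
    """
    report = QcReport()
    clean: List[ReadPair] = []
    for pair in pairs:
        report.n_input_pairs += 1
        mates = (pair.read1, pair.read2)
        if any(_n_rich(r, max_n) for r in mates):
            report.n_removed_n += 1
        elif any(_low_quality(r, lowq_threshold, lowq_fraction) for r in mates):
            report.n_removed_lowq += 1
        elif pair.adapters_detected:
            report.n_removed_adapter += 1
        else:
            clean.append(pair)
            report.n_clean += 1
    return clean, report


def read_fastq_pairs(path1, path2) -> Iterator[ReadPair]:
    """Stream read pairs from two parallel FASTQ files (Phred+33).

    A pair is adapter-flagged iff either mate's description contains the
    ``adapter`` token (adapter detection itself is upstream).
    """
    it1 = SeqIO.parse(str(path1), "fastq")
    it2 = SeqIO.parse(str(path2), "fastq")
    for rec1, rec2 in zip(it1, it2):
        flagged = any(
            ADAPTER_TOKEN in rec.description.split()[1:] for rec in (rec1, rec2)
        )
        yield ReadPair(
            read1=Read(rec1.id, str(rec1.seq),
                       tuple(rec1.letter_annotations["phred_quality"])),
            read2=Read(rec2.id, str(rec2.seq),
                       tuple(rec2.letter_annotations["phred_quality"])),
            adapters_detected=flagged,
        )


def write_fastq_pairs(pairs: Iterable[ReadPair], path1, path2) -> None:
    recs1, recs2 = [], []
    for pair in pairs:
        for read, bucket in ((pair.read1, recs1), (pair.read2, recs2)):
            rec = SeqRecord(Seq(read.sequence), id=read.read_id,
                            description=ADAPTER_TOKEN if pair.adapters_detected else "")
            rec.letter_annotations["phred_quality"] = list(read.qualities)
            bucket.append(rec)
    SeqIO.write(recs1, str(path1), "fastq")
    SeqIO.write(recs2, str(path2), "fastq")


# ---------------------------------------------------------------------------
# CNV calls
# ---------------------------------------------------------------------------

def read_cnv_calls(path) -> List[CnvCall]:
    """CNV TSV: sample_id, chrom, start, end, cnv_type (1-based inclusive)."""
    calls: List[CnvCall] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, 2):
            try:
                calls.append(CnvCall(
                    sample_id=row["sample_id"], chrom=row["chrom"],
                    start=int(row["start"]), end=int(row["end"]),
                    cnv_type=CnvType(row["cnv_type"]),
                ))
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return calls


def write_cnv_calls(calls: Iterable[CnvCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tchrom\tstart\tend\tcnv_type\n")
        for c in calls:
            fh.write(f"{c.sample_id}\t{c.chrom}\t{c.start}\t{c.end}\t{c.cnv_type.value}\n")


# ---------------------------------------------------------------------------
# Known-region catalog and gene lists
# ---------------------------------------------------------------------------

def read_known_regions(path) -> List[KnownRegion]:
    """Catalog TSV: name, chrom, start, end, syndrome, key_genes (';'-joined)."""
    regions = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, 2):
            try:
                regions.append(KnownRegion(
                    name=row["name"], chrom=row["chrom"],
                    start=int(row["start"]), end=int(row["end"]),
                    syndrome=row.get("syndrome", ""),
                    key_genes=tuple(g for g in row.get("key_genes", "").split(";") if g),
                ))
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return regions


def read_gene_list(path) -> GeneList:
    """Gene list TSV: symbol, haploinsufficient {0,1}."""
    records = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            records.append((row["symbol"], row.get("haploinsufficient", "0") == "1"))
    return GeneList.from_records(records)


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Individual:
    family_id: str
    sample_id: str
    father: str  # "0" if unknown
    mother: str
    sex: str  # "male" | "female" | "unknown"
    affected: bool


@dataclass(frozen=True)
class Trio:
    proband: str
    father: str
    mother: str


@dataclass
class Pedigree:
    individuals: List[Individual]
    _by_id: Dict[str, Individual] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._by_id = {ind.sample_id: ind for ind in self.individuals}
        if len(self._by_id) != len(self.individuals):
            raise ParseError("duplicate sample id in pedigree")

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    def __getitem__(self, sample_id: str) -> Individual:
        return self._by_id[sample_id]

    def sex_of(self, sample_id: str) -> str:
        return self._by_id[sample_id].sex

    def trios(self) -> List[Trio]:
        out = []
        for ind in self.individuals:
            if ind.affected and ind.father != "0" and ind.mother != "0":
                out.append(Trio(ind.sample_id, ind.father, ind.mother))
        return out

    def trio_of(self, proband: str) -> Optional[Trio]:
        for trio in self.trios():
            if trio.proband == proband:
                return trio
        return None


_SEX = {"1": "male", "2": "female", "0": "unknown"}
_SEX_CODE = {"male": "1", "female": "2", "unknown": "0"}


def read_pedigree(path) -> Pedigree:
    """6-column PED: family, id, father, mother, sex (1/2), phenotype (2=affected)."""
    inds = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 PED columns")
            fam, sid, father, mother, sex, pheno = fields[:6]
            inds.append(Individual(fam, sid, father, mother,
                                   _SEX.get(sex, "unknown"), pheno == "2"))
    return Pedigree(inds)


def write_pedigree(ped: Pedigree, path) -> None:
    with open(path, "w") as fh:
        for ind in ped.individuals:
            fh.write(" ".join([
                ind.family_id, ind.sample_id, ind.father, ind.mother,
                _SEX_CODE[ind.sex], "2" if ind.affected else "1",
            ]) + "\n")


# ---------------------------------------------------------------------------
# SNV calls (VCF)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnvRecord:
    """One VCF row with its annotation and per-sample genotypes."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: Consequence
    hgvs_c: str
    hgvs_p: Optional[str]
    genotypes: Tuple[Tuple[str, Genotype], ...]  # (sample_id, call)

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    def genotype_of(self, sample_id: str) -> Genotype:
        for sid, gt in self.genotypes:
            if sid == sample_id:
                return gt
        return Genotype.MISSING

    def trio_genotypes(self, trio: Trio) -> TrioGenotypes:
        return TrioGenotypes(
            variant_key=self.key,
            proband=self.genotype_of(trio.proband),
            father=self.genotype_of(trio.father),
            mother=self.genotype_of(trio.mother),
        )


def _gt_from_tuple(gt: tuple) -> Genotype:
    if gt is None or any(a is None for a in gt) or len(gt) == 0:
        return Genotype.MISSING
    alts = sum(1 for a in gt if a != 0)
    if alts == 0:
        return Genotype.HOM_REF
    if alts == len(gt):
        return Genotype.HOM_ALT
    return Genotype.HET


def read_snv_calls(path, pedigree: Optional[Pedigree] = None) -> List[SnvRecord]:
    """Read annotated trio SNVs from a VCF 4.x file.

    Expects INFO fields GENE, CSQ (consequence term), HGVSC and optional
    HGVSP. If ``pedigree`` is given, every pedigree member must appear among
    the VCF sample columns.
    """
    records: List[SnvRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        vcf_samples = list(vcf.header.samples)
        if pedigree is not None:
            missing = [i.sample_id for i in pedigree.individuals
                       if i.sample_id not in vcf_samples]
            if missing:
                raise ParseError(
                    f"{path}: pedigree members absent from VCF: {missing[:5]}"
                )
        for rec in vcf:
            info = rec.info
            gts = tuple(
                (s, _gt_from_tuple(rec.samples[s].get("GT"))) for s in vcf_samples
            )
            records.append(SnvRecord(
                chrom=rec.chrom, pos=rec.pos, ref=rec.ref,
                alt=rec.alts[0] if rec.alts else ".",
                gene=str(info.get("GENE", "")),
                consequence=Consequence(str(info.get("CSQ", "other"))),
                hgvs_c=str(info.get("HGVSC", "")),
                hgvs_p=str(info["HGVSP"]) if "HGVSP" in info else None,
                genotypes=gts,
            ))
    return records


_GT_STR = {
    Genotype.HOM_REF: (0, 0),
    Genotype.HET: (0, 1),
    Genotype.HOM_ALT: (1, 1),
    Genotype.MISSING: (None, None),
}


def write_snv_calls(records: Sequence[SnvRecord], path,
                    contigs: Optional[Sequence[str]] = None) -> None:
    """Write annotated SNVs as an uncompressed VCF 4.2 file."""
    header = pysam.VariantHeader()
    if contigs is None:
        contigs = sorted({r.chrom for r in records})
    for c in contigs:
        header.contigs.add(c, length=500_000_000)
    header.add_meta("INFO", items=[("ID", "GENE"), ("Number", "1"),
                                   ("Type", "String"), ("Description", "Gene symbol")])
    header.add_meta("INFO", items=[("ID", "CSQ"), ("Number", "1"),
                                   ("Type", "String"), ("Description", "Consequence")])
    header.add_meta("INFO", items=[("ID", "HGVSC"), ("Number", "1"),
                                   ("Type", "String"), ("Description", "HGVS cDNA")])
    header.add_meta("INFO", items=[("ID", "HGVSP"), ("Number", "1"),
                                   ("Type", "String"), ("Description", "HGVS protein")])
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"),
                                     ("Type", "String"), ("Description", "Genotype")])
    samples = list(dict.fromkeys(s for r in records for s, _ in r.genotypes))
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
            rec = out.new_record(
                contig=r.chrom, start=r.pos - 1, stop=r.pos - 1 + len(r.ref),
                alleles=(r.ref, r.alt),
            )
            rec.info["GENE"] = r.gene
            rec.info["CSQ"] = r.consequence.value
            # pysam drops INFO strings that are empty; keep a placeholder
            rec.info["HGVSC"] = r.hgvs_c or "."
            if r.hgvs_p:
                rec.info["HGVSP"] = r.hgvs_p
            gt_map = dict(r.genotypes)
            for s in samples:
                rec.samples[s]["GT"] = _GT_STR[gt_map.get(s, Genotype.MISSING)]
                rec.samples[s].phased = False
            out.write(rec)


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

def read_expression_matrix(path, normalized: bool = False) -> ExpressionMatrix:
    """Genes x samples TSV; first column gene_id, remaining columns samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ParseError(f"{path}: missing or non-numeric expression cell")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ParseError(f"{path}: non-numeric expression column {col!r}")
    try:
        return ExpressionMatrix(df, normalized=normalized)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_expression_matrix(m: ExpressionMatrix, path) -> None:
    df = m.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# qPCR plates
# ---------------------------------------------------------------------------

QPCR_COLUMNS = ["sample_id", "target_gene", "role", "is_calibrator",
                "replicate", "Cq", "efficiency"]


def read_qpcr_plate(path) -> QpcrPlate:
    """Long-format CSV: sample_id, target_gene, role, is_calibrator, replicate,
    Cq, efficiency (empty efficiency defaults to perfect doubling, E = 2)."""
    wells = []
    with open(path) as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, 2):
            try:
                eff = row.get("efficiency", "")
                wells.append(Well(
                    sample_id=row["sample_id"], target_gene=row["target_gene"],
                    role=row["role"],
                    is_calibrator=row["is_calibrator"] in ("1", "true", "True"),
                    replicate=int(row["replicate"]), cq=float(row["Cq"]),
                    efficiency=float(eff) if eff else 2.0,
                ))
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    try:
        return QpcrPlate(wells)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_qpcr_plate(plate: QpcrPlate, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(QPCR_COLUMNS)
        for w in plate.wells:
            writer.writerow([w.sample_id, w.target_gene, w.role,
                             int(w.is_calibrator), w.replicate,
                             repr(w.cq), repr(w.efficiency)])


# ---------------------------------------------------------------------------
# Triage findings
# ---------------------------------------------------------------------------

from .variant_triage import Finding  # noqa: E402

FINDING_COLUMNS = ["proband", "kind", "origin", "gene", "hgvs_c", "consequence",
                   "chrom", "start", "end", "cnv_type", "region"]


def write_findings(findings: Iterable[Finding], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(FINDING_COLUMNS) + "\n")
        for f in findings:
            row = [
                f.proband, f.kind, f.origin.value, f.gene or "", f.hgvs_c or "",
                f.consequence.value if f.consequence else "",
                f.chrom or "", str(f.start) if f.start else "",
                str(f.end) if f.end else "",
                f.cnv_type.value if f.cnv_type else "", f.region or "",
            ]
            fh.write("\t".join(row) + "\n")


def read_findings(path) -> List[Finding]:
    findings = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            findings.append(Finding(
                proband=row["proband"], kind=row["kind"],
                origin=Origin(row["origin"]), gene=row["gene"] or None,
                hgvs_c=row["hgvs_c"] or None,
                consequence=Consequence(row["consequence"]) if row["consequence"] else None,
                chrom=row["chrom"] or None,
                start=int(row["start"]) if row["start"] else None,
                end=int(row["end"]) if row["end"] else None,
                cnv_type=CnvType(row["cnv_type"]) if row["cnv_type"] else None,
                region=row["region"] or None,
            ))
    return findings


def snv_calls_from_records(records: Sequence[SnvRecord], pedigree: Pedigree) -> List[SnvCall]:
    """Expand VCF records into per-proband SNV calls with trio genotypes.

    One call per (variant, trio) pair in which the proband carries the
    alternate allele.
    """
    calls: List[SnvCall] = []
    for rec in records:
        for trio in pedigree.trios():
            tg = rec.trio_genotypes(trio)
            if tg.proband.carries():
                calls.append(SnvCall(
                    sample_id=trio.proband, gene=rec.gene, hgvs_c=rec.hgvs_c,
                    hgvs_p=rec.hgvs_p, consequence=rec.consequence, genotypes=tg,
                ))
    return calls
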