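"""Diagnostic triage of trio variant calls.

Implements the filter used for rare-mutation diagnosis in ASD trios:

* de novo protein-truncating SNVs (nonsense, frameshift, canonical +/-1/+/-2
  splice site) in genes from a curated ASD gene list, and
* CNVs at or above the calling resolution (default 100 kb) that either match a
  catalog of known syndromic regions by reciprocal overlap or delete a
  haploinsufficient gene.

Inheritance origin is classified from the trio genotype triple (SNVs) or from
reciprocal overlap against parental call sets (CNVs).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence


class Genotype(enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    def carries(self) -> Optional[bool]:
        """Whether this genotype carries the alternate allele (None if unknown)."""
        if self is Genotype.MISSING:
            return None
        return self in (Genotype.HET, Genotype.HOM_ALT)


class Consequence(enum.Enum):
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE_DONOR = "splice_donor"
    SPLICE_ACCEPTOR = "splice_acceptor"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


class Origin(enum.Enum):
    DE_NOVO = "de_novo"
    PATERNAL = "paternal"
    MATERNAL = "maternal"
    INHERITED_BOTH = "inherited_both"
    AMBIGUOUS = "ambiguous"


class CnvType(enum.Enum):
    DUPLICATION = "duplication"
    DELETION = "deletion"


class ClassificationError(ValueError):
    """Raised when a variant cannot be classified (e.g. unparseable HGVS)."""


@dataclass(frozen=True)
class TrioGenotypes:
    """Genotype triple for one variant: proband, father, mother."""

    variant_key: str
    proband: Genotype
    father: Genotype
    mother: Genotype


@dataclass(frozen=True)
class SnvCall:
    sample_id: str
    gene: str
    hgvs_c: str
    consequence: Consequence
    hgvs_p: Optional[str] = None
    origin: Optional[Origin] = None
    genotypes: Optional[TrioGenotypes] = None


@dataclass(frozen=True)
class CnvCall:
    sample_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    cnv_type: CnvType
    origin: Optional[Origin] = None
    matched_region: Optional["KnownRegion"] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"CNV end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def size(self) -> int:
        """Span in bp, 1-based inclusive: end - start + 1."""
        return self.end - self.start + 1


@dataclass(frozen=True)
class KnownRegion:
    """A recurrent syndromic CNV region (microdeletion/microduplication)."""

    name: str
    chrom: str
    start: int
    end: int
    syndrome: str = ""
    key_genes: tuple = ()

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"region end must exceed start: {self.name}")

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneList:
    """Curated set of disease-associated gene symbols (SFARI-style)."""

    symbols: frozenset
    haploinsufficient: frozenset = frozenset()

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "GeneList":
        syms, hi = set(), set()
        for symbol, flag in records:
            if symbol in syms:
                raise ValueError(f"duplicate gene symbol: {symbol}")
            syms.add(symbol)
            if flag:
                hi.add(symbol)
        return cls(frozenset(syms), frozenset(hi))

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols


@dataclass(frozen=True)
class Finding:
    """One qualifying diagnostic finding for a proband."""

    proband: str
    kind: str  # "snv" or "cnv"
    origin: Origin
    gene: Optional[str] = None
    hgvs_c: Optional[str] = None
    consequence: Optional[Consequence] = None
    chrom: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None
    cnv_type: Optional[CnvType] = None
    region: Optional[str] = None

    def key(self) -> tuple:
        if self.kind == "snv":
            return (self.proband, "snv", self.gene, self.hgvs_c)
        return (self.proband, "cnv", self.chrom, self.start, self.end,
                self.cnv_type.value if self.cnv_type else None)


# ---------------------------------------------------------------------------
# Origin classification
# ---------------------------------------------------------------------------

def classify_origin(tg: TrioGenotypes) -> Origin:
    """Assign inheritance origin from a complete trio genotype triple.

    The proband must carry the allele for any informative call; a missing
    genotype in a slot that would decide the call yields ``ambiguous``.
    """
    p, f, m = tg.proband.carries(), tg.father.carries(), tg.mother.carries()
    if p is not True:
        return Origin.AMBIGUOUS
    if f is None or m is None:
        return Origin.AMBIGUOUS
    if f and m:
        return Origin.INHERITED_BOTH
    if f:
        return Origin.PATERNAL
    if m:
        return Origin.MATERNAL
    return Origin.DE_NOVO


_SPLICE_OFFSET = re.compile(r"c\.[*\d_]+([+-]\d+)")


def splice_offset(hgvs_c: str) -> int:
    """Intronic offset encoded in an HGVS c. description, e.g. c.605+1G>A -> +1."""
    m = _SPLICE_OFFSET.search(hgvs_c.replace(" ", ""))
    if m is None:
        raise ClassificationError(f"cannot parse intronic offset from {hgvs_c!r}")
    return int(m.group(1))


def classify_ptv(consequence: Consequence, hgvs_c: str = "") -> bool:
    """True iff the variant truncates the protein.

    Nonsense and frameshift always qualify; splice-site variants qualify only
    at the canonical +/-1/+/-2 positions, read from the HGVS intronic offset.
    """
    if consequence in (Consequence.NONSENSE, Consequence.FRAMESHIFT):
        return True
    if consequence in (Consequence.SPLICE_DONOR, Consequence.SPLICE_ACCEPTOR):
        return abs(splice_offset(hgvs_c)) <= 2
    return False


# ---------------------------------------------------------------------------
# CNV filters
# ---------------------------------------------------------------------------

def filter_cnv_resolution(cnv: CnvCall, min_size: int = 100_000) -> bool:
    """True iff the CNV is at or above the calling resolution (default 100 kb)."""
    return cnv.size >= min_size


def overlap_bp(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Overlap in bp between two 1-based inclusive intervals."""
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def reciprocal_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    """min(overlap/len(a), overlap/len(b)) for 1-based inclusive intervals."""
    ovl = overlap_bp(a_start, a_end, b_start, b_end)
    if ovl == 0:
        return 0.0
    return min(ovl / (a_end - a_start + 1), ovl / (b_end - b_start + 1))


def match_known_region(
    cnv: CnvCall,
    catalog: Iterable[KnownRegion],
    min_reciprocal_overlap: float = 0.5,
) -> Optional[KnownRegion]:
    """Best catalog region matching the CNV by reciprocal overlap.

    Both quotients (overlap over CNV length, overlap over region length) must
    reach the threshold. Among qualifying regions the one with maximal
    reciprocal overlap wins; ties break to the smaller region, then name.
    """
    best: Optional[tuple] = None
    for region in catalog:
        if region.chrom != cnv.chrom:
            continue
        ovl = overlap_bp(cnv.start, cnv.end, region.start, region.end)
        if ovl == 0:
            continue
        frac_cnv = ovl / cnv.size
        frac_region = ovl / region.size
        if frac_cnv < min_reciprocal_overlap or frac_region < min_reciprocal_overlap:
            continue
        score = (-min(frac_cnv, frac_region), region.size, region.name)
        if best is None or score < best[0]:
            best = (score, region)
    return None if best is None else best[1]


def cnv_origin(
    proband_cnv: CnvCall,
    paternal_cnvs: Sequence[CnvCall],
    maternal_cnvs: Sequence[CnvCall],
    min_reciprocal_overlap: float = 0.5,
) -> Origin:
    """Inheritance origin of a CNV from parental call sets.

    A parent carries the CNV iff any of their same-type calls on the same
    chromosome reciprocally overlaps the proband call at the threshold.
    Presence/absence of calls stands in for genotypes.
    """
    def carried(calls: Sequence[CnvCall]) -> bool:
        return any(
            c.cnv_type == proband_cnv.cnv_type
            and c.chrom == proband_cnv.chrom
            and reciprocal_overlap(proband_cnv.start, proband_cnv.end, c.start, c.end)
            >= min_reciprocal_overlap
            for c in calls
        )

    pat, mat = carried(paternal_cnvs), carried(maternal_cnvs)
    if pat and mat:
        return Origin.INHERITED_BOTH
    if pat:
        return Origin.PATERNAL
    if mat:
        return Origin.MATERNAL
    return Origin.DE_NOVO


# ---------------------------------------------------------------------------
# Triage
# ---------------------------------------------------------------------------

def triage(
    snvs: Iterable[SnvCall],
    cnvs: Mapping[str, Sequence[CnvCall]],
    pedigree: "Pedigree",
    gene_list: GeneList,
    catalog: Iterable[KnownRegion],
    gene_models: Optional[Sequence] = None,
    min_cnv_size: int = 100_000,
    min_reciprocal_overlap: float = 0.5,
) -> list:
    """Apply the diagnostic filter across a cohort.

    A proband is SNV-positive iff it carries at least one de novo
    protein-truncating variant in a gene on ``gene_list``; CNV-positive iff it
    carries a CNV passing the resolution filter that matches the known-region
    catalog (any origin) or is a deletion removing a gene flagged
    haploinsufficient (requires ``gene_models`` with coordinates).

    ``cnvs`` maps sample id (proband or parent) to that individual's calls.
    Returns a sorted, duplicate-free list of :class:`Finding`.
    """
    catalog = list(catalog)
    findings: dict = {}

    for snv in snvs:
        trio = pedigree.trio_of(snv.sample_id)
        if trio is None:
            raise KeyError(f"proband {snv.sample_id!r} not found in pedigree")
        origin = snv.origin
        if origin is None:
            if snv.genotypes is None:
                raise ValueError(
                    f"SNV for {snv.sample_id} has neither origin nor trio genotypes"
                )
            origin = classify_origin(snv.genotypes)
        if origin is not Origin.DE_NOVO:
            continue
        if snv.gene not in gene_list:
            continue
        if not classify_ptv(snv.consequence, snv.hgvs_c):
            continue
        f = Finding(
            proband=snv.sample_id, kind="snv", origin=origin, gene=snv.gene,
            hgvs_c=snv.hgvs_c, consequence=snv.consequence,
        )
        findings[f.key()] = f

    for trio in pedigree.trios():
        for cnv in cnvs.get(trio.proband, ()):  # probands only
            if not filter_cnv_resolution(cnv, min_cnv_size):
                continue
            origin = cnv.origin
            if origin is None:
                origin = cnv_origin(
                    cnv,
                    cnvs.get(trio.father, ()),
                    cnvs.get(trio.mother, ()),
                    min_reciprocal_overlap,
                )
            region = cnv.matched_region or match_known_region(
                cnv, catalog, min_reciprocal_overlap
            )
            qualifies = region is not None
            if not qualifies and cnv.cnv_type is CnvType.DELETION and gene_models:
                deleted = {
                    g.gene_id for g in gene_models
                    if g.chrom == cnv.chrom
                    and overlap_bp(cnv.start, cnv.end, g.start, g.end) > 0
                }
                qualifies = bool(deleted & set(gene_list.haploinsufficient))
            if not qualifies:
                continue
            f = Finding(
                proband=trio.proband, kind="cnv", origin=origin,
                chrom=cnv.chrom, start=cnv.start, end=cnv.end,
                cnv_type=cnv.cnv_type, region=region.name if region else None,
            )
            findings[f.key()] = f

    return sorted(findings.values(), key=lambda f: f.key())
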