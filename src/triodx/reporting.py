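"""Cohort-level summaries: diagnostic yields, sex ratio, CNV/SNV breakdowns,
and a comorbidity keyword tally over free-text clinical features."""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, Mapping, Optional, Sequence

from .variant_triage import CnvType, Finding, Origin

LOST_TO_FOLLOWUP_MARKER = "follow-up"
DEFAULT_COMORBIDITY_GROUPS = (("intellectual",), ("language",))


@dataclass
class CohortSummary:
    n_total: int
    n_male: int
    n_female: int
    male_female_ratio: float
    n_snv_pos: int
    n_cnv_pos: int
    n_pos: int
    n_de_novo_pos: int
    snv_rate: float
    cnv_rate: float
    total_rate: float
    de_novo_rate: float
    cnv_n_dup: int
    cnv_n_del: int
    cnv_n_de_novo: int
    cnv_n_inherited: int
    snv_gene_recurrence: Dict[str, int] = field(default_factory=dict)
    comorbidity_count: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_male + self.n_female != self.n_total:
            raise ValueError("n_male + n_female must equal n_total")
        if self.n_pos > self.n_snv_pos + self.n_cnv_pos:
            raise ValueError("distinct positives cannot exceed SNV + CNV positives")


def percent(k: int, n: int) -> float:
    """100*k/n, rounded half-up to one decimal place."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= k <= n:
        raise ValueError("numerator must be within [0, n]")
    return float(
        (Decimal(k) * 100 / Decimal(n)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


def comorbidity_tally(
    features: Mapping[str, str],
    groups: Sequence[Sequence[str]] = DEFAULT_COMORBIDITY_GROUPS,
) -> int:
    """Patients whose feature string matches every keyword group.

    Matching is case-insensitive substring search; a patient counts iff each
    group contributes at least one matching keyword. Patients whose feature
    string marks loss to follow-up are excluded first.
    """
    for group in groups:
        if not group:
            raise ValueError("empty comorbidity keyword group")
    count = 0
    for text in features.values():
        low = text.lower()
        if LOST_TO_FOLLOWUP_MARKER in low:
            continue
        if all(any(kw.lower() in low for kw in group) for group in groups):
            count += 1
    return count


def summarize(
    findings: Iterable[Finding],
    sex_by_sample: Mapping[str, str],
    features: Optional[Mapping[str, str]] = None,
    comorbidity_groups: Sequence[Sequence[str]] = DEFAULT_COMORBIDITY_GROUPS,
) -> CohortSummary:
    """Aggregate triage findings into cohort-level yields.

    ``sex_by_sample`` covers the whole cohort ("male"/"female" per proband)
    and defines the denominator. A proband with both SNV and CNV findings
    counts once in the total; a proband is a de novo positive iff every one of
    its diagnostic findings is de novo. CNV breakdown counts findings, not
    probands.
    """
    findings = list(findings)
    sexes = dict(sex_by_sample)
    n_total = len(sexes)
    n_male = sum(1 for s in sexes.values() if s == "male")
    n_female = sum(1 for s in sexes.values() if s == "female")

    snv_probands, cnv_probands = set(), set()
    origins_by_proband: Dict[str, list] = {}
    cnv_n_dup = cnv_n_del = cnv_n_de_novo = cnv_n_inherited = 0
    gene_recurrence: Dict[str, int] = {}
    for f in findings:
        if f.proband not in sexes:
            raise KeyError(f"sex metadata missing for proband {f.proband!r}")
        origins_by_proband.setdefault(f.proband, []).append(f.origin)
        if f.kind == "snv":
            snv_probands.add(f.proband)
            if f.gene:
                gene_recurrence[f.gene] = gene_recurrence.get(f.gene, 0) + 1
        else:
            cnv_probands.add(f.proband)
            cnv_n_dup += f.cnv_type is CnvType.DUPLICATION
            cnv_n_del += f.cnv_type is CnvType.DELETION
            if f.origin is Origin.DE_NOVO:
                cnv_n_de_novo += 1
            else:
                cnv_n_inherited += 1

    positives = snv_probands | cnv_probands
    de_novo_pos = sum(
        1 for p, origins in origins_by_proband.items()
        if all(o is Origin.DE_NOVO for o in origins)
    )
    ratio = round(n_male / n_female, 2) if n_female else float("inf")
    return CohortSummary(
        n_total=n_total, n_male=n_male, n_female=n_female,
        male_female_ratio=ratio,
        n_snv_pos=len(snv_probands), n_cnv_pos=len(cnv_probands),
        n_pos=len(positives), n_de_novo_pos=de_novo_pos,
        snv_rate=percent(len(snv_probands), n_total),
        cnv_rate=percent(len(cnv_probands), n_total),
        total_rate=percent(len(positives), n_total),
        de_novo_rate=percent(de_novo_pos, n_total),
        cnv_n_dup=cnv_n_dup, cnv_n_del=cnv_n_del,
        cnv_n_de_novo=cnv_n_de_novo, cnv_n_inherited=cnv_n_inherited,
        snv_gene_recurrence=dict(sorted(gene_recurrence.items())),
        comorbidity_count=(
            comorbidity_tally(features, comorbidity_groups) if features is not None else None
        ),
    )


def render_text(summary: CohortSummary) -> str:
    """Human-readable rendering of a cohort summary."""
    lines = [
        f"Cohort: {summary.n_total} probands "
        f"({summary.n_male} male / {summary.n_female} female, "
        f"ratio {summary.male_female_ratio}:1)",
        f"SNV-positive probands: {summary.n_snv_pos} ({summary.snv_rate}%)",
        f"CNV-positive probands: {summary.n_cnv_pos} ({summary.cnv_rate}%)",
        f"Total positive probands: {summary.n_pos} ({summary.total_rate}%)",
        f"De novo positive probands: {summary.n_de_novo_pos} ({summary.de_novo_rate}%)",
        f"CNV breakdown: {summary.cnv_n_dup} duplications, {summary.cnv_n_del} deletions; "
        f"{summary.cnv_n_de_novo} de novo, {summary.cnv_n_inherited} inherited",
    ]
    recurrent = {g: n for g, n in summary.snv_gene_recurrence.items() if n > 1}
    if recurrent:
        lines.append("Recurrently hit SNV genes: "
                     + ", ".join(f"{g} (x{n})" for g, n in recurrent.items()))
    if summary.comorbidity_count is not None:
        lines.append(f"Patients with all comorbidity keyword groups: "
                     f"{summary.comorbidity_count}")
    return "\n".join(lines)
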