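"""qBase-style relative quantification of copy number from qPCR plates.

Triplicate Cq values are averaged (with a simple range-based outlier drop),
converted to relative quantities RQ = E^(Cq_calibrator - Cq_sample) with
per-gene amplification efficiency E, and normalized to a single reference gene
(GAPDH-style): NRQ = RQ_target / RQ_reference. The calibrator (normal control)
sample has NRQ = 1 by construction; NRQ near 0.5 / 1.5 indicates a
heterozygous deletion / duplication of the target locus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import median
from typing import Iterable, List, Optional, Sequence


class ReplicateError(ValueError):
    """Raised for insufficient or non-finite replicate Cq values."""


class PlateError(ValueError):
    """Raised for structurally invalid plates."""


@dataclass(frozen=True)
class Well:
    sample_id: str
    target_gene: str
    role: str  # "target" | "reference"
    is_calibrator: bool
    replicate: int
    cq: float
    efficiency: float = 2.0  # amplification factor per cycle, in (1, 2]


@dataclass
class QpcrPlate:
    """A set of wells; each (sample, gene) group holds replicate Cq values."""

    wells: List[Well]

    def __post_init__(self) -> None:
        calibrators = {w.sample_id for w in self.wells if w.is_calibrator}
        if len(calibrators) != 1:
            raise PlateError(
                f"plate must have exactly one calibrator sample, found {sorted(calibrators)}"
            )
        eff_by_gene: dict = {}
        for w in self.wells:
            if not 1.0 < w.efficiency <= 2.0:
                raise PlateError(
                    f"efficiency {w.efficiency} for {w.target_gene} outside (1, 2]"
                )
            eff_by_gene.setdefault(w.target_gene, set()).add(w.efficiency)
        for gene, effs in eff_by_gene.items():
            if len(effs) > 1:
                raise PlateError(f"gene {gene} has conflicting efficiencies {sorted(effs)}")
        for (sample, gene), cqs in self.groups().items():
            if len(cqs) < 2:
                raise PlateError(
                    f"well group ({sample}, {gene}) has {len(cqs)} replicate(s); need >= 2"
                )

    @property
    def calibrator(self) -> str:
        return next(w.sample_id for w in self.wells if w.is_calibrator)

    def groups(self) -> dict:
        out: dict = {}
        for w in self.wells:
            out.setdefault((w.sample_id, w.target_gene), []).append(w.cq)
        return out

    def efficiency(self, gene: str) -> float:
        return next(w.efficiency for w in self.wells if w.target_gene == gene)

    def reference_gene(self) -> str:
        refs = {w.target_gene for w in self.wells if w.role == "reference"}
        if len(refs) != 1:
            raise PlateError(f"expected exactly one reference gene, found {sorted(refs)}")
        return next(iter(refs))

    def target_genes(self) -> list:
        return sorted({w.target_gene for w in self.wells if w.role == "target"})


@dataclass(frozen=True)
class CopyNumberCall:
    sample_id: str
    target_gene: str
    delta_cq: float
    nrq: float
    call: str  # "deletion" | "normal" | "duplication"


def aggregate_replicates(cqs: Sequence[float], max_range: float = 0.5) -> float:
    """Mean Cq of a replicate group.

    With >= 3 replicates whose range exceeds ``max_range`` cycles, the single
    value farthest from the median is dropped before averaging.
    """
    vals = list(cqs)
    if len(vals) < 2:
        raise ReplicateError(f"need >= 2 replicate Cq values, got {len(vals)}")
    if not all(math.isfinite(v) for v in vals):
        raise ReplicateError(f"non-finite Cq among replicates: {vals}")
    if len(vals) >= 3 and max(vals) - min(vals) > max_range:
        med = median(vals)
        vals.remove(max(vals, key=lambda v: abs(v - med)))
    return sum(vals) / len(vals)


def relative_quantity(cq_sample: float, cq_calibrator: float, efficiency: float = 2.0) -> float:
    """RQ = E^(Cq_calibrator - Cq_sample); 1 when the sample equals the calibrator."""
    if not (math.isfinite(cq_sample) and math.isfinite(cq_calibrator)):
        raise ReplicateError("non-finite Cq")
    if not 1.0 < efficiency <= 2.0:
        raise ValueError(f"efficiency {efficiency} outside (1, 2]")
    return efficiency ** (cq_calibrator - cq_sample)


def normalized_relative_quantity(rq_target: float, rq_reference: float) -> float:
    """NRQ = RQ_target / RQ_reference (reference-gene normalization)."""
    if rq_target <= 0 or rq_reference <= 0:
        raise ValueError("relative quantities must be positive")
    return rq_target / rq_reference


def call_copy_number(nrq: float, del_max: float = 0.75, dup_min: float = 1.25) -> str:
    """Threshold NRQ into deletion / normal / duplication.

    Defaults are midpoints between the diploid expectation 1.0 and the
    heterozygous expectations 0.5 and 1.5.
    """
    if nrq <= 0:
        raise ValueError("NRQ must be positive")
    if nrq <= del_max:
        return "deletion"
    if nrq >= dup_min:
        return "duplication"
    return "normal"


def quantify_plate(
    plate: QpcrPlate,
    del_max: float = 0.75,
    dup_min: float = 1.25,
) -> List[CopyNumberCall]:
    """Run the full qBase pipeline over a plate.

    For every non-reference (sample, target) pair: aggregate replicates,
    compute RQ against the calibrator for target and reference gene, divide,
    and threshold the NRQ into a copy-number call. The calibrator sample's own
    calls are included (NRQ exactly 1).
    """
    ref_gene = plate.reference_gene()
    groups = {k: aggregate_replicates(v) for k, v in plate.groups().items()}
    cal = plate.calibrator
    samples = sorted({s for s, _ in groups})
    calls = []
    for sample in samples:
        for gene in plate.target_genes():
            if (sample, gene) not in groups:
                continue
            rq_t = relative_quantity(
                groups[(sample, gene)], groups[(cal, gene)], plate.efficiency(gene)
            )
            rq_r = relative_quantity(
                groups[(sample, ref_gene)], groups[(cal, ref_gene)],
                plate.efficiency(ref_gene),
            )
            nrq = normalized_relative_quantity(rq_t, rq_r)
            calls.append(CopyNumberCall(
                sample_id=sample, target_gene=gene,
                delta_cq=groups[(cal, gene)] - groups[(sample, gene)],
                nrq=nrq, call=call_copy_number(nrq, del_max, dup_min),
            ))
    return calls
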