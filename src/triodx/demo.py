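"""Bundled demo cohort: transcriptions of the published diagnostic tables.

The package ships small TSVs with the 19 positive probands of the reference
ASD cohort — their clinical feature strings, diagnosed CNVs and SNVs with
inheritance origin, the known-region catalog, the ASD gene list, and the
printed dosage-validation statistics. These drive the worked example and the
printed-tally tests; raw patient data remain controlled-access and are not
included.
"""

from __future__ import annotations

import csv
from importlib import resources
from typing import Dict, List, Tuple

from .expression_validation import DosageValidationResult, SnvExpressionResult
from .io_formats import Individual, Pedigree, read_gene_list, read_known_regions
from .variant_triage import (
    CnvCall,
    CnvType,
    Consequence,
    Finding,
    GeneList,
    Genotype,
    KnownRegion,
    Origin,
    SnvCall,
    TrioGenotypes,
    triage,
)

# diagnosed probands in the reference cohort: 12 male, 7 female of 279/75
COHORT_SIZE = 354
COHORT_MALES = 279
COHORT_FEMALES = 75

_ORIGIN_GT = {
    Origin.DE_NOVO: (Genotype.HET, Genotype.HOM_REF, Genotype.HOM_REF),
    Origin.PATERNAL: (Genotype.HET, Genotype.HET, Genotype.HOM_REF),
    Origin.MATERNAL: (Genotype.HET, Genotype.HOM_REF, Genotype.HET),
    Origin.INHERITED_BOTH: (Genotype.HET, Genotype.HET, Genotype.HET),
}


def _data_path(name: str):
    return resources.files("triodx.data").joinpath(name)


def _read_rows(name: str) -> List[dict]:
    with _data_path(name).open() as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def load_known_regions() -> List[KnownRegion]:
    with resources.as_file(_data_path("known_regions.tsv")) as p:
        return read_known_regions(p)


def load_gene_list() -> GeneList:
    with resources.as_file(_data_path("asd_genes.tsv")) as p:
        return read_gene_list(p)


def load_clinical_features() -> Dict[str, str]:
    return {r["sample_id"]: r["features"] for r in _read_rows("clinical_features.tsv")}


def load_diagnosed_snvs() -> List[SnvCall]:
    calls = []
    for r in _read_rows("diagnosed_snvs.tsv"):
        origin = Origin(r["origin"])
        p, f, m = _ORIGIN_GT[origin]
        calls.append(SnvCall(
            sample_id=r["sample_id"], gene=r["gene"], hgvs_c=r["hgvs_c"],
            hgvs_p=r["hgvs_p"] or None,
            consequence=Consequence(r["consequence"]),
            genotypes=TrioGenotypes(
                variant_key=f"{r['gene']}:{r['hgvs_c']}", proband=p, father=f, mother=m,
            ),
        ))
    return calls


def load_diagnosed_cnvs() -> Dict[str, List[CnvCall]]:
    """Per-member CNV call sets; parental calls are derived from the origin."""
    calls: Dict[str, List[CnvCall]] = {}
    for r in _read_rows("diagnosed_cnvs.tsv"):
        proband = r["sample_id"]
        cnv = CnvCall(proband, r["chrom"], int(r["start"]), int(r["end"]),
                      CnvType(r["cnv_type"]))
        calls.setdefault(proband, []).append(cnv)
        origin = Origin(r["origin"])
        parents = {
            Origin.DE_NOVO: (), Origin.PATERNAL: (proband + "_fa",),
            Origin.MATERNAL: (proband + "_mo",),
            Origin.INHERITED_BOTH: (proband + "_fa", proband + "_mo"),
        }[origin]
        for parent in parents:
            calls.setdefault(parent, []).append(
                CnvCall(parent, cnv.chrom, cnv.start, cnv.end, cnv.cnv_type)
            )
    return calls


def load_pedigree() -> Pedigree:
    """Trios for every diagnosed proband, with the published proband sexes."""
    sexes = {r["sample_id"]: r["sex"] for r in _read_rows("clinical_features.tsv")}
    inds: List[Individual] = []
    for i, (proband, sex) in enumerate(sorted(sexes.items())):
        fam, father, mother = f"FAM{i:04d}", proband + "_fa", proband + "_mo"
        inds.append(Individual(fam, father, "0", "0", "male", False))
        inds.append(Individual(fam, mother, "0", "0", "female", False))
        inds.append(Individual(fam, proband, father, mother, sex, True))
    return Pedigree(inds)


def cohort_sex_table() -> Dict[str, str]:
    """Sex per proband for the full cohort (279 male / 75 female).

    Diagnosed probands carry their published sexes; the remaining,
    molecularly unexplained probands are synthetic placeholders filling the
    published totals.
    """
    sexes = {r["sample_id"]: r["sex"] for r in _read_rows("clinical_features.tsv")}
    n_male = sum(1 for s in sexes.values() if s == "male")
    n_female = len(sexes) - n_male
    for i in range(COHORT_MALES - n_male):
        sexes[f"UNEXPLAINED_M{i:03d}"] = "male"
    for i in range(COHORT_FEMALES - n_female):
        sexes[f"UNEXPLAINED_F{i:03d}"] = "female"
    return sexes


def load_dosage_rows() -> List[Tuple[DosageValidationResult, CnvType]]:
    """The published per-CNV dosage statistics as result objects."""
    out = []
    for r in _read_rows("dosage_rows.tsv"):
        cnv_type = CnvType(r["cnv_type"])
        key = f"{r['sample_id']}:{r['region']}"
        if r["zscore_cnv"] == "-":
            res = DosageValidationResult(
                cnv_key=key, gene_in_cnv=int(r["gene_in_cnv"]),
                rna_in_cnv=int(r["rna_in_cnv"]), status="not_expressed",
            )
        else:
            res = DosageValidationResult(
                cnv_key=key, gene_in_cnv=int(r["gene_in_cnv"]),
                rna_in_cnv=int(r["rna_in_cnv"]), status="evaluable",
                zscore_chr=float(r["zscore_chr"]),
                zscore_cnv=float(r["zscore_cnv"]),
                zscore_random=tuple(float(r[f"zscore_random{i}"]) for i in (1, 2, 3)),
                log2fc_chr=float(r["log2fc_chr"]),
                log2fc_cnv=float(r["log2fc_cnv"]),
                log2fc_random=tuple(float(r[f"log2fc_random{i}"]) for i in (1, 2, 3)),
            )
        out.append((res, cnv_type))
    return out


def load_snv_expression_rows() -> List[SnvExpressionResult]:
    out = []
    for r in _read_rows("snv_expression_rows.tsv"):
        if r["expressed_in_blood"] == "no":
            out.append(SnvExpressionResult(gene=r["gene"], expressed_in_blood=False))
        else:
            level = float(r["patient_level"])
            mean = float(r["cohort_mean_level"])
            out.append(SnvExpressionResult(
                gene=r["gene"], expressed_in_blood=True, patient_level=level,
                cohort_mean_level=mean, reduced=level < mean,
            ))
    return out


def run_demo_triage() -> List[Finding]:
    """Triage the bundled demo cohort with the bundled catalog and gene list."""
    return triage(
        snvs=load_diagnosed_snvs(),
        cnvs=load_diagnosed_cnvs(),
        pedigree=load_pedigree(),
        gene_list=load_gene_list(),
        catalog=load_known_regions(),
    )
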