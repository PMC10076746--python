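# Methods

## Scope and pipeline

`triodx` implements the post-variant-calling stages of a trio genomic
diagnostic workflow for ASD cohorts: read-pair QC filtering, diagnostic
triage of small variants and CNVs, blood-RNA dosage validation, qBase qPCR
copy-number confirmation, and cohort yield reporting. Upstream steps —
alignment, SNV/CNV/SV calling, annotation, ACMG evidence grading — are out of
scope: the package consumes their outputs (an annotated VCF, CNV call tables,
a gene-level counts matrix) and a simplified PTV + known-gene filter stands
in for expert ACMG classification.

## Coordinate and QC conventions

Internal coordinates are 1-based inclusive on both ends everywhere; BED input
and output convert at the boundary. CNV size is `end − start + 1` bp.

The read-pair QC filter removes a pair when, in either mate, the N count
strictly exceeds 3, or the fraction of bases with Phred quality below 5
strictly exceeds 20%, or adapter sequence was detected; boundary values
(exactly 3 N, exactly 20%) pass. The removal set is the union of the three
rules; the report attributes each removed pair to the first matching rule in
the order N → low-quality → adapter, so the counts always sum to the input
count. Adapter detection itself is delegated upstream: the record carries a
boolean flag, serialized in FASTQ as an `adapter` token on the description
line.

## Triage

* **Origin** of an SNV from the trio genotype triple: the proband must carry
  the allele; neither parent carrying → de novo; one → paternal/maternal;
  both → inherited from both; any decisive genotype missing (or proband
  non-carrier) → ambiguous. The rule is total over all 4³ genotype triples
  and is checked against a brute-force enumeration in the tests.
* **PTV** = nonsense, frameshift, or splice-site variant whose HGVS intronic
  offset satisfies |d| ≤ 2 (canonical donor/acceptor). Deeper splice-region
  variants are not truncating. Unparseable splice HGVS raises rather than
  silently failing open.
* **CNV resolution**: calls below 100 kb (configurable) are ignored,
  matching the resolution of low-depth whole-genome CNV calling.
* **Known-region match**: reciprocal overlap — intersection over each
  interval's length — must reach 0.5 on both quotients; the best match
  maximizes the reciprocal overlap, ties broken to the smaller region then
  lexicographic name. The same 50% reciprocal-overlap rule decides whether a
  parent's call set carries the proband's CNV (parental carriage from
  presence/absence of calls, not genotypes, matching low-depth calling).
* A deletion that matches no catalog region still qualifies if it removes a
  gene flagged haploinsufficient (requires gene coordinates).
* Inherited CNVs remain diagnostic when catalog-matched; inherited SNVs are
  excluded by the de novo dominant rule. Multiple findings per proband are
  all reported; yields count each proband once.

The bundled demo catalog stores one entry per distinct syndromic region of
the reference cohort; where two published carriers of the same recurrent
region have different breakpoints, the union span is stored (both carriers
match it at reciprocal overlap ≥ 0.86).

## Expression validation

Counts are normalized by median-of-ratios size factors (computed over genes
with a strictly positive geometric mean), the standard bulk RNA-seq library
size correction. A gene is "expressed in blood" when its cohort mean
normalized value is ≥ 1 (configurable); the cutoff only needs to separate
silent genes (near-zero counts) from expressed ones, which are orders of
magnitude higher.

Per-gene statistics for carrier *p*:

* `z(g, p)` standardizes against the cohort using the population
  (n-denominator) standard deviation; a constant gene yields z = 0 by
  convention. Consequently per-gene z values have cohort mean 0 and variance
  1 exactly, and set averages over many genes sit near 0 under the null —
  which is why the whole-chromosome background means hover near zero.
* `log2FC(g, p)` uses a pseudocount of 1.0 on the normalized scale, which
  guards zeros and is negligible at typical expressed magnitudes (10²–10³).
* The cohort mean and sd include the index patient; the SNV expression check
  exposes `include_index=False` to use the leave-one-out control instead.
  With hundreds of samples the two differ negligibly.

For a CNV, in-CNV membership is ≥ 1 bp overlap between gene span and CNV
span (most permissive, monotone under CNV growth). The three random control
sets draw `rna_in_cnv` genes uniformly without replacement from the
*expressed* out-CNV genes of the same chromosome — unexpressed genes would
deflate the control means — with sets mutually independent and reproducible
under the seed. Direction consistency requires the in-CNV mean to beat every
random-set mean on both statistics (strictly greater for duplications,
strictly smaller for deletions).

The published per-CNV statistics of the reference cohort are shipped as a
fixture and are all direction-consistent under this rule; their exact values
are not reproducible here because the raw data are controlled-access and the
original normalization units are unspecified, so tests assert the direction
property rather than the printed numbers.

## qPCR quantification

Replicate Cq values (≥ 2, typically triplicate) are averaged; when ≥ 3
replicates span more than 0.5 cycles, the single value farthest from the
median is dropped first — a plain robustness convention for a stray well.
Relative quantity RQ = E^(Cq_calibrator − Cq_sample) with per-gene
amplification efficiency E ∈ (1, 2], default 2 (perfect doubling);
NRQ = RQ_target / RQ_reference with a single reference gene (GAPDH-style;
the multi-reference geometric-mean extension is a natural hook but is not
implemented). The calibrator's NRQ is identically 1. Calls use thresholds
0.75 / 1.25, the midpoints between the diploid expectation 1.0 and the
heterozygous expectations 0.5 / 1.5.

## Synthetic cohort generator

The generator emulates the study conditions the analysis assumes:

* 354 trios by default, probands 279 male / 75 female (ratio 3.72:1); sex is
  pedigree metadata only, with no X-linkage modelling.
* Gene baselines are lognormal (log2 mean 8, sd 2 → median ≈ 256,
  matching the 10²–10³ magnitudes of expressed genes in blood);
  a blood-expression mask silences 30% of genes (near-zero Poisson counts);
  sample noise is multiplicative lognormal with log2 sd 0.2; counts are
  rounded to integers for the raw matrix (disable via `integer_counts` for
  closed-form checks).
* Planted CNVs multiply the carrier's blood-expressed in-CNV genes by the
  copy ratio (1.5 duplication / 0.5 deletion); planted PTVs multiply the
  mutant gene by an expression ratio of 0.6, i.e. partial nonsense-mediated
  decay consistent with the modest reductions seen in blood.
* Trio genotypes are consistent with each planted origin; parental CNV
  carriage is encoded as matching parental calls. Decoy variants (de novo
  missense in a listed gene, inherited PTV, synonymous) exercise the filters
  without creating findings.
* qPCR plates follow Cq_sample = Cq_calibrator − log_E(ratio) + ε with
  ε ~ N(0, sd) per case well (measurement noise around the noise-free
  calibrator baseline); FASTQ generation plants exact counts of N-rich,
  low-quality and adapter-flagged pairs on disjoint subsets.
* Every component draws from its own `numpy` Generator seeded by
  (seed, component-id), so outputs are bitwise reproducible per seed,
  end to end.

`study_config(seed)` plants the reference structure: 9 catalog-matching
multi-gene CNVs (6 dup / 3 del; 5 de novo / 4 inherited) and 10 de novo PTVs
in listed genes, all carriers distinct, so triage recovers exactly 19
positive probands.

What the generator does **not** emulate: count dispersion fitted to real
blood RNA-seq, correlated co-expression, batch effects, mosaicism, complex
SVs, sex-linked effects, or annotation noise. Passing tests therefore show
the statistics behave correctly under the assumed generative model, not that
the pipeline is robust to every artefact of real cohort data.

## Reporting

Percentages are rounded half-up to one decimal (`Decimal` arithmetic, no
binary-float surprises). The male:female ratio is rounded to two decimals.
A proband is a "de novo positive" iff every one of its diagnostic findings
is de novo. The comorbidity tally does case-insensitive substring matching
of keyword groups (defaults: {"intellectual"} and {"language"}) against
verbatim feature strings, excluding patients marked lost to follow-up; no
clinical ontology mapping is attempted. Note that 19/354 = 5.367% rounds to
5.4% under any standard rounding; the reference publication prints 5.3%, a
rounding inconsistency on its side, so the overall rate is documented rather
than asserted.

## Problem sizes used in tests

The acceptance-style simulations run at the sizes the analysis design calls
for: 100 replicate cohorts of 100 samples × 200 genes per CNV type for the
dosage-recovery property, 200 plates per truth class for qPCR call recovery,
and 50 small null cohorts for the centering check. The full study-scale
synthetic cohort (354 trios, 9 chromosomes × 120 genes) is generated once
per session and shared across tests.
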