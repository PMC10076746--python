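import numpy as np
import pandas as pd
import pytest

from triodx import demo
from triodx import expression_validation as ev
from triodx import synthetic_cohort as sc
from triodx.expression_validation import ExpressionMatrix
from triodx.io_formats import GeneModel
from triodx.variant_triage import CnvCall, CnvType


class TestNormalizeCounts:
    def test_scaled_sample_gets_proportional_size_factor(self):
        # closed form: identical profiles, one column scaled x2 -> its median
        # of ratios is exactly 2x the others, so normalization equalizes columns
        base = np.array([10.0, 50.0, 200.0, 5.0])
        df = pd.DataFrame({"a": base, "b": base, "c": 2 * base},
                          index=list("wxyz"))
        out = ev.normalize_counts(ExpressionMatrix(df))
        assert out.normalized
        pd.testing.assert_series_equal(out.values["c"], out.values["a"],
                                       check_names=False)

    def test_equal_profiles_unchanged_up_to_constant(self):
        base = np.array([3.0, 9.0, 27.0])
        df = pd.DataFrame({"a": base, "b": base}, index=list("xyz"))
        out = ev.normalize_counts(ExpressionMatrix(df))
        np.testing.assert_allclose(out.values.to_numpy(), df.to_numpy())

    def test_errors(self):
        with pytest.raises(ev.NormalizationError):
            ev.normalize_counts(ExpressionMatrix(
                pd.DataFrame({"only": [1.0, 2.0]}, index=["g1", "g2"])))
        with pytest.raises(ev.NormalizationError):
            ev.normalize_counts(ExpressionMatrix(
                pd.DataFrame({"a": [0.0, 1.0], "b": [1.0, 0.0]}, index=["g1", "g2"])))


class TestPerGeneStats:
    def test_zscore_hand_computed(self, toy_matrix):
        # cohort values {10,20,30,20}: mean 20, population sd sqrt(50)
        assert ev.gene_zscore(toy_matrix, "g1", "s3") == pytest.approx(
            10 / np.sqrt(50))
        cohort = ExpressionMatrix(pd.DataFrame(
            {"a": [1.0], "b": [2.0], "c": [3.0]}, index=["g"]), normalized=True)
        assert ev.gene_zscore(cohort, "g", "c") == pytest.approx(1.2247, abs=1e-4)

    def test_zscore_degenerate_cases(self, toy_matrix):
        assert ev.gene_zscore(toy_matrix, "g2", "s1") == 0.0  # constant gene
        assert ev.gene_zscore(toy_matrix, "g1", "s2") == 0.0  # at the mean

    def test_zscores_standardized_across_cohort(self, study_cohort):
        # per-gene z over all samples has mean 0 and population variance 1
        _, _, cohort = study_cohort
        m = ev.normalize_counts(cohort.expression)
        rng = np.random.default_rng(0)
        genes = rng.choice(
            [g.gene_id for g in cohort.genes if ev.expressed_in_blood(m, g.gene_id)],
            size=20, replace=False)
        for gene in genes:
            zs = np.array([ev.gene_zscore(m, gene, s) for s in m.samples])
            assert abs(zs.mean()) < 1e-10
            assert zs.var() == pytest.approx(1.0, abs=1e-10)

    def test_log2fc(self, toy_matrix):
        assert ev.gene_log2fc(toy_matrix, "g2", "s1") == 0.0
        # large values: pseudocount negligible, patient at 1.5x cohort mean
        assert ev.gene_log2fc(toy_matrix, "g1", "s3", pseudocount=0.0) == pytest.approx(
            np.log2(1.5))
        assert ev.gene_log2fc(toy_matrix, "g4", "s1") == 0.0  # 0/0 + pseudocount

    def test_expressed_in_blood(self, toy_matrix):
        assert ev.expressed_in_blood(toy_matrix, "g5")
        assert not ev.expressed_in_blood(toy_matrix, "g4")  # all-zero row
        assert not ev.expressed_in_blood(toy_matrix, "absent")


def five_gene_models():
    return [GeneModel(f"g{i}", "chr1", i * 1000, i * 1000 + 500) for i in range(1, 6)]


class TestCnvDosageValidation:
    def test_brute_force_oracle_on_five_gene_chromosome(self):
        # recompute every statistic from first principles on a tiny chromosome
        rng = np.random.default_rng(42)
        df = pd.DataFrame(rng.uniform(5, 100, (5, 6)),
                          index=[f"g{i}" for i in range(1, 6)],
                          columns=[f"s{i}" for i in range(6)])
        m = ExpressionMatrix(df, normalized=True)
        genes = five_gene_models()
        cnv = CnvCall("s2", "chr1", 1000, 2600, CnvType.DUPLICATION)  # g1, g2
        res = ev.cnv_dosage_validation(m, cnv, genes, seed=7)

        def z(gene):
            row = df.loc[gene].to_numpy()
            return (df.at[gene, "s2"] - row.mean()) / row.std()

        def fc(gene):
            row = df.loc[gene].to_numpy()
            return np.log2((df.at[gene, "s2"] + 1) / (row.mean() + 1))

        assert res.gene_in_cnv == 2 and res.rna_in_cnv == 2
        assert res.zscore_cnv == pytest.approx(np.mean([z("g1"), z("g2")]))
        assert res.zscore_chr == pytest.approx(np.mean([z(f"g{i}") for i in range(1, 6)]))
        assert res.log2fc_cnv == pytest.approx(np.mean([fc("g1"), fc("g2")]))
        # random sets drawn from the out-CNV pool {g3,g4,g5}, reproducible by seed
        pool = ["g3", "g4", "g5"]
        rng2 = np.random.default_rng(7)
        for zr, fr in zip(res.zscore_random, res.log2fc_random):
            picked = [pool[i] for i in rng2.choice(3, size=2, replace=False)]
            assert zr == pytest.approx(np.mean([z(g) for g in picked]))
            assert fr == pytest.approx(np.mean([fc(g) for g in picked]))

    def test_noise_free_duplication_recovers_copy_ratio(self):
        cfg = sc.SimulationConfig(
            seed=2, n_trios=40, n_chromosomes=1, genes_per_chromosome=40,
            noise_sd_log2=0.0, integer_counts=False, blood_expressed_fraction=1.0,
            include_decoys=False,
        )
        genes = sc.generate_genome(cfg)
        start, end = sc.span_of_genes(genes, "chr1", 5, 10)
        cfg2 = sc.SimulationConfig(**{**cfg.__dict__, "planted_cnvs": (
            sc.PlantedCnv(0, "chr1", start, end, CnvType.DUPLICATION, 1.5),)})
        cohort = sc.generate_cohort(cfg2, genes)
        m = ev.normalize_counts(cohort.expression)
        res = ev.cnv_dosage_validation(
            m, CnvCall("ASD0000", "chr1", start, end, CnvType.DUPLICATION),
            genes, seed=3)
        assert res.rna_in_cnv == 10
        # one carrier among 40: cohort mean is baseline*(39+1.5)/40
        expected_fc = np.log2(1.5 * 40 / 40.5)
        assert res.log2fc_cnv == pytest.approx(expected_fc, abs=0.01)
        assert res.zscore_cnv > 3
        for zr, fr in zip(res.zscore_random, res.log2fc_random):
            assert abs(fr) < 0.02
        assert ev.direction_consistent(res, CnvType.DUPLICATION)

    def test_unexpressed_cnv_not_evaluable(self):
        df = pd.DataFrame({"s1": [0.0, 50.0], "s2": [0.0, 60.0], "s3": [0.0, 55.0]},
                          index=["g1", "g2"])
        m = ExpressionMatrix(df, normalized=True)
        genes = [GeneModel("g1", "chr1", 1000, 2000), GeneModel("g2", "chr1", 9000, 9900)]
        res = ev.cnv_dosage_validation(
            m, CnvCall("s1", "chr1", 900, 2100, CnvType.DELETION), genes)
        assert (res.gene_in_cnv, res.rna_in_cnv, res.status) == (1, 0, "not_expressed")
        with pytest.raises(ev.NotEvaluableError):
            ev.direction_consistent(res, CnvType.DELETION)

    def test_sampling_error_when_pool_too_small(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.uniform(5, 50, (5, 4)),
                          index=[f"g{i}" for i in range(1, 6)],
                          columns=list("abcd"))
        m = ExpressionMatrix(df, normalized=True)
        cnv = CnvCall("a", "chr1", 1000, 4600, CnvType.DUPLICATION)  # g1..g4
        with pytest.raises(ev.SamplingError, match="gene universe"):
            ev.cnv_dosage_validation(m, cnv, five_gene_models())

    def test_deterministic_under_seed(self, study_cohort):
        cfg, genes, cohort = study_cohort
        m = ev.normalize_counts(cohort.expression)
        pc = cfg.planted_cnvs[0]
        cnv = CnvCall("ASD0000", pc.chrom, pc.start, pc.end, pc.cnv_type)
        a = ev.cnv_dosage_validation(m, cnv, genes, seed=17)
        b = ev.cnv_dosage_validation(m, cnv, genes, seed=17)
        c = ev.cnv_dosage_validation(m, cnv, genes, seed=18)
        assert a == b
        assert a.zscore_random != c.zscore_random


class TestDirectionConsistency:
    def test_published_rows_all_consistent(self):
        rows = demo.load_dosage_rows()
        evaluable = [(r, t) for r, t in rows if r.status == "evaluable"]
        assert len(evaluable) == 8
        assert all(ev.direction_consistent(r, t) for r, t in evaluable)

    def test_wrong_direction_rejected(self):
        r = ev.DosageValidationResult(
            cnv_key="x", gene_in_cnv=5, rna_in_cnv=5, status="evaluable",
            zscore_chr=0.0, zscore_cnv=-1.0, zscore_random=(0.1, -0.05, 0.0),
            log2fc_chr=0.0, log2fc_cnv=-0.2, log2fc_random=(0.01, 0.0, -0.01))
        assert not ev.direction_consistent(r, CnvType.DUPLICATION)
        assert ev.direction_consistent(r, CnvType.DELETION)


class TestSnvExpressionCheck:
    def test_reduced_against_cohort_mean(self):
        # cohort of 3: patient 3095.66 vs mean 3948.45 (values chosen to mirror
        # the published magnitudes)
        df = pd.DataFrame({"p1": [3095.66], "p2": [4200.0], "p3": [4549.69]},
                          index=["PTEN"])
        m = ExpressionMatrix(df, normalized=True)
        res = ev.snv_expression_check(m, "PTEN", "p1")
        assert res.expressed_in_blood
        assert res.patient_level == pytest.approx(3095.66)
        assert res.cohort_mean_level == pytest.approx(3948.45, abs=0.01)
        assert res.reduced

    def test_absent_gene_not_expressed(self, toy_matrix):
        res = ev.snv_expression_check(toy_matrix, "SHANK3", "s1")
        assert not res.expressed_in_blood
        assert res.patient_level is None

    def test_patient_at_mean_not_reduced(self, toy_matrix):
        res = ev.snv_expression_check(toy_matrix, "g2", "s1")
        assert not res.reduced

    def test_exclude_index_flag(self):
        df = pd.DataFrame({"a": [10.0], "b": [20.0], "c": [30.0]}, index=["g"])
        m = ExpressionMatrix(df, normalized=True)
        inc = ev.snv_expression_check(m, "g", "a")
        exc = ev.snv_expression_check(m, "g", "a", include_index=False)
        assert inc.cohort_mean_level == pytest.approx(20.0)
        assert exc.cohort_mean_level == pytest.approx(25.0)

    def test_planted_ptv_reduced_in_synthetic_cohort(self, study_cohort):
        cfg, genes, cohort = study_cohort
        m = ev.normalize_counts(cohort.expression)
        for ps in cfg.planted_snvs:
            res = ev.snv_expression_check(m, ps.gene, f"ASD{ps.carrier:04d}")
            if res.expressed_in_blood:
                assert res.reduced
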