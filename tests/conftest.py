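import numpy as np
import pandas as pd
import pytest

from triodx import synthetic_cohort as sc
from triodx.expression_validation import ExpressionMatrix


@pytest.fixture(scope="session")
def study_cohort():
    """A full synthetic cohort under the reference study conditions."""
    cfg = sc.study_config(seed=11)
    genes = sc.generate_genome(cfg)
    return cfg, genes, sc.generate_cohort(cfg, genes)


@pytest.fixture
def small_cfg():
    return sc.SimulationConfig(
        seed=5, n_trios=12, n_chromosomes=2, genes_per_chromosome=30,
        planted_snvs=(sc.PlantedSnv(carrier=1, gene="chr1_g0005"),),
        planted_cnvs=(sc.PlantedCnv(
            carrier=0, chrom="chr2", start=1, end=5_000_000,
            cnv_type=sc.CnvType.DUPLICATION, copy_ratio=1.5),),
    )


@pytest.fixture
def toy_matrix():
    """5 genes x 4 samples, hand-sized for closed-form checks."""
    df = pd.DataFrame(
        {
            "s1": [10.0, 100.0, 40.0, 0.0, 7.0],
            "s2": [20.0, 100.0, 40.0, 0.0, 7.0],
            "s3": [30.0, 100.0, 40.0, 0.0, 7.0],
            "s4": [20.0, 100.0, 40.0, 0.0, 7.0],
        },
        index=[f"g{i}" for i in range(1, 6)],
    )
    return ExpressionMatrix(df, normalized=True)
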