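import numpy as np
import pandas as pd
import pytest

from liverqtl import preprocess as pp
from liverqtl.simulate import (
    SimConfig,
    gen_annotation,
    gen_expression,
    gen_genotypes,
)


def int_transform(tpm: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize to the average distribution, then per-gene INT."""
    norm = pp.quantile_normalize_to_average(tpm)
    return pd.DataFrame(
        np.vstack([pp.inverse_normal_transform(norm.loc[g]) for g in norm.index]),
        index=norm.index,
        columns=norm.columns,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """192-sample cohort with one latent-scale and one aFC-scale effect."""
    config = SimConfig(
        n_samples=192,
        n_variants=100,
        n_genes=20,
        seed=3,
        effect_table=[("G0001", "v00001", 0.8, None), ("G0002", "v00002", 0.0, 2.0)],
        noise_sd=1.0,
        maf_range=(0.2, 0.5),
    )
    annotation = gen_annotation(config)
    genotypes, truth = gen_genotypes(config, annotation)
    expr, truth = gen_expression(genotypes, annotation, config, truth)
    return config, annotation, genotypes, expr, truth


@pytest.fixture(scope="session")
def small_cohort_int(small_cohort):
    _, _, _, expr, _ = small_cohort
    return int_transform(expr.tpm)
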