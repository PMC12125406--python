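import numpy as np
import pytest

from hipssm import (
    SyntheticConfig,
    fit_ssm,
    procrustes_align,
    sample_cohort,
    zscores_table,
)


@pytest.fixture(scope="session")
def cohort_small():
    """A quick 60-patient synthetic cohort with its fitted shape model."""
    hips, records, truth = sample_cohort(SyntheticConfig(n_patients=60, seed=0))
    aligned, mean = procrustes_align([h.contour_array() for h in hips])
    model = fit_ssm(aligned)
    zs = zscores_table(model, hips, pre_aligned_shapes=aligned)
    return {
        "hips": hips,
        "records": records,
        "truth": truth,
        "aligned": aligned,
        "model": model,
        "zscores": zs,
    }


@pytest.fixture(scope="session")
def cohort_default():
    """The default-conditions cohort (n = 500) used for recovery checks."""
    hips, records, truth = sample_cohort(SyntheticConfig(n_patients=500, seed=0))
    aligned, mean = procrustes_align([h.contour_array() for h in hips])
    model = fit_ssm(aligned)
    zs = zscores_table(model, hips, pre_aligned_shapes=aligned)
    return {
        "hips": hips,
        "records": records,
        "truth": truth,
        "aligned": aligned,
        "model": model,
        "zscores": zs,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
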