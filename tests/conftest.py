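import warnings

import numpy as np
import pandas as pd
import pytest

from ceburden import synthetic as syn
from ceburden.containers import AbundanceMatrix

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def cohort():
    """A paper-sized cohort (n=90) with default generator settings."""
    meta, traits, gt = syn.generate_cohort(n_subjects=90, seed=11)
    return meta, traits, gt


@pytest.fixture(scope="session")
def ce_matrix(cohort):
    import ceburden as cb

    meta, traits, gt = cohort
    ct = syn.generate_ct_table(meta, gt, seed=11)
    controls = list(meta.index[meta["group"] == "Control"])
    return cb.ce_matrix_from_ct(ct, controls)


@pytest.fixture()
def small_abundance():
    """A 50x12 complete abundance matrix with two batches and GIS channels."""
    rng = np.random.default_rng(5)
    vals = rng.normal(0, 1, (50, 12))
    cols = [f"s{i}" for i in range(12)]
    annot = pd.DataFrame(
        {
            "batch": ["b1"] * 6 + ["b2"] * 6,
            "is_reference": [True, False, False, False, False, False] * 2,
            "group": [""] * 12,
        },
        index=cols,
    )
    return AbundanceMatrix(
        pd.DataFrame(vals, index=[f"f{i}" for i in range(50)], columns=cols), annot
    )
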