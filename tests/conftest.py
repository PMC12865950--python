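import numpy as np
import pandas as pd
import pytest

from paircore import AbundanceTable, CohortSpec, generate_cohort

#: reduced sequencing depths used throughout the test simulations —
#: preserves the WGS-heavy-tailed / amplicon-deep ordering at desk scale
TEST_DEPTHS = {"WGS": 20_000.0, "FL": 30_000.0, "SR": 60_000.0}


def make_spec(seed: int = 0, **kw) -> CohortSpec:
    base = dict(n_pairs=25, n_taxa=60, n_disease_taxa=6, n_health_taxa=6,
                effect_log2=2.0, depth_means=dict(TEST_DEPTHS), seed=seed)
    base.update(kw)
    return CohortSpec(**base)


def null_spec(seed: int = 0, **kw) -> CohortSpec:
    kw.setdefault("effect_log2", 0.0)
    return make_spec(seed=seed, **kw)


@pytest.fixture(scope="session")
def cohort25():
    return generate_cohort(make_spec(seed=7))


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(make_spec(seed=11, n_pairs=6, n_taxa=40,
                                     n_disease_taxa=4, n_health_taxa=4))


def table_from(values, taxa=None, samples=None, mode="counts", **kw):
    arr = np.asarray(values, dtype=float)
    taxa = taxa or [f"t{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    df = pd.DataFrame(arr, index=pd.Index(taxa, name="taxon"),
                      columns=samples)
    return AbundanceTable(df, mode=mode, **kw)
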