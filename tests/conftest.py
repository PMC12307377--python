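import numpy as np
import pandas as pd
import pytest

from phenodiv import CohortSpec, PhenotypeTable, default_registry, generate_cohort
from phenodiv.traits import qualitative_abbrevs, quantitative_abbrevs

#: Fixed seed used by fixtures that feed deterministic assertions.
SEED = 20230515


@pytest.fixture(scope="session")
def registry():
    return default_registry()


def make_table(registry, n=6, seed=1):
    """Small valid phenotype table with plausible values."""
    rng = np.random.default_rng(seed)
    data = {
        "accession_id": [f"A{i:03d}" for i in range(1, n + 1)],
        "accession_name": [f"acc-{i}" for i in range(1, n + 1)],
        "material_class": ["landrace"] * n,
    }
    for t in registry:
        if t.kind == "quantitative":
            data[t.abbreviation] = np.round(rng.uniform(5, 100, size=n), 2)
        else:
            data[t.abbreviation] = rng.integers(
                1, t.category_count + 1, size=n
            ).astype(float)
    return PhenotypeTable(registry=registry, data=pd.DataFrame(data))


@pytest.fixture
def small_table(registry):
    return make_table(registry)


@pytest.fixture(scope="session")
def panel_cohort(registry):
    """Default-condition synthetic panel at the study size (n=1558)."""
    return generate_cohort(CohortSpec(n_accessions=1558, seed=SEED), registry)


@pytest.fixture(scope="session")
def quant_traits(registry):
    return quantitative_abbrevs(registry)


@pytest.fixture(scope="session")
def qual_traits(registry):
    return qualitative_abbrevs(registry)
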