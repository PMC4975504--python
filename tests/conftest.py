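"""Shared fixtures: the study's printed genotype tables and small cohorts."""

import numpy as np
import pandas as pd
import pytest

from geneenv.assoc import GenotypeTable
from geneenv.synthetic import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def discovery() -> GenotypeTable:
    """Discovery-set genotype counts (cases / controls x GG/AG/AA)."""
    return GenotypeTable.from_rows([495, 558, 119], [526, 463, 97], "discovery")


@pytest.fixture(scope="session")
def replication() -> GenotypeTable:
    return GenotypeTable.from_rows([481, 529, 135], [632, 560, 126], "replication")


@pytest.fixture(scope="session")
def merged() -> GenotypeTable:
    return GenotypeTable.from_rows([976, 1087, 254], [1158, 1023, 223], "merged")


def grouped_strata(yes: tuple, no: tuple) -> pd.DataFrame:
    """Eight-cell grouped data for one binary stratifier.

    ``yes``/``no`` are (cases_GG, cases_carrier, controls_GG,
    controls_carrier) for the exposed / unexposed stratum.
    """
    rows = []
    for e, (cgg, cd, kgg, kd) in ((1, yes), (0, no)):
        rows += [
            {"status": 1, "g": 0, "e": e, "w": cgg},
            {"status": 1, "g": 1, "e": e, "w": cd},
            {"status": 0, "g": 0, "e": e, "w": kgg},
            {"status": 0, "g": 1, "e": e, "w": kd},
        ]
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def t2dm_strata() -> pd.DataFrame:
    return grouped_strata((263, 487, 289, 325), (713, 854, 869, 921))


@pytest.fixture(scope="session")
def hyperlipidemia_strata() -> pd.DataFrame:
    return grouped_strata((238, 443, 266, 283), (738, 898, 892, 963))


@pytest.fixture(scope="session")
def bmi_strata() -> pd.DataFrame:
    return grouped_strata((444, 673, 456, 455), (532, 668, 702, 791))


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """600-subject synthetic cohort with the default embedded structure."""
    cfg = CohortConfig(n_cases=300, n_controls=300, seed=101)
    df = simulate_cohort(cfg)
    df["genotype_dominant"] = (df["genotype"] != "GG").astype(int)
    return df


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
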