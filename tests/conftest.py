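"""Shared fixtures: a seeded synthetic library and its fitted analysis.

The library (10 drug-like scaffold cores x 7 substituents, planted
methyl->hydroxyl effect of +1.0 log units, Gaussian noise 0.1) is built
once per session; most integration-level tests read from it.
"""

from __future__ import annotations

import pytest

from mmpamp.chem import standardize
from mmpamp.config import AnalysisConfig
from mmpamp.library import generate_library
from mmpamp.model import MMPAnalysis

LIBRARY_SEED = 1


@pytest.fixture(scope="session")
def library():
    return generate_library(seed=LIBRARY_SEED)


@pytest.fixture(scope="session")
def fitted(library):
    return MMPAnalysis(library.molecules, "activity", config=AnalysisConfig()).fit()


@pytest.fixture(scope="session")
def stats_by_id(fitted):
    return {s.transformation_id: s for s in fitted.stats}


@pytest.fixture
def toluene():
    return standardize("Cc1ccccc1", "toluene")


@pytest.fixture
def phenol():
    return standardize("Oc1ccccc1", "phenol")


@pytest.fixture
def benzene():
    return standardize("c1ccccc1", "benzene")
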