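import os

import numpy as np
import pytest

from segqtl.genome import GenomeLayout, HaplotypeMosaic, SUPERIOR, INFERIOR

DATA = os.path.join(os.path.dirname(__file__), "data")


@pytest.fixture
def data_dir() -> str:
    return DATA


@pytest.fixture
def small_layout() -> GenomeLayout:
    return GenomeLayout(names=("chrA", "chrB"), lengths=(300_000, 200_000), cm_per_kb=0.35)


@pytest.fixture
def parents(small_layout):
    return (
        HaplotypeMosaic.uniform(small_layout, SUPERIOR),
        HaplotypeMosaic.uniform(small_layout, INFERIOR),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
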