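import numpy as np
import pytest

from mhf import (
    AnalysisRegion,
    DomainAnnotation,
    DomainMap,
    MutationSet,
    datasets,
)


@pytest.fixture(scope="session")
def toy_region():
    return AnalysisRegion(1, 10)


@pytest.fixture(scope="session")
def toy_map(toy_region):
    return DomainMap(
        toy_region,
        [DomainAnnotation("A", 1, 5), DomainAnnotation("B", 6, 10)],
    )


@pytest.fixture(scope="session")
def demo_sequence():
    return datasets.load_demo_sequence()


@pytest.fixture(scope="session")
def demo_catalog():
    return datasets.load_demo_catalog()


@pytest.fixture(scope="session")
def demo_controls():
    return datasets.load_demo_controls()


@pytest.fixture(scope="session")
def demo_full_map():
    return datasets.load_demo_domains("full")


@pytest.fixture(scope="session")
def demo_cterm_map():
    return datasets.load_demo_domains("cterm")


def mutation_set(positions, region):
    return MutationSet(np.asarray(positions, dtype=np.int64), region)
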