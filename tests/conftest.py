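import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vfforage.count_features import WordResources
from vfforage.lexicon import classify_tokens
from vfforage.pipeline import extract_features
from vfforage.segmentation import segment_esa
from vfforage.synthetic import (CohortSpec, default_category_table,
                                default_lexicon, worked_example_embeddings,
                                generate_cohort, generate_embeddings,
                                generate_word_resources, make_worked_example)
from vfforage.time_features import trim_and_renormalize

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def worked_example():
    """The 7-word worked example: (response, adjacent similarities)."""
    return make_worked_example()


@pytest.fixture(scope="session")
def example_sequence(worked_example):
    response, _ = worked_example
    return trim_and_renormalize(response)


@pytest.fixture(scope="session")
def example_segmentation(worked_example):
    _, sims = worked_example
    return segment_esa(sims, 0.05)


@pytest.fixture(scope="session")
def example_store():
    return worked_example_embeddings()


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def category_table():
    return default_category_table()


@pytest.fixture(scope="session")
def embedding_store(category_table):
    return generate_embeddings(category_table, dim=16, seed=11)


@pytest.fixture(scope="session")
def word_resources(category_table):
    return generate_word_resources(category_table, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """A 10 MCI / 14 CI cohort of raw responses (fast to extract)."""
    return generate_cohort(CohortSpec(n_mci=10, n_ci=14, seed=5))


@pytest.fixture(scope="session")
def cohort_matrix(small_cohort, lexicon, category_table, embedding_store,
                  word_resources):
    return extract_features(small_cohort, lexicon, method="esa",
                            store=embedding_store, table=category_table,
                            resources=word_resources)
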