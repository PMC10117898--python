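from importlib import resources
from pathlib import Path

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from orthosav import apoe_precursor
from orthosav.predictor_io import load_annotations, load_score_table


@pytest.fixture(scope="session")
def apoe():
    return apoe_precursor()


@pytest.fixture(scope="session")
def published_scores():
    """The six printed worked-example variant rows (five candidates plus the
    unanimously non-damaging one)."""
    ref = resources.files("orthosav.data").joinpath("apoe_published_scores.tsv")
    with resources.as_file(ref) as p:
        return load_score_table(p)


@pytest.fixture(scope="session")
def published_annotations():
    ref = resources.files("orthosav.data").joinpath("apoe_published_annotations.tsv")
    with resources.as_file(ref) as p:
        return load_annotations(p)
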