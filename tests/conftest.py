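import numpy as np
import pandas as pd
import pytest

from ra_interact import synthetic
from ra_interact.prep import InteractionTerm


@pytest.fixture(scope="session")
def schema():
    return synthetic.default_schema()


@pytest.fixture(scope="session")
def null_truth():
    return synthetic.GroundTruth(intercept=0.0, effects={})


@pytest.fixture(scope="session")
def small_cohort(schema):
    truth = synthetic.GroundTruth(
        intercept=-1.0, effects={InteractionTerm(("age",)): 0.6}
    )
    return synthetic.generate_cohort(schema, truth, 1500, seed=7)


def make_binormal_scores(rng, n1, n0, a=1.0, b=1.0):
    """Scores whose class-conditional laws are exactly binormal with the
    stated (a, b): controls N(0,b^2)... cases N(a,1) on the latent scale."""
    cases = rng.normal(a, 1.0, size=n1)
    controls = rng.normal(0.0, b, size=n0)
    scores = np.concatenate([cases, controls])
    labels = np.concatenate([np.ones(n1, dtype=int), np.zeros(n0, dtype=int)])
    return scores, labels


@pytest.fixture
def binormal_scores():
    return make_binormal_scores
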