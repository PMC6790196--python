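import logging

import numpy as np
import pytest

from splicekin.alleles import call_pipeline
from splicekin.cohort import CohortConfig, simulate_cohort
from splicekin.splicing import AlignmentError, GeneIndex, classify_transcript

logging.disable(logging.WARNING)

SEED = 0  # canonical suite seed


@pytest.fixture(scope="session")
def cohort0():
    """Default study conditions at error rate 0 (exact-recovery regime)."""
    cfg = CohortConfig(seed=SEED, clone_error_rate=0.0)
    models, ped, truth, clones = simulate_cohort(cfg)
    return cfg, models, ped, truth, clones


@pytest.fixture(scope="session")
def cohort_err():
    """Default study conditions (clone errors at 5e-4 substitutions/site)."""
    cfg = CohortConfig(seed=SEED)
    models, ped, truth, clones = simulate_cohort(cfg)
    return cfg, models, ped, truth, clones


@pytest.fixture(scope="session")
def classified0(cohort0):
    """Per-clone classification of the error-free cohort."""
    _, models, _, _, clones = cohort0
    indexes = {g: GeneIndex(m) for g, m in models.items()}
    out = []
    for c in clones:
        chain, events = classify_transcript(c, indexes[c.gene_hint])
        out.append((c, chain, events))
    return out


@pytest.fixture(scope="session")
def called0(cohort0):
    _, models, _, _, clones = cohort0
    return call_pipeline(clones, models)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SEED)
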