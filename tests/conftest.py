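import warnings

import numpy as np
import pandas as pd
import pytest

from fourc.fragments import Enzyme, annotate_ends, digest_genome, locate_viewpoint
from fourc.pipeline import analyze_viewpoint
from fourc.simulate import (SimulationTruth, make_toy_fragment_table,
                            make_toy_genome, simulate_counts)

FIRST = Enzyme("first", "GATC", 0)
SECOND = Enzyme("second", "CATG", 0)


@pytest.fixture(scope="session")
def toy_genome():
    """Small planted genome plus ground truth of site positions."""
    genome, truth = make_toy_genome(length=20000, site_spacing=1000, seed=3)
    return genome, truth


@pytest.fixture(scope="session")
def toy_reference(toy_genome):
    genome, truth = toy_genome
    frags = annotate_ends(digest_genome(genome, FIRST), genome, SECOND)
    vp = locate_viewpoint(truth["primer"], genome, frags, name="vp1")
    return genome, frags, vp


@pytest.fixture(scope="session")
def null_dataset():
    """Count-level null simulation: 2000 cis fragments, 2x2 samples."""
    frags, vp, d = make_toy_fragment_table(n_cis=2000, n_trans=50, seed=5)
    truth = SimulationTruth(seed=9)
    counts, samples = simulate_counts(frags, vp, truth, n_replicates=2)
    return frags, vp, d, truth, counts, samples


@pytest.fixture(scope="session")
def null_analysis(null_dataset):
    frags, vp, d, truth, counts, samples = null_dataset
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return analyze_viewpoint(counts, frags, vp, samples, distances=d)
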