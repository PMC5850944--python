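import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper

from bnstratify import (
    PKN,
    Clause,
    PatientDataset,
    ProcessedDataset,
    SignedEdge,
    SynthConfig,
    generate,
)


@pytest.fixture
def chain_pkn() -> PKN:
    """S -> A -> R with a repressing side input I -| A."""
    return PKN(
        [
            SignedEdge("S", "A", 1),
            SignedEdge("I", "A", -1),
            SignedEdge("A", "R", 1),
        ]
    )


@pytest.fixture
def tiny_bundle():
    """Deterministic noise-free synthetic study with divergent class models."""
    return generate(
        SynthConfig(
            n_stimuli=3,
            n_inhibitors=3,
            n_readouts=2,
            n_patients_per_class=10,
            n_holdout_per_class=8,
            divergence=2,
            noise_sd=0.0,
            seed=7,
        )
    )


def make_processed(bits_cr, bits_pr, readouts_cr, readouts_pr, proteins=None, robs=None):
    """Assemble a ProcessedDataset from per-class bit/readout row lists."""
    n_cr, n_pr = len(bits_cr), len(bits_pr)
    proteins = proteins or [f"p{i+1}" for i in range(len(bits_cr[0]))]
    robs = robs or [f"r{i+1}" for i in range(len(readouts_cr[0]))]
    ids = [f"CR{i+1}" for i in range(n_cr)] + [f"PR{i+1}" for i in range(n_pr)]
    inputs = pd.DataFrame(list(bits_cr) + list(bits_pr), index=ids, columns=proteins)
    readouts = pd.DataFrame(
        list(readouts_cr) + list(readouts_pr), index=ids, columns=robs
    )
    labels = pd.Series(["CR"] * n_cr + ["PR"] * n_pr, index=ids)
    return ProcessedDataset(inputs=inputs, readouts=readouts, labels=labels)


@pytest.fixture
def make_proc():
    return make_processed


def random_selection_instance(rng: np.random.Generator):
    """A small random selection problem within the oracle-checkable range."""
    n_proteins = int(rng.integers(3, 9))
    n_cr = int(rng.integers(2, 7))
    n_pr = int(rng.integers(2, 7))
    n_readouts = int(rng.integers(1, 4))
    k = int(rng.integers(1, min(n_proteins, 4) + 1))
    bits_cr = rng.integers(0, 2, size=(n_cr, n_proteins)).tolist()
    bits_pr = rng.integers(0, 2, size=(n_pr, n_proteins)).tolist()
    r_cr = np.round(rng.random(size=(n_cr, n_readouts)), 3).tolist()
    r_pr = np.round(rng.random(size=(n_pr, n_readouts)), 3).tolist()
    return bits_cr, bits_pr, r_cr, r_pr, k
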