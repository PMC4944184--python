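"""Shared fixtures: packaged reference and small simulated repertoires.

Session-scoped so the (alignment-heavy) annotation step runs once per
repertoire across the whole suite.
"""
import pytest

from igprofile import (SimConfig, annotate_repertoire, default_reference,
                       simulate_repertoire)


@pytest.fixture(scope="session")
def reference():
    return default_reference()


@pytest.fixture(scope="session")
def sim_small(reference):
    """~70 sequences, default study conditions, fixed seed."""
    return simulate_repertoire(SimConfig(n_clones=30, seed=11), reference)


@pytest.fixture(scope="session")
def annotated_small(reference, sim_small):
    annotated, rejected = annotate_repertoire(sim_small.sequences, reference)
    assert not rejected
    return annotated


@pytest.fixture(scope="session")
def sim_unmutated(reference):
    """Unmutated clones (no SHM, no switching), 2 members each."""
    cfg = SimConfig(n_clones=25, clone_size_law=("fixed", 2), shm_rate=0.0,
                    switch_prob=0.0, seed=7)
    return simulate_repertoire(cfg, reference)


@pytest.fixture(scope="session")
def annotated_unmutated(reference, sim_unmutated):
    annotated, rejected = annotate_repertoire(sim_unmutated.sequences,
                                              reference)
    assert not rejected
    return annotated
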