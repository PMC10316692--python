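"""Shared fixtures: small seeded models, references and simulated reads."""

import numpy as np
import pytest

import squigmap as sm


@pytest.fixture(scope="session")
def model_k2():
    """Complete 2-mer model with well-separated levels."""
    return sm.generate_pore_model(2, rng_seed=11)


@pytest.fixture(scope="session")
def model_k6():
    """Complete 6-mer model (the default flowcell-like configuration)."""
    return sm.generate_pore_model(6, rng_seed=12)


@pytest.fixture(scope="session")
def fp_default():
    return sm.FixedPointConfig()


@pytest.fixture(scope="session")
def ref_2kb():
    return sm.generate_reference(2000, rng_seed=21)


@pytest.fixture(scope="session")
def index_2kb(ref_2kb, model_k6, fp_default):
    return sm.build_reference_index(ref_2kb, model_k6, fp_default, name="ref2kb")


@pytest.fixture(scope="session")
def sim_batch(ref_2kb, model_k6):
    """A small simulated dataset with truth, on the 2 kb reference."""
    params = sm.SimParams(seed=31, noise_sigma=0.3)
    reads, truths = sm.simulate_dataset(ref_2kb, model_k6, params, 12)
    return reads, truths, params


def expected_read_end_base(read, truth, model_k, base_length, trim, query_size=250):
    """Truth-derived forward-strand base where the selected query ends.

    Maps the last raw sample of the last selected event back through the
    true event segmentation; None when that sample still lies in the
    adapter.
    """
    events = sm.detect_events(read)
    last = events[trim:trim + query_size][-1]
    return sm.truth_sample_to_forward_base(
        truth, last.start + last.length - 1, model_k, base_length
    )
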