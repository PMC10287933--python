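import pytest

import dicodex as dx


@pytest.fixture(scope="session")
def code():
    return dx.STANDARD_CODE


@pytest.fixture
def toy_seqs():
    """Three tiny hand-built coding sequences (trailing stop already removed)."""
    return [
        dx.CodingSequence("g1", ("ATG", "GCT", "GCT", "GCC", "AAA"), 5),
        dx.CodingSequence("g2", ("ATG", "AAA", "AAG", "GCT", "GCC", "GCC"), 6),
        dx.CodingSequence("g3", ("ATG", "GCT", "AAA", "GCT", "AAA"), 5),
    ]


@pytest.fixture(scope="session")
def default_sim():
    """One synthetic dataset at the generator's default study conditions."""
    params = dx.SimulationParams()
    records, profile, truth = dx.simulate_genes(params)
    seqs = dx.qc_filter(records)
    weights = dx.weights_from_expression(profile)
    return {
        "params": params,
        "records": records,
        "profile": profile,
        "truth": truth,
        "seqs": seqs,
        "weights": weights,
    }


@pytest.fixture(scope="session")
def small_sim():
    """A reduced synthetic dataset for fast unit-level checks."""
    params = dx.SimulationParams(n_genes=300, length_range=(60, 200), seed=11)
    records, profile, truth = dx.simulate_genes(params)
    seqs = dx.qc_filter(records)
    return {
        "params": params,
        "records": records,
        "profile": profile,
        "truth": truth,
        "seqs": seqs,
        "weights": dx.weights_from_expression(profile),
    }
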