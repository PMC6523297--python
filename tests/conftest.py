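import pytest

from isokit.simulate import (
    SimulationConfig,
    generate_genome_and_annotation,
    simulate_fl_counts,
    simulate_isoform_truth,
    simulate_sr_evidence,
)


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(n_genes=40, seed=123)


@pytest.fixture(scope="session")
def simulated(sim_config):
    """A complete small synthetic dataset shared across tests."""
    genome, annotation = generate_genome_and_annotation(sim_config)
    truth = simulate_isoform_truth(annotation, sim_config)
    counts = simulate_fl_counts(truth, sim_config)
    coverage, sr_detected = simulate_sr_evidence(truth, sim_config)
    return {
        "config": sim_config,
        "genome": genome,
        "annotation": annotation,
        "truth": truth,
        "counts": counts,
        "coverage": coverage,
        "sr_detected": sr_detected,
    }
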