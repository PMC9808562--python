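import numpy as np
import pytest

import origamipore as op


@pytest.fixture(scope="session")
def species():
    return {sp.name: sp for sp in op.calibrated_species()}


@pytest.fixture(scope="session")
def monomer_run(species):
    """A 40 s pure-monomer recording at default settings (~200 events),
    detected once and shared across tests."""
    config = op.GeneratorConfig(duration=40.0, seed=42)
    trace, truth = op.simulate_trace(
        config, op.SampleComposition.pure(species["monomer"]), label="monomer"
    )
    baseline = op.estimate_baseline(trace)
    table = op.detect_events(trace, baseline)
    return {"config": config, "trace": trace, "truth": truth,
            "baseline": baseline, "table": table}


@pytest.fixture(scope="session")
def noiseless_run(species):
    """A short noise-free monomer recording for oracle-equivalence checks.

    With no noise the MAD-based sigma is undefined, so detection uses an
    explicitly constructed baseline with a small nominal sigma.
    """
    config = op.GeneratorConfig(duration=4.0, seed=3, baseline_noise_sd=0.0)
    trace, truth = op.simulate_trace(
        config, op.SampleComposition.pure(species["monomer"]), label="clean"
    )
    baseline = op.BaselineModel(
        baseline=np.zeros(trace.n_samples), sigma=0.25,
        event_mask=np.zeros(trace.n_samples, dtype=bool),
    )
    table = op.detect_events(trace, baseline)
    return {"config": config, "trace": trace, "truth": truth,
            "baseline": baseline, "table": table}
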