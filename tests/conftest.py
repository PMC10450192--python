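"""Shared fixtures: small simulated ensembles and noise calibrations.

Everything is generated at test time from fixed seeds; the expensive
default 39-event ensemble analysis is session-scoped because several
acceptance checks read different statistics from the same run.
"""

from __future__ import annotations

import numpy as np
import pytest

import dnaexit as d


@pytest.fixture(scope="session")
def elastic() -> d.ElasticParams:
    return d.ElasticParams()


@pytest.fixture(scope="session")
def noise_model() -> d.NoiseModel:
    cfg = d.SimConfig(seed=11)
    rng = np.random.default_rng(11)
    controls = [d.simulate_control(cfg, 60.0, rng=rng, event_id=f"c{i}")
                for i in range(3)]
    return d.calibrate_noise(controls)


@pytest.fixture(scope="session")
def default_ensemble_bundle():
    """Full pipeline on the default Na+/5 pN study ensemble (n=39)."""
    cfg = d.SimConfig(seed=1)
    traces, _ = d.simulate_ensemble(cfg, 39)
    return d.run_pipeline(traces, d.AnalysisConfig(seed=1), applied_force=5.0)
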