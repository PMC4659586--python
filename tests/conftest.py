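"""Shared fixtures: converged toy metadynamics runs reused across modules."""
import numpy as np
import pytest

import ptmetad as pm


@pytest.fixture(scope="session")
def double_well_run():
    """Converged 1D well-tempered metadynamics run on the tilted double well.

    Reused by the metadynamics, FES and IO tests; barrier 10 kJ/mol,
    basin offset 4 kJ/mol, bias factor 8.
    """
    pot = pm.make_double_well(10.0, 4.0)
    params = pm.MetadParams(height=1.2, widths=(0.1,), deposition_stride=500,
                            bias_factor=8.0, temperature=305.0)
    cfg = pm.SamplerConfig(temperature=305.0, n_steps=800_000, seed=11,
                           save_stride=50)
    res = pm.run_wtmetad(pot, [pm.CoordinateCV(0)], params, cfg)
    axes = [np.linspace(-2.2, 2.2, 221)]
    return pot, res, axes


@pytest.fixture(scope="session")
def three_hill_log():
    """A tiny deposited hill log (first hills of a short biased run)."""
    pot = pm.make_double_well(6.0, 2.0)
    params = pm.MetadParams(height=1.5, widths=(0.12,), deposition_stride=200,
                            bias_factor=5.0, temperature=305.0)
    cfg = pm.SamplerConfig(temperature=305.0, n_steps=600, seed=3,
                           save_stride=100)
    res = pm.run_wtmetad(pot, [pm.CoordinateCV(0)], params, cfg)
    assert res.hills.n_hills == 3
    return res.hills
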