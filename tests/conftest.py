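import pytest

from xsikit import ensemble, extraction, maxent, synthetic
from xsikit.forward import build_basis_matrix, default_d_grid, default_q_grid


@pytest.fixture(scope="session")
def q_small():
    """Reduced q grid for fast unit tests."""
    return default_q_grid(n=96)


def make_bundle(preset: str, seed: int, q=None, **overrides):
    """Generate a scenario bundle, optionally scaled down for speed."""
    from dataclasses import replace

    scenario = replace(synthetic.get_scenario(preset), **overrides)
    return synthetic.generate_xsi_bundle(scenario, q_grid=q, seed=seed)


@pytest.fixture
def bundle_factory():
    return make_bundle


@pytest.fixture
def inverter():
    return invert_bundle


def invert_bundle(bundle, **kwargs):
    pattern = extraction.extract_bundle(bundle)
    basis = build_basis_matrix(bundle.q, default_d_grid())
    return maxent.fit_distribution(pattern, basis, **kwargs)


@pytest.fixture(scope="session")
def high_mg_bh_summary():
    """Full-pipeline recovery of the high-divalent-salt BH ensemble.

    Session-scoped: the same inversion serves the mode, area and
    free-energy checks.
    """
    bundle = make_bundle("high_Mg_BH", seed=11)
    dist = invert_bundle(bundle)
    return ensemble.summarize(dist)


@pytest.fixture(scope="session")
def fret_trace_set():
    """77 simulated 10 s traces at the high-divalent-salt rate constants."""
    from xsikit import fret

    model = fret.StateModel()
    traces = [synthetic.generate_fret_trace(model, 10.0, fps=306.0, seed=3000 + i)
              for i in range(77)]
    return model, traces
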