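from dataclasses import replace

import numpy as np
import pytest

from xsikit import fret, synthetic
from xsikit.synthetic import Scenario, ScenarioState, generate_fret_trace, generate_xsi_bundle


def _one_state(jitter=0.0, noise=0.0, n_conformers=3, **kw):
    return Scenario("BH", (ScenarioState(54.0, 1.0),), jitter=jitter,
                    noise=noise, n_conformers=n_conformers, **kw)


class TestScenarioValidation:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            Scenario("BH", (ScenarioState(54.0, 0.5), ScenarioState(89.0, 0.4)))

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="noise"):
            _one_state(noise=-0.01)

    def test_zero_states_rejected(self):
        with pytest.raises(ValueError, match="state"):
            Scenario("BH", ())

    def test_required_presets_ship(self):
        for name in ("high_Mg_BH", "high_Mg_HR", "high_Mg_BR",
                     "intermediate_Mg_BH", "low_salt_BR", "low_salt_HR",
                     "low_salt_RX"):
            scenario = synthetic.get_scenario(name)
            assert sum(s.weight for s in scenario.states) == pytest.approx(1.0)

    def test_high_mg_presets_encode_reported_ensembles(self):
        bh = synthetic.get_scenario("high_Mg_BH")
        assert {s.distance for s in bh.states} == {54.0, 89.0}
        assert max(s.weight for s in bh.states) == pytest.approx(0.84)
        assert synthetic.get_scenario("low_salt_BR").states[0].distance == 93.0


class TestXsiBundleGeneration:
    def test_deterministic_given_seed(self, q_small):
        scenario = _one_state(jitter=2.0, noise=0.01)
        b1 = generate_xsi_bundle(scenario, q_grid=q_small, seed=5)
        b2 = generate_xsi_bundle(scenario, q_grid=q_small, seed=5)
        for role in ("AB", "A", "B", "U", "Au", "Buf"):
            np.testing.assert_array_equal(b1[role].intensity, b2[role].intensity)

    def test_different_seeds_differ(self, q_small):
        scenario = _one_state(jitter=0.0, noise=0.01)
        b1 = generate_xsi_bundle(scenario, q_grid=q_small, seed=1)
        b2 = generate_xsi_bundle(scenario, q_grid=q_small, seed=2)
        assert not np.array_equal(b1["AB"].intensity, b2["AB"].intensity)

    def test_mixture_degeneracy(self, q_small):
        """Splitting one conformer into two identical states changes nothing."""
        one = Scenario("BH", (ScenarioState(54.0, 1.0),), jitter=0.0, noise=0.0,
                       n_conformers=4)
        two = Scenario("BH", (ScenarioState(54.0, 0.5), ScenarioState(54.0, 0.5)),
                       jitter=0.0, noise=0.0, n_conformers=4)
        b1 = generate_xsi_bundle(one, q_grid=q_small, seed=0)
        b2 = generate_xsi_bundle(two, q_grid=q_small, seed=0)
        for role in ("AB", "A", "B", "U"):
            np.testing.assert_allclose(b1[role].intensity, b2[role].intensity,
                                       rtol=1e-12)

    def test_noise_averages_to_noiseless_curve(self, q_small):
        """Mean over many seeds converges to the noiseless profile (LLN)."""
        noisy = _one_state(jitter=0.0, noise=0.01, n_conformers=2)
        clean = generate_xsi_bundle(replace(noisy, noise=0.0),
                                    q_grid=q_small, seed=0)["AB"]
        n_rep = 50
        bundles = [generate_xsi_bundle(noisy, q_grid=q_small, seed=s)["AB"]
                   for s in range(n_rep)]
        stack = np.stack([b.intensity for b in bundles])
        assert not np.array_equal(stack[0], stack[1])
        se = bundles[0].sigma / np.sqrt(n_rep)
        z = (stack.mean(axis=0) - clean.intensity) / se
        # fixed seeds: the largest standardized deviation stays in the 3-sigma
        # regime expected for ~100 comparisons
        assert np.max(np.abs(z)) < 4.5

    def test_sigma_positive_even_without_noise(self, q_small):
        bundle = generate_xsi_bundle(_one_state(), q_grid=q_small, seed=0)
        for role in ("AB", "A", "B", "U", "Au", "Buf"):
            assert np.all(bundle[role].sigma > 0)

    def test_buffer_profile_is_flat_baseline(self, q_small):
        bundle = generate_xsi_bundle(_one_state(), q_grid=q_small, seed=0)
        np.testing.assert_allclose(bundle["Buf"].intensity, 50.0)


class TestFretTraceGeneration:
    def test_symmetric_rates_give_half_occupancy(self):
        model = fret.StateModel(k_i_to_ii=20.0, k_ii_to_i=20.0)
        trace = generate_fret_trace(model, 200.0, fps=306.0, noise_sd=0.0, seed=1)
        frac = trace.true_occupancy.mean()
        se = 0.5 / np.sqrt(200.0 * 10.0)  # ~ sqrt(n_dwells) scaling
        assert frac == pytest.approx(0.5, abs=3 * se)

    def test_frozen_limit_constant_trace(self):
        """Vanishing rates freeze the trace at a single E value."""
        model = fret.StateModel(k_i_to_ii=1e-9, k_ii_to_i=1e-9)
        trace = generate_fret_trace(model, 5.0, fps=306.0, noise_sd=0.0, seed=0)
        e = fret.fret_efficiency(trace.donor, trace.acceptor)
        assert np.ptp(e) == pytest.approx(0.0, abs=1e-12)
        assert e[0] in (pytest.approx(0.14), pytest.approx(0.58))

    def test_mean_dwell_matches_exponential(self):
        """Latent isoI dwells average 1/k_I->II within 10% over a long trace.

        Sampled finely (3000 fps) so frame discretization of the latent
        path is negligible next to the 10% Monte-Carlo tolerance.
        """
        model = fret.StateModel()
        trace = generate_fret_trace(model, 100.0, fps=3000.0, noise_sd=0.0, seed=4)
        runs = fret._run_lengths(trace.true_states)[1:-1]
        dwells = [length / 3000.0 for state, length, _ in runs if state == fret.ISO_I]
        assert len(dwells) > 300
        assert np.mean(dwells) == pytest.approx(1 / 45.6, rel=0.10)

    def test_deterministic_given_seed(self):
        model = fret.StateModel()
        t1 = generate_fret_trace(model, 2.0, seed=9)
        t2 = generate_fret_trace(model, 2.0, seed=9)
        np.testing.assert_array_equal(t1.donor, t2.donor)

    def test_occupancy_matches_stationary_distribution(self):
        model = fret.StateModel()
        trace = generate_fret_trace(model, 300.0, fps=306.0, noise_sd=0.0, seed=2)
        p_ii = 45.6 / (45.6 + 7.9)
        se = np.sqrt(p_ii * (1 - p_ii)) / np.sqrt(300.0 * 7.9)  # dwell-limited
        assert trace.true_occupancy.mean() == pytest.approx(p_ii, abs=4 * se)

    def test_invalid_duration_rejected(self):
        with pytest.raises(ValueError):
            generate_fret_trace(fret.StateModel(), 0.0)
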