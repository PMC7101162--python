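"""Simulation design fidelity and generator statistical properties."""

import numpy as np
import pytest

from coccomix import (
    FieldSampleSpec,
    MorphotypeSpec,
    Scenario,
    coccolith_mass,
    simulate_field_sample,
    simulate_thickness_sample,
    table2_scenarios,
)


class TestDesignTable:
    def test_eight_groups_sixteen_samples(self):
        scenarios = table2_scenarios()
        assert [s.group for s in scenarios] == list(range(1, 9))
        assert sum(s.n_sims for s in scenarios) == 16
        # 12 two-component + 4 four-component samples = 40 components
        assert sum(s.n_sims * s.k for s in scenarios) == 40

    def test_two_component_rows(self):
        g1, g2, g3, g4 = table2_scenarios()[:4]
        for s in (g1, g2, g3, g4):
            assert (s.n, s.k, s.n_sims, s.sample_sd) == (200, 2, 3, 0.020)
        assert g1.weights == (0.25, 0.75)
        assert g1.true_means == (0.100, 0.120)
        assert g2.weights == (0.10, 0.90)
        assert g3.true_means == g4.true_means == (0.110, 0.110)
        # equal-mean groups: component SD equals the pooled SD; the
        # separated groups remove the between-mean variance
        assert g3.true_sd == g4.true_sd == 0.020
        assert g1.true_sd == pytest.approx(
            np.sqrt(0.02 ** 2 - 0.25 * 0.75 * 0.02 ** 2))
        assert g2.true_sd == pytest.approx(
            np.sqrt(0.02 ** 2 - 0.10 * 0.90 * 0.02 ** 2))

    def test_four_component_rows(self):
        g5, g6, g7, g8 = table2_scenarios()[4:]
        for s in (g5, g6, g7, g8):
            assert (s.n, s.k, s.n_sims, s.sample_sd) == (500, 4, 1, 0.02)
            assert 0 < s.true_sd < 0.02
        assert g5.weights == (0.10, 0.35, 0.35, 0.20)
        assert g6.weights == (0.35, 0.10, 0.35, 0.20)
        assert g7.weights == (0.35, 0.35, 0.10, 0.20)
        assert g8.true_means == (0.080, 0.100, 0.120, 0.140)

    def test_scenario_invariants_enforced(self):
        with pytest.raises(ValueError):
            Scenario(1, 1, 100, 2, (0.4, 0.4), (0.1, 0.12), 0.02)
        with pytest.raises(ValueError):
            Scenario(1, 1, 100, 2, (0.5, 0.5), (0.1,), 0.02)


class TestThicknessSampler:
    def test_labels_and_weights(self):
        scenario = Scenario(1, 1, 20000, 2, (0.25, 0.75), (0.1, 0.12), 0.02)
        values, labels = simulate_thickness_sample(scenario, 7)
        assert set(np.unique(labels)) <= {1, 2}
        frac = (labels == 1).mean()
        se = np.sqrt(0.25 * 0.75 / scenario.n)
        assert abs(frac - 0.25) < 3 * se

    def test_component_mean_within_standard_error(self):
        scenario = table2_scenarios()[0]
        values, labels = simulate_thickness_sample(scenario, 99)
        m1 = values[labels == 1].mean()
        n1 = (labels == 1).sum()
        assert abs(m1 - 0.100) < 3 * 0.020 / np.sqrt(n1)

    def test_seed_determinism(self):
        scenario = table2_scenarios()[4]
        v1, l1 = simulate_thickness_sample(scenario, 42)
        v2, l2 = simulate_thickness_sample(scenario, 42)
        assert np.array_equal(v1, v2) and np.array_equal(l1, l2)


class TestFieldSampler:
    def test_zero_variance_spec_gives_identical_records(self):
        spec = FieldSampleSpec(
            sample_id="s",
            morphotypes={"A": MorphotypeSpec(1.0, 3.3, 0.0, 1.2, 0.12, 0.0)},
            n_coccoliths=10, cell_density=1000.0, mass_noise_cv=0.0,
        )
        sem, lm, meta = simulate_field_sample(spec, 3)
        assert len({(r.length, r.width) for r in sem}) == 1
        assert len({(r.mass, r.mean_thickness) for r in lm}) == 1

    def test_noise_free_mass_is_volumetric_model(self, separated_field_spec):
        spec = FieldSampleSpec(
            sample_id=separated_field_spec.sample_id,
            morphotypes=separated_field_spec.morphotypes,
            n_coccoliths=50,
            cell_density=separated_field_spec.cell_density,
            mass_noise_cv=0.0,
        )
        sem, lm, _ = simulate_field_sample(spec, 5)
        for s, l in zip(sem, lm):
            assert l.mass == pytest.approx(
                coccolith_mass(s.length, s.width, l.mean_thickness))

    def test_only_overcalcified_lm_distinguishable(self):
        spec = FieldSampleSpec(
            sample_id="s",
            morphotypes={
                "A": MorphotypeSpec(0.5, 3.3, 0.1, 1.2, 0.12, 0.01),
                "OA": MorphotypeSpec(0.5, 3.0, 0.1, 1.2, 0.13, 0.01),
            },
            n_coccoliths=100, cell_density=1000.0,
        )
        sem, lm, _ = simulate_field_sample(spec, 11)
        for s, l in zip(sem, lm):
            expected = "overcalcified" if s.morphotype == "OA" else "open"
            assert l.central_area == expected

    def test_abundances_recover_spec_proportions(self, separated_field_spec):
        sem, _, _ = simulate_field_sample(separated_field_spec, 21)
        frac_a = np.mean([r.morphotype == "A" for r in sem])
        se = np.sqrt(0.7 * 0.3 / separated_field_spec.n_coccoliths)
        assert abs(frac_a - 0.70) < 3 * se

    def test_central_tube_only_for_type_a(self, separated_field_spec):
        sem, _, _ = simulate_field_sample(separated_field_spec, 21)
        for r in sem:
            if r.morphotype == "A":
                assert r.ct_left is not None and r.ct_right is not None
            else:
                assert r.ct_left is None

    def test_determinism(self, separated_field_spec):
        a = simulate_field_sample(separated_field_spec, 8)
        b = simulate_field_sample(separated_field_spec, 8)
        assert a[0] == b[0] and a[1] == b[1] and a[2] == b[2]
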