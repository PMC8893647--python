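"""Stochastic population simulator: hazard, division noise, regulation."""

import numpy as np
import pytest
from scipy import stats

from cngrowth import (DivisionRule, GrowthMode, RegulationSpec,
                      division_hazard, fit_growth_rate, run_population,
                      sample_division_deltas, simulate_generations,
                      step_population)
from cngrowth.population import (POP_FIELDS, _population_rhs,
                                 initialize_ensemble)
from cngrowth.model import rhs_array


class TestDivisionHazard:
    def test_uniform_distribution_closed_form(self):
        """For ω uniform on [a,b] the hazard is 1/(b−V), analytically."""
        a, b = 40.0, 60.0
        rule = DivisionRule.from_pdf(
            lambda v: np.where((v >= a) & (v <= b), 1 / (b - a), 0.0),
            support=(a, b))
        for V in [42.0, 50.0, 55.0, 58.0]:
            assert division_hazard(V, rule) == pytest.approx(
                1.0 / (b - V), rel=5e-3)

    def test_zero_below_support(self):
        rule = DivisionRule.normal(mean=55.0)
        assert division_hazard(10.0, rule) == 0.0

    def test_diverges_at_upper_edge(self):
        rule = DivisionRule.normal(mean=55.0)
        assert np.isinf(division_hazard(rule.grid[-1] + 1.0, rule))

    def test_rejects_unnormalized_pdf(self):
        with pytest.raises(ValueError):
            DivisionRule.from_pdf(lambda v: np.full_like(v, 0.5),
                                  support=(0.0, 10.0))


class TestDivisionNoise:
    def test_sample_std_matches_configured_sigma(self, rng):
        d = sample_division_deltas(rng, 100_000, sigma_div=0.125)
        assert d.std() == pytest.approx(0.125, abs=0.002)
        assert np.all(np.abs(d) < 1.0)

    def test_zero_noise_gives_exact_halving(self, yeast, rng):
        ens = initialize_ensemble(yeast.initial_state, yeast.parameters,
                                  GrowthMode.rich(), 8, rng,
                                  RegulationSpec.single())
        # certain division: support far below the cells' volumes
        rule = DivisionRule.from_pdf(
            lambda v: np.where((v >= 0.1) & (v <= 1.1), 1.0, 0.0),
            support=(0.1, 1.1), sigma_div=1e-12)
        before = ens.states.sum(axis=0) + 0.02 * _population_rhs(
            ens.states, yeast.parameters, ens.mode,
            RegulationSpec.single()).sum(axis=0)
        out = step_population(ens, rule, RegulationSpec.single(), dt=0.02)
        assert out.n_cells == 16
        np.testing.assert_allclose(out.states.sum(axis=0), before,
                                   rtol=1e-9)
        # each mother yields two exactly equal daughters
        half = np.sort(out.states[:, 1])
        np.testing.assert_allclose(half[0::2], half[1::2], rtol=1e-9)

    def test_mass_conserved_across_noisy_division(self, yeast, rng):
        ens = initialize_ensemble(yeast.initial_state, yeast.parameters,
                                  GrowthMode.rich(), 10, rng,
                                  RegulationSpec.single())
        rule = DivisionRule.from_pdf(
            lambda v: np.where((v >= 0.1) & (v <= 1.1), 1.0, 0.0),
            support=(0.1, 1.1), sigma_div=0.125)
        drift = 0.02 * _population_rhs(ens.states, yeast.parameters,
                                       ens.mode,
                                       RegulationSpec.single()).sum(axis=0)
        out = step_population(ens, rule, RegulationSpec.single(), dt=0.02)
        np.testing.assert_allclose(out.states.sum(axis=0),
                                   ens.states.sum(axis=0) + drift,
                                   rtol=1e-9)


class TestTwoSpeciesKinetics:
    def test_species_sum_recovers_single_species_model(self, yeast, rng):
        """Two species with shared coefficients must sum to the base RHS."""
        y7 = np.abs(rng.uniform(0.5, 50, size=(5, 7)))
        reg = RegulationSpec.equal(s=yeast.parameters.s1 / 2)
        for row in y7:
            y9 = np.array([row[0], row[1] / 2, row[1] / 2, row[2], row[3],
                           row[4] / 2, row[4] / 2, row[5], row[6]])
            d9 = _population_rhs(y9[None, :], yeast.parameters,
                                 GrowthMode.rich(), reg)[0]
            d7 = rhs_array(row, yeast.parameters, GrowthMode.rich())
            combined = np.array([d9[0], d9[1] + d9[2], d9[3], d9[4],
                                 d9[5] + d9[6], d9[7], d9[8]])
            np.testing.assert_allclose(combined, d7, rtol=1e-12)

    def test_suppression_coefficient_clamped_at_zero(self, yeast):
        reg = RegulationSpec.suppress()
        P1 = np.array([0.0, 10.0, 40.0])
        _, s12 = reg.coefficients(P1, yeast.parameters)
        np.testing.assert_allclose(s12, [145.0, 95.0, 0.0])


class TestPopulationRuns:
    def test_seed_determinism(self, yeast):
        _, s1 = run_population(yeast, n_cells=30, horizon=3.0, seed=7)
        ens_a, _ = run_population(yeast, n_cells=30, horizon=3.0, seed=7)
        ens_b, s2 = run_population(yeast, n_cells=30, horizon=3.0, seed=7)
        np.testing.assert_array_equal(ens_a.states, ens_b.states)
        assert s1.n_divisions == s2.n_divisions

    def test_ensemble_growth_matches_single_cell_rate(self, yeast,
                                                      yeast_rich_traj):
        """Total ensemble volume grows at the lineage growth rate (±10%)."""
        lam_single = fit_growth_rate(yeast_rich_traj)
        reg = RegulationSpec.single()
        rng = np.random.default_rng(3)
        ens = initialize_ensemble(yeast.initial_state, yeast.parameters,
                                  GrowthMode.rich(), 200, rng, reg)
        rule = DivisionRule.normal(
            mean=2 * (yeast.initial_state.P_C + yeast.initial_state.RP_C
                      + yeast.initial_state.R_C) / yeast.parameters.r1)
        t_log, v_log = [], []
        for i in range(300):  # 6 h at dt = 0.02
            ens = step_population(ens, rule, reg, dt=0.02)
            t_log.append(ens.time)
            v_log.append(ens.states.sum())
        t_log, v_log = np.array(t_log), np.array(v_log)
        keep = t_log > 2.0  # discard the synchronization transient
        lam_pop = np.polyfit(t_log[keep], np.log(v_log[keep]), 1)[0]
        assert lam_pop == pytest.approx(lam_single, rel=0.10)

    def test_division_volumes_follow_configured_distribution(self, yeast):
        """KS check of realized division volumes against ω (σ_div = 0)."""
        mean = 2 * (yeast.initial_state.P_C + yeast.initial_state.RP_C
                    + yeast.initial_state.R_C) / yeast.parameters.r1
        rule = DivisionRule.normal(mean=mean, sigma_div=1e-12)
        ens, _ = run_population(yeast, n_cells=300, horizon=17.0, seed=11,
                                rule=rule, max_cells=3000)
        v = np.array(ens.division_volumes)
        assert v.size >= 10_000
        def cdf(x):
            return np.interp(x, rule.grid, rule.cdf_grid, left=0, right=1)
        stat = stats.kstest(v, cdf).statistic
        # small residual bias from the finite Euler step is expected
        assert stat < 0.08

    def test_equal_synthesis_slope_is_one(self, yeast):
        _, summ = run_population(yeast, reg=RegulationSpec.equal(),
                                 n_cells=100, horizon=6.0, seed=5)
        assert summ.slope == pytest.approx(1.0, abs=0.05)

    def test_suppression_gives_concave_proteome_relation(self, yeast):
        """s12 = 145 − 5·P1 bends the P1–P2 cloud downward (P2 ∝ P1 − P1²)."""
        _, summ = run_population(yeast, reg=RegulationSpec.suppress(),
                                 n_cells=150, horizon=10.0, seed=2)
        assert summ.curvature < 0

    def test_enhancement_gives_convex_proteome_relation(self, yeast):
        _, summ = run_population(yeast, reg=RegulationSpec.enhance(),
                                 n_cells=150, horizon=10.0, seed=2)
        assert summ.curvature > 0

    def test_population_frame_columns(self, yeast):
        ens, _ = run_population(yeast, n_cells=10, horizon=0.5, seed=1)
        df = ens.to_frame()
        assert list(df.columns[:9]) == list(POP_FIELDS)
        assert (df["V_C"] > 0).all()
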