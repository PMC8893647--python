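"""Unit tests for the state types, volume law and flux families."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cngrowth import (CellState, DegenerateVolumeError, GrowthMode,
                      KineticParameters, compartment_volumes,
                      degradation_fluxes, rhs, rhs_array, synthesis_fluxes,
                      transport_fluxes)
from cngrowth.model import STATE_FIELDS

YEAST_NEWBORN = CellState(A_C=3200, P_C=15, RP_C=1.35, R_C=0.135,
                          P_N=1.65, RP_N=0.15, R_N=0.015)


def yeast_params(**over):
    base = dict(s1=155, s2=125, s3=48, n1=400, n2=400, n3=80,
                t1=400, t2=9, t3=1.2, t4=0.8, t5=0.75,
                d1C=0.1, d1N=0.1, d2C=0.1, d2N=0.1, d3C=0.1, d3N=0.1,
                r1=0.6, r2=0.6)
    base.update(over)
    return KineticParameters(**base)


counts = st.floats(min_value=0.0, max_value=1e4, allow_nan=False)


def random_states(rng, n=100):
    y = rng.uniform(0.01, 100, size=(n, 7))
    return [CellState.from_array(row) for row in y]


class TestVolumes:
    def test_tabulated_yeast_compartments(self):
        V_C, V_N = compartment_volumes(YEAST_NEWBORN, yeast_params())
        assert V_C == pytest.approx((15 + 0.135 + 1.35) / 0.6)  # ≈27.5 fL
        assert V_N == pytest.approx((1.65 + 0.015 + 0.15) / 0.6)  # ≈3.0 fL
        assert V_C == pytest.approx(27, rel=0.02)
        assert V_N == pytest.approx(3, rel=0.01)

    def test_empty_cell_has_zero_volume(self):
        empty = CellState(0, 0, 0, 0, 0, 0, 0)
        assert compartment_volumes(empty, yeast_params()) == (0.0, 0.0)

    @given(scale=st.floats(min_value=0.1, max_value=100))
    @settings(max_examples=25, deadline=None)
    def test_volume_is_linear_in_counts(self, scale):
        p = yeast_params()
        V0 = compartment_volumes(YEAST_NEWBORN, p)
        scaled = CellState.from_array(YEAST_NEWBORN.as_array() * scale)
        V1 = compartment_volumes(scaled, p)
        assert V1[0] == pytest.approx(scale * V0[0])
        assert V1[1] == pytest.approx(scale * V0[1])


class TestSynthesis:
    def test_translation_rate_arithmetic(self):
        p = yeast_params()
        V_C, _ = compartment_volumes(YEAST_NEWBORN, p)
        fx = synthesis_fluxes(YEAST_NEWBORN, p)
        assert fx.P_C == pytest.approx(155 * 3200 * 0.135 / (400 * V_C))
        assert fx.P_C == pytest.approx(6.09, rel=1e-2)
        assert fx.RP_C == pytest.approx(125 * 3200 * 0.135 / (400 * V_C))

    def test_ribosome_assembly_rate(self):
        fx = synthesis_fluxes(YEAST_NEWBORN, yeast_params())
        assert fx.R_N == pytest.approx(48 / 80 * 0.15)  # 0.09
        assert fx.RP_N == pytest.approx(-48 * 0.15)

    def test_no_translation_without_ribosomes(self):
        state = YEAST_NEWBORN.replace(R_C=0.0)
        fx = synthesis_fluxes(state, yeast_params())
        assert fx.P_C == fx.RP_C == fx.A_C == 0.0

    def test_amino_acid_stoichiometry(self):
        """With s2 = 0, exactly n1 amino acids are consumed per protein."""
        p = yeast_params(s2=1e-30)
        fx = synthesis_fluxes(YEAST_NEWBORN, p)
        assert -fx.A_C / fx.P_C == pytest.approx(p.n1, rel=1e-12)


class TestTransport:
    def test_rich_uptake_scales_with_transporters(self):
        p = yeast_params()
        V_C, V_N = compartment_volumes(YEAST_NEWBORN, p)
        fx = transport_fluxes(YEAST_NEWBORN, p, GrowthMode.rich())
        assert fx.A_C == pytest.approx(V_C / (V_C + V_N) * 400 * 15)
        assert fx.A_C == pytest.approx(5404, rel=1e-3)

    def test_poor_uptake_is_constant(self):
        fx = transport_fluxes(YEAST_NEWBORN, yeast_params(),
                              GrowthMode.poor(2850))
        V_C, V_N = compartment_volumes(YEAST_NEWBORN, yeast_params())
        assert fx.A_C == pytest.approx(V_C / (V_C + V_N) * 2850)

    def test_net_nonribosomal_import(self):
        p = yeast_params(t4=0.8, t5=0.75)
        V_C, V_N = compartment_volumes(YEAST_NEWBORN, p)
        fx = transport_fluxes(YEAST_NEWBORN, p, GrowthMode.rich())
        expect = (0.8 * 15 / V_C - 0.75 * 1.65 / V_N) * 15
        assert fx.P_N == pytest.approx(expect)
        assert expect == pytest.approx(0.42, abs=0.01)

    def test_envelope_fluxes_conserve_each_species(self, rng):
        p = yeast_params()
        for state in random_states(rng, 50):
            fx = transport_fluxes(state, p, GrowthMode.rich())
            assert fx.P_C + fx.P_N == pytest.approx(0, abs=1e-9)
            assert fx.RP_C + fx.RP_N == pytest.approx(0, abs=1e-9)
            assert fx.R_C + fx.R_N == pytest.approx(0, abs=1e-9)


class TestDegradation:
    def test_bimolecular_loss_rates(self):
        p = yeast_params()
        V_C, _ = compartment_volumes(YEAST_NEWBORN, p)
        fx = degradation_fluxes(YEAST_NEWBORN, p, GrowthMode.rich())
        assert fx.P_C == pytest.approx(-0.1 * 15 ** 2 / V_C)
        assert -fx.P_C == pytest.approx(0.819, rel=2e-3)

    def test_disassembly_returns_n3_ribosomal_proteins(self):
        p = yeast_params(d2C=1e-30)  # isolate the disassembly contribution
        V_C, _ = compartment_volumes(YEAST_NEWBORN, p)
        fx = degradation_fluxes(YEAST_NEWBORN, p, GrowthMode.rich())
        assert fx.RP_C == pytest.approx(80 * 0.1 * 0.135 * 15 / V_C)
        assert fx.RP_C == pytest.approx(0.59, abs=0.005)
        assert fx.R_C == pytest.approx(-0.1 * 0.135 * 15 / V_C)

    def test_quiescent_decay_is_first_order(self):
        mode = GrowthMode.quiescent(t1_bar_const=2850, d_quiescent=0.8,
                                    s3_override=5)
        fx = degradation_fluxes(YEAST_NEWBORN, yeast_params(), mode)
        assert fx.P_C == pytest.approx(-0.8 * 15)  # -12 per hour
        assert fx.R_C == pytest.approx(-0.8 * 0.135)

    def test_degenerate_volume_raises(self):
        state = CellState(A_C=10, P_C=1, RP_C=0, R_C=1,
                          P_N=0, RP_N=0, R_N=0)  # V_N = 0
        with pytest.raises(DegenerateVolumeError):
            degradation_fluxes(state, yeast_params(), GrowthMode.rich())


class TestRHS:
    @pytest.mark.parametrize("mode", [
        GrowthMode.rich(),
        GrowthMode.poor(2850),
        GrowthMode.quiescent(2850, 0.8, 5.0),
    ])
    def test_rhs_is_sum_of_flux_families(self, mode, rng):
        """The assembled system must equal the three families term by term."""
        p = yeast_params()
        for state in random_states(rng, 100):
            eff = mode.effective_params(p)
            expect = (synthesis_fluxes(state, eff).as_array()
                      + transport_fluxes(state, eff, mode).as_array()
                      + degradation_fluxes(state, eff, mode).as_array())
            got = rhs(state, p, mode).as_array()
            np.testing.assert_allclose(got, expect, rtol=1e-12, atol=1e-12)

    @pytest.mark.parametrize("mode", [
        GrowthMode.rich(),
        GrowthMode.poor(2850),
        GrowthMode.quiescent(2850, 0.8, 5.0),
    ])
    def test_array_path_matches_dataclass_path(self, mode, rng):
        p = yeast_params()
        states = random_states(rng, 60)
        Y = np.stack([s.as_array() for s in states], axis=1)
        fast = rhs_array(Y, p, mode)
        for j, state in enumerate(states):
            np.testing.assert_allclose(fast[:, j],
                                       rhs(state, p, mode).as_array(),
                                       rtol=1e-12, atol=1e-12)

    def test_zero_state_has_zero_derivative_in_rich_mode(self):
        zero = CellState(0, 0, 0, 0, 0, 0, 0)
        np.testing.assert_array_equal(
            rhs(zero, yeast_params(), GrowthMode.rich()).as_array(), 0.0)

    def test_poor_mode_adds_constant_uptake_term(self):
        p = yeast_params()
        V_C, V_N = compartment_volumes(YEAST_NEWBORN, p)
        base = rhs(YEAST_NEWBORN, p, GrowthMode.poor(2850)).as_array()[0]
        off = rhs(YEAST_NEWBORN, p, GrowthMode.poor(1e-30)).as_array()[0]
        assert base - off == pytest.approx(V_C / (V_C + V_N) * 2850)

    def test_positive_orthant_is_forward_invariant(self, rng):
        """Pools at zero can only be produced, never consumed."""
        p = yeast_params()
        for mode in (GrowthMode.rich(), GrowthMode.quiescent(2850, 0.8, 5)):
            for state in random_states(rng, 40):
                arr = state.as_array()
                mask = rng.uniform(size=7) < 0.4
                arr[mask] = 0.0
                if arr[1:4].sum() == 0 or arr[4:7].sum() == 0:
                    continue
                dy = rhs(CellState.from_array(arr), p, mode).as_array()
                assert np.all(dy[mask] >= -1e-12)
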