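"""Unit-bridge conversions, RHS assembly and stiff integration oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flashlysis.constants import CONC_PER_G_PER_GY
from flashlysis.kinetics_engine import (
    ConcentrationState,
    PrimaryYieldSet,
    background_water,
    build_rhs,
    concentration_from_g,
    default_time_grid,
    g_from_concentration,
    handoff_initialize,
    integrate,
)
from flashlysis.pulse_structure import make_pulse_train
from flashlysis.reaction_network import parse_reaction_table

K1A = 5.50e9


def oh_only_network():
    return parse_reaction_table("1a\tOH + OH -> H2O2\t5.50e9\tM-1s-1")


class TestUnitBridge:
    def test_one_g_one_gray(self):
        assert concentration_from_g(1.0, 1.0) == pytest.approx(1.0365e-7, rel=1e-4)

    def test_linear_in_g_and_dose(self):
        assert concentration_from_g(2.8, 10.0) == pytest.approx(2.902e-6, rel=1e-3)
        assert concentration_from_g(0.0, 123.0) == 0.0

    def test_inverse_conversion(self):
        assert g_from_concentration(1.0365e-6, 10.0) == pytest.approx(1.0, rel=1e-4)

    @settings(deadline=None, max_examples=50)
    @given(g=st.floats(0, 10), dose=st.floats(1e-3, 100))
    def test_roundtrip(self, g, dose):
        assert g_from_concentration(
            concentration_from_g(g, dose), dose
        ) == pytest.approx(g, rel=1e-12, abs=1e-12)

    def test_zero_dose_normalization_is_error(self):
        with pytest.raises(ValueError):
            g_from_concentration(1e-6, 0.0)

    def test_full_pulse_normalization_halves_midpulse_g(self):
        """Normalizing to the full pulse energy gives half the G that a
        dose-so-far normalization would report at half delivery."""
        c = concentration_from_g(2.8, 5.0)  # state after half of a 10 Gy pulse
        assert g_from_concentration(c, 10.0) == pytest.approx(
            0.5 * g_from_concentration(c, 5.0)
        )


class TestRhs:
    def test_first_order_textbook(self):
        net = parse_reaction_table(
            "species\tA\t0\tH:1\nspecies\tB\t0\tH:1\nd\tA -> B\t2.0\ts-1"
        )
        rhs = build_rhs(net)
        dy = rhs(0.0, np.array([3.0, 0.0]))
        np.testing.assert_allclose(dy, [-6.0, 6.0])

    def test_self_reaction_factor_two(self):
        rhs = build_rhs(oh_only_network())
        c = 1e-6
        dy = rhs(0.0, np.array([c, 0.0]))
        assert dy[0] == pytest.approx(-2 * K1A * c * c)
        assert dy[1] == pytest.approx(+K1A * c * c)

    def test_injection_term_scales_with_dose_rate(self):
        net = oh_only_network()
        inj = np.array([CONC_PER_G_PER_GY * 2.5 * (10.0 / 1.8e-6), 0.0])
        rhs = build_rhs(net, lambda t: inj)
        dy = rhs(0.0, np.zeros(2))
        assert dy[0] == pytest.approx(1.0365e-7 * 2.5 * 5.556e6, rel=1e-3)

    def test_constant_species_rows_forced_to_zero(self, network):
        rhs = build_rhs(network)
        y = np.array(
            [network.get_species(n).constant_concentration or 1e-7
             for n in network.species_names()]
        )
        dy = rhs(0.0, y)
        assert dy[network.species_index["H2O"]] == 0.0


class TestIntegrationOracles:
    def test_no_reactions_no_source_is_constant(self):
        net = parse_reaction_table("species\tA\t0\tH:1\nd\tA -> A\t1e-30\ts-1")
        grid = np.geomspace(1e-9, 10.0, 100)
        out = integrate(net, ConcentrationState({"A": 1e-5}), None, None, grid)
        np.testing.assert_allclose(out.concentration("A"), 1e-5, rtol=1e-7)

    def test_second_order_closed_form_8_decades(self):
        """Pure hydroxyl recombination matches 1/C(t) = 1/C0 + 2 k t to
        0.1% from 1 ns to 0.1 s."""
        c0 = 1e-5
        grid = np.geomspace(1e-9, 1e-1, 200)
        out = integrate(oh_only_network(), ConcentrationState({"OH": c0}),
                        None, None, grid)
        exact = c0 / (1 + 2 * K1A * c0 * grid)
        rel = np.abs(out.concentration("OH") - exact) / exact
        assert rel.max() < 1e-3
        # midpoint check: C = C0/2 at t = 1/(2 k C0)
        t_half = 1 / (2 * K1A * c0)
        out2 = integrate(oh_only_network(), ConcentrationState({"OH": c0}),
                         None, None, np.array([1e-9, t_half]))
        assert out2.concentration("OH")[-1] == pytest.approx(c0 / 2, rel=1e-3)

    def test_first_order_exponential_closed_form(self):
        net = parse_reaction_table(
            "species\tA\t0\tH:1\nspecies\tB\t0\tH:1\nd\tA -> B\t1e3\ts-1"
        )
        grid = np.geomspace(1e-7, 1e-2, 120)
        out = integrate(net, ConcentrationState({"A": 1e-6}), None, None, grid)
        np.testing.assert_allclose(
            out.concentration("A"), 1e-6 * np.exp(-1e3 * grid), rtol=1e-3
        )

    def test_rate_constant_recovery_from_decay(self):
        """Least squares on 1/C(t) of a simulated pure second-order decay
        recovers the input rate constant within 1%."""
        c0 = 1e-5
        grid = np.linspace(1e-6, 2e-4, 100)
        out = integrate(oh_only_network(), ConcentrationState({"OH": c0}),
                        None, None, grid)
        slope = np.polyfit(grid, 1.0 / out.concentration("OH"), 1)[0]
        assert slope / 2 == pytest.approx(K1A, rel=1e-2)

    def test_element_conservation_without_reservoir_flux(self, network):
        """H and O totals over dynamic species are conserved when only
        reactions without solvent exchange run (1a, 1b, 2b)."""
        sub = parse_reaction_table(
            "1a\tOH + OH -> H2O2\t5.50e9\tM-1s-1\n"
            "1b\tOH + O2- -> O2 + OH-\t1.07e10\tM-1s-1\n"
            "2b\tHO2 + O2- -> HO2- + O2\t9.70e7\tM-1s-1"
        )
        init = {"OH": 2e-6, "O2-": 1e-6, "HO2": 5e-7, "H2O2": 0, "O2": 0, "OH-": 0,
                "HO2-": 0}
        grid = np.geomspace(1e-9, 1.0, 80)
        out = integrate(sub, ConcentrationState(dict(init)), None, None, grid)
        for element, w in (
            ("H", {"OH": 1, "H2O2": 2, "HO2": 1, "HO2-": 1, "OH-": 1}),
            ("O", {"OH": 1, "O2-": 2, "H2O2": 2, "HO2": 2, "HO2-": 2, "O2": 2,
                   "OH-": 1}),
        ):
            total = sum(w.get(s, 0) * out.concentration(s) for s in out.species)
            np.testing.assert_allclose(total, total[0], rtol=1e-6,
                                       err_msg=f"{element} not conserved")

    def test_dose_conservation_through_injection(self):
        """Total injected amount equals yields x dose regardless of
        bunching/pulse structure (inert species, source on)."""
        net = parse_reaction_table("species\tX\t0\t\nd\tX + X -> X + X\t1e-30\tM-1s-1")
        yields = PrimaryYieldSet({"X": 2.0}, mode="per_pulse_injection")
        for width in (1.8e-6, 0.0):
            train = make_pulse_train(5.0, width, 1)
            grid = np.geomspace(1e-8, 1e-3, 60) if width else np.geomspace(1e-8, 1e-3, 60)
            out = integrate(net, ConcentrationState({"X": 0.0}), train, yields, grid)
            assert out.concentration("X")[-1] == pytest.approx(
                concentration_from_g(2.0, 5.0), rel=1e-6
            )


class TestHandoff:
    def test_zero_yields_gives_background(self):
        state = handoff_initialize(PrimaryYieldSet({}), 10.0)
        bg = background_water()
        assert state.concentrations == pytest.approx(bg)

    def test_neutral_ph_background(self):
        bg = background_water()
        assert bg["H3O+"] == pytest.approx(1.0e-7)
        assert bg["OH-"] == pytest.approx(1.0e-7)

    def test_yield_adds_converted_concentration(self):
        state = handoff_initialize(PrimaryYieldSet({"OH": 2.5}), 10.0)
        assert state.concentrations["OH"] == pytest.approx(2.59e-6, rel=1e-3)

    def test_negative_yields_rejected(self):
        with pytest.raises(ValueError):
            PrimaryYieldSet({"OH": -0.1})


class TestTrainIntegration:
    def test_instantaneous_kick_applied_at_pulse_time(self):
        net = parse_reaction_table("species\tX\t0\t\nd\tX + X -> X + X\t1e-30\tM-1s-1")
        train = make_pulse_train(10.0, 0.0, 1)
        yields = PrimaryYieldSet({"X": 1.0}, mode="per_pulse_injection")
        grid = np.geomspace(1e-9, 1e-3, 50)
        out = integrate(net, ConcentrationState({"X": 0.0}), train, yields, grid)
        np.testing.assert_allclose(
            out.concentration("X"), concentration_from_g(1.0, 10.0), rtol=1e-9
        )

    def test_multi_pulse_accumulates_total_dose(self):
        net = parse_reaction_table("species\tX\t0\t\nd\tX + X -> X + X\t1e-30\tM-1s-1")
        train = make_pulse_train(1.0, 1.8e-6, 3, 100.0)
        yields = PrimaryYieldSet({"X": 1.0}, mode="per_pulse_injection")
        grid = default_time_grid(1e-9, 0.1, train=train)
        out = integrate(net, ConcentrationState({"X": 0.0}), train, yields, grid)
        assert out.concentration("X")[-1] == pytest.approx(
            concentration_from_g(1.0, 3.0), rel=1e-6
        )
        assert out.normalization_dose == 3.0

    def test_g_normalized_to_full_train_energy(self):
        net = parse_reaction_table("species\tX\t0\t\nd\tX + X -> X + X\t1e-30\tM-1s-1")
        train = make_pulse_train(10.0, 1.8e-6, 1)
        yields = PrimaryYieldSet({"X": 3.0}, mode="per_pulse_injection")
        grid = np.concatenate([[0.9e-6], np.geomspace(1e-5, 1e-3, 10)])
        out = integrate(net, ConcentrationState({"X": 0.0}), train, yields, grid)
        # halfway through the pulse, half the material at full normalization
        assert out.g_value("X")[0] == pytest.approx(1.5, rel=1e-6)
        assert out.g_value("X")[-1] == pytest.approx(3.0, rel=1e-6)

    def test_grid_before_initial_time_rejected(self):
        net = oh_only_network()
        grid = np.array([0.5, 1.0])
        with pytest.raises(ValueError, match="t_grid"):
            integrate(net, ConcentrationState({"OH": 1e-5}, time=2.0), None,
                      None, grid)
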