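"""Bigeleisen engine: per-mode factors, the KIE chain, and the TST oracle."""

import numpy as np
import pytest

from _oracles import tst_kie
from isokie.bigeleisen import mode_factor_table, semiclassical_kie
from isokie.thermo import ThermoSettings
from isokie.vibrations import FrequencySet, IsotopeSubstitution, isotopolog_frequency_sets


def fset(real=(), imaginary=None):
    return FrequencySet(real=np.asarray(real, dtype=float), imaginary=imaginary)


class TestModeFactors:
    def test_identical_sets_give_unit_factors(self, th_room):
        t = mode_factor_table(fset([500.0, 1500.0]), fset([500.0, 1500.0]), th_room)
        np.testing.assert_allclose(t.factors, 1.0, rtol=1e-12)
        assert t.g == pytest.approx(1.0)

    def test_single_mode_closed_form(self, th_room):
        # 2990/2144 cm^-1 at 298.15 K: u_L = 14.428, u_H = 10.346
        t = mode_factor_table(fset([2990.0]), fset([2144.0]), th_room)
        assert t.u_light[0] == pytest.approx(14.428, abs=1e-3)
        assert t.u_heavy[0] == pytest.approx(10.346, abs=1e-3)
        assert t.g == pytest.approx(0.18110, abs=2e-4)

    def test_classical_limit_all_factors_one(self):
        hot = ThermoSettings(temperature=1e8)
        t = mode_factor_table(fset([2990.0]), fset([2144.0]), hot)
        np.testing.assert_allclose(t.factors, 1.0, atol=1e-6)

    def test_mode_count_mismatch_raises(self, th_room):
        with pytest.raises(ValueError, match="mismatch"):
            mode_factor_table(fset([100.0, 200.0]), fset([100.0]), th_room)


class TestSemiclassicalKIE:
    def test_identity_when_heavy_equals_light(self, th_room):
        r = fset([2990.0])
        t = fset([800.0], imaginary=1500.0)
        kie = semiclassical_kie(r, r, t, t, th_room)
        assert kie.value == pytest.approx(1.0, rel=1e-12)

    def test_single_mode_chain(self, th_room):
        # reactant 2990/2144, TS only an imaginary 1500i/1100i pair
        kie = semiclassical_kie(
            fset([2990.0]), fset([2144.0]),
            fset([], imaginary=1500.0), fset([], imaginary=1100.0),
            th_room,
        )
        assert kie.value == pytest.approx(7.530, abs=5e-3)
        assert kie.components["g_ts"] == pytest.approx(1.0)

    def test_kie_decreases_with_temperature(self):
        values = []
        for temp in (250.0, 298.15, 400.0, 600.0, 1000.0):
            kie = semiclassical_kie(
                fset([2990.0]), fset([2144.0]),
                fset([], imaginary=1500.0), fset([], imaginary=1100.0),
                ThermoSettings(temperature=temp),
            )
            values.append(kie.value)
        assert np.all(np.diff(values) < 0)

    def test_missing_imaginary_mode_raises(self, th_room):
        r = fset([2990.0])
        with pytest.raises(ValueError, match="imaginary"):
            semiclassical_kie(r, r, fset([800.0]), fset([800.0]), th_room)

    def test_imaginary_reactant_raises(self, th_room):
        t = fset([800.0], imaginary=1500.0)
        with pytest.raises(ValueError, match="minimum"):
            semiclassical_kie(t, t, t, t, th_room)


class TestInvariants:
    @pytest.mark.parametrize("element,index_label", [("H", "H"), ("C", "C"), ("Cl", "Cl")])
    def test_oracle_equivalence(self, transfer_reaction, th_room, element, index_label):
        """Engine equals brute-force partition-function TST to < 1e-6 relative.

        The oracle applies no Bigeleisen factorization, so agreement verifies
        the Teller–Redlich product rule numerically on the 4-atom toy.
        """
        reactant, ts = transfer_reaction
        idx = reactant.labels.index(index_label)
        sub = IsotopeSubstitution(idx, element)
        r_l, r_h = isotopolog_frequency_sets(reactant, sub)
        t_l, t_h = isotopolog_frequency_sets(ts, sub)
        engine = semiclassical_kie(r_l, r_h, t_l, t_h, th_room).value
        oracle = tst_kie(reactant, ts, sub, th_room)
        assert engine == pytest.approx(oracle, rel=1e-6)

    def test_oracle_equivalence_three_atom(self, transfer_reaction_3atom, th_room):
        reactant, ts = transfer_reaction_3atom
        sub = IsotopeSubstitution(reactant.labels.index("H"), "H")
        r_l, r_h = isotopolog_frequency_sets(reactant, sub)
        t_l, t_h = isotopolog_frequency_sets(ts, sub)
        engine = semiclassical_kie(r_l, r_h, t_l, t_h, th_room).value
        assert engine == pytest.approx(tst_kie(reactant, ts, sub, th_room), rel=1e-6)

    def test_classical_limit_is_frequency_ratio(self, transfer_reaction):
        """At T = 1e6 K the KIE collapses onto ν̃‡_L/ν̃‡_H to < 1e-4 relative."""
        reactant, ts = transfer_reaction
        sub = IsotopeSubstitution(reactant.labels.index("H"), "H")
        r_l, r_h = isotopolog_frequency_sets(reactant, sub)
        t_l, t_h = isotopolog_frequency_sets(ts, sub)
        hot = ThermoSettings(temperature=1e6)
        kie = semiclassical_kie(r_l, r_h, t_l, t_h, hot)
        assert kie.value == pytest.approx(t_l.imaginary / t_h.imaginary, rel=1e-4)

    def test_isotope_exchange_symmetry(self, transfer_reaction, th_room):
        """Swapping light/heavy roles inverts the KIE exactly."""
        reactant, ts = transfer_reaction
        sub = IsotopeSubstitution(reactant.labels.index("H"), "H")
        r_l, r_h = isotopolog_frequency_sets(reactant, sub)
        t_l, t_h = isotopolog_frequency_sets(ts, sub)
        forward = semiclassical_kie(r_l, r_h, t_l, t_h, th_room).value
        backward = semiclassical_kie(r_h, r_l, t_h, t_l, th_room).value
        assert forward * backward == pytest.approx(1.0, rel=1e-12)

    def test_lost_stretch_gives_normal_kie(self, th_room):
        """A reactant X–H stretch absent at the TS yields KIE > 1 for H→D."""
        for temp in (100.0, 298.15, 1000.0):
            kie = semiclassical_kie(
                fset([2990.0]), fset([2144.0]),
                fset([], imaginary=1000.0), fset([], imaginary=1000.0 * 0.999),
                ThermoSettings(temperature=temp),
            )
            assert kie.value > 1.0
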