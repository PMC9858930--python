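"""Membrane currents, pump fluxes, GHK unitary flux and balance assembly."""

import dataclasses

import numpy as np
import pytest

from sparkcell import currents
from sparkcell.currents import (assemble_derivatives, gate_steady_states,
                                ghk_unitary_current, lcc_unitary_flux,
                                lr_gate_derivatives, ncx_current, serca_flux)
from sparkcell.params import default_parameters
from sparkcell.state import CellState, GateVariables


class TestSerca:
    def test_zero_pump_concentration(self, params):
        pu = dataclasses.replace(params.pumps, ap=0.0)
        assert serca_flux(0.5, 1000.0, pu) == 0.0

    def test_exact_linearity_in_ap(self, params):
        pu = params.pumps
        pu15 = dataclasses.replace(pu, ap=1.5 * pu.ap)
        for ca, nsr in ((0.1, 500.0), (0.7, 1500.0), (2.0, 2500.0)):
            assert serca_flux(ca, nsr, pu15) == \
                pytest.approx(1.5 * serca_flux(ca, nsr, pu))

    def test_hill_formula_value(self, params):
        # vcycle_max = 5/s = 5e-3/ms, h = 2, km = 0.3 µM, ca = 0.3 µM
        # → vcycle = 2.5/s and J = 2 · 2.5/s · Ap (no NSR back-pressure at 0)
        pu = dataclasses.replace(params.pumps, vcycle_max=5.0e-3, hill=2.0,
                                 km_fwd=0.3, ap=100.0)
        j = serca_flux(0.3, 0.0, pu)
        assert j == pytest.approx(2.0 * 2.5e-3 * 100.0)

    def test_nsr_back_pressure_monotone(self, params):
        pu = params.pumps
        js = [serca_flux(0.5, nsr, pu) for nsr in (0.0, 1000.0, 2000.0,
                                                   pu.nsr_cap, 2 * pu.nsr_cap)]
        assert all(b <= a for a, b in zip(js, js[1:]))
        assert js[-1] == 0.0

    def test_negative_rejected(self, params):
        with pytest.raises(ValueError):
            serca_flux(-0.1, 0.0, params.pumps)


class TestNCX:
    def test_zero_at_reversal_potential(self, params):
        ca_myo = 0.2  # µM
        rt = params.rt_over_f
        e_na = rt * np.log(params.na_o / params.na_i)
        e_ca = 0.5 * rt * np.log(params.ca_o / (ca_myo * 1e-3))
        v_rev = 3 * e_na - 2 * e_ca
        assert ncx_current(v_rev, params.na_i, ca_myo, params) == \
            pytest.approx(0.0, abs=1e-9)

    def test_more_inward_with_cytosolic_ca(self, params):
        vals = [ncx_current(-40.0, 10.0, ca, params)
                for ca in (0.1, 0.5, 1.0, 2.0)]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_hand_evaluated_formula(self, params):
        # independent evaluation of the saturating 3Na:1Ca expression
        v, na_i, ca = -40.0, 10.0, 1.0
        p = params.pumps
        w = v / params.rt_over_f
        num = (np.exp(p.eta * w) * na_i ** 3 * params.ca_o
               - np.exp((p.eta - 1) * w) * params.na_o ** 3 * ca * 1e-3)
        den = ((p.km_na ** 3 + params.na_o ** 3) * (p.km_ca + params.ca_o)
               * (1 + p.ksat * np.exp((p.eta - 1) * w)))
        assert ncx_current(v, na_i, ca, params) == \
            pytest.approx(p.k_ncx * num / den, rel=1e-12)

    def test_submembrane_sensing_weight(self, params):
        pu = dataclasses.replace(params.pumps, ncx_ds_weight=0.5)
        p = dataclasses.replace(params, pumps=pu)
        mixed = ncx_current(-40.0, 10.0, 0.2, p, ca_ds=10.0)
        assert mixed == pytest.approx(ncx_current(-40.0, 10.0, 5.1, p))


class TestGHK:
    def test_zero_at_ghk_reversal(self, params):
        ca_ds, ca_o = 50.0, params.ca_o
        rt = params.rt_over_f
        # reversal where γi·ca_i·e^w = γo·ca_o (w = 2V/rt)
        w = np.log(0.341 * ca_o * 1e3 / ca_ds)  # ca_o mM → µM
        v_rev = w * rt / 2.0
        i = ghk_unitary_current(v_rev, ca_ds, ca_o, params.channels.p_dhpr, rt)
        assert i == pytest.approx(0.0, abs=1e-9)

    def test_permeability_scaling_pointwise(self, params):
        p = params.channels.p_dhpr
        for v in (-80.0, -20.0, 0.0, 25.0):
            f1 = lcc_unitary_flux(v, 0.5, params.ca_o, p)
            f2 = lcc_unitary_flux(v, 0.5, params.ca_o, 1.4 * p)
            assert f2 == pytest.approx(1.4 * f1, rel=1e-12)

    def test_v0_series_matches_limit(self, params):
        p = params.channels.p_dhpr
        i0 = ghk_unitary_current(0.0, 0.5, params.ca_o, p)
        eps = 1e-7
        i_lim = 0.5 * (ghk_unitary_current(eps, 0.5, params.ca_o, p)
                       + ghk_unitary_current(-eps, 0.5, params.ca_o, p))
        assert i0 == pytest.approx(i_lim, rel=1e-9)

    def test_inward_at_rest(self, params):
        i = ghk_unitary_current(-85.0, 0.1, params.ca_o, params.channels.p_dhpr)
        assert i < 0.0  # Ca flows into the cell


class TestGates:
    def test_fixed_point_has_zero_derivative(self):
        for v in (-85.0, -40.0, 0.0, 30.0):
            ss = gate_steady_states(v)
            g = GateVariables(m=ss[0], h=ss[1], j=ss[2], x=ss[3])
            assert np.allclose(lr_gate_derivatives(g, v), 0.0, atol=1e-12)

    def test_h_inf_monotone_decreasing(self):
        grid = np.linspace(-90.0, 0.0, 46)
        h_inf = [gate_steady_states(v)[1] for v in grid]
        assert all(b <= a + 1e-12 for a, b in zip(h_inf, h_inf[1:]))

    def test_gate_bounds_enforced(self):
        with pytest.raises(ValueError):
            lr_gate_derivatives(GateVariables(m=1.2), -40.0)

    def test_na_current_blocked_by_h_gate(self, params):
        state = CellState.resting(default_parameters(n_cru=4))
        state.glob.v = -20.0
        state.glob.gates = GateVariables(m=0.9, h=0.0, j=0.5, x=0.1)
        cur = currents.membrane_currents(state, default_parameters(n_cru=4))
        assert cur.i_na == 0.0


class TestAssembleDerivatives:
    def test_all_zero_state_gives_zero_derivatives(self):
        p = default_parameters(n_cru=8)
        state = CellState.resting(p)
        state.glob.ca_myo = 0.0
        state.glob.ca_nsr = 0.0
        state.crus.ca_jsr[:] = 0.0
        state.crus.ca_ds[:] = 0.0
        ss = gate_steady_states(state.glob.v)
        state.glob.gates = GateVariables(*ss)
        der, cur, flux = assemble_derivatives(state, p, sealed_membrane=True)
        assert der.dca_myo == 0.0
        assert der.dca_nsr == 0.0
        assert np.all(der.dca_jsr == 0.0)
        assert der.dv == 0.0

    def test_serca_only_directions(self):
        """With SERCA the only active flux, bulk Ca falls and NSR rises."""
        p = default_parameters(n_cru=8)
        pu = dataclasses.replace(p.pumps, k_leak=0.0, tau_tr=1e12,
                                 tau_xfer=1e12)
        p = dataclasses.replace(p, pumps=pu)
        state = CellState.resting(p)
        state.glob.ca_myo = 0.5
        state.glob.ca_nsr = 500.0
        state.crus.ca_jsr[:] = 500.0
        state.crus.ca_ds[:] = 0.5
        der, _, _ = assemble_derivatives(state, p, sealed_membrane=True)
        assert der.dca_myo < 0.0
        assert der.dca_nsr > 0.0

    def test_release_flux_zero_without_open_channels(self):
        p = default_parameters(n_cru=8)
        state = CellState.resting(p)
        _, _, flux = assemble_derivatives(state, p, sealed_membrane=True)
        assert np.all(flux.j_rel_unit == 0.0)

    def test_charge_consistency(self):
        """dV/dt has the opposite sign of the net membrane current."""
        p = default_parameters(n_cru=8)
        state = CellState.resting(p)
        state.glob.v = -40.0  # off equilibrium
        der, cur, _ = assemble_derivatives(state, p)
        assert der.dv == pytest.approx(-cur.total())

    def test_nan_detection(self):
        p = default_parameters(n_cru=4)
        state = CellState.resting(p)
        state.glob.ca_myo = np.nan
        with pytest.raises(FloatingPointError):
            assemble_derivatives(state, p)
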