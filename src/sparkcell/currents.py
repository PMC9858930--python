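"""Deterministic membrane currents, pump/exchanger fluxes and balance equations.

The sarcolemmal current set follows the Luo–Rudy guinea-pig formulations:
fast Na⁺ current (m³hj), time-dependent K⁺ current (x·Xi), inward rectifier
I_K1, plateau I_Kp, Na⁺/K⁺ pump, a linear background current and a small
background Ca²⁺ leak.  The L-type Ca²⁺ current is not a deterministic
conductance: it is the sum over CRUs of open-channel GHK unitary currents
from the stochastic six-state channels.

Sign conventions: outward membrane current is positive and
dV/dt = −ΣI / Cm; with currents in µA/µF this is mV/ms directly.  Fluxes
are µM/ms referred to the compartment named in each function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .params import ModelParameters, PumpExchangerParams, rapid_buffer_factor
from .state import CellState, GateVariables

__all__ = [
    "CurrentSet", "FluxSet", "Derivatives",
    "serca_flux", "ncx_current", "nak_current", "ghk_unitary_current",
    "lcc_unitary_flux", "lr_gate_derivatives", "gate_steady_states",
    "assemble_derivatives", "amp_to_flux_factor",
]


@dataclass
class CurrentSet:
    """Membrane currents, µA/µF (outward positive)."""

    i_na: float = 0.0
    i_ca_l: float = 0.0
    i_k: float = 0.0
    i_k1: float = 0.0
    i_kp: float = 0.0
    i_ncx: float = 0.0
    i_nak: float = 0.0
    i_bg: float = 0.0
    i_cab: float = 0.0
    i_stim: float = 0.0

    def total(self) -> float:
        return (self.i_na + self.i_ca_l + self.i_k + self.i_k1 + self.i_kp
                + self.i_ncx + self.i_nak + self.i_bg + self.i_cab
                + self.i_stim)


@dataclass
class FluxSet:
    """Ca²⁺ fluxes.  Whole-cell fluxes are µM/ms; per-CRU fluxes are arrays."""

    j_serca: float            # myo → NSR, myo-referred
    j_leak: float             # NSR → myo, myo-referred
    j_rel_unit: np.ndarray    # JSR → subspace per CRU, subspace-referred
    j_xfer_unit: np.ndarray   # subspace → myo per CRU, subspace-referred
    j_tr_unit: np.ndarray     # NSR → JSR per CRU, JSR-referred
    j_lcc_unit: np.ndarray    # sarcolemma → subspace per CRU, subspace-referred


@dataclass
class Derivatives:
    """Time derivatives of every continuous variable."""

    dv: float
    dca_myo: float
    dca_nsr: float
    dca_jsr: np.ndarray
    dca_ds: np.ndarray
    dgates: np.ndarray        # d(m, h, j, x)/dt
    dna_i: float = 0.0
    dk_i: float = 0.0


# ---------------------------------------------------------------------------
# njit kernels

@njit(cache=True)
def _serca(ca_myo, ca_nsr, vcycle_max, km, hill, ap, nsr_cap):
    if ca_myo <= 0.0:
        return 0.0
    x = ca_myo ** hill
    back = 1.0 - ca_nsr / nsr_cap
    if back < 0.0:
        back = 0.0
    vcycle = vcycle_max * x / (x + km ** hill) * back
    return 2.0 * vcycle * ap


@njit(cache=True)
def _ncx(v, na_i, ca_myo_mm, ca_o, na_o, k_ncx, km_na, km_ca, eta, ksat, rt):
    w = v / rt
    num = (np.exp(eta * w) * na_i ** 3 * ca_o
           - np.exp((eta - 1.0) * w) * na_o ** 3 * ca_myo_mm)
    den = ((km_na ** 3 + na_o ** 3) * (km_ca + ca_o)
           * (1.0 + ksat * np.exp((eta - 1.0) * w)))
    return k_ncx * num / den


@njit(cache=True)
def _nak(v, na_i, na_o, k_o, p_nak, km_nai, km_ko, rt):
    sigma = (np.exp(na_o / 67.3) - 1.0) / 7.0
    f = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * v / rt)
               + 0.0365 * sigma * np.exp(-v / rt))
    return (p_nak * f * (k_o / (k_o + km_ko))
            / (1.0 + (km_nai / na_i) ** 1.5))


@njit(cache=True)
def _ghk_current(v, ca_ds_um, ca_o_mm, p_dhpr, rt):
    """Single L-type channel GHK current in pA.

    ``p_dhpr`` in cm³/s, concentrations converted to mol/cm³; activity
    coefficients 1.0 (in) and 0.341 (out).  The removable singularity at
    v = 0 is handled by a series expansion.
    """
    z = 2.0
    gamma_i = 1.0
    gamma_o = 0.341
    ca_i = ca_ds_um * 1.0e-9      # µM → mol/cm³
    ca_o = ca_o_mm * 1.0e-6       # mM → mol/cm³
    w = z * v / rt
    f = 96485.0
    if abs(w) < 1.0e-5:
        # w/(e^w−1) ≈ 1 − w/2 + w²/12
        corr = 1.0 - w / 2.0 + w * w / 12.0
        flux = (gamma_i * ca_i * np.exp(w) - gamma_o * ca_o) * corr
    else:
        flux = w * (gamma_i * ca_i * np.exp(w) - gamma_o * ca_o) / (np.exp(w) - 1.0)
    return p_dhpr * z * f * flux * 1.0e12   # A → pA


@njit(cache=True)
def _gate_rates(v, x_scale=1.0):
    """LR-style α/β for m, h, j, x.  Returns (alphas, betas), 1/ms.

    ``x_scale`` multiplies the K-activation gate kinetics (its steady state
    is unchanged; only the time constant shrinks).
    """
    a = np.empty(4)
    b = np.empty(4)
    dvm = v + 47.13
    if abs(dvm) < 1.0e-6:
        a[0] = 3.2
    else:
        a[0] = 0.32 * dvm / (1.0 - np.exp(-0.1 * dvm))
    b[0] = 0.08 * np.exp(-v / 11.0)
    if v < -40.0:
        a[1] = 0.135 * np.exp((80.0 + v) / -6.8)
        b[1] = 3.56 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.35 * v)
        a[2] = ((-1.2714e5 * np.exp(0.2444 * v)
                 - 3.474e-5 * np.exp(-0.04391 * v)) * (v + 37.78)
                / (1.0 + np.exp(0.311 * (v + 79.23))))
        b[2] = (0.1212 * np.exp(-0.01052 * v)
                / (1.0 + np.exp(-0.1378 * (v + 40.14))))
    else:
        a[1] = 0.0
        b[1] = 1.0 / (0.13 * (1.0 + np.exp((v + 10.66) / -11.1)))
        a[2] = 0.0
        b[2] = (0.3 * np.exp(-2.535e-7 * v)
                / (1.0 + np.exp(-0.1 * (v + 32.0))))
    a[3] = (0.0005 * np.exp(0.083 * (v + 50.0))
            / (1.0 + np.exp(0.057 * (v + 50.0))))
    b[3] = (0.0013 * np.exp(-0.06 * (v + 20.0))
            / (1.0 + np.exp(-0.04 * (v + 20.0))))
    a[3] *= x_scale
    b[3] *= x_scale
    return a, b


@njit(cache=True)
def _xi(v):
    """Rectification factor of the time-dependent K current."""
    if v > -100.0:
        dv = v + 77.0
        if abs(dv) < 1.0e-6:
            return 2.837 * 0.04 / np.exp(0.04 * (v + 35.0))
        return 2.837 * (np.exp(0.04 * dv) - 1.0) / (dv * np.exp(0.04 * (v + 35.0)))
    return 1.0


@njit(cache=True)
def _k1_inf(v, e_k1):
    ak1 = 1.02 / (1.0 + np.exp(0.2385 * (v - e_k1 - 59.215)))
    bk1 = ((0.49124 * np.exp(0.08032 * (v - e_k1 + 5.476))
            + np.exp(0.06175 * (v - e_k1 - 594.31)))
           / (1.0 + np.exp(-0.5143 * (v - e_k1 + 4.753))))
    return ak1 / (ak1 + bk1)


@njit(cache=True)
def _kp(v):
    return 1.0 / (1.0 + np.exp((7.488 - v) / 5.98))


# ---------------------------------------------------------------------------
# Python API

def serca_flux(ca_myo: float, ca_nsr: float,
               pumps: PumpExchangerParams) -> float:
    """Whole-cell SERCA uptake J = 2·v_cycle·Ap, µM/ms myoplasm-referred.

    v_cycle is a Hill function of bulk myoplasmic Ca (``vcycle_max``,
    ``km_fwd``, ``hill``) times a linear NSR back-pressure factor
    (1 − ca_nsr/nsr_cap, clipped at 0): pumping against a loaded SR slows
    the cycle.  The flux is exactly linear in the pump concentration Ap.
    """
    if ca_myo < 0 or ca_nsr < 0:
        raise ValueError("concentrations must be non-negative")
    return _serca(ca_myo, ca_nsr, pumps.vcycle_max, pumps.km_fwd,
                  pumps.hill, pumps.ap, pumps.nsr_cap)


def ncx_current(v: float, na_i: float, ca_myo: float,
                params: ModelParameters,
                ca_ds: float | None = None) -> float:
    """Electrogenic 3Na⁺:1Ca²⁺ exchange current, µA/µF.

    Positive (outward) in Ca-entry mode; negative (inward, depolarizing)
    while extruding Ca.  Zero at V = 3·E_Na − 2·E_Ca.  The exchanger senses
    a submembrane Ca level: a weighted mix of bulk and (if given) mean
    subspace Ca with weight ``ncx_ds_weight``.
    """
    p = params.pumps
    ca = ca_myo if ca_ds is None else (
        (1.0 - p.ncx_ds_weight) * ca_myo + p.ncx_ds_weight * ca_ds)
    return _ncx(v, na_i, ca * 1.0e-3, params.ca_o, params.na_o,
                p.k_ncx, p.km_na, p.km_ca, p.eta, p.ksat, params.rt_over_f)


def nak_current(v: float, na_i: float, params: ModelParameters) -> float:
    """Na⁺/K⁺ pump current, µA/µF (always outward)."""
    p = params.pumps
    return _nak(v, na_i, params.na_o, params.k_o, p.p_nak, p.km_nai,
                p.km_ko, params.rt_over_f)


def ghk_unitary_current(v: float, ca_ds: float, ca_o: float, p_dhpr: float,
                        rt_over_f: float = 26.712) -> float:
    """Single open L-type channel current (pA) from the GHK constant-field form."""
    return _ghk_current(v, ca_ds, ca_o, p_dhpr, rt_over_f)


def lcc_unitary_flux(v: float, ca_ds: float, ca_o: float, p_dhpr: float,
                     v_ds: float = 0.5e-18,
                     rt_over_f: float = 26.712) -> float:
    """Ca²⁺ flux of one open L-type channel into its subspace, µM/ms.

    Positive into the subspace; zero at the GHK reversal potential and
    pointwise proportional to ``p_dhpr``.
    """
    i_pa = _ghk_current(v, ca_ds, ca_o, p_dhpr, rt_over_f)
    # pA → mol/ms → µM/ms in v_ds litres
    return -i_pa * 1.0e-12 / (2.0 * 96485.0) / v_ds * 1.0e6 * 1.0e-3


def lr_gate_derivatives(gates: GateVariables, v: float) -> np.ndarray:
    """d(m, h, j, x)/dt (1/ms) with fixed point at g∞ = α/(α+β)."""
    g = gates.as_array()
    if np.any(g < 0) or np.any(g > 1):
        raise ValueError("gates must lie in [0, 1]")
    a, b = _gate_rates(v)
    return a * (1.0 - g) - b * g


def gate_steady_states(v: float) -> np.ndarray:
    """(m∞, h∞, j∞, x∞) at voltage v."""
    a, b = _gate_rates(v)
    return a / (a + b)


def amp_to_flux_factor(params: ModelParameters) -> float:
    """µM/ms of myoplasmic Ca per µA/µF of a divalent Ca current."""
    return params.c_tot * 1.0e-3 / (2.0 * params.faraday
                                    * params.geometry.v_myo)


def reversal_potentials(params: ModelParameters, ca_myo: float):
    rt = params.rt_over_f
    pr = 0.01833
    e_na = rt * np.log(params.na_o / params.na_i)
    e_k = rt * np.log((params.k_o + pr * params.na_o)
                      / (params.k_i + pr * params.na_i))
    e_k1 = rt * np.log(params.k_o / params.k_i)
    e_ca = 0.5 * rt * np.log(params.ca_o / max(ca_myo * 1.0e-3, 1.0e-12))
    return e_na, e_k, e_k1, e_ca


def membrane_currents(state: CellState, params: ModelParameters,
                      i_stim: float = 0.0) -> CurrentSet:
    """Evaluate every sarcolemmal current at the given state."""
    g = state.glob
    p = params.pumps
    e_na, e_k, e_k1, _ = reversal_potentials(params, g.ca_myo)
    gt = g.gates
    i_na = p.g_na * gt.m ** 3 * gt.h * gt.j * (g.v - e_na)
    i_k = p.g_k * gt.x * _xi(g.v) * (g.v - e_k)
    i_k1 = p.g_k1 * np.sqrt(params.k_o / 5.4) * _k1_inf(g.v, e_k1) * (g.v - e_k1)
    i_kp = p.g_kp * _kp(g.v) * (g.v - e_k1)
    i_ncx = ncx_current(g.v, g.na_i, g.ca_myo, params)
    i_nak = nak_current(g.v, g.na_i, params)
    i_bg = p.g_bg * (g.v + 59.87)
    e_ca = reversal_potentials(params, g.ca_myo)[3]
    i_cab = p.g_cab * (g.v - e_ca)
    # whole-cell L-type current from open stochastic channels
    n_open = state.crus.open_lcc
    i_single = _ghk_current(g.v, float(state.crus.ca_ds.mean()),
                            params.ca_o, params.channels.p_dhpr,
                            params.rt_over_f)
    # scale to full complement so desk-scale CRU counts keep whole-cell units
    scale = 20000.0 / params.geometry.n_cru if params.geometry.n_cru else 1.0
    i_ca_l = float(n_open.sum()) * scale * i_single * 1.0e-6 / params.c_tot
    return CurrentSet(i_na=i_na, i_ca_l=i_ca_l, i_k=i_k, i_k1=i_k1,
                      i_kp=i_kp, i_ncx=i_ncx, i_nak=i_nak, i_bg=i_bg,
                      i_cab=i_cab, i_stim=i_stim)


def assemble_derivatives(state: CellState, params: ModelParameters,
                         i_stim: float = 0.0,
                         sealed_membrane: bool = False,
                         quasi_static_subspace: bool = False):
    """Reference (vectorized numpy) assembly of all continuous derivatives.

    This is the slow, transparent counterpart of the compiled engine step:
    balance equations for V, bulk Ca, NSR, per-CRU JSR and subspace Ca, and
    the HH gates.  ``sealed_membrane`` zeroes every sarcolemmal flux (for
    conservation checks).  Returns ``(Derivatives, CurrentSet, FluxSet)``.

    Raises
    ------
    FloatingPointError
        If any derivative is non-finite (with a state snapshot in the
        message).
    """
    g = state.glob
    geo = params.geometry
    pu = params.pumps
    crus = state.crus
    scale = 20000.0 / geo.n_cru

    if sealed_membrane:
        cur = CurrentSet()
    else:
        cur = membrane_currents(state, params, i_stim)

    alpha = amp_to_flux_factor(params)
    j_serca = serca_flux(g.ca_myo, g.ca_nsr, pu)
    j_leak = pu.k_leak * (g.ca_nsr - g.ca_myo)

    n_open_ryr = crus.ryr[:, 1].astype(np.float64)
    n_open_lcc = (crus.lcc[:, 1] + crus.lcc[:, 2]).astype(np.float64)
    j_rel = params.channels.ryr2.v_ryr * n_open_ryr * (crus.ca_jsr - crus.ca_ds)
    if sealed_membrane:
        j_lcc = np.zeros_like(j_rel)
    else:
        i_single = np.array([_ghk_current(g.v, c, params.ca_o,
                                          params.channels.p_dhpr,
                                          params.rt_over_f)
                             for c in crus.ca_ds])
        j_lcc = n_open_lcc * (-i_single * 1.0e-12 / (2.0 * 96485.0)
                              / geo.v_ds_unit * 1.0e3)
    j_xfer = (crus.ca_ds - g.ca_myo) / pu.tau_xfer
    j_tr = (g.ca_nsr - crus.ca_jsr) / pu.tau_tr

    r_ds_myo = geo.v_ds_unit / geo.v_myo * scale
    r_ds_jsr = geo.v_ds_unit / geo.v_jsr_unit
    r_jsr_nsr = geo.v_jsr_unit / geo.v_nsr * scale
    r_myo_nsr = geo.v_myo / geo.v_nsr

    beta_myo = rapid_buffer_factor(g.ca_myo, params.buffers.myo)
    beta_jsr = np.array([rapid_buffer_factor(c, [params.buffers.casq])
                         for c in crus.ca_jsr])
    beta_ds = np.array([rapid_buffer_factor(c, [params.buffers.subspace])
                        for c in crus.ca_ds])

    # i_ca_l enters via the subspace (j_lcc); i_cab is a divalent Ca current;
    # i_ncx carries one net charge per Ca, so its Ca flux is 2·alpha·I
    # (into the cell when the current is outward, i.e. Ca-entry mode)
    j_ca_membrane = 0.0 if sealed_membrane else (
        -cur.i_cab * alpha + 2.0 * cur.i_ncx * alpha)

    dca_myo = beta_myo * (np.sum(j_xfer) * r_ds_myo - j_serca + j_leak
                          + j_ca_membrane)
    dca_nsr = (j_serca - j_leak) * r_myo_nsr - np.sum(j_tr) * r_jsr_nsr
    dca_jsr = beta_jsr * (j_tr - j_rel * r_ds_jsr)
    if quasi_static_subspace:
        dca_ds = np.zeros_like(crus.ca_ds)
    else:
        dca_ds = beta_ds * (j_rel + j_lcc - j_xfer)
    dv = 0.0 if sealed_membrane else -cur.total()
    dgates = lr_gate_derivatives(g.gates, g.v)

    vals = np.concatenate([[dv, dca_myo, dca_nsr], dca_jsr, dca_ds, dgates])
    if not np.all(np.isfinite(vals)):
        raise FloatingPointError(
            f"non-finite derivative at V={g.v:.3f} mV, ca_myo={g.ca_myo:.4g}, "
            f"ca_nsr={g.ca_nsr:.4g}")

    flux = FluxSet(j_serca=j_serca, j_leak=j_leak, j_rel_unit=j_rel,
                   j_xfer_unit=j_xfer, j_tr_unit=j_tr, j_lcc_unit=j_lcc)
    der = Derivatives(dv=dv, dca_myo=dca_myo, dca_nsr=dca_nsr,
                      dca_jsr=dca_jsr, dca_ds=dca_ds, dgates=dgates)
    return der, cur, flux
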