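"""Time-stepping engine: stochastic CRU ensemble + deterministic membrane.

Integration scheme (operator-split explicit Euler):

* Continuous compartment variables advance at ``dt`` (default 0.05 ms).
  Buffered compartments (myoplasm, junctional SR) are integrated in *total*
  Ca and inverted to free Ca through the rapid-buffer binding curve each
  step, so Ca mass is conserved to round-off.
* The dyadic subspace of each CRU is quasi-steady-state: its Ca level is the
  algebraic balance of RyR2 release, L-type GHK influx and diffusion to the
  bulk (all linear in subspace Ca), solved exactly per step.  The QSS
  identity (ca_ds − ca_myo)/τ_xfer = J_rel + J_lcc makes the subspace a
  storage-free conduit, which keeps whole-cell Ca bookkeeping exact.
* Channel gating uses the frozen-rate scheme: each channel leaves its state
  with probability 1 − exp(−k_exit·dt), destinations proportional to the
  outgoing rates, sampled as aggregated binomial counts.  Quiescent CRUs
  take a single-uniform shortcut: when the total transition propensity λ·dt
  is below 0.02 the step draws "no event" with its exact probability
  exp(−λ·dt) and otherwise executes one transition.
* Membrane potential and HH gates are sub-stepped adaptively inside each dt
  (Rush–Larsen gates, Euler voltage) so the Na⁺ upstroke stays resolved
  without paying the fine step in the CRU ensemble.

A single master seed drives one RNG stream; identical (config, seed) give
bit-identical traces.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .params import ModelParameters, apply_scenario, default_parameters
from .state import CellState

__all__ = [
    "PacingProtocol", "SimulationConfig", "SimulationTrace", "SparkEvent",
    "build_protocol", "stimulus_times", "run_protocol", "detect_spark_events",
    "calibrate_stimulus", "IntegrationError", "FULL_SCALE_N_CRU",
]

FULL_SCALE_N_CRU = 20000

TRACE_COLUMNS = [
    "time_s", "v", "ca_myo", "ca_nsr", "ca_jsr_mean", "ca_ds_mean",
    "i_na", "i_ca_l", "i_k", "i_k1", "i_kp", "i_ncx", "i_nak", "i_bg",
    "i_stim", "open_ryr", "open_lcc", "na_i",
]


class IntegrationError(RuntimeError):
    """Numerical blow-up (NaN/Inf) during integration."""


# ---------------------------------------------------------------------------
# protocols

@dataclass(frozen=True)
class PacingProtocol:
    """Ordered pacing segments plus the stimulus pulse definition."""

    segments: tuple                   # ((frequency_hz, duration_s), ...)
    stim_amplitude: float = -60.0     # µA/µF (inward)
    stim_width_ms: float = 1.0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        for f, d in self.segments:
            if f <= 0 or d <= 0:
                raise ValueError("frequencies and durations must be > 0")
            if self.stim_width_ms >= 1000.0 / f:
                raise ValueError("stimulus width must be below cycle length")

    @property
    def total_duration_s(self) -> float:
        return float(sum(d for _, d in self.segments))


def build_protocol(kind: str, f_slow: float = 1.0, f_fast: float = 5.0,
                   durations: float | Sequence[float] = 10.0,
                   stim_amplitude: float = -60.0,
                   stim_width_ms: float = 1.0) -> PacingProtocol:
    """Build a pacing protocol.

    ``kind='constant'``: one segment at ``f_slow`` for ``durations`` seconds.
    ``kind='srs'``: slow–rapid–slow, [(f_slow, d1), (f_fast, d2),
    (f_slow, d3)]; a scalar ``durations`` is used for all three phases.
    """
    if kind == "constant":
        d = durations if np.isscalar(durations) else durations[0]
        segs = ((float(f_slow), float(d)),)
    elif kind == "srs":
        ds = [durations] * 3 if np.isscalar(durations) else list(durations)
        if len(ds) != 3:
            raise ValueError("srs needs three durations")
        segs = ((float(f_slow), float(ds[0])),
                (float(f_fast), float(ds[1])),
                (float(f_slow), float(ds[2])))
    else:
        raise ValueError(f"unknown protocol kind {kind!r}")
    return PacingProtocol(segments=segs, stim_amplitude=stim_amplitude,
                          stim_width_ms=stim_width_ms)


def stimulus_times(protocol: PacingProtocol) -> np.ndarray:
    """Stimulus onset times in seconds: floor(duration × frequency) per segment."""
    times = []
    t0 = 0.0
    for f, d in protocol.segments:
        n = int(np.floor(d * f + 1e-9))
        times.extend(t0 + k / f for k in range(n))
        t0 += d
    return np.asarray(times)


@dataclass
class SimulationConfig:
    """Run configuration (time step, recording, seed, scale, scenario)."""

    dt_ms: float = 0.05
    record_every_ms: float = 0.5
    seed: int = 0
    n_cru: int = 2000
    scenario: str = "wt_control"
    protocol: PacingProtocol = field(
        default_factory=lambda: build_protocol("constant", 1.0, durations=10.0))
    spark_threshold: int = 2
    spark_gap_ms: float = 5.0
    record_cru_open: bool = False
    sealed_membrane: bool = False
    dynamic_na: bool = True
    init_ca_nsr: float = 1100.0
    init_ca_myo: float = 0.12

    def __post_init__(self) -> None:
        if self.dt_ms <= 0:
            raise ValueError("dt must be > 0")
        if self.record_every_ms < self.dt_ms:
            raise ValueError("record_every must be >= dt")
        if self.n_cru < 1:
            raise ValueError("n_cru must be >= 1")
        if self.spark_threshold < 1:
            raise ValueError("spark_threshold must be >= 1")


@dataclass
class SparkEvent:
    """One elementary release episode of a single CRU."""

    cru_id: int
    start_s: float
    end_s: float
    peak_open_ryr: int
    peak_ca_ds: float


@dataclass
class SimulationTrace:
    """Recorded time series plus spark events and run metadata.

    ``df`` has one row per sample (columns in :data:`TRACE_COLUMNS`);
    ``events`` one row per spark; ``stim_times_s`` the stimulus onsets;
    ``meta`` the reproducibility sidecar (config hash, seed, scenario).
    """

    df: pd.DataFrame
    events: pd.DataFrame
    stim_times_s: np.ndarray
    meta: dict
    cru_open: np.ndarray | None = None   # (n_samples, n_cru) if recorded

    @property
    def time_s(self) -> np.ndarray:
        return self.df["time_s"].to_numpy()

    @property
    def v(self) -> np.ndarray:
        return self.df["v"].to_numpy()

    def to_csv(self, path: str) -> None:
        """Write the trace CSV plus a JSON metadata sidecar (path + '.meta.json')."""
        self.df.to_csv(path, index=False)
        side = dict(self.meta)
        side["stim_times_s"] = list(map(float, self.stim_times_s))
        with open(str(path) + ".meta.json", "w") as fh:
            json.dump(side, fh, indent=1)
        self.events.to_csv(str(path) + ".events.csv", index=False)

    @classmethod
    def from_csv(cls, path: str) -> "SimulationTrace":
        df = pd.read_csv(path)
        try:
            with open(str(path) + ".meta.json") as fh:
                meta = json.load(fh)
            stim = np.asarray(meta.pop("stim_times_s"))
        except FileNotFoundError:
            meta, stim = {}, np.array([])
        try:
            events = pd.read_csv(str(path) + ".events.csv")
        except FileNotFoundError:
            events = pd.DataFrame(columns=["cru_id", "start_s", "end_s",
                                           "peak_open_ryr", "peak_ca_ds"])
        return cls(df=df, events=events, stim_times_s=stim, meta=meta)


# ---------------------------------------------------------------------------
# parameter packing for the compiled kernel

_PARAM_ORDER = [
    "dt", "v_ryr", "tau_xfer", "tau_tr", "k_leak",
    "vcycle_max", "km_fwd", "hill_serca", "ap", "nsr_cap",
    "k_ncx", "km_na", "km_ca", "eta", "ksat", "ncx_ds_weight",
    "p_nak", "km_nai", "km_ko",
    "g_k", "g_k1", "g_kp", "g_na", "g_bg", "g_cab", "x_rate_scale",
    "ca_o", "na_o", "k_o", "na_i", "k_i",
    "rt", "c_tot", "v_myo", "v_nsr", "v_jsr_unit", "v_ds_unit", "scale",
    "p_dhpr", "phi_m", "phi_b",
    "k_open_max", "hill_ryr", "k_ca", "k_close", "k_adapt", "k_recover",
    "act_max", "act_vhalf", "act_slope",
    "deact_max", "deact_vhalf", "deact_slope",
    "k_o2o3", "k_o3o2", "ca_inact_slope", "k_c4_rec",
    "vinact_max", "vinact_vhalf", "vinact_slope", "k_c5_rec",
    "c6_max", "c6_vhalf", "c6_slope", "k_c6_exit", "rec_vhalf", "rec_slope",
    "casq_btot", "casq_kd", "trpn_btot", "trpn_kd", "cmdn_btot", "cmdn_kd",
    "stim_amp", "stim_width", "spark_thr", "spark_gap", "sealed",
]
_PK = {name: i for i, name in enumerate(_PARAM_ORDER)}

# compile-time integer constants for the njit kernels
for _k, _i in _PK.items():
    globals()["I_" + _k.upper()] = _i
del _k, _i


def _pack(params: ModelParameters, config: SimulationConfig) -> np.ndarray:
    p = np.zeros(len(_PK))
    geo, bufs, ch, pu = (params.geometry, params.buffers, params.channels,
                         params.pumps)
    r, c = ch.ryr2, ch.lcc
    vals = dict(
        dt=config.dt_ms, v_ryr=r.v_ryr, tau_xfer=pu.tau_xfer,
        tau_tr=pu.tau_tr, k_leak=pu.k_leak,
        vcycle_max=pu.vcycle_max, km_fwd=pu.km_fwd, hill_serca=pu.hill,
        nsr_cap=pu.nsr_cap,
        ap=pu.ap, k_ncx=pu.k_ncx, km_na=pu.km_na, km_ca=pu.km_ca,
        eta=pu.eta, ksat=pu.ksat, ncx_ds_weight=pu.ncx_ds_weight,
        p_nak=pu.p_nak, km_nai=pu.km_nai,
        km_ko=pu.km_ko, g_k=pu.g_k, g_k1=pu.g_k1, g_kp=pu.g_kp,
        x_rate_scale=pu.x_rate_scale,
        g_na=pu.g_na, g_bg=pu.g_bg, g_cab=pu.g_cab,
        ca_o=params.ca_o, na_o=params.na_o, k_o=params.k_o,
        na_i=params.na_i, k_i=params.k_i, rt=params.rt_over_f,
        c_tot=params.c_tot, v_myo=geo.v_myo, v_nsr=geo.v_nsr,
        v_jsr_unit=geo.v_jsr_unit, v_ds_unit=geo.v_ds_unit,
        scale=FULL_SCALE_N_CRU / geo.n_cru,
        p_dhpr=ch.p_dhpr, phi_m=ch.phi_m, phi_b=ch.phi_b,
        k_open_max=r.k_open_max, hill_ryr=r.hill_ca_ds, k_ca=r.k_ca,
        k_close=r.k_close, k_adapt=r.k_adapt, k_recover=r.k_recover,
        act_max=c.act_max, act_vhalf=c.act_vhalf, act_slope=c.act_slope,
        deact_max=c.deact_max, deact_vhalf=c.deact_vhalf,
        deact_slope=c.deact_slope,
        k_o2o3=c.k_o2o3, k_o3o2=c.k_o3o2, ca_inact_slope=c.ca_inact_slope,
        k_c4_rec=c.k_c4_recover, vinact_max=c.vinact_max,
        vinact_vhalf=c.vinact_vhalf, vinact_slope=c.vinact_slope,
        k_c5_rec=c.k_c5_recover, c6_max=c.c6_entry_max, c6_vhalf=c.c6_vhalf,
        c6_slope=c.c6_slope, k_c6_exit=c.k_c6_exit,
        rec_vhalf=c.rec_vhalf, rec_slope=c.rec_slope,
        casq_btot=bufs.casq.btot, casq_kd=bufs.casq.kd,
        trpn_btot=bufs.troponin.btot, trpn_kd=bufs.troponin.kd,
        cmdn_btot=bufs.calmodulin.btot, cmdn_kd=bufs.calmodulin.kd,
        stim_amp=config.protocol.stim_amplitude,
        stim_width=config.protocol.stim_width_ms,
        spark_thr=float(config.spark_threshold),
        spark_gap=config.spark_gap_ms,
        sealed=1.0 if config.sealed_membrane else 0.0,
    )
    for k, v in vals.items():
        p[_PK[k]] = v
    return p


# ---------------------------------------------------------------------------
# compiled kernel helpers

@njit(cache=True, inline="always")
def _free_from_total_1(total, btot, kd):
    """Free Ca from total in a single-buffer compartment (exact quadratic)."""
    b = btot + kd - total
    return 0.5 * (-b + np.sqrt(b * b + 4.0 * kd * total))


@njit(cache=True, inline="always")
def _free_from_total_2(total, free_guess, b1, k1, b2, k2):
    """Free Ca from total with two buffers (Newton, warm-started)."""
    f = free_guess
    for _ in range(3):
        g = f + b1 * f / (f + k1) + b2 * f / (f + k2) - total
        dg = 1.0 + b1 * k1 / ((f + k1) * (f + k1)) \
            + b2 * k2 / ((f + k2) * (f + k2))
        f -= g / dg
        if f < 1.0e-9:
            f = 1.0e-9
    return f


@njit(cache=True, inline="always")
def _total_from_free_2(f, b1, k1, b2, k2):
    return f + b1 * f / (f + k1) + b2 * f / (f + k2)


@njit(cache=True)
def _membrane(v, m, h, jg, x, ca_myo, ca_ncx, na_i, i_ca_l, i_stim, P,
              e_na, e_k, e_k1, dt):
    """One membrane substep (Rush–Larsen gates, Euler voltage)."""
    rt = P[I_RT]
    dvm = v + 47.13
    if abs(dvm) < 1.0e-6:
        am = 3.2
    else:
        am = 0.32 * dvm / (1.0 - np.exp(-0.1 * dvm))
    bm = 0.08 * np.exp(-v / 11.0)
    if v < -40.0:
        ah = 0.135 * np.exp((80.0 + v) / -6.8)
        bh = 3.56 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.35 * v)
        aj = ((-1.2714e5 * np.exp(0.2444 * v)
               - 3.474e-5 * np.exp(-0.04391 * v)) * (v + 37.78)
              / (1.0 + np.exp(0.311 * (v + 79.23))))
        bj = (0.1212 * np.exp(-0.01052 * v)
              / (1.0 + np.exp(-0.1378 * (v + 40.14))))
    else:
        ah = 0.0
        bh = 1.0 / (0.13 * (1.0 + np.exp((v + 10.66) / -11.1)))
        aj = 0.0
        bj = (0.3 * np.exp(-2.535e-7 * v)
              / (1.0 + np.exp(-0.1 * (v + 32.0))))
    ax = (0.0005 * np.exp(0.083 * (v + 50.0))
          / (1.0 + np.exp(0.057 * (v + 50.0)))) * P[I_X_RATE_SCALE]
    bx = (0.0013 * np.exp(-0.06 * (v + 20.0))
          / (1.0 + np.exp(-0.04 * (v + 20.0)))) * P[I_X_RATE_SCALE]

    i_na = P[I_G_NA] * m ** 3 * h * jg * (v - e_na)
    if v > -100.0:
        dvk = v + 77.0
        if abs(dvk) < 1.0e-6:
            xi = 2.837 * 0.04 / np.exp(0.04 * (v + 35.0))
        else:
            xi = (2.837 * (np.exp(0.04 * dvk) - 1.0)
                  / (dvk * np.exp(0.04 * (v + 35.0))))
    else:
        xi = 1.0
    i_k = P[I_G_K] * x * xi * (v - e_k)
    ak1 = 1.02 / (1.0 + np.exp(0.2385 * (v - e_k1 - 59.215)))
    bk1 = ((0.49124 * np.exp(0.08032 * (v - e_k1 + 5.476))
            + np.exp(0.06175 * (v - e_k1 - 594.31)))
           / (1.0 + np.exp(-0.5143 * (v - e_k1 + 4.753))))
    i_k1 = P[I_G_K1] * np.sqrt(P[I_K_O] / 5.4) * ak1 / (ak1 + bk1) * (v - e_k1)
    i_kp = P[I_G_KP] / (1.0 + np.exp((7.488 - v) / 5.98)) * (v - e_k1)

    w = v / rt
    ca_mm = ca_ncx * 1.0e-3
    num = (np.exp(P[I_ETA] * w) * na_i ** 3 * P[I_CA_O]
           - np.exp((P[I_ETA] - 1.0) * w) * P[I_NA_O] ** 3 * ca_mm)
    den = ((P[I_KM_NA] ** 3 + P[I_NA_O] ** 3) * (P[I_KM_CA] + P[I_CA_O])
           * (1.0 + P[I_KSAT] * np.exp((P[I_ETA] - 1.0) * w)))
    i_ncx = P[I_K_NCX] * num / den

    sigma = (np.exp(P[I_NA_O] / 67.3) - 1.0) / 7.0
    fnak = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * w)
                  + 0.0365 * sigma * np.exp(-w))
    i_nak = (P[I_P_NAK] * fnak * (P[I_K_O] / (P[I_K_O] + P[I_KM_KO]))
             / (1.0 + (P[I_KM_NAI] / na_i) ** 1.5))

    i_bg = P[I_G_BG] * (v + 59.87)
    e_ca = 0.5 * rt * np.log(P[I_CA_O] / max(ca_myo * 1.0e-3, 1.0e-12))
    i_cab = P[I_G_CAB] * (v - e_ca)

    total = (i_na + i_ca_l + i_k + i_k1 + i_kp + i_ncx + i_nak + i_bg
             + i_cab + i_stim)
    v_new = v - dt * total
    m = am / (am + bm) + (m - am / (am + bm)) * np.exp(-dt * (am + bm))
    h = ah / (ah + bh) + (h - ah / (ah + bh)) * np.exp(-dt * (ah + bh))
    jg = aj / (aj + bj) + (jg - aj / (aj + bj)) * np.exp(-dt * (aj + bj))
    x = ax / (ax + bx) + (x - ax / (ax + bx)) * np.exp(-dt * (ax + bx))
    return v_new, m, h, jg, x, i_na, i_k, i_k1, i_kp, i_ncx, i_nak, i_bg, i_cab


@njit(cache=True, inline="always")
def _split_two(n, k1, k2):
    """Distribute n movers between two destinations with rates k1, k2."""
    if n == 0:
        return 0, 0
    if k2 == 0.0:
        return n, 0
    n1 = np.random.binomial(n, k1 / (k1 + k2))
    return n1, n - n1


@njit(cache=True)
def _run_kernel(P, n_steps, rec_steps, stim_t_ms, seed,
                v0, ca_myo0, ca_nsr0, gates0, ca_jsr0, ryr0, lcc0,
                rec, ev_cru, ev_start, ev_end, ev_peak_n, ev_peak_ds,
                cru_open_rec, record_cru_open, dynamic_na):
    np.random.seed(seed)
    n_cru = ca_jsr0.shape[0]
    dt = P[I_DT]
    sealed = P[I_SEALED] > 0.5
    rt = P[I_RT]
    scale = P[I_SCALE]
    c_tot = P[I_C_TOT]
    v_myo = P[I_V_MYO]
    v_nsr = P[I_V_NSR]
    v_jsr = P[I_V_JSR_UNIT]
    v_ds = P[I_V_DS_UNIT]
    tau_xfer = P[I_TAU_XFER]
    tau_tr = P[I_TAU_TR]
    k_leak = P[I_K_LEAK]
    v_ryr = P[I_V_RYR]
    phi_m = P[I_PHI_M]
    phi_b = P[I_PHI_B]
    k_open_max = P[I_K_OPEN_MAX]
    hill_ryr = P[I_HILL_RYR]
    k_ca_h = P[I_K_CA] ** hill_ryr
    k_close = P[I_K_CLOSE]
    k_adapt = P[I_K_ADAPT]
    k_recover = P[I_K_RECOVER]
    casq_btot = P[I_CASQ_BTOT]
    casq_kd = P[I_CASQ_KD]
    trpn_btot = P[I_TRPN_BTOT]
    trpn_kd = P[I_TRPN_KD]
    cmdn_btot = P[I_CMDN_BTOT]
    cmdn_kd = P[I_CMDN_KD]
    spark_thr = int(P[I_SPARK_THR])
    spark_gap = P[I_SPARK_GAP]
    stim_amp = P[I_STIM_AMP]
    stim_width = P[I_STIM_WIDTH]
    hill_serca = P[I_HILL_SERCA]
    km_serca_h = P[I_KM_FWD] ** hill_serca
    vcycle_max = P[I_VCYCLE_MAX]
    ap = P[I_AP]
    k_o2o3 = P[I_K_O2O3]
    k_o3o2 = P[I_K_O3O2]
    ca_slope = P[I_CA_INACT_SLOPE]

    r_ds_myo = v_ds / v_myo * scale
    r_ds_jsr = v_ds / v_jsr
    r_jsr_nsr = v_jsr / v_nsr * scale
    r_myo_nsr = v_myo / v_nsr
    conv_ds = 1.0e-12 / (2.0 * 96485.0) / v_ds * 1.0e3
    pzf = P[I_P_DHPR] * 2.0 * 96485.0 * 1.0e12
    alpha = c_tot * 1.0e-3 / (2.0 * 96485.0 * v_myo)

    pr = 0.01833
    na_i = P[I_NA_I]
    e_na = rt * np.log(P[I_NA_O] / na_i)
    e_k = rt * np.log((P[I_K_O] + pr * P[I_NA_O])
                      / (P[I_K_I] + pr * na_i))
    e_k1 = rt * np.log(P[I_K_O] / P[I_K_I])
    # mM of Na_i per (µA/µF)·ms of a monovalent current
    na_conv = c_tot * 1.0e-6 / (96485.0 * v_myo)

    v = v0
    ca_myo = ca_myo0
    t_myo = _total_from_free_2(ca_myo, trpn_btot, trpn_kd, cmdn_btot, cmdn_kd)
    ca_nsr = ca_nsr0
    m, h, jg, x = gates0[0], gates0[1], gates0[2], gates0[3]
    ca_jsr = ca_jsr0.copy()
    t_jsr = np.empty(n_cru)
    for i in range(n_cru):
        t_jsr[i] = ca_jsr[i] + casq_btot * ca_jsr[i] / (ca_jsr[i] + casq_kd)
    ca_ds = np.full(n_cru, ca_myo)
    ryr = ryr0.copy()
    lcc = lcc0.copy()

    in_ep = np.zeros(n_cru, dtype=np.uint8)
    ep_start = np.zeros(n_cru)
    ep_last = np.zeros(n_cru)
    ep_pk_n = np.zeros(n_cru, dtype=np.int64)
    ep_pk_ds = np.zeros(n_cru)
    n_events = 0
    max_events = ev_cru.shape[0]

    i_na = i_k = i_k1 = i_kp = i_ncx = i_nak = i_bg = i_cab = 0.0
    i_ca_l = 0.0
    stim_idx = 0
    n_stim = stim_t_ms.shape[0]

    rec_row = 0
    status = 0

    for step in range(n_steps + 1):
        t = step * dt

        i_stim_now = 0.0
        if not sealed:
            while stim_idx < n_stim and t >= stim_t_ms[stim_idx] + stim_width:
                stim_idx += 1
            if stim_idx < n_stim and stim_t_ms[stim_idx] <= t:
                i_stim_now = stim_amp

        # voltage-dependent per-step precomputations
        w = 2.0 * v / rt
        ew = np.exp(w)
        if abs(w) < 1.0e-5:
            wfac = 1.0 - w / 2.0 + w * w / 12.0
        else:
            wfac = w / (ew - 1.0)
        ghk_a = pzf * wfac * 1.0e-9 * ew      # pA per µM subspace Ca
        ghk_b = pzf * wfac * 0.341 * P[I_CA_O] * 1.0e-6

        bz = 1.0 / (1.0 + np.exp(-(v - P[I_ACT_VHALF]) / P[I_ACT_SLOPE]))
        r_act = P[I_ACT_MAX] * bz
        bz = 1.0 / (1.0 + np.exp(-(v - P[I_DEACT_VHALF]) / P[I_DEACT_SLOPE]))
        r_deact = P[I_DEACT_MAX] * (1.0 - bz)
        bz = 1.0 / (1.0 + np.exp(-(v - P[I_VINACT_VHALF]) / P[I_VINACT_SLOPE]))
        r_vinact = P[I_VINACT_MAX] * bz
        bz = 1.0 / (1.0 + np.exp(-(v - P[I_C6_VHALF]) / P[I_C6_SLOPE]))
        r_c6in = P[I_C6_MAX] * bz
        rec_gate = 1.0 - 1.0 / (1.0 + np.exp(-(v - P[I_REC_VHALF])
                                             / P[I_REC_SLOPE]))
        k_c4r = P[I_K_C4_REC] * rec_gate
        k_c5r = P[I_K_C5_REC] * rec_gate
        k_c6x = P[I_K_C6_EXIT] * rec_gate
        k_c1 = r_act + r_c6in

        sum_xfer = 0.0
        sum_tr = 0.0
        sum_i_single = 0.0
        sum_ds = 0.0
        sum_jsr = 0.0
        tot_open_ryr = 0
        tot_open_lcc = 0

        for i in range(n_cru):
            n_or = ryr[i, 1]
            n_ol = lcc[i, 1] + lcc[i, 2]
            cj = ca_jsr[i]

            # quasi-steady subspace Ca
            krel = v_ryr * n_or
            if sealed:
                a_lcc = 0.0
                b_lcc = 0.0
            else:
                a_lcc = n_ol * conv_ds * ghk_a
                b_lcc = n_ol * conv_ds * ghk_b
            cd = ((ca_myo + tau_xfer * (krel * cj + b_lcc))
                  / (1.0 + tau_xfer * (krel + a_lcc)))
            if cd < 0.0:
                cd = 0.0
            ca_ds[i] = cd

            j_rel = krel * (cj - cd)
            j_tr = (ca_nsr - cj) / tau_tr
            t_jsr[i] += dt * (j_tr - j_rel * r_ds_jsr)
            ca_jsr[i] = _free_from_total_1(t_jsr[i], casq_btot, casq_kd)

            if not sealed:
                sum_i_single += n_ol * (ghk_a * cd - ghk_b)
            sum_xfer += (cd - ca_myo) / tau_xfer
            sum_tr += j_tr
            sum_ds += cd
            sum_jsr += ca_jsr[i]
            tot_open_ryr += n_or
            tot_open_lcc += n_ol

            # --- RyR2 gating (aggregated counts, frozen rates)
            if cd > 0.0:
                xh = cd ** hill_ryr
                k_open = ((phi_m * cj + phi_b) * k_open_max * xh
                          / (xh + k_ca_h))
            else:
                k_open = 0.0
            lam = dt * (ryr[i, 0] * k_open
                        + ryr[i, 1] * (k_close + k_adapt)
                        + ryr[i, 2] * k_recover)
            do_full = True
            if lam < 0.02:
                do_full = False
                if np.random.random() >= np.exp(-lam):
                    u = np.random.random() * lam
                    c0 = dt * ryr[i, 0] * k_open
                    c1 = c0 + dt * ryr[i, 1] * k_close
                    c2 = c1 + dt * ryr[i, 1] * k_adapt
                    if u < c0:
                        ryr[i, 0] -= 1
                        ryr[i, 1] += 1
                    elif u < c1:
                        ryr[i, 1] -= 1
                        ryr[i, 0] += 1
                    elif u < c2:
                        ryr[i, 1] -= 1
                        ryr[i, 2] += 1
                    else:
                        ryr[i, 2] -= 1
                        ryr[i, 0] += 1
            if do_full:
                n1 = 0
                if ryr[i, 0] > 0 and k_open > 0.0:
                    n1 = np.random.binomial(ryr[i, 0], -np.expm1(-k_open * dt))
                n2 = 0
                if ryr[i, 1] > 0:
                    n2 = np.random.binomial(
                        ryr[i, 1], -np.expm1(-(k_close + k_adapt) * dt))
                n3 = 0
                if ryr[i, 2] > 0 and k_recover > 0.0:
                    n3 = np.random.binomial(ryr[i, 2],
                                            -np.expm1(-k_recover * dt))
                n2c, n2a = _split_two(n2, k_close, k_adapt)
                ryr[i, 0] += n2c + n3 - n1
                ryr[i, 1] += n1 - n2
                ryr[i, 2] += n2a - n3

            # --- LCC gating (aggregated counts over 6 states)
            k_o2 = r_deact + k_o2o3 + ca_slope * cd + r_vinact
            lam_l = dt * (lcc[i, 0] * k_c1 + lcc[i, 1] * k_o2
                          + lcc[i, 2] * k_o3o2 + lcc[i, 3] * k_c4r
                          + lcc[i, 4] * k_c5r + lcc[i, 5] * k_c6x)
            do_full = True
            if lam_l < 0.02:
                do_full = False
                if np.random.random() >= np.exp(-lam_l):
                    u = np.random.random() * lam_l
                    c0 = dt * lcc[i, 0] * r_act
                    c1 = c0 + dt * lcc[i, 0] * r_c6in
                    c2 = c1 + dt * lcc[i, 1] * r_deact
                    c3 = c2 + dt * lcc[i, 1] * k_o2o3
                    c4 = c3 + dt * lcc[i, 1] * ca_slope * cd
                    c5 = c4 + dt * lcc[i, 1] * r_vinact
                    c6 = c5 + dt * lcc[i, 2] * k_o3o2
                    c7 = c6 + dt * lcc[i, 3] * k_c4r
                    c8 = c7 + dt * lcc[i, 4] * k_c5r
                    if u < c0:
                        lcc[i, 0] -= 1
                        lcc[i, 1] += 1
                    elif u < c1:
                        lcc[i, 0] -= 1
                        lcc[i, 5] += 1
                    elif u < c2:
                        lcc[i, 1] -= 1
                        lcc[i, 0] += 1
                    elif u < c3:
                        lcc[i, 1] -= 1
                        lcc[i, 2] += 1
                    elif u < c4:
                        lcc[i, 1] -= 1
                        lcc[i, 3] += 1
                    elif u < c5:
                        lcc[i, 1] -= 1
                        lcc[i, 4] += 1
                    elif u < c6:
                        lcc[i, 2] -= 1
                        lcc[i, 1] += 1
                    elif u < c7:
                        lcc[i, 3] -= 1
                        lcc[i, 0] += 1
                    elif u < c8:
                        lcc[i, 4] -= 1
                        lcc[i, 0] += 1
                    else:
                        lcc[i, 5] -= 1
                        lcc[i, 0] += 1
            if do_full:
                if lcc[i, 0] > 0 and k_c1 > 0.0:
                    nl = np.random.binomial(lcc[i, 0], -np.expm1(-k_c1 * dt))
                    na_, nb_ = _split_two(nl, r_act, r_c6in)
                    lcc[i, 0] -= nl
                    lcc[i, 1] += na_
                    lcc[i, 5] += nb_
                if lcc[i, 1] > 0 and k_o2 > 0.0:
                    nl = np.random.binomial(lcc[i, 1], -np.expm1(-k_o2 * dt))
                    if nl > 0:
                        rem = nl
                        ktot = k_o2
                        nd = np.random.binomial(rem, r_deact / ktot)
                        rem -= nd
                        ktot -= r_deact
                        no3 = 0
                        if rem > 0:
                            no3 = np.random.binomial(rem, k_o2o3 / ktot)
                            rem -= no3
                        ktot -= k_o2o3
                        nc4 = 0
                        if rem > 0 and ktot > 0.0:
                            nc4 = np.random.binomial(rem, ca_slope * cd / ktot)
                        nc5 = rem - nc4
                        lcc[i, 1] -= nl
                        lcc[i, 0] += nd
                        lcc[i, 2] += no3
                        lcc[i, 3] += nc4
                        lcc[i, 4] += nc5
                if lcc[i, 2] > 0 and k_o3o2 > 0.0:
                    nl = np.random.binomial(lcc[i, 2], -np.expm1(-k_o3o2 * dt))
                    lcc[i, 2] -= nl
                    lcc[i, 1] += nl
                if lcc[i, 3] > 0 and k_c4r > 0.0:
                    nl = np.random.binomial(lcc[i, 3], -np.expm1(-k_c4r * dt))
                    lcc[i, 3] -= nl
                    lcc[i, 0] += nl
                if lcc[i, 4] > 0 and k_c5r > 0.0:
                    nl = np.random.binomial(lcc[i, 4], -np.expm1(-k_c5r * dt))
                    lcc[i, 4] -= nl
                    lcc[i, 0] += nl
                if lcc[i, 5] > 0 and k_c6x > 0.0:
                    nl = np.random.binomial(lcc[i, 5], -np.expm1(-k_c6x * dt))
                    lcc[i, 5] -= nl
                    lcc[i, 0] += nl

            # --- spark episode tracking (post-update open count)
            n_or_new = ryr[i, 1]
            if n_or_new >= spark_thr:
                if in_ep[i] == 1 and t - ep_last[i] >= spark_gap:
                    # gap elapsed: close the previous episode, start fresh
                    if n_events < max_events:
                        ev_cru[n_events] = i
                        ev_start[n_events] = ep_start[i]
                        ev_end[n_events] = ep_last[i]
                        ev_peak_n[n_events] = ep_pk_n[i]
                        ev_peak_ds[n_events] = ep_pk_ds[i]
                        n_events += 1
                    else:
                        status = 2
                    in_ep[i] = 0
                if in_ep[i] == 0:
                    in_ep[i] = 1
                    ep_start[i] = t
                    ep_pk_n[i] = n_or_new
                    ep_pk_ds[i] = cd
                else:
                    if n_or_new > ep_pk_n[i]:
                        ep_pk_n[i] = n_or_new
                    if cd > ep_pk_ds[i]:
                        ep_pk_ds[i] = cd
                ep_last[i] = t
            elif in_ep[i] == 1 and t - ep_last[i] >= spark_gap:
                if n_events < max_events:
                    ev_cru[n_events] = i
                    ev_start[n_events] = ep_start[i]
                    ev_end[n_events] = ep_last[i]
                    ev_peak_n[n_events] = ep_pk_n[i]
                    ev_peak_ds[n_events] = ep_pk_ds[i]
                    n_events += 1
                else:
                    status = 2
                in_ep[i] = 0

        # --- whole-cell continuous update
        ca_h = ca_myo ** hill_serca
        back = 1.0 - ca_nsr / P[I_NSR_CAP]
        if back < 0.0:
            back = 0.0
        j_serca_v = (2.0 * vcycle_max * ca_h / (ca_h + km_serca_h)
                     * back * ap)
        j_leak_v = k_leak * (ca_nsr - ca_myo)

        if sealed:
            dt_myo = sum_xfer * r_ds_myo - j_serca_v + j_leak_v
        else:
            i_ca_l = sum_i_single * scale * 1.0e-6 / c_tot
            dt_myo = (sum_xfer * r_ds_myo - j_serca_v + j_leak_v
                      - i_cab * alpha + 2.0 * i_ncx * alpha)
        t_myo += dt * dt_myo
        ca_nsr += dt * ((j_serca_v - j_leak_v) * r_myo_nsr
                        - sum_tr * r_jsr_nsr)
        ca_myo = _free_from_total_2(t_myo, ca_myo, trpn_btot, trpn_kd,
                                    cmdn_btot, cmdn_kd)

        if not sealed:
            dv_est = abs(i_na + i_ca_l + i_k + i_k1 + i_kp + i_ncx + i_nak
                         + i_bg + i_cab + i_stim_now) * dt
            n_sub = int(dv_est) + 1
            if n_sub > 40:
                n_sub = 40
            dts = dt / n_sub
            wds = P[I_NCX_DS_WEIGHT]
            ca_ncx = (1.0 - wds) * ca_myo + wds * (sum_ds / n_cru)
            for _ in range(n_sub):
                (v, m, h, jg, x, i_na, i_k, i_k1, i_kp, i_ncx, i_nak,
                 i_bg, i_cab) = _membrane(v, m, h, jg, x, ca_myo, ca_ncx,
                                          na_i, i_ca_l, i_stim_now, P, e_na,
                                          e_k, e_k1, dts)
            if dynamic_na:
                # 3 Na per NCX cycle (with its single net charge) and per
                # NaK cycle; fast Na current carries Na directly
                na_i -= dt * na_conv * (i_na + 3.0 * i_ncx + 3.0 * i_nak)
                e_na = rt * np.log(P[I_NA_O] / na_i)

        if not (np.isfinite(v) and np.isfinite(ca_myo)
                and np.isfinite(ca_nsr)):
            status = 1
            rec[rec_row, 0] = t * 1.0e-3
            break

        if step % rec_steps == 0:
            rec[rec_row, 0] = t * 1.0e-3
            rec[rec_row, 1] = v
            rec[rec_row, 2] = ca_myo
            rec[rec_row, 3] = ca_nsr
            rec[rec_row, 4] = sum_jsr / n_cru
            rec[rec_row, 5] = sum_ds / n_cru
            rec[rec_row, 6] = i_na
            rec[rec_row, 7] = i_ca_l
            rec[rec_row, 8] = i_k
            rec[rec_row, 9] = i_k1
            rec[rec_row, 10] = i_kp
            rec[rec_row, 11] = i_ncx
            rec[rec_row, 12] = i_nak
            rec[rec_row, 13] = i_bg + i_cab
            rec[rec_row, 14] = i_stim_now
            rec[rec_row, 15] = tot_open_ryr
            rec[rec_row, 16] = tot_open_lcc
            rec[rec_row, 17] = na_i
            if record_cru_open:
                for i in range(n_cru):
                    cru_open_rec[rec_row, i] = np.int16(ryr[i, 1])
            rec_row += 1

    for i in range(n_cru):
        if in_ep[i] == 1:
            if n_events < max_events:
                ev_cru[n_events] = i
                ev_start[n_events] = ep_start[i]
                ev_end[n_events] = ep_last[i]
                ev_peak_n[n_events] = ep_pk_n[i]
                ev_peak_ds[n_events] = ep_pk_ds[i]
                n_events += 1
            else:
                status = 2

    return (status, rec_row, n_events, v, ca_myo, ca_nsr, m, h, jg, x)


# ---------------------------------------------------------------------------
# driver

def run_protocol(params: ModelParameters | None,
                 config: SimulationConfig) -> SimulationTrace:
    """Integrate the model under the configured pacing protocol.

    ``params`` is the *baseline* (wild-type) parameter set; the scenario
    named in ``config`` is applied on top of it.  Identical (params, config)
    including the seed give bit-identical traces.
    """
    if params is None:
        params = default_parameters()
    if params.geometry.n_cru != config.n_cru:
        from dataclasses import replace
        params = replace(params, geometry=replace(params.geometry,
                                                  n_cru=config.n_cru))
    run_params = apply_scenario(params, config.scenario)

    proto = config.protocol
    stim_s = stimulus_times(proto)
    total_ms = proto.total_duration_s * 1000.0
    n_steps = int(round(total_ms / config.dt_ms))
    rec_steps = max(1, int(round(config.record_every_ms / config.dt_ms)))
    n_rec = n_steps // rec_steps + 2

    state = CellState.resting(run_params)
    state.glob.ca_nsr = config.init_ca_nsr
    state.glob.ca_myo = config.init_ca_myo
    state.crus.ca_jsr[:] = config.init_ca_nsr

    P = _pack(run_params, config)
    rec = np.zeros((n_rec, len(TRACE_COLUMNS)))
    max_ev = max(20000, int(config.n_cru * proto.total_duration_s * 60))
    ev_cru = np.zeros(max_ev, dtype=np.int64)
    ev_start = np.zeros(max_ev)
    ev_end = np.zeros(max_ev)
    ev_peak_n = np.zeros(max_ev, dtype=np.int64)
    ev_peak_ds = np.zeros(max_ev)
    if config.record_cru_open:
        cru_open = np.zeros((n_rec, config.n_cru), dtype=np.int16)
    else:
        cru_open = np.zeros((1, 1), dtype=np.int16)

    gates0 = state.glob.gates.as_array()
    out = _run_kernel(P, n_steps, rec_steps, stim_s * 1000.0,
                      int(config.seed) & 0x7FFFFFFF,
                      state.glob.v, state.glob.ca_myo, state.glob.ca_nsr,
                      gates0, state.crus.ca_jsr, state.crus.ryr,
                      state.crus.lcc,
                      rec, ev_cru, ev_start, ev_end, ev_peak_n, ev_peak_ds,
                      cru_open, config.record_cru_open, config.dynamic_na)
    status, rec_row, n_events = out[0], out[1], out[2]
    if status == 1:
        raise IntegrationError(
            f"non-finite state at t = {rec[rec_row, 0]:.4f} s "
            f"(V or Ca diverged); reduce dt or check parameters")

    df = pd.DataFrame(rec[:rec_row], columns=TRACE_COLUMNS)
    events = pd.DataFrame({
        "cru_id": ev_cru[:n_events],
        "start_s": ev_start[:n_events] * 1.0e-3,
        "end_s": ev_end[:n_events] * 1.0e-3,
        "peak_open_ryr": ev_peak_n[:n_events],
        "peak_ca_ds": ev_peak_ds[:n_events],
    })
    cfg_meta = asdict(config)
    cfg_meta["protocol"] = {"segments": list(map(list, proto.segments)),
                            "stim_amplitude": proto.stim_amplitude,
                            "stim_width_ms": proto.stim_width_ms}
    meta = {
        "scenario": config.scenario,
        "seed": int(config.seed),
        "n_cru": config.n_cru,
        "dt_ms": config.dt_ms,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_meta, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "spark_buffer_overflow": bool(status == 2),
        "columns": TRACE_COLUMNS,
    }
    return SimulationTrace(
        df=df, events=events, stim_times_s=stim_s, meta=meta,
        cru_open=cru_open[:rec_row] if config.record_cru_open else None)


# ---------------------------------------------------------------------------
# offline spark detection (same semantics as the in-kernel detector)

def detect_spark_events(open_counts: np.ndarray, times_s: np.ndarray,
                        threshold: int = 2,
                        gap_ms: float = 5.0) -> list[SparkEvent]:
    """Detect spark episodes from per-CRU open-RyR2 counts over time.

    A spark is a maximal episode during which a CRU's open count is
    ≥ ``threshold``; sub-threshold interruptions shorter than ``gap_ms`` are
    merged into the surrounding episode.

    Parameters
    ----------
    open_counts : (n_samples, n_cru) array
    times_s : (n_samples,) array, seconds
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    open_counts = np.asarray(open_counts)
    if open_counts.ndim == 1:
        open_counts = open_counts[:, None]
    if open_counts.shape[0] != len(times_s):
        raise ValueError("open_counts and times_s length mismatch")
    gap_s = gap_ms * 1.0e-3
    events: list[SparkEvent] = []
    for cru in range(open_counts.shape[1]):
        col = open_counts[:, cru]
        above = col >= threshold
        if not above.any():
            continue
        idx = np.flatnonzero(above)
        run_starts = [idx[0]]
        run_ends = []
        for a, b in zip(idx[:-1], idx[1:]):
            if b != a + 1:
                run_ends.append(a)
                run_starts.append(b)
        run_ends.append(idx[-1])
        merged = [[run_starts[0], run_ends[0]]]
        for s, e in zip(run_starts[1:], run_ends[1:]):
            if times_s[s] - times_s[merged[-1][1]] < gap_s:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        for s, e in merged:
            seg = col[s:e + 1]
            mask = seg >= threshold
            events.append(SparkEvent(
                cru_id=cru,
                start_s=float(times_s[s]),
                end_s=float(times_s[e]),
                peak_open_ryr=int(seg[mask].max()),
                peak_ca_ds=float("nan")))
    events.sort(key=lambda ev: (ev.start_s, ev.cru_id))
    return events


def calibrate_stimulus(params: ModelParameters | None = None,
                       n_cru: int = 200, width_ms: float = 1.0,
                       safety: float = 1.5, seed: int = 0) -> float:
    """Find the diastolic stimulus threshold and return ``safety`` × it.

    Bisects the pulse amplitude (µA/µF, inward negative) that elicits an
    action potential from rest with a single pulse.
    """
    lo, hi = 0.0, 200.0
    for _ in range(9):
        mid = 0.5 * (lo + hi)
        proto = PacingProtocol(segments=((1.0, 0.5),),
                               stim_amplitude=-mid, stim_width_ms=width_ms)
        cfg = SimulationConfig(n_cru=n_cru, seed=seed, protocol=proto,
                               record_every_ms=0.5)
        tr = run_protocol(params, cfg)
        if tr.df["v"].max() > 0.0:
            hi = mid
        else:
            lo = mid
    return -safety * hi
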