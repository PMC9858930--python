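"""Stochastic Markov gating of the RyR2 cluster and L-type channels.

Two chains live in every calcium release unit:

* RyR2 (49 per CRU): three states — C1 (closed) ⇄ O2 (open) → C3
  (adapted) → C1.  Opening is Hill-activated by dyadic-subspace Ca and
  multiplied by the luminal regulation function Φ = Φm·[Ca]_jsr + Φb, the
  mechanism through which junctional-SR load (and its calsequestrin-dependent
  rise time) drives release.

* L-type Ca channel (14 per CRU): six states — C1 (resting closed),
  O2 and O3 (open), C4 (Ca-inactivated from O2), C5 (voltage-inactivated
  from O2), C6 (deep closed state entered at strong depolarization, slow
  recovery).

The production engine advances both chains with a frozen-rate fixed step:
each channel leaves its state with probability 1 − exp(−k_exit·dt) and the
destination is drawn proportionally to the outgoing rates.  Channels in the
same state are exchangeable, so cluster updates draw aggregated
binomial/multinomial counts rather than touching channels one by one.
:func:`gillespie_exact` provides the statistically exact jump process used
to validate the fixed-step scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .params import ChannelParams, LCCParams, RyR2Params

__all__ = [
    "N_RYR_STATES", "N_LCC_STATES", "LCC_OPEN_STATES",
    "RyR2ClusterState", "LCCChannelState", "RateSet", "StepSizeError",
    "luminal_phi", "ryr2_rate_matrix", "lcc_rate_matrix",
    "ryr2_rates", "lcc_rates", "step_counts", "step_channels",
    "gillespie_exact", "stationary_distribution",
]

#: RyR2 state order: C1, O2, C3
N_RYR_STATES = 3
#: LCC state order: C1, O2, O3, C4, C5, C6
N_LCC_STATES = 6
LCC_OPEN_STATES = (1, 2)

MAX_EXIT_PROB = 0.1  # cap on per-channel exit rate × dt


class StepSizeError(ValueError):
    """dt too large for the current rate magnitudes; substep the gating update."""


# ---------------------------------------------------------------------------
# rate kernels (njit scalars, shared by the Python API and the engine)

@njit(cache=True)
def _phi(phi_m, phi_b, ca_sr):
    return phi_m * ca_sr + phi_b


@njit(cache=True)
def _ryr2_open_rate(ca_ds, ca_jsr, phi_m, phi_b, k_open_max, hill, k_ca):
    if ca_ds <= 0.0:
        return 0.0
    x = ca_ds ** hill
    return _phi(phi_m, phi_b, ca_jsr) * k_open_max * x / (x + k_ca ** hill)


@njit(cache=True)
def _boltz(v, vhalf, slope):
    # rising sigmoid in v
    return 1.0 / (1.0 + np.exp(-(v - vhalf) / slope))


@njit(cache=True)
def _lcc_q(v, ca_ds,
           act_max, act_vhalf, act_slope,
           deact_max, deact_vhalf, deact_slope,
           k_o2o3, k_o3o2, ca_inact_slope, k_c4_recover,
           vinact_max, vinact_vhalf, vinact_slope, k_c5_recover,
           c6_entry_max, c6_vhalf, c6_slope, k_c6_exit):
    """6×6 per-channel rate matrix (1/ms), states C1,O2,O3,C4,C5,C6."""
    q = np.zeros((6, 6))
    q[0, 1] = act_max * _boltz(v, act_vhalf, act_slope)
    q[1, 0] = deact_max * (1.0 - _boltz(v, deact_vhalf, deact_slope))
    q[1, 2] = k_o2o3
    q[2, 1] = k_o3o2
    q[1, 3] = ca_inact_slope * max(ca_ds, 0.0)
    q[3, 0] = k_c4_recover
    q[1, 4] = vinact_max * _boltz(v, vinact_vhalf, vinact_slope)
    q[4, 0] = k_c5_recover
    q[0, 5] = c6_entry_max * _boltz(v, c6_vhalf, c6_slope)
    q[5, 0] = k_c6_exit
    return q


@njit(cache=True)
def _ryr2_q(ca_ds, ca_jsr, phi_m, phi_b,
            k_open_max, hill, k_ca, k_close, k_adapt, k_recover):
    """3×3 per-channel rate matrix (1/ms), states C1,O2,C3."""
    q = np.zeros((3, 3))
    q[0, 1] = _ryr2_open_rate(ca_ds, ca_jsr, phi_m, phi_b,
                              k_open_max, hill, k_ca)
    q[1, 0] = k_close
    q[1, 2] = k_adapt
    q[2, 0] = k_recover
    return q


# ---------------------------------------------------------------------------
# Python-facing types

@dataclass
class RyR2ClusterState:
    """Aggregated occupancy of one RyR2 cluster (counts sum to cluster size)."""

    n_c1: int
    n_o2: int
    n_c3: int

    @classmethod
    def resting(cls, n: int = 49) -> "RyR2ClusterState":
        return cls(n_c1=n, n_o2=0, n_c3=0)

    @property
    def n_total(self) -> int:
        return self.n_c1 + self.n_o2 + self.n_c3

    def counts(self) -> np.ndarray:
        return np.array([self.n_c1, self.n_o2, self.n_c3], dtype=np.int64)


@dataclass
class LCCChannelState:
    """Per-channel states of the L-type channels of one CRU (ints 0..5)."""

    states: np.ndarray

    @classmethod
    def resting(cls, n: int = 14) -> "LCCChannelState":
        return cls(states=np.zeros(n, dtype=np.int64))

    @property
    def n_open(self) -> int:
        return int(np.isin(self.states, LCC_OPEN_STATES).sum())

    def counts(self) -> np.ndarray:
        return np.bincount(self.states, minlength=N_LCC_STATES).astype(np.int64)


@dataclass
class RateSet:
    """Per-channel transition-rate matrix with the context it was built for."""

    q: np.ndarray                      # (n_states, n_states), 1/ms
    context: dict = field(default_factory=dict)

    def rate(self, i: int, j: int) -> float:
        return float(self.q[i, j])

    @property
    def max_exit_rate(self) -> float:
        return float(self.q.sum(axis=1).max())


# ---------------------------------------------------------------------------
# rate-set constructors

def luminal_phi(phi_m: float, phi_b: float, ca_sr: float) -> float:
    """Luminal regulation multiplier Φ = Φm·[Ca]_sr + Φb on RyR2 opening."""
    if phi_m < 0 or phi_b < 0 or ca_sr < 0:
        raise ValueError("luminal_phi arguments must be non-negative")
    return _phi(phi_m, phi_b, ca_sr)


def ryr2_rate_matrix(ca_ds: float, ca_jsr: float,
                     params: ChannelParams) -> np.ndarray:
    r = params.ryr2
    return _ryr2_q(ca_ds, ca_jsr, params.phi_m, params.phi_b,
                   r.k_open_max, r.hill_ca_ds, r.k_ca,
                   r.k_close, r.k_adapt, r.k_recover)


def ryr2_rates(state: RyR2ClusterState, ca_ds: float, ca_jsr: float,
               params: ChannelParams) -> RateSet:
    """Per-channel RyR2 rates at the given subspace/junctional-SR Ca."""
    if ca_ds < 0 or ca_jsr < 0:
        raise ValueError("concentrations must be non-negative")
    q = ryr2_rate_matrix(ca_ds, ca_jsr, params)
    return RateSet(q=q, context={"ca_ds": ca_ds, "ca_jsr": ca_jsr,
                                 "occupancy": state.counts()})


def lcc_rate_matrix(v: float, ca_ds: float, params: ChannelParams) -> np.ndarray:
    c = params.lcc
    return _lcc_q(v, ca_ds,
                  c.act_max, c.act_vhalf, c.act_slope,
                  c.deact_max, c.deact_vhalf, c.deact_slope,
                  c.k_o2o3, c.k_o3o2, c.ca_inact_slope, c.k_c4_recover,
                  c.vinact_max, c.vinact_vhalf, c.vinact_slope,
                  c.k_c5_recover,
                  c.c6_entry_max, c.c6_vhalf, c.c6_slope, c.k_c6_exit)


def lcc_rates(state: LCCChannelState, v: float, ca_ds: float,
              params: ChannelParams) -> RateSet:
    """Per-channel L-type rates at the given voltage and subspace Ca."""
    q = lcc_rate_matrix(v, ca_ds, params)
    return RateSet(q=q, context={"v": v, "ca_ds": ca_ds,
                                 "occupancy": state.counts()})


# ---------------------------------------------------------------------------
# fixed-step stochastic update

def _check_dt(q: np.ndarray, dt: float) -> None:
    if dt <= 0:
        raise ValueError("dt must be > 0")
    kmax = q.sum(axis=1).max()
    if kmax * dt > MAX_EXIT_PROB:
        raise StepSizeError(
            f"max exit rate {kmax:.3g}/ms × dt {dt:.3g} ms = {kmax * dt:.3g} "
            f"> {MAX_EXIT_PROB}; substep the gating update (use a smaller dt "
            f"or split this step into ceil(k·dt/{MAX_EXIT_PROB}) substeps)")


def step_counts(counts: np.ndarray, q: np.ndarray, dt: float,
                rng: np.random.Generator) -> np.ndarray:
    """One frozen-rate step of an aggregated (exchangeable) channel cluster.

    Each channel in state i leaves with probability 1 − exp(−k_i·dt),
    k_i = Σ_j q[i, j]; destinations are multinomial with probabilities
    q[i, j] / k_i.  Total count is conserved exactly.
    """
    _check_dt(q, dt)
    counts = np.asarray(counts, dtype=np.int64)
    new = counts.copy()
    for i in range(len(counts)):
        n = counts[i]
        k = q[i].sum()
        if n == 0 or k == 0.0:
            continue
        n_leave = rng.binomial(n, -np.expm1(-k * dt))
        if n_leave == 0:
            continue
        dest = rng.multinomial(n_leave, q[i] / k)
        new[i] -= n_leave
        new += dest
    return new


def step_channels(state, rates: RateSet, dt: float,
                  rng: np.random.Generator):
    """Advance a RyR2 cluster or an LCC channel vector by one gating step.

    Identical (state, rates, dt, rng state) give identical output.  Raises
    :class:`StepSizeError` when the per-channel exit probability cap would be
    violated.
    """
    if isinstance(state, RyR2ClusterState):
        c = step_counts(state.counts(), rates.q, dt, rng)
        return RyR2ClusterState(n_c1=int(c[0]), n_o2=int(c[1]), n_c3=int(c[2]))
    if isinstance(state, LCCChannelState):
        _check_dt(rates.q, dt)
        q = rates.q
        k_exit = q.sum(axis=1)
        out = state.states.copy()
        for idx, s in enumerate(state.states):
            k = k_exit[s]
            if k == 0.0:
                continue
            if rng.random() < -np.expm1(-k * dt):
                u = rng.random() * k
                acc = 0.0
                for j in range(q.shape[1]):
                    acc += q[s, j]
                    if u < acc:
                        out[idx] = j
                        break
        return LCCChannelState(states=out)
    raise TypeError(f"unsupported state type {type(state).__name__}")


# ---------------------------------------------------------------------------
# exact oracle

def gillespie_exact(initial_counts: np.ndarray, q: np.ndarray, t_end: float,
                    rng: np.random.Generator):
    """Statistically exact (SSA) trajectory of an exchangeable channel cluster.

    Rates are frozen over the interval (piecewise-constant oracle).  Returns
    ``(times, trajectory)`` where ``times[0] = 0`` and ``trajectory[k]`` is
    the count vector after the k-th jump; the final entry is the state at
    ``t_end``.
    """
    counts = np.asarray(initial_counts, dtype=np.int64).copy()
    q = np.asarray(q, dtype=np.float64)
    times = [0.0]
    traj = [counts.copy()]
    t = 0.0
    while True:
        props = counts[:, None] * q          # propensity of each i→j
        a0 = props.sum()
        if a0 == 0.0:
            break
        t += rng.exponential(1.0 / a0)
        if t >= t_end:
            break
        u = rng.random() * a0
        acc = 0.0
        done = False
        for i in range(q.shape[0]):
            for j in range(q.shape[1]):
                acc += props[i, j]
                if u < acc:
                    counts[i] -= 1
                    counts[j] += 1
                    done = True
                    break
            if done:
                break
        times.append(t)
        traj.append(counts.copy())
    times.append(t_end)
    traj.append(counts.copy())
    return np.array(times), np.array(traj)


def stationary_distribution(q: np.ndarray) -> np.ndarray:
    """Stationary distribution π of a single channel with rate matrix q.

    Solves π·G = 0, Σπ = 1 where G is the generator (q with diagonal
    −row-sums).
    """
    q = np.asarray(q, dtype=np.float64)
    g = q - np.diag(q.sum(axis=1))
    n = g.shape[0]
    a = np.vstack([g.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    return pi
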