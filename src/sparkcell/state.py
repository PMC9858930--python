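"""In-memory state containers for the whole-cell model."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ModelParameters

__all__ = ["GateVariables", "GlobalState", "CRUEnsembleState", "CellState"]


@dataclass
class GateVariables:
    """Deterministic Hodgkin–Huxley gates (each in [0, 1]).

    m, h, j gate the fast Na⁺ current; x is the time-dependent K⁺ activation.
    """

    m: float = 0.0017
    h: float = 0.983
    j: float = 0.989
    x: float = 0.0057

    def as_array(self) -> np.ndarray:
        return np.array([self.m, self.h, self.j, self.x])


@dataclass
class GlobalState:
    """Membrane potential, bulk concentrations and gate variables."""

    v: float = -85.0          # mV
    ca_myo: float = 0.1       # µM
    ca_nsr: float = 1000.0    # µM
    na_i: float = 10.0        # mM
    k_i: float = 145.0        # mM
    gates: GateVariables = field(default_factory=GateVariables)


@dataclass
class CRUEnsembleState:
    """Per-CRU state arrays: junctional-SR Ca, subspace Ca and channel occupancy."""

    ca_jsr: np.ndarray        # (n_cru,), µM
    ca_ds: np.ndarray         # (n_cru,), µM
    ryr: np.ndarray           # (n_cru, 3) int64 counts: C1, O2, C3
    lcc: np.ndarray           # (n_cru, 6) int64 counts: C1, O2, O3, C4, C5, C6

    @classmethod
    def resting(cls, n_cru: int, n_ryr: int = 49, n_lcc: int = 14,
                ca_jsr: float = 1000.0, ca_ds: float = 0.1) -> "CRUEnsembleState":
        ryr = np.zeros((n_cru, 3), dtype=np.int64)
        ryr[:, 0] = n_ryr
        lcc = np.zeros((n_cru, 6), dtype=np.int64)
        lcc[:, 0] = n_lcc
        return cls(ca_jsr=np.full(n_cru, float(ca_jsr)),
                   ca_ds=np.full(n_cru, float(ca_ds)),
                   ryr=ryr, lcc=lcc)

    @property
    def n_cru(self) -> int:
        return self.ca_jsr.shape[0]

    @property
    def open_ryr(self) -> np.ndarray:
        return self.ryr[:, 1]

    @property
    def open_lcc(self) -> np.ndarray:
        return self.lcc[:, 1] + self.lcc[:, 2]


@dataclass
class CellState:
    """Complete model state: global variables plus the CRU ensemble."""

    glob: GlobalState
    crus: CRUEnsembleState

    @classmethod
    def resting(cls, params: ModelParameters) -> "CellState":
        g = params.geometry
        return cls(glob=GlobalState(),
                   crus=CRUEnsembleState.resting(
                       g.n_cru, g.n_ryr_per_cru, g.n_lcc_per_cru))
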