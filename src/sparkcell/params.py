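"""Model parameters, compartment geometry, buffers and the scenario system.

The cell is a guinea-pig ventricular myocyte represented as bulk myoplasm,
a network SR (NSR), and ``n_cru`` calcium release units (CRUs).  Each CRU is
a dyadic subspace coupling a cluster of 49 RyR2 channels (fed by its own
junctional-SR compartment) to 14 sarcolemmal L-type channels.

All concentrations are in µM except Na⁺/K⁺ (mM); volumes in litres; time in
ms; voltage in mV; membrane currents in µA/µF.

Scenarios map the two biological perturbations studied here onto static
parameter multipliers:

* CASQ2 loss (CPVT2 mutant): calsequestrin buffer reduced to 5 % of control,
  SR volumes +50 %, RyR2 luminal-regulation slope Φm +90 %.
* β-adrenergic stimulation: L-type single-channel permeability +40 %,
  SERCA pump concentration +50 %.

``mutant_bar`` composes both sets; ``wt_control`` is the identity.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

SCHEMA_VERSION = 1

__all__ = [
    "Buffer",
    "BufferSet",
    "ChannelParams",
    "CompartmentGeometry",
    "ConfigurationError",
    "ModelParameters",
    "PumpExchangerParams",
    "ScenarioModifiers",
    "SCENARIOS",
    "apply_scenario",
    "default_parameters",
    "rapid_buffer_factor",
    "parameters_from_json",
    "parameters_to_json",
]


class ConfigurationError(ValueError):
    """Invalid parameter value or unknown scenario."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(msg)


@dataclass(frozen=True)
class CompartmentGeometry:
    """Compartment volumes (L) and CRU composition."""

    v_myo: float = 25.84e-12
    v_nsr: float = 2.1e-12
    v_jsr_unit: float = 4.85e-18   # junctional SR per CRU
    v_ds_unit: float = 0.5e-18    # dyadic subspace per CRU
    n_cru: int = 20000
    n_ryr_per_cru: int = 49
    n_lcc_per_cru: int = 14

    def __post_init__(self) -> None:
        for name in ("v_myo", "v_nsr", "v_jsr_unit", "v_ds_unit"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")
        _require(self.n_cru >= 1, "n_cru must be >= 1")
        _require(self.n_ryr_per_cru >= 1, "n_ryr_per_cru must be >= 1")
        _require(self.n_lcc_per_cru >= 1, "n_lcc_per_cru must be >= 1")

    @property
    def v_jsr_total(self) -> float:
        return self.n_cru * self.v_jsr_unit

    @property
    def v_ds_total(self) -> float:
        return self.n_cru * self.v_ds_unit


@dataclass(frozen=True)
class Buffer:
    """One rapid-equilibrium Ca²⁺ buffer: total sites and dissociation constant (µM)."""

    btot: float
    kd: float

    def __post_init__(self) -> None:
        _require(self.btot >= 0, "btot must be >= 0")
        _require(self.kd > 0, "kd must be > 0")


@dataclass(frozen=True)
class BufferSet:
    """Rapid buffers per compartment.

    ``casq`` is calsequestrin in the junctional SR (JSR-referred
    concentration); ``troponin`` and ``calmodulin`` buffer the bulk myoplasm;
    ``subspace`` is the anionic sarcolemmal buffer of the dyad (used only by
    the dynamic-subspace integration mode).
    """

    casq: Buffer = Buffer(btot=3000.0, kd=900.0)
    troponin: Buffer = Buffer(btot=108.0, kd=0.5)
    calmodulin: Buffer = Buffer(btot=50.0, kd=2.38)
    subspace: Buffer = Buffer(btot=1124.0, kd=13.0)

    @property
    def myo(self) -> tuple[Buffer, Buffer]:
        return (self.troponin, self.calmodulin)


@dataclass(frozen=True)
class RyR2Params:
    """RyR2 cluster gating constants (three-state chain C1 ⇄ O2 → C3 → C1).

    Opening C1→O2 is Hill-activated by subspace Ca and multiplied by the
    luminal regulation function Φ = phi_m·[Ca]_jsr + phi_b.  O2→C3 is
    adaptation, C3→C1 slow recovery.
    """

    k_open_max: float = 0.3      # 1/ms, saturating opening rate (before Φ)
    hill_ca_ds: float = 3.0      # Hill coefficient on subspace Ca
    k_ca: float = 6.3           # µM, half-activation subspace Ca
    k_close: float = 0.72        # 1/ms, O2→C1
    k_adapt: float = 0.16        # 1/ms, O2→C3
    k_recover: float = 0.05    # 1/ms, C3→C1
    v_ryr: float = 1.6        # 1/ms per open channel, JSR→subspace permeation

    def __post_init__(self) -> None:
        for f_ in dataclasses.fields(self):
            _require(getattr(self, f_.name) >= 0, f"{f_.name} must be >= 0")


@dataclass(frozen=True)
class LCCParams:
    """Six-state L-type channel constants.

    States: C1 (resting closed), O2/O3 (open), C4 (Ca-inactivated),
    C5 (voltage-inactivated), C6 (deep closed, entered at strong
    depolarization, slow recovery).  Activation C1→O2 is a Boltzmann
    function of voltage; Ca-dependent inactivation O2→C4 is linear in
    subspace Ca.
    """

    act_max: float = 1.1         # 1/ms, C1→O2 saturating rate
    act_vhalf: float = -12.0     # mV
    act_slope: float = 5.0       # mV
    deact_max: float = 2.0       # 1/ms, O2→C1 at hyperpolarized V
    deact_vhalf: float = -18.0   # mV
    deact_slope: float = 6.0     # mV
    k_o2o3: float = 0.25         # 1/ms
    k_o3o2: float = 1.0          # 1/ms
    ca_inact_slope: float = 1.6e-4  # 1/(µM·ms), O2→C4 rate per µM subspace Ca
    k_c4_recover: float = 2.5e-3    # 1/ms, C4→C1
    vinact_max: float = 0.030    # 1/ms, O2→C5
    vinact_vhalf: float = -16.0  # mV
    vinact_slope: float = 7.0    # mV
    k_c5_recover: float = 4.0e-3  # 1/ms, C5→C1
    c6_entry_max: float = 0.010  # 1/ms, C1→C6 at strong depolarization
    c6_vhalf: float = -20.0      # mV
    c6_slope: float = 6.0        # mV
    k_c6_exit: float = 2.0e-3    # 1/ms, C6→C1
    rec_vhalf: float = -55.0     # mV, recovery-from-inactivation gate midpoint
    rec_slope: float = 8.0       # mV (recovery allowed below ~rec_vhalf)

    def __post_init__(self) -> None:
        for f_ in dataclasses.fields(self):
            if f_.name.endswith(("vhalf",)):
                continue
            _require(getattr(self, f_.name) >= 0 or "slope" in f_.name,
                     f"{f_.name} must be >= 0")


@dataclass(frozen=True)
class ChannelParams:
    """Stochastic-channel parameters: L-type permeability, luminal regulation, rate constants."""

    p_dhpr: float = 1.05e-12      # cm³/s, single L-type channel GHK permeability
    phi_m: float = 1.5e-3        # 1/µM, luminal regulation slope
    phi_b: float = 0.05          # dimensionless offset
    ryr2: RyR2Params = field(default_factory=RyR2Params)
    lcc: LCCParams = field(default_factory=LCCParams)

    def __post_init__(self) -> None:
        _require(self.p_dhpr >= 0, "p_dhpr must be >= 0")
        _require(self.phi_m >= 0, "phi_m must be >= 0")
        _require(self.phi_b >= 0, "phi_b must be >= 0")


@dataclass(frozen=True)
class PumpExchangerParams:
    """SERCA, NCX, Na/K pump and background conductances.

    The whole-cell SERCA flux is J = 2·v_cycle·Ap with Ap the SERCA
    concentration per litre cytosol and v_cycle a Hill function of bulk Ca;
    the factor 2 reflects two Ca²⁺ translocated per pump cycle.
    """

    ap: float = 120.0            # µM SERCA per L cytosol
    vcycle_max: float = 3.5e-3   # 1/ms per molecule
    km_fwd: float = 0.22         # µM
    hill: float = 1.8
    nsr_cap: float = 2800.0      # µM, NSR back-pressure ceiling (v_cycle → 0)
    k_ncx: float = 3700.0        # µA/µF scale
    km_na: float = 87.5          # mM
    km_ca: float = 1.38          # mM (extracellular-site Michaelis constant)
    eta: float = 0.35
    ksat: float = 0.1
    ncx_ds_weight: float = 0.0  # fraction of NCX Ca sensing from the subspace
    p_nak: float = 1.0           # µA/µF
    km_nai: float = 10.0         # mM
    km_ko: float = 1.5           # mM
    g_k: float = 0.22            # mS/µF, time-dependent K conductance scale
    x_rate_scale: float = 1.22    # multiplier on the K-activation gate kinetics
    g_k1: float = 0.75         # mS/µF (scaled by sqrt(ko/5.4))
    g_kp: float = 0.0183         # mS/µF
    g_na: float = 13.0           # mS/µF
    g_bg: float = 0.03921        # mS/µF, LR background (reversal −59.87 mV)
    g_cab: float = 0.92e-4       # mS/µF, background Ca leak conductance
    tau_tr: float = 25.0          # ms, NSR→JSR refill time constant
    tau_xfer: float = 0.015      # ms, subspace→myoplasm relaxation
    k_leak: float = 0.66e-4       # 1/ms, passive NSR→myo leak

    def __post_init__(self) -> None:
        _require(self.ap >= 0, "ap must be >= 0")
        _require(self.vcycle_max >= 0, "vcycle_max must be >= 0")
        for name in ("km_fwd", "km_na", "km_ca", "km_nai", "km_ko",
                     "tau_tr", "tau_xfer"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")


#: built-in scenario names, in the two-way factorial order of the study design
SCENARIO_NAMES = ("wt_control", "mutant_control", "wt_bar", "mutant_bar")


@dataclass(frozen=True)
class ScenarioModifiers:
    """Multiplicative parameter changes defining one study condition."""

    name: str
    phi_m_scale: float = 1.0
    serca_ap_scale: float = 1.0
    jsr_volume_scale: float = 1.0
    nsr_volume_scale: float = 1.0
    casq_btot_scale: float = 1.0
    p_dhpr_scale: float = 1.0

    def __post_init__(self) -> None:
        for f_ in dataclasses.fields(self):
            if f_.name == "name":
                continue
            _require(getattr(self, f_.name) > 0, f"{f_.name} must be > 0")


_MUTANT = dict(phi_m_scale=1.9, jsr_volume_scale=1.5, nsr_volume_scale=1.5,
               casq_btot_scale=0.05)
_BAR = dict(p_dhpr_scale=1.4, serca_ap_scale=1.5)

SCENARIOS: Mapping[str, ScenarioModifiers] = {
    "wt_control": ScenarioModifiers(name="wt_control"),
    "mutant_control": ScenarioModifiers(name="mutant_control", **_MUTANT),
    "wt_bar": ScenarioModifiers(name="wt_bar", **_BAR),
    "mutant_bar": ScenarioModifiers(name="mutant_bar", **_MUTANT, **_BAR),
}


@dataclass(frozen=True)
class ModelParameters:
    """Complete parameter set of the cell model."""

    geometry: CompartmentGeometry = field(default_factory=CompartmentGeometry)
    buffers: BufferSet = field(default_factory=BufferSet)
    channels: ChannelParams = field(default_factory=ChannelParams)
    pumps: PumpExchangerParams = field(default_factory=PumpExchangerParams)
    ca_o: float = 1.8            # mM
    na_o: float = 140.0          # mM
    k_o: float = 5.4             # mM
    na_i: float = 10.0           # mM (clamped by default)
    k_i: float = 145.0           # mM (clamped by default)
    cm: float = 1.0              # µF/cm²
    area: float = 1.534e-4       # cm², capacitive membrane area
    temperature: float = 310.0   # K
    faraday: float = 96485.0     # C/mol
    gas_const: float = 8314.0    # mJ/(mol·K)

    def __post_init__(self) -> None:
        for name in ("ca_o", "na_o", "k_o", "na_i", "k_i", "cm", "area",
                     "temperature"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")

    @property
    def c_tot(self) -> float:
        """Total membrane capacitance, µF."""
        return self.cm * self.area

    @property
    def rt_over_f(self) -> float:
        """Thermal voltage RT/F in mV."""
        return self.gas_const * self.temperature / self.faraday


def default_parameters(n_cru: int | None = None) -> ModelParameters:
    """Wild-type baseline (calibrated) parameter set.

    Parameters
    ----------
    n_cru : int, optional
        Number of calcium release units.  The physiological full-scale count
        is 20,000; pass a smaller count for desk-scale runs.  Per-CRU volumes
        are fixed, and whole-cell release fluxes are scaled by
        ``20000 / n_cru`` so bulk concentrations are n_cru-invariant in
        expectation (stochastic fluctuations grow as the count shrinks).
    """
    p = ModelParameters()
    if n_cru is not None:
        p = replace(p, geometry=replace(p.geometry, n_cru=int(n_cru)))
    return p


def apply_scenario(params: ModelParameters,
                   scenario: ScenarioModifiers | str) -> ModelParameters:
    """Return a new parameter set with the scenario's multipliers applied.

    The input is untouched.  ``scenario`` may be a name from
    :data:`SCENARIOS` or an explicit :class:`ScenarioModifiers`.
    """
    if isinstance(scenario, str):
        try:
            scenario = SCENARIOS[scenario]
        except KeyError:
            raise ConfigurationError(
                f"unknown scenario {scenario!r}; "
                f"built-ins: {', '.join(SCENARIOS)}") from None
    geo = replace(params.geometry,
                  v_jsr_unit=params.geometry.v_jsr_unit * scenario.jsr_volume_scale,
                  v_nsr=params.geometry.v_nsr * scenario.nsr_volume_scale)
    bufs = replace(params.buffers,
                   casq=Buffer(btot=params.buffers.casq.btot * scenario.casq_btot_scale,
                               kd=params.buffers.casq.kd))
    chans = replace(params.channels,
                    phi_m=params.channels.phi_m * scenario.phi_m_scale,
                    p_dhpr=params.channels.p_dhpr * scenario.p_dhpr_scale)
    pumps = replace(params.pumps, ap=params.pumps.ap * scenario.serca_ap_scale)
    return replace(params, geometry=geo, buffers=bufs, channels=chans,
                   pumps=pumps)


def rapid_buffer_factor(ca: float, buffers: Iterable[Buffer]) -> float:
    """Instantaneous-buffering factor β = 1 / (1 + Σ btot·kd/(kd+ca)²).

    Under the rapid-equilibrium approximation, the free-Ca derivative of a
    buffered compartment is the unbuffered derivative multiplied by β(ca).
    β ∈ (0, 1]; β → 1 as total buffer vanishes.
    """
    if ca < 0:
        raise ValueError(f"ca must be >= 0, got {ca}")
    s = 0.0
    for b in buffers:
        s += b.btot * b.kd / (b.kd + ca) ** 2
    return 1.0 / (1.0 + s)


# ---------------------------------------------------------------------------
# JSON round-trip

def _asdict(p: ModelParameters) -> dict:
    return {"schema_version": SCHEMA_VERSION, **dataclasses.asdict(p)}


def parameters_to_json(p: ModelParameters, path=None, **json_kw) -> str:
    """Serialize a parameter set to JSON (optionally writing ``path``)."""
    json_kw.setdefault("indent", 2)
    text = json.dumps(_asdict(p), **json_kw)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def _build(cls, d: dict):
    kw = {}
    for f_ in dataclasses.fields(cls):
        if f_.name not in d:
            continue
        v = d[f_.name]
        if dataclasses.is_dataclass(f_.type) if isinstance(f_.type, type) else False:
            v = _build(f_.type, v)
        kw[f_.name] = v
    return cls(**kw)


def parameters_from_json(source: str) -> ModelParameters:
    """Rebuild a parameter set from a JSON string or file path."""
    if "{" not in source:
        with open(source) as fh:
            source = fh.read()
    d = json.loads(source)
    version = d.pop("schema_version", None)
    if version is not None and version != SCHEMA_VERSION:
        raise ConfigurationError(f"unsupported schema_version {version}")
    geo = CompartmentGeometry(**d["geometry"])
    bufs = BufferSet(**{k: Buffer(**v) for k, v in d["buffers"].items()})
    chans = ChannelParams(
        p_dhpr=d["channels"]["p_dhpr"],
        phi_m=d["channels"]["phi_m"],
        phi_b=d["channels"]["phi_b"],
        ryr2=RyR2Params(**d["channels"]["ryr2"]),
        lcc=LCCParams(**d["channels"]["lcc"]),
    )
    pumps = PumpExchangerParams(**d["pumps"])
    scalars = {k: v for k, v in d.items()
               if k not in ("geometry", "buffers", "channels", "pumps")}
    return ModelParameters(geometry=geo, buffers=bufs, channels=chans,
                           pumps=pumps, **scalars)
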