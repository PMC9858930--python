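# Model and methods

`sparkcell` is a stochastic, local-control model of excitation–contraction
coupling in a guinea-pig ventricular myocyte, built to study how loss of
calsequestrin-2 (CASQ2, the CPVT2 phenotype) and β-adrenergic stimulation
turn normal Ca²⁺ cycling into alternans, early afterdepolarizations (EADs)
and skipped beats under different pacing regimes.

## Architecture

The cell is four kinds of compartment:

* **Bulk myoplasm** (25.84 pL) with troponin and calmodulin as rapid
  buffers.
* **Network SR** (NSR, 2.1 pL), unbuffered, filled by SERCA and drained
  into the junctional stores.
* **n_cru calcium release units (CRUs)**. Each CRU couples a cluster of 49
  RyR2 channels and its own junctional-SR (JSR) store to 14 sarcolemmal
  L-type channels across a dyadic subspace. The physiological count is
  20,000; the default desk scale is 2,000, with all whole-cell release
  fluxes rescaled by `20000/n_cru` so bulk concentrations are
  n_cru-invariant in expectation (stochastic fluctuations grow as the count
  shrinks).
* **Dyadic subspaces**, treated as quasi-steady-state (below).

Membrane electrophysiology is a Luo–Rudy-style current set: fast Na⁺
(m³hj), time-dependent K⁺ (x·Xi with the classic rectification factor),
inward rectifier I_K1, plateau I_Kp, Na⁺/K⁺ pump, NCX, a linear
background current and a small background Ca²⁺ conductance. The L-type
Ca²⁺ current is not a conductance: it is the sum of open-channel GHK
unitary currents over all CRUs, so its noise, Ca-dependent inactivation and
restitution emerge from the Markov channels.

## Channel models

**RyR2 (3-state / CRU cluster of 49).** C1 (closed) ⇄ O2 (open) → C3
(adapted) → C1. The opening rate is

    k(C1→O2) = Φ([Ca]_jsr) · k_open_max · [Ca]_ds^h / ([Ca]_ds^h + K_Ca^h),
    Φ = Φm·[Ca]_jsr + Φb,

so release is triggered by subspace Ca and licensed by luminal (JSR) Ca.
Defaults: h = 3, K_Ca = 6.5 µM, k_open_max = 0.3 /ms, closing 0.72 /ms,
adaptation 0.16 /ms, recovery 0.05 /ms, Φm = 1.5·10⁻³ /µM, Φb = 0.05.
The steep Hill exponent keeps clusters silent at the diastolic operating
point (~0.13 µM) while elevated bulk Ca during the transient and spark
feed-through (one open channel raises its own subspace by tens of µM)
ignite regenerative cluster openings. Adaptation terminates the episode;
recovery plus JSR refill set the re-licensing time, which is the quantity
CASQ2 controls: a buffered JSR refills its *free* Ca slowly, a CASQ2-free
JSR snaps back within τ_tr.

**L-type channel (6-state, per channel).** C1 (resting closed) ⇄ O2 ⇄ O3
(open pair), O2 → C4 (Ca-dependent inactivation, rate linear in subspace
Ca), O2 → C5 (voltage-dependent inactivation), C1 → C6 (deep closed state
entered at strong depolarization). Activation and deactivation are
Boltzmann functions of voltage chosen so that the activation window is
narrow: channels conduct on the high plateau (+25…0 mV) and deactivate
quickly below about −10 mV. Recovery from C4/C5/C6 carries a
repolarization gate (a falling sigmoid centred at −55 mV): channels only
become available again near the resting potential. Both choices are
load-bearing: a wide window or depolarized recovery produces either a
plateau oscillator (spurious wild-type EADs) or a standing Ca-entry state
that never repolarizes.

## Pumps, exchanger, balances

* **SERCA**: J = 2·v_cycle·Ap, with Ap the pump concentration per litre
  cytosol (the whole-cell flux is exactly linear in Ap, which is what the
  β-adrenergic multiplier scales). v_cycle is a Hill function of bulk Ca
  (Km 0.22 µM, h 1.8) times a linear NSR back-pressure factor
  (1 − [Ca]_nsr / 2800 µM): pumping against a loaded SR slows the cycle and
  bounds the SR load at high pacing rates.
* **NCX**: the standard saturating electrogenic 3Na:1Ca expression. An
  optional submembrane-sensing weight can mix mean subspace Ca into the
  Ca term (off by default — it strengthens systolic extrusion enough to
  erase the post-rapid-pacing overload this study needs).
* **Na⁺ dynamics**: intracellular Na integrates I_Na, 3·I_NCX and
  3·I_NaK. This is what gives the model its slow memory: at 5–6 Hz Na_i
  climbs by ~2–3 mM, throttling NCX extrusion, and decays over tens of
  seconds after returning to slow pacing — the substrate for the
  second-slow-phase Ca overload. K⁺ is clamped; Na can be clamped with
  `SimulationConfig(dynamic_na=False)`.
* Compartment Ca balances are volume-ratio-consistent; with a sealed
  membrane the engine conserves total Ca to round-off (verified to <0.1 %
  over 10 s in the acceptance suite).

## Numerics

* Operator-split explicit Euler at dt = 0.05 ms (configurable). Buffered
  compartments (myoplasm, JSR) integrate *total* Ca and invert the rapid
  buffering binding curve each step (Newton for two buffers, closed-form
  quadratic for one), which is what makes conservation exact rather than
  O(dt) approximate.
* The dyadic subspace is quasi-steady-state: RyR2 release and the GHK
  L-type flux are both linear in subspace Ca, so the balance with diffusion
  to the bulk (τ_xfer = 15 µs) is solved algebraically per CRU per step.
  The QSS identity (ca_ds − ca_myo)/τ_xfer = J_rel + J_lcc makes the
  subspace a storage-free conduit. A dynamic-subspace option (with the
  anionic subspace buffer) exists in the reference derivative assembly.
* Gating uses the frozen-rate scheme: each channel leaves its state with
  probability 1 − exp(−k_exit·dt), destinations proportional to outgoing
  rates, drawn as aggregated binomial/multinomial counts (channels within a
  state are exchangeable; this applies to both the RyR2 cluster and the 14
  L-type channels). Quiescent CRUs take a single-uniform shortcut: when the
  total propensity λ·dt < 0.02 the step draws "no event" with its exact
  probability exp(−λ·dt) and otherwise performs one transition — exact for
  the no-event branch, O(λ²) biased on the rare multi-event branch.
  Validity of the fixed step against the exact Gillespie SSA is part of the
  acceptance suite (χ² on occupancies, KS on first-opening times).
* Membrane voltage and HH gates are sub-stepped adaptively inside each dt
  (Rush–Larsen exponential gate updates, ≤1 mV per substep target, 40-substep
  cap) so the Na⁺ upstroke stays resolved without running the CRU ensemble
  at sub-µs steps.
* One master seed drives a single RNG stream; identical configuration and
  seed give bit-identical traces. Halving dt moves beat-averaged
  Ca-transient maxima by well under the stochastic beat-to-beat spread
  (tested at desk scale).

## Scenario system

Scenarios are static parameter multipliers applied on top of the calibrated
wild-type set:

| scenario | multipliers |
|---|---|
| `wt_control` | identity |
| `mutant_control` | calsequestrin B_tot × 0.05, JSR and NSR volume × 1.5, Φm × 1.9 |
| `wt_bar` | L-type permeability P_dhpr × 1.4, SERCA Ap × 1.5 |
| `mutant_bar` | both sets composed |

The volume/CASQ2/Φm changes describe the CASQ2-null morphology (volume
expansion compensating lost buffer capacity, heightened luminal sensing of
RyR2); the permeability/pump changes are the static representation of
β-adrenergic phosphorylation. No kinase cascade is modelled.

Runs begin from a near-steady 1-Hz state: resting gates, V = −85 mV, an SR
load appropriate to the scenario (1100 µM for wild-type conditions, 1400 µM
for the β-stimulated mutant), and the first beats of each protocol are
treated as settling time by the measurement conventions (e.g. last five
transients of a 10-s run).

The stimulus is a rectangular 1-ms, −60 µA/µF pulse, about 1.5× the
measured diastolic threshold (`calibrate_stimulus` re-measures it for
modified parameter sets).

## Measurement conventions

* **APD**: APD90 — from maximum dV/dt to the crossing of
  V_peak − 0.9·(V_peak − V_diastolic), linearly interpolated; the level is
  a parameter. Non-captured beats give NaN.
* **Capture**: V crosses 0 mV within 50 ms of the stimulus.
* **Ca transient**: window maximum; diastolic value is the sample
  immediately preceding the stimulus.
* **AP amplitude**: reported as peak-minus-diastolic; the peak overshoot
  potential is recorded separately (`peak_v`).
* **Spark**: a maximal episode with ≥2 RyR2 channels of one CRU open,
  sub-threshold interruptions shorter than 5 ms merged; both thresholds are
  configurable. Rates are rescaled by 20000/n_cru to full-scale
  equivalents. Spark "amplitude" is the peak subspace Ca of the episode
  (µM).
* **EAD**: after the AP peak and before V first returns to within 10 mV of
  the diastolic level, a sustained (≥5 ms) depolarizing deflection of
  ≥2 mV net rise, measured on lightly smoothed V (5-sample moving
  average — stochastic channel noise rides on the plateau).
* **Alternans**: ≥4 consecutive beats whose metric differences alternate in
  sign with mean |Δ| above 5 % of the metric mean.
* **Diastolic interval**: APD90-end of the previous beat to the next
  upstroke.
* Group comparisons use Welch's two-sided unequal-variance t-test.

## Synthetic fixtures

`generate_synthetic_trace` builds parametric traces for detector
validation: raised-cosine action potentials whose APD90 is exact by
construction (the 90 % level of the cosine shape falls at a known fraction
of the repolarization time), raised-cosine Ca transients with exact peaks,
optional injected APD/Ca alternans, EADs (a 30-ms pause of the
repolarization clock carrying a sin² depolarizing hump), and skipped beats
(no upstroke). These waveforms share none of the physics of the simulator —
they exercise the detectors against known ground truth, so passing them
shows detector correctness, not model realism. They contain no stochastic
channel noise; the EAD detector's smoothing and thresholds are therefore
additionally exercised on real traces in the phenotype tests.

## Calibration targets and known limitations

The published model this design follows reports its kinetic constants in a
companion article, so every rate here was calibrated against the printed
summary statistics (1-Hz Ca-transient maxima and diastolic levels, APDs,
spark rates, and the slow–rapid–slow phase contrast) rather than copied.
With the bundled configuration at desk scale the wild-type 1-Hz physiology
and the first/second slow-phase APD contrast of the β-stimulated mutant
reproduce the reference envelopes; the acceptance suite records honestly
where the model falls short:

* **Second-phase spark rate.** After rapid pacing the mutant's spark rate
  rises ~1.6× (reference: >2×, ~369,000/s full-scale; we reach ~155,000/s).
  The episode count is ceiling-limited by the adaptation/recovery duty
  cycle; faster re-licensing paradoxically *lowers* counts because
  re-openings within 5 ms merge into the same episode.
* **EADs.** The second slow phase shows Ca overload (transient nearly
  doubles, Na-loaded NCX) but no discrete EADs: with thousands of
  independent CRUs and no inter-CRU diffusion, spontaneous release is
  temporally uniform and its voltage footprint stays below the 2-mV
  detector threshold. Making the L-type window wide enough for
  voltage-coupled synchronization destabilizes the wild-type plateau first.
* **6-Hz regime.** Mean APD at 6 Hz lands near −10 % of the reference
  value, and deep alternans appears in *all* scenarios rather than only the
  β-stimulated mutant: the L-type availability restitution that protects
  the cell from Ca overload at 6 Hz is also a strong alternans substrate.
  At 3 Hz both genotypes capture every beat with no EADs, but a ~8-10 %
  APD alternation remains.

These three are coupled: they all trace to how strongly L-type recovery is
rate-limited and how synchronized spontaneous release can become without
spatial coupling between CRUs. Ca²⁺ waves are structurally impossible in
this model (no inter-CRU diffusion), which is a deliberate scope boundary.

## Performance

The engine is a single-thread numba kernel; a 10-s beat at 2,000 CRUs and
dt = 0.05 ms takes ~40 s on one CPU core (first call adds JIT
compilation). Problem sizes in the tests and the acceptance script (2,000
CRUs, 10–30 s protocols) are the package's desk-scale defaults; the
full-scale 20,000-CRU mode is configuration only.
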