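# Methods

## Model

The device is a volatile diffusive memristor: a nearly formed Ag
filament whose final gap of size `L` contains one or two mobile Ag
clusters.  Cluster positions set the tunnelling resistance
(`core.resistance_one` / `core.resistance_two`); the memristor sits in
series with a load `R_ext` and capacitance `C` (circuit constant
`τ = R_ext C`), so the voltage `V` across the gap obeys the divider
equation with relaxation time `τ`.  Cluster motion is overdamped
Langevin dynamics in an electro-chemical potential `U(x)` plus the
electric force `q V / L`, with thermal noise of intensity `D = 2 k_B T`
(Itô convention; the temperature enters the diffusion coefficient at
the current step).  The device temperature integrates Joule dissipation
`V²/R` against Newton cooling at rate `κ` toward the bath `T0(t)`.
Optional voltage noise of intensity `D_V` enters the circuit equation
scaled by `1/τ` (so `D_V` carries voltage²·time units).

The deterministic companion model (`deterministic.rhs`) replaces
thermal fluctuations by forces carried by the thermal and electric
gradients `T′`, `V′` in the gap, coupled to the cluster through a
thermal charge `q_T` (thermophoresis / Seebeck).  It is the object of
the fixed-point, Hopf and hysteresis analysis; the stochastic and
deterministic models share every other parameter.

**Sign convention.** The electric force is `field_sign · q V / L` with
`field_sign = +1` by default: for `V > 0` the force pulls the cluster
from the filament-tip well toward the counter-electrode.  The switch
exists because either convention appears in the literature depending on
the assumed charge polarity of the cluster.

## Spiking mechanism

The reference potential (`potential.reference_potential`) has slope

    U'(x) = (x + 0.4)((x − 0.05)² + 0.004) + 2000 · max(x − 0.05, 0)³

(in gap units, `L = 1`): a single well at `x = −0.4`, an escape-barrier
slope peaking near `x = −0.25` (max ≈ 0.014), a shallow slope minimum
(≈ 0.002) just right of the gap centre where the tunnelling resistance
is minimal, and a steep one-sided confinement shoulder beyond
`x = 0.05`.  This makes the circuit a relaxation oscillator: the
electric force must exceed the barrier slope to pull the cluster off
the well; crossing the low-resistance centre collapses `V` through the
divider; the residual force then falls below the slope minimum and the
cluster returns.  At high drive the force instead balances against the
shoulder — a *latched-conducting* state in which the field holds the
cluster near the gap centre and spiking stops.  Noise-driven switching
between the relaxation cycle and this latch produces intermittent
bursting.

A pure quartic profile without the shoulder (`default_potential`) is
kept as the simplest example; with it the high-drive attractor is a
deeply pinned, absorbing state on the far flank, which supports neither
bursting nor the phase comparator.  The shoulder variant was therefore
adopted as the reference — a deliberate design choice, shipped as a
dense tabulated spec (the piecewise-quartic is C², interpolated with a
cubic spline).

## Reference parameter set (dimensionless)

Lengths are in units of `L`, resistance in `R_ext`, time in
`τ = R_ext C`, and `k_B = 1` so temperature is in energy units of the
potential scale.  The set was calibrated once so that increasing DC
drive traverses the canonical regime sequence, and is a repository
artefact (no published normalisation exists for this unit system):

| parameter | value | meaning |
| --- | --- | --- |
| `R_t` | `0.01·e⁻¹⁰` | tunnelling amplitude → `R0 = 0.02` (on-state ≪ load) |
| `λ` | 0.05 | tunnelling length (`L = 20 λ`; well-state resistance ≈ 30) |
| `η` | 0.004 | cluster viscosity (fast cluster, slow circuit) |
| `q` | 0.04 | effective cluster charge |
| `q_T` | 30 | thermal charge (deterministic model only) |
| `C_th` | 2·10⁵ | thermal capacitance |
| `κ` | 0.2 | cooling rate (heat integrates over ≈ 5 τ) |
| `T0` | 10⁻⁶ | bath temperature (≈ 10⁻³ of the well-to-barrier climb) |
| `D_V` | 10⁻⁶ | circuit voltage-noise intensity |
| `dt` | 5·10⁻⁴ τ | Euler–Maruyama step |

With these values the noise-free skeleton (`q_T = 0`) has a first Hopf
threshold near `V_ext ≈ 0.65`, a relaxation cycle to `V_ext ≈ 3.0`, and
a latched state coexisting with the cycle over `V_ext ≈ 1.5–3.0`.  The
stochastic regimes at the anchor voltages are:

| anchor | `V_ext` | behaviour |
| --- | --- | --- |
| quiescent | 0.5 | no spikes (rare thermal escapes only) |
| regular | 1.35 | limit-cycle spiking, CV1 ≈ 0.07 |
| sparse | 1.95 | noise-disrupted cycle, CV1 ≈ 0.5, no burst structure |
| bursting | 2.3 | cycle/latch switching, CV1 ≈ 3.5–4, tens of bursts |

Two further windows exist and are reported by the survey but not used
as anchors: noise-induced sparse spiking below the first Hopf
(`V_ext ≈ 0.7`) and a second sparse window above the bursting band
(`V_ext ≈ 2.8–3.0`, deep latch with rare escapes).

## Spike detection

`detect_spikes` is scale-free by default: threshold = median baseline
plus half the robust amplitude (to the 99.5th-percentile peak), peaks
merged within a minimum separation keeping the taller, and a prominence
floor so ripple on a suprathreshold plateau does not count.  For
simulated traces the protocols use an absolute variant
(`detect_reference_spikes`): current normalised by `V_ext/R_ext` with
threshold 2 and prominence 1.  On that scale relaxation-spike peaks sit
at ≈ 10–60, the latched plateau at ≈ 1 and the quiescent divider
current at ≈ 0.03, so one threshold separates the states at every
drive level — a relative threshold would count noise ripple in traces
that contain no true spikes.

## Statistics

* **CV1** = std(ISI)/mean(ISI), population convention (`ddof=0`,
  switchable) — the choice matters only at small counts.
* **CV2** = trial mean of `2|Δt_{n+1} − Δt_n|/(Δt_{n+1} + Δt_n)`;
  bounded in `[0, 2)` by construction.  Per-pair values are exposed for
  distribution plots.
* **PSD**: Welch — mean-removed, Hann-tapered, 50%-overlapping
  segments, density scaling (integral ≈ variance).
* **2-D ISI histograms**: logarithmic ISI bins (bursting spans
  decades), column-normalised to unit mass; the mode curve takes the
  geometric bin centre.
* **Hull coverage**: fraction of reference points inside the convex
  hull of a cloud (Qhull Delaunay membership with a boundary tolerance
  of 10⁻⁹); verified against a ray-casting oracle in the tests.
* **Preferred period** `t_p*`: quadratic interpolation through the
  discrete rate argmax and its neighbours, clipped to the bracket.

## Regime classification

`classify_regime` uses config-exposed cuts: rate < 0.02 → quiescent;
CV1 < 0.3 → regular; CV1 ≥ 1.5 with ≥ 5 bursts (runs of ISIs below 5×
the median with ≥ 3 spikes) → bursting; otherwise sparse.  The cuts
were chosen against the anchor conditions above and are unanimous
across seeds there; they are thresholds on continuous quantities, so
borderline drives (e.g. `V_ext ≈ 1.8` or `2.1`) can flip label between
seeds.

## Experiments

* **Selectivity** (`run_selectivity`): drive
  `V_ext = V_DC (1 + frac·cos(2πt/t_p))` at the regular anchor
  (`V_DC = 1.35`, natural period ≈ 0.62 τ), `frac ∈ {0.25, 0.5, 0.75}`,
  `t_p` spanning 0.5–2.2× the natural period.  The modal ISI tracks
  `t_p` within 10% over a locking band of roughly 0.8–1.25× the natural
  period, and `t_p*` shifts to shorter periods as the AC amplitude
  grows.
* **Phase comparator** (`run_phase_detector`):
  `V_ext = 2.3 + 0.6 sin ωt` against
  `T0 = 10⁻⁶ (1 + 0.9 sin(ωt + φ))`, `ω = 2π/200` (about 1/130 of the
  spiking rate), five periods per seed, 20 seeds.  The drive straddles
  the cycle/latch bistable band: high bath temperature at low voltage
  un-latches the neuron (small latch basin there), low temperature at
  high voltage keeps it on the cycle, so antiphase signals spike
  strongly and in-phase signals barely at all (rate ratio ≈ 20 at the
  shipped settings).  This experiment uses a weak-thermal-feedback
  device variant (`C_th = 2·10⁶`): at the reference `C_th` the latch's
  own Joule self-heating (it conducts) swamps the bath-temperature
  signal and the gate disappears.  Only the relative phase matters; the
  curve is 2π-periodic.
* **Energy estimate** (`estimate_energy_power`): closed form
  `E = C_Ag ρ_Ag N (4π r³/3) ΔT` with rigorous unit conversion
  (nm → cm); defaults `C = 0.236 J/(g·°C)`, `ρ = 10.49 g/cm³`,
  `N = 10`, `r = 10 nm`, `ΔT = 100 °C` give `E ≈ 1.04·10⁻¹⁴ J`
  (≈ 0.01 pJ) and `P ≈ 10⁻⁶ W` at 0.1 GHz.

## Numerics

* **Stochastic integrator**: explicit Euler–Maruyama with reflecting
  walls at `±L/2` and ascending relabelling for two clusters, compiled
  with numba.  `dt = τ/2000` keeps `dt·U''/η` below ≈ 1.4 at the
  confinement shoulder (the stability-limiting stiffness); halving `dt`
  changes the reference firing rate by well under 5%.  Noise comes from
  numba's global MT19937 stream seeded per run — identical inputs give
  bit-identical traces.  The conservative force is evaluated by linear
  interpolation on an 8193-point grid (error ≪ the plateau force).
* **Deterministic integrator**: fixed-step RK4 (numba) at the same
  `dt` for bulk scans — hysteresis sweeps, limit-cycle scans, basins —
  cross-checked against scipy's LSODA (rtol 10⁻⁸) in the tests; LSODA
  is available via `integrate(..., method="lsoda")` for one-off
  precision work.  Fixed-step RK4 was chosen because the scans
  integrate millions of steps on one core.
* **Fixed points**: the `(T′, V, V′)` subsystem is linear at frozen
  `x`, so equilibria reduce to a scalar force balance; roots are
  bracketed on a 2001-point grid and refined by Brent's method, then
  classified by the spectrum of a central-difference Jacobian
  (`h = 10⁻⁶`).
* **Hopf detection**: sign changes of the leading complex pair's real
  part between grid points on the nearest-`x` matched branch, refined
  by bisection in `V_ext` to `|Re λ| < 10⁻⁶`.
* **Limit cycles**: long integrations (transient-discarding) from
  perturbed fixed points and warm starts in both sweep directions; the
  tail of `x` oscillating by more than `10⁻³ L` over the last 20% of
  the run counts as a cycle.  Unstable cycles cannot be found this way
  and are not reported; the coexistence windows list drives where a
  stable fixed point and a stable cycle are both observed.
* **Hysteresis**: triangular `V_ext` ramp (default 2000 τ per leg,
  slow against every relaxation rate), binned on a common grid; the
  reported window is the widest contiguous run of bins where one pass
  oscillates and the other sits on a fixed point (means are only
  compared where both passes are quiescent, because the mean over an
  oscillating bin is phase-sensitive).  At the reference set the
  up-pass stays on the cycle through `V_ext ≈ 1.9–2.1` where the
  down-pass sits on the re-stabilised focus, overlapping the
  continuation's coexistence window (≈ 1.95–2.05).

## Surrogate data

The surrogate module generates what the analysis stack needs to be
tested without any recording: periodic, Poisson, gamma-renewal and
jittered-periodic renewal trains; a two-state Markov (doubly-stochastic
Poisson) bursting train with exponential dwell times; a deterministic
alternating-ISI train (the CV2-adversarial case); Gaussian-pulse
current traces with known spike times; and (CV1, CV2) clouds assembled
from these classes with realised statistics always recomputed, never
copied from the request.  Analytic anchors: Poisson → CV1 = CV2 = 1,
gamma(k) → CV1 = 1/√k, periodic → 0.

What these surrogates do not emulate: refractoriness, rate drift,
serial ISI correlations beyond the two-state construction, or any
recording noise — so passing tests certify the estimators on clean
renewal-class inputs, not robustness to real electrophysiology.
External spike trains and CV tables are consumed as-is from CSV
(`timestamp` column; `cv1, cv2` columns) and never recomputed from raw
physiology here.

## Known limitations

* The regime sequence, thresholds and windows are properties of the
  calibrated dimensionless reference set, not predictions for any
  specific fabricated device.
* The one-sided confinement shoulder that creates the latched state is
  a modelling device for the high-drive conducting state; its position
  and stiffness control where bursting lives.
* Hopf classification is linear (eigenvalue crossing); criticality
  (sub- vs supercritical) and the nonlocal bifurcation of the
  high-drive cycle are not classified.
* The two-cluster model is integrated and tested (resistance law,
  ordering, confinement) but all shipped experiment calibrations use
  one cluster.
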