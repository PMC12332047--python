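# transneuron

A simulator and analysis toolkit for a **stochastic diffusive-memristor
artificial neuron**: a volatile Ag-filament memristor in series with a
load resistor and capacitor, whose current spikes like a biological
neuron and whose spiking statistics can be tuned — by voltage, load and
bath temperature — across the regimes seen in cortical recordings.

It is aimed at neuromorphic-device and computational-neuroscience
researchers who want a reproducible, desk-scale model of this circuit:
regime exploration, inter-spike-interval statistics, frequency
selectivity, bifurcation analysis, and a two-signal phase comparator.

## The model

One or two mobile Ag clusters at positions `x_i` diffuse in the gap of
size `L` between the filament tip (at `−L/2`) and the counter-electrode
(`+L/2`), in an electro-chemical potential `U(x)` with a well near the
filament tip.  Electron tunnelling sets the memristor resistance

    R(x)       = R0 cosh(x/λ),   R0 = 2 R_t e^{L/2λ}          (one cluster)
    R(x1, x2)  = R_t (e^{(L/2+x1)/λ} + e^{(x2−x1)/λ} + e^{(L/2−x2)/λ})

and the circuit couples back through the voltage divider.  The
stochastic dynamics are Langevin equations with Joule heating and
Newton cooling:

    η dx_i/dt = −∂U/∂x_i + q V/L + √(2 k_B T η) ξ_i(t)
      dT/dt   = V²/(C_th R) − κ (T − T0(t))
    τ dV/dt   = V_ext(t) − (1 + R_ext/R) V + √(D_V) ς_V(t)

with τ = R_ext·C.  A deterministic companion model replaces thermal
noise by thermophoretic forces carried by the gap's thermal and
electric gradients `T′`, `V′` (thermal charge `q_T`); it is the object
of the bifurcation analysis.  All reference values are in dimensionless
units: length in `L`, resistance in `R_ext`, time in `τ`, `k_B = 1`.

## Worked example

```python
import numpy as np
from transneuron import (DriveProtocol, SimConfig, simulate,
                         reference_device, reference_circuit,
                         detect_reference_spikes, cv1, cv2)

dev, cir = reference_device(), reference_circuit()
trace = simulate(dev, cir, DriveProtocol.dc(1.35, 1e-6),
                 SimConfig(t_max=2000.0, seed=1))
train = detect_reference_spikes(trace, V_ext=1.35)
print(f"rate={train.rate:.2f}  CV1={cv1(train):.2f}  CV2={cv2(train):.2f}")
```

prints

```
rate=1.60  CV1=0.07  CV2=0.07
```

— at `V_ext = 1.35` the neuron fires ~1.6 spikes per circuit time with
near-clockwork regularity (CV1 = CV2 ≈ 0.07): the self-sustained
relaxation-oscillation regime.  Re-running at `V_ext = 1.95` gives
CV1 ≈ 0.5 (irregular "sparse" spiking) and at `V_ext = 2.3` CV1 ≈ 3.5
with tens of bursts (intermittent bursting), the canonical sequence as
the drive increases.  The same objects drive the higher-level
experiments:

```python
from transneuron import run_phase_detector
table, curve, (phi_min, phi_max) = run_phase_detector(
    phi_values=[0.0, np.pi], seeds=range(1, 21))
print(curve)       # mean spiking rate vs relative phase
```

shows the phase-comparator behaviour: minimal spiking for in-phase
voltage/temperature signals (rate ≈ 0.07) and strong spiking for
antiphase signals (rate ≈ 1.42).

A command-line surface wraps the same drivers:

```sh
transneuron analyze            # regime survey -> labels + CSV
transneuron bifurcate          # fixed points, Hopf points, cycles
transneuron phase-detect       # phase-comparator curve
transneuron estimate-energy    # per-cycle heating energy and power
```

## Layout

| module | contents |
| --- | --- |
| `transneuron.core` | device/circuit parameters, resistance laws, drive protocols, YAML config round-trip |
| `transneuron.potential` | potential shapes (polynomial / tabulated) and the reference profile |
| `transneuron.simulate` | Euler–Maruyama integrator (numba kernel), `Trace` container and CSV I/O |
| `transneuron.deterministic` | thermophoretic model: fixed points, stability, Hopf continuation, hysteresis sweeps, basins |
| `transneuron.spikes` | spike detection, CV1/CV2, Welch spectra, 2-D ISI histograms, CV maps, bursts, hull coverage |
| `transneuron.surrogate` | renewal / bursting surrogate trains and synthetic traces with ground truth |
| `transneuron.protocols` | experiment drivers (regimes, CV cloud, selectivity, phase detector) and the energy estimate |
| `transneuron.cli` | `transneuron` command-line entry point |

See `docs/methods.md` for the model assumptions, the calibrated
reference parameter set, and the numerical choices.
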