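# mechanoca

Analysis toolkit for **mechanically evoked Ca²⁺ transients in epithelial
monolayers**: a single-cell kinetic model of cytosolic Ca²⁺/Na⁺ handling with
Ca²⁺-induced Ca²⁺ release (CICR) and a Na⁺-inhibited Na⁺/Ca²⁺ exchanger
(NCX), the fluorescence-trace feature pipeline used to quantify such
recordings, model fitting to quantile-averaged traces, in-silico
perturbation experiments, and a synthetic-data generator so that the whole
chain is testable without microscopy data.

It is aimed at people analyzing Ca²⁺-indicator time-lapse recordings of
mechanically stimulated cells (e.g. substrate shear sensed by
mechanosensitive cation channels such as Piezo1) who want a mechanistic
readout of why directly stimulated cells and their gap-junction-coupled
neighbors decay at different rates.

## The model

Relative cytosolic concentrations (resting level ≡ 1) of Ca²⁺ (*c*) and Na⁺
(*n*), plus a slow CRU inactivation gate *h*:

    dc/dt = J_θ(t) + J_CRU + J_pump + J_leak + J_NCX
    dn/dt = J_θ*(t) + J_pump* + J_leak*

    J_CRU  =  V_cru · h · c^m / (K_cru^m + c^m)      (CICR, ER release)
    J_pump = −V_pump · c² / (K_pump² + c²)           (SERCA/PMCA, lumped)
    J_NCX  = −V_ncx · c/(K_ncx + c) · n^(−q_ncx)     (Na⁺-inhibited exchange)
    J_pump* = −k_na · n,  dh/dt = (h_inf(c) − h)/τ_h,
    h_inf(c) = K_h²/(K_h² + c²)

J_θ is a rectangular influx pulse. In **target cells** (directly stimulated
through nonselective mechanosensitive channels) the Na⁺ twin J_θ* equals
J_θ; in **neighbor cells** (reached through gap junctions, which amplify
Ca²⁺ via CICR but deliver no Na⁺) J_θ* = 0. The constant leaks are solved
at construction so that *c* = *n* = 1 is an exact equilibrium. The single
mechanistic knob `q_ncx > 0` implements "raised cytosolic Na⁺ weakens the
exchanger": target cells accumulate Na⁺ during the pulse, extrude Ca²⁺ more
slowly, and therefore show a longer 50% decay time than neighbors of equal
amplitude.

Trace features follow the standard definitions: intensities are normalized
by the mean of the 10 frames before stimulation (I_basal), the **amplitude**
is the post-stimulus maximum of I/I_basal, and the **50% decay time** is the
interpolated time from the maximum to the mid-level between maximum and
baseline.

## Worked example

```python
import numpy as np
from mechanoca import (default_parameters, default_stimulus, simulate_trace,
                       features)
from mechanoca.perturb import (sodium_free, store_depletion, influx_sweep,
                               ms_fraction_estimate)

params = default_parameters()      # shipped calibrated set
stim = default_stimulus()          # standard target-cell pulse

f = features(simulate_trace(params, stim))
print(f"target   amplitude {f.amplitude:.3f}  decay50 {f.decay50:.1f} s")

nf = sodium_free(params, stim)     # Na+ pathway disabled
print(f"Na+-free amplitude {nf.amplitude:.3f}  decay50 {nf.decay50:.1f} s")

print(f"store depletion: {store_depletion(params, stim):.1f} % amplitude loss")

curve = influx_sweep(params, stim, np.linspace(0, 1, 21))
print(f"influx loss implied by a KO with baseline increase 0.71 vs 1.22: "
      f"{ms_fraction_estimate(curve, 1.22, 0.71):.1f} %")
```

prints

```
target   amplitude 2.404  decay50 71.0 s
Na+-free amplitude 1.996  decay50 40.0 s
store depletion: 69.6 % amplitude loss
influx loss implied by a KO with baseline increase 0.71 vs 1.22: 54.9 %
```

Reading: the calibrated target-cell response peaks at 2.4× baseline and
takes 71 s to fall halfway back; removing the Na⁺ pathway barely changes
the peak (2.0) but halves the decay time (40 s) because the exchanger keeps
running at full strength — the model's central kinetic effect. Emptying the
ER store (V_cru = 0) removes ~70% of the response, i.e. most of the signal
is CICR amplification rather than direct influx. Inverting the influx-sweep
curve at a knockout's amplitude says a ~42% amplitude drop requires losing
~55% of the stimulus influx.

Fitting uses the statsmodels-style pair `CalciumTransientModel` /
`CalciumTransientResults`:

```python
from mechanoca import CalciumTransientModel
model = CalciumTransientModel.from_traces(normalized_traces, params,
                                          quantiles=4)
res = model.fit(n_starts=8, seed=0)
print(res.summary())        # shared kinetics ± std err, per-bin influx, SSE
res.plot()                  # observed (solid) vs fitted (dashed) overlays
```

A `mechanoca` command-line tool wraps the pipeline
(`synth`, `analyze`, `fit`, `perturb`, `metrics`, `run`); see
`mechanoca --help`.

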