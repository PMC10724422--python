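# Methods

## Model

The package models a mechanically evoked cytosolic Ca²⁺ transient in a
single cell with three ordinary differential equations for the relative
Ca²⁺ concentration *c*, the relative Na⁺ concentration *n* (both
normalized so the resting state is 1) and a CRU inactivation gate *h*.
The Ca²⁺ balance sums a rectangular stimulus influx J_θ(t), Hill-type
Ca²⁺-induced Ca²⁺ release from the ER (J_CRU, gated by *h*), a lumped
SERCA/PMCA pump with Hill coefficient 2, a constant inward leak, and
Na⁺/Ca²⁺ exchange whose rate carries the factor n^(−q_ncx). The Na⁺
balance has its own influx J_θ*(t), first-order extrusion −k_na·n and a
constant leak. NCX turnover does not feed back on *n*: the cytosolic Na⁺
pool is orders of magnitude larger than the Ca²⁺ pool, so the exchanger's
Na⁺ flux is negligible on the *n* scale.

Assumptions worth stating explicitly:

* **Well-mixed single cell.** No spatial Ca²⁺ diffusion, no explicit
  gap-junction flux term; a neighbor cell is represented solely by
  receiving a Ca²⁺-only pulse (J_θ* = 0), a target cell by a pulse that
  carries Na⁺ alongside (J_θ* = J_θ), since the mechanosensitive channels
  are nonselective cation channels.
* **Excitable, non-oscillatory regime.** The calibrated parameter set has a
  single stable equilibrium at c = 1 (verified numerically over
  c ∈ [0.4, 3.5]); any finite pulse returns to rest.
* **Linear fluorescence proxy.** Normalized indicator intensity is taken
  equal to *c* (no indicator saturation or bleaching), so model output can
  be compared frame-by-frame with normalized traces.
* **Rectangular pulse.** The stimulus is fully described by its timing,
  duration and intensity — exactly the per-cell free parameters of the
  fitting problem.
* **Gate optionality.** τ_h → 0 recovers a gateless, algebraic CRU; the
  shipped set uses τ_h ≈ 9 s, which terminates the CICR burst and shapes
  the plateau-free decay.

The constant leaks are never user input: `k_leak` and `k_leak_na` are
solved at construction so that c = n = 1, h = h_inf(1) is an exact
equilibrium, and `resting_state()` re-verifies the balance to 1e−10 s⁻¹,
rejecting hand-edited parameter files that would drift at rest.

## Parameters and defaults

| name | meaning | default | unit |
|------|---------|---------|------|
| v_pump, k_pump | pump max rate, half-saturation | 0.121, 0.6 | 1/s, – |
| v_cru, k_cru, m_cru | CRU max release, half-activation, Hill exponent | 1.125, 1.68, 4 | 1/s, –, – |
| k_h, tau_h | gate half-inactivation, time constant | 0.59, 9.24 | –, s |
| v_ncx, k_ncx, q_ncx | NCX max rate, half-saturation, Na⁺-inhibition exponent | 0.155, 1.0, 0.50 | 1/s, –, – |
| k_na | Na⁺ relaxation rate | 0.0088 | 1/s |
| stimulus | onset 12.3 s, duration 2.81 s, intensity 0.163 | | s, s, 1/s |

The defaults were calibrated once (`scripts/calibrate.py`, seed 20231109,
six bounded multi-starts in log-parameter space) against the package's
reference response summaries: target-cell amplitude ≈ 2.4 with ≈ 71 s
mid-level decay; amplitude ≈ 2.0 with ≈ 40 s decay when the Na⁺ pathway is
disabled; ≈ 70% loss of the amplitude increase under store depletion; and a
sweep curve retaining ≈ 62% of its response at half influx. k_pump (0.6),
m_cru (4) and k_ncx (1.0) were held fixed during calibration — they are
weakly identified by these summaries. The achieved values are 2.404 / 70.98 s,
1.996 / 40.01 s, 69.6%, 0.63.

## Trace features

Traces are normalized by I_basal, the mean of the 10 frames immediately
before the stimulus frame; amplitude is the post-stimulus maximum of the
normalized trace (spontaneous baseline fluctuations are excluded from the
search window). The 50% decay time runs from the frame of the maximum to
the first crossing of the mid-level (amplitude + 1)/2, linearly
interpolated between frames because the 1.23 s frame interval is coarse
relative to 40–70 s decays; a trace that never crosses within the recording
is flagged undefined (NaN) rather than extrapolated. A "half of maximum"
level (amplitude/2) is available via `decay_mode="half_max"` since both
definitions circulate; the mid-level form is the default operational
definition. Cell classification is geometric: target = positive-area
overlap with a stimulation rectangle, neighbor = within 0.5 µm boundary
distance of a target, other = neither.

## Fitting

`CalciumTransientModel` fits the kinetic model to amplitude-quantile
averaged traces: one shared kinetic parameter set across all bins (default
free subset: v_cru, v_ncx, q_ncx), and per-bin pulse timing, duration and
intensity, with the Na⁺ coupling fixed by group, never fitted. The
objective is unweighted SSE on frame-wise residuals — quantile averages
have near-homogeneous noise. Timing is bounded to ±3 frames around the
known stimulation frame; duration to [0.03, 10] s.

The optimization is bounded trust-region least squares with two numerical
choices that matter:

1. **Finite-difference step 1e−4 (relative), 3-point jacobian.** The
   residuals are ODE solutions with relative tolerance ~1e−7; a default-size
   difference step turns the jacobian into integrator noise and collapses
   the trust region far from the optimum.
2. **Two-pass multi-start over a duration grid.** The frame grid aliases
   the rectangular pulse edges, producing local minima at onsets shifted by
   a frame or more; random multi-starts land in them. Each start therefore
   pins the onset at the known stimulation time and the duration at one
   value of a geometric grid over [1, 6] s, fits shared kinetics and
   intensities first (pass A), then releases all influx parameters
   (pass B); the lowest final SSE wins. The seed jitters the intensity
   initialization of the non-first starts; identical seeds give bitwise
   identical results. Iteration budgets (80/120 trust-region steps per
   pass) cap noise-driven wandering in the flat duration-intensity valley.

Standard errors are Gauss–Newton estimates from the final jacobian; they
describe curvature at the optimum, not identifiability of the
duration–intensity trade-off, which is genuinely weak at 1.23 s sampling
(the influx *charge*, intensity × duration, is much better determined than
either factor).

## Perturbation experiments

* **Influx sweep** scales only the pulse intensity (Na⁺ twin scaling with
  it) over fractions of the calibrated value and reads the amplitude
  increase off the standard frame-grid pipeline; the curve is monotone and
  anchored at (0, 0). Inverting it at measured wild-type/knockout
  amplitude increases (after rescaling so fraction 1 maps to wild type)
  yields the influx percentage lost in the knockout.
* **Store depletion** sets v_cru = 0 (leak re-solved so the depleted model
  still rests at 1) and reports the percentage drop of the amplitude
  increase.
* **Na⁺-free** removes the stimulus Na⁺ influx and keeps cytosolic Na⁺ at
  rest. Because dn/dt = J_θ* − k_na·n + k_na has the exact solution
  n(t) ≡ 1 when J_θ* = 0, the clamp is implemented by dropping the Na⁺
  coupling — the exchanger then runs at full strength throughout.

## Synthetic data

The generator emulates the statistical structure the analysis assumes: a
grid of 20 µm square cells with a 1.4 × 80 µm stimulation stripe through
the middle row (replicated fields for larger n), geometric group labels,
per-group responder probabilities (target 0.7, neighbor 0.5, other 0.1 —
explicit configuration, not measured values), per-cell log-normal scaling
of the influx intensity (σ = 0.35) for the observed cell-to-cell amplitude
heterogeneity, log-normal baseline brightness, and multiplicative (σ = 0.02)
plus additive (σ = 0.01·I_basal) Gaussian noise on the recording protocol of
10 baseline + 121 post-stimulus frames at 1.23 s. Neighbor cells receive
0.6× the target influx with no Na⁺ coupling; "other" cells are never
stimulated. Everything is deterministic given the seed and ships with a
ground-truth table.

What it does **not** emulate — and hence what passing tests do not
establish about real recordings: indicator nonlinearity and bleaching,
spatially correlated noise and segmentation errors, wave-like onset delays
between cells, spontaneous transients, heterogeneous kinetic parameters
across cells (only the influx varies), or drift in I_basal.

## Numerical choices

* Integration: LSODA, rtol 1e−8 / atol 1e−10 (1e−7/1e−9 inside the fit
  objective), integrated piecewise across the pulse edges so the
  discontinuous right-hand side never crosses an integration step; a test
  pins the solver against an independent fixed-step RK4 oracle at 1 ms to
  1e−4 relative error.
* Decay-time crossing: first downward crossing, linear interpolation, exact
  hit counts as crossing.
* Quantile binning: rank-based with ties broken by cell id; groups with
  fewer responders than bins reduce the bin count with a warning.
* Sweep inversion: monotone linear interpolation; queries outside the curve
  range raise rather than extrapolate.
* Degenerate inputs: non-positive baselines, non-monotone or gapped frame
  indices, zero-variance correlation inputs and unbalanced resting states
  are rejected with typed exceptions rather than propagated as NaN.

## Known limitations

* The flux functional forms are a minimal excitable CICR formulation chosen
  for this package; other forms (e.g. IP₃-receptor-based release) could fit
  the same summaries. Conclusions should rest on the mechanism (Na⁺-
  inhibited extrusion), not the specific algebra.
* k_pump, m_cru and k_ncx are fixed by convention, not estimated; the
  calibration surface does not identify them.
* Pulse duration and intensity trade off strongly at 1.23 s sampling; only
  their product is sharply determined. Recovery of intensity to ~10%
  requires pooling many cells per averaged trace.
* The model is deterministic; stochastic channel gating and spontaneous
  activity are outside its scope.
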