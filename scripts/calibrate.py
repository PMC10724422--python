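"""Calibrate the shipped default parameter set.

Fits the kinetic parameters and the standard stimulus so that the model
reproduces the package's reference response summaries:

* target-cell amplitude ~2.4 and mid-level half-decay ~71 s;
* amplitude ~2.0 and half-decay ~40 s with the Na+ pathway disabled;
* ~70% loss of the amplitude increase when the ER store is emptied;
* a sweep curve retaining ~62% of its amplitude increase at half influx.

Bounded least squares in log-parameter space with a seeded multi-start
(seed 20231109).  Writes the winning parameter set and stimulus to
``src/mechanoca/data/`` when run with ``--write``.

Usage::

    python scripts/calibrate.py [--starts 6] [--write]
"""

from __future__ import annotations

import argparse
import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

from mechanoca.exceptions import MechanocaError
from mechanoca.model import ModelParameters, StimulusInflux, simulate_trace

SEED = 20231109

FIXED = dict(k_pump=0.6, m_cru=4.0, k_ncx=1.0)
NAMES = ["v_pump", "v_cru", "k_cru", "k_h", "tau_h", "v_ncx", "q_ncx", "k_na",
         "intensity", "duration"]
LO = dict(v_pump=0.005, v_cru=0.05, k_cru=1.15, k_h=0.2, tau_h=1.5, v_ncx=0.01,
          q_ncx=0.3, k_na=0.004, intensity=0.05, duration=2.0)
HI = dict(v_pump=0.25, v_cru=2.0, k_cru=3.0, k_h=1.2, tau_h=30.0, v_ncx=0.4,
          q_ncx=4.0, k_na=0.1, intensity=1.0, duration=5.0)

TARGETS = dict(amp=2.4, dec=71.0, amp_nf=2.0, dec_nf=40.0, depl=70.0,
               rel_half=0.62)
WEIGHTS = dict(amp=2.0, dec=2.0, amp_nf=2.0, dec_nf=2.0, depl=1.0,
               rel_half=0.5)


def build(x):
    vals = dict(zip(NAMES, np.exp(x)))
    stim = StimulusInflux(t_on=12.3, duration=vals.pop("duration"),
                          intensity=vals.pop("intensity"), na_coupled=True)
    return ModelParameters(**FIXED, **vals), stim


def amp_dec(params, stim):
    """Amplitude and mid-level decay time; the decay time is linearly
    extrapolated from the mean decay slope when the trace does not cross
    within the recording, which keeps the objective smooth."""
    tr = simulate_trace(params, stim, rtol=1e-7, atol=1e-9)
    t, v = tr.time, tr.intensity
    k = int(np.argmax(v[tr.stim_frame:])) + tr.stim_frame
    amp = float(v[k])
    level = (amp + 1) / 2
    for j in range(k, len(v) - 1):
        if v[j] >= level > v[j + 1]:
            frac = (v[j] - level) / (v[j] - v[j + 1])
            return amp, float(t[j] + frac * (t[j + 1] - t[j]) - t[k])
    slope = (amp - v[-1]) / max(t[-1] - t[k], 1e-9)
    if slope <= 1e-9:
        return amp, 1e4
    return amp, float((amp - level) / slope)


def measure(x):
    params, stim = build(x)
    a, d = amp_dec(params, stim)
    a_nf, d_nf = amp_dec(params, dataclasses.replace(stim, na_coupled=False))
    a_depl, _ = amp_dec(params.replace(v_cru=0.0), stim)
    a_half, _ = amp_dec(params, stim.scaled(0.5))
    return dict(amp=a, dec=d, amp_nf=a_nf, dec_nf=d_nf,
                depl=100 * (1 - (a_depl - 1) / (a - 1)),
                rel_half=(a_half - 1) / (a - 1))


def resid(x):
    try:
        m = measure(x)
    except MechanocaError:
        return np.full(len(TARGETS), 10.0)
    return np.array([WEIGHTS[k] * (m[k] / t - 1.0) for k, t in TARGETS.items()])


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--starts", type=int, default=6)
    ap.add_argument("--write", action="store_true",
                    help="overwrite the shipped default JSON files")
    args = ap.parse_args()

    x0 = np.log([0.03, 0.4, 1.5, 0.45, 6.0, 0.06, 2.0, 0.02, 0.13, 3.7])
    lo = np.log([LO[n] for n in NAMES])
    hi = np.log([HI[n] for n in NAMES])
    rng = np.random.default_rng(SEED)
    best = None
    for i in range(args.starts):
        start = x0 if i == 0 else rng.uniform(lo, hi)
        sol = least_squares(resid, np.clip(start, lo, hi), bounds=(lo, hi),
                            diff_step=1e-4, xtol=1e-12, ftol=1e-12,
                            max_nfev=300)
        print(f"start {i}: cost {sol.cost:.6g}")
        if best is None or sol.cost < best.cost:
            best = sol

    params, stim = build(best.x)
    print("calibrated:", {n: round(float(v), 6)
                          for n, v in zip(NAMES, np.exp(best.x))})
    print("achieved:", {k: round(v, 3) for k, v in measure(best.x).items()})

    if args.write:
        data_dir = Path(__file__).resolve().parent.parent / "src/mechanoca/data"
        blob = {n: round(float(np.exp(v)), 6)
                for n, v in zip(NAMES, best.x) if n not in ("intensity", "duration")}
        blob.update(FIXED)
        blob.update({"k_leak": None, "k_leak_na": None})
        order = ["v_pump", "k_pump", "v_cru", "k_cru", "m_cru", "k_h", "tau_h",
                 "v_ncx", "k_ncx", "q_ncx", "k_na", "k_leak", "k_leak_na"]
        (data_dir / "default_params.json").write_text(
            json.dumps({k: blob[k] for k in order}, indent=2) + "\n")
        (data_dir / "default_stimulus.json").write_text(json.dumps({
            "t_on": 12.3,
            "duration": round(float(np.exp(best.x[NAMES.index("duration")])), 6),
            "intensity": round(float(np.exp(best.x[NAMES.index("intensity")])), 6),
            "na_coupled": True,
        }, indent=2) + "\n")
        print("wrote default_params.json and default_stimulus.json")


if __name__ == "__main__":
    main()
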