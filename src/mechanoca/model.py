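"""Single-cell kinetic model of mechanically evoked Ca2+ transients.

The model tracks three state variables on a dimensionless scale where the
resting state is 1: the relative cytosolic Ca2+ concentration ``c``, the
relative cytosolic Na+ concentration ``n``, and a slow inactivation gate
``h`` of the ER calcium release unit (CRU).

Ca2+ balance::

    dc/dt = J_theta(t) + J_CRU + J_pump + J_leak + J_NCX

Na+ balance::

    dn/dt = J_theta*(t) + J_pump* + J_leak*

with

* ``J_theta``   -- rectangular influx pulse through mechanically opened
  cation channels (target cells) or gap junctions (neighbor cells);
* ``J_CRU``     -- Hill-type Ca2+-induced Ca2+ release from the ER, gated by
  the inactivation variable ``h`` (CICR amplification);
* ``J_pump``    -- lumped SERCA/PMCA extrusion, Hill coefficient 2;
* ``J_leak``    -- constant inward leak, solved so the resting state balances;
* ``J_NCX``     -- Na+/Ca2+ exchange, attenuated by cytosolic Na+ through a
  factor ``n**(-q_ncx)``: a raised Na+ level weakens the inward Na+ gradient
  that powers Ca2+ extrusion;
* ``J_theta*``  -- Na+ twin of the stimulus pulse. It equals ``J_theta`` in
  directly stimulated (target) cells, where the nonselective channels pass
  Na+ alongside Ca2+, and is zero in neighbor cells reached via gap
  junctions;
* ``J_pump*``   -- first-order Na+ extrusion ``-k_na * n``;
* ``J_leak*``   -- constant Na+ leak, again solved for resting balance.

Na+ dynamics is deliberately not fed back from NCX: the absolute cytosolic
Na+ pool is orders of magnitude larger than the Ca2+ pool, so the exchanger
turnover perturbs ``n`` negligibly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import (
    ConfigurationError,
    DomainError,
    NumericalError,
    PreconditionError,
)

__all__ = [
    "ModelParameters",
    "ModelState",
    "StimulusInflux",
    "FluxSet",
    "Trajectory",
    "fluxes",
    "resting_state",
    "simulate",
    "simulate_trace",
    "trajectory_to_trace",
]

#: tolerance on the resting flux balance (1/s)
REST_BALANCE_TOL = 1e-10


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants of the Ca2+/Na+ flux balance.

    All rates are in 1/s and all half-saturations on the relative
    concentration scale.  ``k_leak`` and ``k_leak_na`` are normally left
    ``None`` and solved at construction so that the resting state
    ``c = n = 1``, ``h = h_inf(1)`` is an exact equilibrium; passing them
    explicitly is allowed (e.g. when reloading from JSON) and is validated
    later by :func:`resting_state`.
    """

    v_pump: float
    k_pump: float
    v_cru: float
    k_cru: float
    m_cru: float
    k_h: float
    tau_h: float
    v_ncx: float
    k_ncx: float
    q_ncx: float
    k_na: float
    k_leak: float | None = None
    k_leak_na: float | None = None

    def __post_init__(self) -> None:
        for name in ("v_pump", "k_pump", "v_cru", "k_cru", "k_h", "tau_h",
                     "v_ncx", "k_ncx", "k_na"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ConfigurationError(f"{name} must be finite and >= 0, got {value!r}")
        for name in ("k_pump", "k_cru", "k_h", "k_ncx", "tau_h"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.m_cru < 1:
            raise ConfigurationError(f"m_cru must be >= 1, got {self.m_cru!r}")
        if self.q_ncx < 0:
            raise ConfigurationError(f"q_ncx must be >= 0, got {self.q_ncx!r}")
        if self.k_leak is None:
            object.__setattr__(self, "k_leak", self._solve_k_leak())
        if self.k_leak_na is None:
            object.__setattr__(self, "k_leak_na", self.k_na)
        if self.k_leak < 0:
            raise ConfigurationError(
                "resting balance requires a negative Ca2+ leak: the CRU resting "
                "release exceeds pump plus NCX extrusion at c = n = 1"
            )
        if self.k_leak_na < 0:
            raise ConfigurationError("k_leak_na must be >= 0")

    def _solve_k_leak(self) -> float:
        c = 1.0
        h = self.h_inf(c)
        j_cru = self.v_cru * h * c**self.m_cru / (self.k_cru**self.m_cru + c**self.m_cru)
        j_pump = -self.v_pump * c**2 / (self.k_pump**2 + c**2)
        j_ncx = -self.v_ncx * c / (self.k_ncx + c)
        return -(j_cru + j_pump + j_ncx)

    def h_inf(self, c: float) -> float:
        """Steady-state value of the CRU inactivation gate at Ca2+ level ``c``."""
        return self.k_h**2 / (self.k_h**2 + c**2)

    def replace(self, **changes) -> "ModelParameters":
        """Return a copy with ``changes`` applied and the leaks re-solved
        (unless they are overridden explicitly)."""
        fields = dataclasses.asdict(self)
        if not {"k_leak", "k_leak_na"} & set(changes):
            fields["k_leak"] = None
            fields["k_leak_na"] = None
        fields.update(changes)
        return ModelParameters(**fields)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ModelParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class ModelState:
    """Instantaneous model state (relative concentrations plus CRU gate)."""

    c: float
    n: float
    h: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.c) and self.c > 0):
            raise DomainError(f"c must be finite and > 0, got {self.c!r}")
        if not (np.isfinite(self.n) and self.n > 0):
            raise DomainError(f"n must be finite and > 0, got {self.n!r}")
        if not (0.0 <= self.h <= 1.0):
            raise DomainError(f"h must lie in [0, 1], got {self.h!r}")


@dataclass(frozen=True)
class StimulusInflux:
    """Rectangular stimulus pulse J_theta(t) and its Na+ twin J_theta*(t).

    ``na_coupled=True`` models a directly stimulated (target) cell where the
    mechanosensitive channels pass Na+ alongside Ca2+ (J_theta* = J_theta);
    ``False`` models a neighbor cell reached through gap junctions
    (J_theta* = 0).  The pulse is active on the half-open interval
    ``[t_on, t_on + duration)``.
    """

    t_on: float
    duration: float
    intensity: float
    na_coupled: bool = True

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigurationError(f"duration must be > 0, got {self.duration!r}")
        if self.intensity < 0:
            raise ConfigurationError(f"intensity must be >= 0, got {self.intensity!r}")
        if self.t_on < 0:
            raise ConfigurationError(f"t_on must be >= 0, got {self.t_on!r}")

    def j_theta(self, t: float) -> float:
        if self.t_on <= t < self.t_on + self.duration:
            return self.intensity
        return 0.0

    def j_theta_star(self, t: float) -> float:
        return self.j_theta(t) if self.na_coupled else 0.0

    def scaled(self, fraction: float) -> "StimulusInflux":
        """Same pulse with the intensity scaled by ``fraction``."""
        return dataclasses.replace(self, intensity=self.intensity * fraction)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusInflux":
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "StimulusInflux":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class FluxSet:
    """Instantaneous value of every flux term (1/s)."""

    j_theta: float
    j_cru: float
    j_pump: float
    j_leak: float
    j_ncx: float
    j_theta_star: float
    j_pump_star: float
    j_leak_star: float

    @property
    def dc_dt(self) -> float:
        return self.j_theta + self.j_cru + self.j_pump + self.j_leak + self.j_ncx

    @property
    def dn_dt(self) -> float:
        return self.j_theta_star + self.j_pump_star + self.j_leak_star


def fluxes(state: ModelState, params: ModelParameters,
           stimulus: StimulusInflux | None, t: float) -> FluxSet:
    """Evaluate every flux term at state ``state`` and time ``t``.

    ``stimulus=None`` means no pulse (both J_theta terms are zero).
    """
    c, n, h = state.c, state.n, state.h
    if c <= 0:
        raise DomainError(f"c must be positive, got {c!r}")
    if n <= 0:
        raise DomainError(f"n must be positive, got {n!r}")
    cm = c**params.m_cru
    j_cru = params.v_cru * h * cm / (params.k_cru**params.m_cru + cm)
    j_pump = -params.v_pump * c**2 / (params.k_pump**2 + c**2)
    j_ncx = -params.v_ncx * (c / (params.k_ncx + c)) * n ** (-params.q_ncx)
    j_theta = stimulus.j_theta(t) if stimulus is not None else 0.0
    j_theta_star = stimulus.j_theta_star(t) if stimulus is not None else 0.0
    return FluxSet(
        j_theta=j_theta,
        j_cru=j_cru,
        j_pump=j_pump,
        j_leak=params.k_leak,
        j_ncx=j_ncx,
        j_theta_star=j_theta_star,
        j_pump_star=-params.k_na * n,
        j_leak_star=params.k_leak_na,
    )


def resting_state(params: ModelParameters) -> ModelState:
    """The resting steady state (c = 1, n = 1, h = h_inf(1)).

    Verifies by direct evaluation that both total fluxes vanish to within
    ``1e-10`` 1/s; a violation (e.g. a leak rate edited without re-solving
    the balance) raises :class:`ConfigurationError`.
    """
    state = ModelState(c=1.0, n=1.0, h=params.h_inf(1.0))
    fs = fluxes(state, params, None, 0.0)
    if abs(fs.dc_dt) > REST_BALANCE_TOL or abs(fs.dn_dt) > REST_BALANCE_TOL:
        raise ConfigurationError(
            "resting flux balance violated: "
            f"|dc/dt| = {abs(fs.dc_dt):.3e}, |dn/dt| = {abs(fs.dn_dt):.3e} "
            f"(tolerance {REST_BALANCE_TOL:g}); re-solve k_leak/k_leak_na"
        )
    return state


@dataclass(frozen=True)
class Trajectory:
    """Model solution sampled on a fixed time grid."""

    times: np.ndarray
    c: np.ndarray
    n: np.ndarray
    h: np.ndarray
    stimulus: StimulusInflux | None
    params: ModelParameters

    def state(self, i: int) -> ModelState:
        return ModelState(c=float(self.c[i]), n=float(self.n[i]), h=float(self.h[i]))

    def flux_table(self):
        """Per-sample flux terms as a pandas DataFrame."""
        import pandas as pd

        rows = []
        for i, t in enumerate(self.times):
            fs = fluxes(self.state(i), self.params, self.stimulus, float(t))
            rows.append(dataclasses.asdict(fs))
        df = pd.DataFrame(rows)
        df.insert(0, "time_s", self.times)
        return df

    def to_dataframe(self, include_fluxes: bool = False):
        import pandas as pd

        df = pd.DataFrame({"time_s": self.times, "c": self.c, "n": self.n, "h": self.h})
        if include_fluxes:
            df = df.merge(self.flux_table(), on="time_s")
        return df


def _rhs(t, y, params: ModelParameters, stimulus: StimulusInflux | None):
    c, n, h = y
    # Guard against tiny negative excursions from the integrator; the flux
    # forms themselves keep the equilibrium away from zero.
    c = max(c, 1e-12)
    n = max(n, 1e-12)
    cm = c**params.m_cru
    j_cru = params.v_cru * h * cm / (params.k_cru**params.m_cru + cm)
    j_pump = -params.v_pump * c**2 / (params.k_pump**2 + c**2)
    j_ncx = -params.v_ncx * (c / (params.k_ncx + c)) * n ** (-params.q_ncx)
    j_theta = stimulus.j_theta(t) if stimulus is not None else 0.0
    j_theta_star = stimulus.j_theta_star(t) if stimulus is not None else 0.0
    dc = j_theta + j_cru + j_pump + params.k_leak + j_ncx
    dn = j_theta_star - params.k_na * n + params.k_leak_na
    h_inf = params.k_h**2 / (params.k_h**2 + c**2)
    dh = (h_inf - h) / params.tau_h
    return (dc, dn, dh)


def _integrate(params: ModelParameters, stimulus: StimulusInflux | None,
               t_eval: np.ndarray, y0: Sequence[float],
               rtol: float = 1e-8, atol: float = 1e-10) -> np.ndarray:
    """Integrate the model over ``t_eval``, splitting at the pulse edges.

    The rectangular pulse makes the right-hand side discontinuous at
    ``t_on`` and ``t_on + duration``; integrating each smooth segment
    separately keeps the adaptive error control honest.
    """
    t_eval = np.asarray(t_eval, dtype=float)
    t0, t_end = float(t_eval[0]), float(t_eval[-1])
    breaks = [t0]
    if stimulus is not None:
        for edge in (stimulus.t_on, stimulus.t_on + stimulus.duration):
            if t0 < edge < t_end:
                breaks.append(edge)
    breaks.append(t_end)
    breaks = sorted(set(breaks))

    out = np.empty((3, len(t_eval)))
    y = np.asarray(y0, dtype=float)
    for a, b in zip(breaks[:-1], breaks[1:]):
        mask = (t_eval >= a) & (t_eval <= b) if b == t_end else (t_eval >= a) & (t_eval < b)
        seg_eval = t_eval[mask]
        # Always integrate through to the segment end so the state handed to
        # the next segment is the state at the pulse edge, not at the last
        # requested output sample.
        eval_ext = seg_eval if seg_eval.size and seg_eval[-1] == b \
            else np.append(seg_eval, b)
        sol = solve_ivp(
            _rhs, (a, b), y, method="LSODA", t_eval=eval_ext,
            rtol=rtol, atol=atol, args=(params, stimulus), dense_output=False,
        )
        if not sol.success:
            raise NumericalError(
                f"integration failed in segment [{a:g}, {b:g}] s: {sol.message}"
            )
        if seg_eval.size:
            out[:, mask] = sol.y[:, : seg_eval.size]
        y = sol.y[:, -1]
    return out


def simulate(params: ModelParameters, stimulus: StimulusInflux | None,
             t_end: float, dt_out: float,
             initial_state: ModelState | None = None,
             rtol: float = 1e-8, atol: float = 1e-10) -> Trajectory:
    """Simulate the model from rest (or ``initial_state``) up to ``t_end``.

    The trajectory is sampled at multiples of ``dt_out``.  Integration uses
    an adaptive stiff-capable solver (LSODA) with relative tolerance 1e-8,
    split at the pulse edges.
    """
    if dt_out <= 0:
        raise PreconditionError(f"dt_out must be > 0, got {dt_out!r}")
    if stimulus is not None and t_end <= stimulus.t_on + stimulus.duration:
        raise PreconditionError(
            "t_end must exceed the end of the stimulus pulse "
            f"({stimulus.t_on + stimulus.duration:g} s), got {t_end!r}"
        )
    if initial_state is None:
        initial_state = resting_state(params)
    t_eval = np.arange(0.0, t_end + dt_out / 2, dt_out)
    y = _integrate(params, stimulus, t_eval,
                   (initial_state.c, initial_state.n, initial_state.h),
                   rtol=rtol, atol=atol)
    return Trajectory(times=t_eval, c=y[0], n=y[1], h=y[2],
                      stimulus=stimulus, params=params)


def trajectory_to_trace(traj: Trajectory, frame_interval: float,
                        n_baseline_frames: int, n_post_frames: int | None = None):
    """Resample a trajectory onto the imaging frame grid as an IntensityTrace.

    Fluorescence is taken proportional to ``c`` (linear indicator, no
    saturation), so the normalized intensity of the resulting trace is the
    model ``c`` itself.  The frame grid is aligned so that exactly
    ``n_baseline_frames`` frames precede the stimulus onset.
    """
    from .traces import IntensityTrace

    if frame_interval <= 0:
        raise PreconditionError("frame_interval must be > 0")
    if traj.stimulus is not None:
        t_on = traj.stimulus.t_on
    else:
        # no pulse: anchor the grid at the trajectory start
        t_on = float(traj.times[0]) + n_baseline_frames * frame_interval
    t_first = t_on - n_baseline_frames * frame_interval
    if t_first < traj.times[0] - 1e-9:
        raise PreconditionError(
            f"trajectory starts at {traj.times[0]:g} s; cannot supply "
            f"{n_baseline_frames} baseline frames before t_on = {t_on:g} s"
        )
    if n_post_frames is None:
        n_post_frames = int(np.floor((traj.times[-1] - t_on) / frame_interval)) + 1
    n_frames = n_baseline_frames + n_post_frames
    frame_times = t_first + frame_interval * np.arange(n_frames)
    if frame_times[-1] > traj.times[-1] + 1e-9:
        raise PreconditionError("trajectory too short for the requested frame count")
    intensity = np.interp(frame_times, traj.times, traj.c)
    return IntensityTrace(
        cell_id="model",
        frame_index=np.arange(n_frames),
        time=frame_times,
        intensity=intensity,
        stim_frame=n_baseline_frames,
        group="target" if (traj.stimulus is not None and traj.stimulus.na_coupled)
        else ("neighbor" if traj.stimulus is not None else "unlabeled"),
        normalized=True,
    )


def simulate_trace(params: ModelParameters, stimulus: StimulusInflux,
                   frame_interval: float = 1.23, n_baseline_frames: int = 10,
                   n_post_frames: int = 121,
                   rtol: float = 1e-8, atol: float = 1e-10):
    """Simulate and sample ``c`` exactly on the imaging frame grid.

    The grid mirrors the recording protocol the package assumes:
    ``n_baseline_frames`` pre-stimulus frames followed by ``n_post_frames``
    frames at ``frame_interval`` seconds.  Requires
    ``stimulus.t_on >= n_baseline_frames * frame_interval``.
    """
    from .traces import IntensityTrace

    t_first = stimulus.t_on - n_baseline_frames * frame_interval
    if t_first < -1e-9:
        raise PreconditionError(
            f"stimulus onset {stimulus.t_on:g} s leaves no room for "
            f"{n_baseline_frames} baseline frames at {frame_interval:g} s"
        )
    n_frames = n_baseline_frames + n_post_frames
    frame_times = t_first + frame_interval * np.arange(n_frames)
    rest = resting_state(params)
    if t_first > 1e-9:
        # burn-in from t=0 to the first frame is unnecessary: the model rests
        t_eval = frame_times
    else:
        t_eval = frame_times
    y = _integrate(params, stimulus, t_eval, (rest.c, rest.n, rest.h),
                   rtol=rtol, atol=atol)
    return IntensityTrace(
        cell_id="model",
        frame_index=np.arange(n_frames),
        time=frame_times,
        intensity=y[0],
        stim_frame=n_baseline_frames,
        group="target" if stimulus.na_coupled else "neighbor",
        normalized=True,
    )
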