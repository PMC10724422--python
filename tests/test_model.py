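"""Kinetic model: flux balance, domain guards, integration accuracy."""

import dataclasses

import numpy as np
import pytest

from mechanoca.exceptions import (
    ConfigurationError,
    DomainError,
    PreconditionError,
)
from mechanoca.model import (
    ModelParameters,
    ModelState,
    StimulusInflux,
    fluxes,
    resting_state,
    simulate,
    simulate_trace,
    trajectory_to_trace,
)


class TestFluxes:
    def test_resting_balance_is_exact(self, params, stimulus):
        rest = resting_state(params)
        fs = fluxes(rest, params, stimulus, t=0.0)  # before pulse onset
        assert abs(fs.dc_dt) < 1e-10
        assert abs(fs.dn_dt) < 1e-10

    def test_pulse_adds_intensity_to_both_balances(self, params, stimulus):
        rest = resting_state(params)
        t_in = stimulus.t_on + stimulus.duration / 2
        fs = fluxes(rest, params, stimulus, t=t_in)
        assert fs.dc_dt == pytest.approx(stimulus.intensity, abs=1e-10)
        assert fs.dn_dt == pytest.approx(stimulus.intensity, abs=1e-10)

    def test_pulse_interval_is_half_open(self, params, stimulus):
        rest = resting_state(params)
        end = stimulus.t_on + stimulus.duration
        assert fluxes(rest, params, stimulus, stimulus.t_on).j_theta == \
            stimulus.intensity
        assert fluxes(rest, params, stimulus, end).j_theta == 0.0

    def test_sodium_inhibits_ncx(self, params):
        """Raising cytosolic Na+ weakens the Ca2+ extrusion through NCX."""
        h = params.h_inf(2.0)
        low = fluxes(ModelState(c=2.0, n=1.0, h=h), params, None, 0.0)
        high = fluxes(ModelState(c=2.0, n=2.0, h=h), params, None, 0.0)
        assert params.q_ncx > 0
        assert abs(high.j_ncx) < abs(low.j_ncx)

    def test_flux_signs(self, params, stimulus):
        fs = fluxes(ModelState(c=1.7, n=1.2, h=0.3), params, stimulus,
                    stimulus.t_on)
        assert fs.j_pump <= 0 and fs.j_ncx <= 0 and fs.j_pump_star <= 0
        assert fs.j_leak >= 0 and fs.j_cru >= 0 and fs.j_theta >= 0
        assert fs.j_leak_star >= 0 and fs.j_theta_star >= 0

    def test_nonpositive_concentration_rejected(self, params):
        with pytest.raises(DomainError, match="c"):
            ModelState(c=0.0, n=1.0, h=0.5)
        with pytest.raises(DomainError, match="n"):
            ModelState(c=1.0, n=-1.0, h=0.5)


class TestRestingState:
    def test_resting_state_is_unit_concentrations(self, params):
        rest = resting_state(params)
        assert rest.c == 1.0 and rest.n == 1.0
        assert rest.h == pytest.approx(params.h_inf(1.0))

    def test_edited_leak_without_resolve_is_rejected(self, params):
        broken = params.replace(k_leak=params.k_leak * 1.1)
        with pytest.raises(ConfigurationError, match="balance"):
            resting_state(broken)

    def test_replace_resolves_balance_by_default(self, params):
        tweaked = params.replace(v_cru=params.v_cru * 0.5)
        resting_state(tweaked)  # must not raise


class TestSimulate:
    def test_zero_intensity_stays_at_rest(self, params, stimulus):
        quiet = dataclasses.replace(stimulus, intensity=0.0)
        traj = simulate(params, quiet, t_end=60.0, dt_out=1.0)
        assert np.allclose(traj.c, 1.0, atol=1e-7)
        assert np.allclose(traj.n, 1.0, atol=1e-7)

    def test_sodium_coupling_slows_the_decay(self, params, stimulus):
        """With q_ncx > 0 the Na+-coupled trajectory keeps more Ca2+ late."""
        coupled = simulate(params, stimulus, t_end=120.0, dt_out=1.0)
        uncoupled = simulate(
            params, dataclasses.replace(stimulus, na_coupled=False),
            t_end=120.0, dt_out=1.0)
        late = coupled.times > stimulus.t_on + 30
        assert np.all(coupled.c[late] > uncoupled.c[late])

    def test_sodium_coupling_is_inert_when_q_is_zero(self, params, stimulus):
        p0 = params.replace(q_ncx=0.0)
        a = simulate(p0, stimulus, t_end=80.0, dt_out=1.0)
        b = simulate(p0, dataclasses.replace(stimulus, na_coupled=False),
                     t_end=80.0, dt_out=1.0)
        assert np.allclose(a.c, b.c, atol=1e-9)

    def test_concentrations_stay_positive_across_random_parameters(self):
        rng = np.random.default_rng(42)
        n_valid = 0
        for _ in range(25):
            try:
                p = ModelParameters(
                    v_pump=rng.uniform(0.01, 0.3), k_pump=rng.uniform(0.3, 1.5),
                    v_cru=rng.uniform(0.0, 1.5), k_cru=rng.uniform(1.2, 3.0),
                    m_cru=rng.uniform(1.0, 5.0), k_h=rng.uniform(0.2, 1.2),
                    tau_h=rng.uniform(2.0, 20.0), v_ncx=rng.uniform(0.01, 0.3),
                    k_ncx=rng.uniform(0.5, 2.0), q_ncx=rng.uniform(0.0, 3.0),
                    k_na=rng.uniform(0.005, 0.1))
            except ConfigurationError:
                continue  # CRU resting release exceeds extrusion: no balance
            n_valid += 1
            s = StimulusInflux(t_on=5.0, duration=rng.uniform(1.0, 4.0),
                               intensity=rng.uniform(0.0, 0.5))
            traj = simulate(p, s, t_end=60.0, dt_out=0.5)
            assert np.all(traj.c > 0) and np.all(traj.n > 0)
            assert np.all((traj.h >= 0) & (traj.h <= 1 + 1e-9))
        assert n_valid >= 10

    def test_peak_amplitude_monotone_in_intensity(self, params, stimulus):
        peaks = []
        for f in np.linspace(0.1, 2.0, 10):
            traj = simulate(params, stimulus.scaled(f), t_end=60.0, dt_out=0.5)
            peaks.append(traj.c.max())
        assert np.all(np.diff(peaks) >= -1e-9)

    def test_returns_to_rest_after_finite_pulse(self, params, stimulus):
        traj = simulate(params, stimulus, t_end=2000.0, dt_out=20.0)
        assert abs(traj.c[-1] - 1.0) < 0.01

    def test_t_end_must_cover_the_pulse(self, params, stimulus):
        with pytest.raises(PreconditionError):
            simulate(params, stimulus, t_end=stimulus.t_on, dt_out=1.0)

    def test_adaptive_solver_matches_fixed_step_rk4(self, params):
        """Independent fixed-step RK4 oracle at dt = 1 ms, evaluated on a
        hand-written right-hand side."""
        s = StimulusInflux(t_on=5.0, duration=3.0, intensity=0.2,
                           na_coupled=True)
        p = params

        def rhs(t, c, n, h):
            cm = c**p.m_cru
            jc = p.v_cru * h * cm / (p.k_cru**p.m_cru + cm)
            jp = -p.v_pump * c * c / (p.k_pump**2 + c * c)
            jx = -p.v_ncx * (c / (p.k_ncx + c)) * n ** (-p.q_ncx)
            jt = s.intensity if s.t_on <= t < s.t_on + s.duration else 0.0
            dc = jt + jc + jp + p.k_leak + jx
            dn = jt - p.k_na * n + p.k_leak_na
            hi = p.k_h**2 / (p.k_h**2 + c * c)
            return dc, dn, (hi - h) / p.tau_h

        dt = 1e-3
        t_end = 40.0
        y = (1.0, 1.0, p.h_inf(1.0))
        t = 0.0
        samples = {}
        out_times = np.arange(0.0, t_end + 1e-9, 1.0)
        next_out = 0
        for _ in range(int(round(t_end / dt))):
            if next_out < len(out_times) and abs(t - out_times[next_out]) < dt / 2:
                samples[round(t)] = y[0]
                next_out += 1
            k1 = rhs(t, *y)
            k2 = rhs(t + dt / 2, *(yi + dt / 2 * ki for yi, ki in zip(y, k1)))
            k3 = rhs(t + dt / 2, *(yi + dt / 2 * ki for yi, ki in zip(y, k2)))
            k4 = rhs(t + dt, *(yi + dt * ki for yi, ki in zip(y, k3)))
            y = tuple(yi + dt / 6 * (a + 2 * b + 2 * c_ + d)
                      for yi, a, b, c_, d in zip(y, k1, k2, k3, k4))
            t += dt
        samples[round(t)] = y[0]

        traj = simulate(p, s, t_end=t_end, dt_out=1.0)
        for i, tt in enumerate(traj.times):
            ref = samples[round(float(tt))]
            assert abs(traj.c[i] - ref) / ref < 1e-4


class TestTrajectoryToTrace:
    def test_unstimulated_trace_is_unity(self, params):
        traj = simulate(params, None, t_end=30.0, dt_out=0.1)
        trace = trajectory_to_trace(traj, frame_interval=1.23,
                                    n_baseline_frames=5)
        assert np.allclose(trace.intensity, 1.0, atol=1e-7)

    def test_frame_alignment_with_protocol_grid(self, target_trace):
        assert target_trace.stim_frame == 10
        assert target_trace.n_frames == 131
        assert target_trace.time[10] == pytest.approx(12.3)
        assert np.allclose(np.diff(target_trace.time), 1.23)

    def test_frame_peak_bounded_by_dense_peak(self, params, stimulus):
        traj = simulate(params, stimulus, t_end=160.0, dt_out=0.05)
        trace = trajectory_to_trace(traj, frame_interval=1.23,
                                    n_baseline_frames=10)
        assert trace.intensity.max() <= traj.c.max() + 1e-12

    def test_insufficient_baseline_span_is_rejected(self, params):
        s = StimulusInflux(t_on=2.0, duration=3.0, intensity=0.2)
        traj = simulate(params, s, t_end=30.0, dt_out=0.5)
        with pytest.raises(PreconditionError):
            trajectory_to_trace(traj, frame_interval=1.23, n_baseline_frames=10)
        with pytest.raises(PreconditionError):
            simulate_trace(params, s)
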