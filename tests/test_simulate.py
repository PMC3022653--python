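import numpy as np
import pytest

from pkmz_switch import (
    DOWN,
    UP,
    AmbiguousOutcomeError,
    Perturbation,
    Protocol,
    RelaxationError,
    StimSegment,
    SystemState,
    Trajectory,
    classify_outcome,
    find_equilibria,
    initial_state,
    simulate,
)
from pkmz_switch.protocols import run_outcome


def pulse(strength, duration=30.0, t_end=20_000.0, initial=DOWN):
    return Protocol(
        stim_segments=(StimSegment(0.0, duration, strength),),
        t_end=t_end,
        initial=initial,
    )


class TestPulseResponses:
    """The weak/intermediate/strong square-wave stimulus triad."""

    def test_intermediate_pulse_potentiates(self, params):
        traj, outcome = run_outcome(pulse(25.0), params, sample_dt=10.0)
        assert outcome == UP
        assert traj.p[-1] == pytest.approx(0.72, abs=0.01)
        assert traj.epsc[-1] == pytest.approx(1.93, abs=0.01)

    def test_weak_pulse_transient_only(self, params):
        traj, outcome = run_outcome(pulse(5.0), params, sample_dt=10.0)
        assert outcome == DOWN
        assert traj.p.max() > 10 * traj.p[-1]  # rises, then collapses
        assert traj.p[-1] < 0.01

    def test_strong_pulse_overshoots(self, params):
        traj, outcome = run_outcome(pulse(125.0), params, sample_dt=10.0)
        assert outcome == UP
        assert traj.p.max() > traj.p[-1] + 0.05
        assert traj.p[-1] == pytest.approx(0.72, abs=0.01)


class TestInitialState:
    def test_down_state_near_origin(self, params):
        state = initial_state(DOWN, params)
        assert 0 < state.p < 0.01
        # basal stim keeps the DOWN state slightly off the origin; F sits
        # at its closed-form value for that P
        from pkmz_switch import steady_f_of_p

        assert state.f == pytest.approx(float(steady_f_of_p(state.p, params)))

    def test_up_state_value(self, params):
        assert initial_state(UP, params).p == pytest.approx(0.72, abs=0.01)

    def test_up_state_missing_below_lower_fold(self, params):
        with pytest.raises(ValueError, match="UP"):
            initial_state(UP, params.replace(j1=40.0))

    def test_explicit_state_passthrough(self, params):
        state = SystemState(0.5, 0.2, 0.1, 1.0)
        assert initial_state(state, params) is state


class TestIntegratorProperties:
    def test_equilibrium_persistence(self, params):
        """A trajectory started at an attractor stays on it for 10^4 min."""
        for spec in (UP, DOWN):
            start = initial_state(spec, params)
            traj = simulate(Protocol(t_end=10_000.0, initial=spec), params,
                            sample_dt=100.0)
            assert np.max(np.abs(traj.p - start.p)) < 1e-6
            assert np.max(np.abs(traj.epsc - start.epsc)) < 1e-6

    def test_forward_invariance_unit_box(self, params):
        rng = np.random.default_rng(7)
        for _ in range(5):
            y0 = SystemState(*rng.uniform(0, 1, 3), 1.0)
            proto = Protocol(
                stim_segments=(StimSegment(0.0, 30.0, 25.0),
                               StimSegment(100.0, 130.0, 5.0)),
                t_end=5000.0,
                initial=y0,
            )
            traj = simulate(proto, params, sample_dt=5.0)
            tol = 1e-7
            assert traj.states[:, :3].min() >= -tol
            assert traj.states[:, :3].max() <= 1 + tol

    def test_sampling_grid_independence(self, params):
        a = simulate(pulse(25.0, t_end=2000.0), params, sample_dt=2.0)
        b = simulate(pulse(25.0, t_end=2000.0), params, sample_dt=1.0)
        assert np.max(np.abs(a.states[-1] - b.states[-1])) < 1e-6

    def test_tolerance_convergence(self, params):
        for strength in (5.0, 25.0, 125.0):
            a = simulate(pulse(strength), params, sample_dt=100.0)
            b = simulate(pulse(strength), params, sample_dt=100.0,
                         rtol=1e-9, atol=1e-11)
            assert abs(a.p[-1] - b.p[-1]) < 1e-6

    def test_tau_scaling_rescales_time(self, params):
        """Scaling tau1-3 and the schedule by c time-rescales (P,F,R)."""
        c = 10.0
        scaled = params.replace(tau1=c * params.tau1, tau2=c * params.tau2,
                                tau3=c * params.tau3)
        base = simulate(pulse(25.0, duration=30.0, t_end=5000.0), params,
                        sample_dt=10.0)
        slow = simulate(pulse(25.0, duration=c * 30.0, t_end=c * 5000.0),
                        scaled, sample_dt=c * 10.0)
        assert np.allclose(base.states[:, :3], slow.states[:, :3], atol=1e-6)


class TestPerturbations:
    def test_clamp_holds_and_couples(self, params):
        proto = Protocol(
            perturbations=(Perturbation("clamp_variable", 0.0, 50.0, "p", 0.5),),
            t_end=200.0,
            initial=DOWN,
        )
        traj = simulate(proto, params, sample_dt=1.0)
        window = traj.times <= 50.0
        assert np.all(traj.p[window][1:] == 0.5)
        # F-actin must see the clamped value: it approaches its P=0.5 fixed point
        f_target = (params.j2 + params.j3 * 0.5) / (1 + params.j2 + params.j3 * 0.5)
        assert traj.f[50] == pytest.approx(f_target, abs=1e-6)

    def test_clamp_release_resumes_from_clamped_value(self, params):
        proto = Protocol(
            perturbations=(Perturbation("clamp_variable", 0.0, 5.0, "p", 10.0),),
            t_end=2000.0,
            initial=DOWN,
        )
        traj = simulate(proto, params, sample_dt=0.5)
        i_release = int(np.searchsorted(traj.times, 5.0))
        assert traj.p[i_release] == 10.0
        # Eq. 1's (1 - P) factor drives an exogenous excess back below 1 fast
        assert traj.p[-1] < 1.0

    def test_decay_removal_saturates_factin(self, params):
        proto = Protocol(
            perturbations=(Perturbation("remove_factin_decay", 0.0, 60.0),),
            t_end=200.0,
            initial=DOWN,
        )
        traj = simulate(proto, params, sample_dt=1.0)
        # growth rate (j2 + j3*P)/tau2 ~ 0.1/min near the DOWN state
        assert traj.f[60] == pytest.approx(1.0, abs=5e-3)
        assert traj.f[-1] < 0.9  # decays again after the window

    def test_parameter_override_window(self, params):
        proto = Protocol(
            perturbations=(Perturbation("set_parameter", 0.0, 540.0, "j1", 0.0),),
            t_end=2000.0,
            initial=UP,
        )
        traj = simulate(proto, params, sample_dt=1.0)
        p0 = traj.p[0]
        # pure exponential decay of P at rate 1/tau1 while synthesis is off
        assert traj.p[540] == pytest.approx(p0 * np.exp(-540.0 / params.tau1),
                                            rel=1e-4)
        assert traj.p[-1] > traj.p[540]  # recovers after washout


class TestOutcomeClassification:
    def test_relaxation_guard(self, params):
        traj = simulate(pulse(25.0, t_end=100.0), params, sample_dt=10.0)
        with pytest.raises(RelaxationError):
            classify_outcome(traj, params)

    def test_active_perturbation_guard(self, params):
        proto = Protocol(
            perturbations=(Perturbation("clamp_variable", 0.0, 100.0, "p", 0.0),),
            t_end=100.0,
            initial=DOWN,
        )
        traj = simulate(proto, params, sample_dt=10.0)
        with pytest.raises(RelaxationError):
            classify_outcome(traj, params)

    def test_saddle_endpoint_is_ambiguous(self, params):
        saddle = next(e for e in find_equilibria(params) if not e.is_stable)
        start = SystemState(saddle.p, saddle.f, saddle.r, 1.0)
        traj = simulate(Protocol(t_end=100.0, initial=start), params,
                        sample_dt=10.0)
        with pytest.raises(AmbiguousOutcomeError):
            classify_outcome(traj, params)


class TestValidationAndIO:
    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            Protocol(stim_segments=(StimSegment(0, 30, 5), StimSegment(20, 40, 5)),
                     t_end=100.0)

    def test_t_end_must_cover_schedule(self):
        with pytest.raises(ValueError, match="t_end"):
            Protocol(stim_segments=(StimSegment(0, 30, 5),), t_end=10.0)

    def test_protocol_json_roundtrip(self, tmp_path):
        proto = Protocol(
            stim_segments=(StimSegment(0.0, 30.0, 25.0),),
            perturbations=(Perturbation("set_parameter", 0.0, 60.0, "j2", 0.0),
                           Perturbation("remove_factin_decay", 10.0, 20.0)),
            t_end=500.0,
            initial=SystemState(0.1, 0.2, 0.3, 1.0),
        )
        path = tmp_path / "protocol.json"
        proto.to_json(path)
        assert Protocol.from_json(path) == proto

    def test_trajectory_tsv_roundtrip(self, tmp_path, params):
        traj = simulate(pulse(25.0, t_end=100.0), params, sample_dt=10.0)
        path = tmp_path / "traj.tsv"
        traj.write_tsv(path)
        header = path.read_text().splitlines()[0]
        assert header == "time\tP\tFActin\tRNAactive\tEPSC"
        times, states = Trajectory.read_tsv(path)
        assert np.array_equal(times, traj.times)
        assert np.array_equal(states, traj.states)
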