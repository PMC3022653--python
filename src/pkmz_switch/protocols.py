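"""Named virtual experiments and stimulus-threshold analyses.

The registry reproduces the classic pharmacological and behavioural
manipulations of late-phase LTP as in-silico protocols: ZIP wash-in
(clamp P = 0), exogenous kinase perfusion (clamp P = 10), protein
synthesis inhibition (j1 = 0), actin assembly inhibitors (j2 = j3 = 0),
an F-actin stabilizer (drop the F-actin decay term) and memory
reactivation (a brief P = 0 clamp).  Each protocol returns a trajectory
plus a binary UP/DOWN outcome.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from . import bifurcation
from .params import ModelParams
from .simulate import (
    DOWN,
    UP,
    DEFAULT_T_END,
    P_THRESHOLD,
    Perturbation,
    Protocol,
    RelaxationError,
    StimSegment,
    Trajectory,
    classify_outcome,
    simulate,
)

__all__ = [
    "NamedProtocol",
    "PROTOCOL_REGISTRY",
    "ResponseGrid",
    "ThresholdCurve",
    "run_named",
    "run_outcome",
    "response_grid",
    "stim_threshold",
    "threshold_curve",
]

_LTP_STIM = StimSegment(0.0, 30.0, 25.0)  # standard LTP-inducing pulse
_WEAK_STIM = StimSegment(0.0, 30.0, 5.0)  # subthreshold pulse


@dataclasses.dataclass(frozen=True)
class NamedProtocol:
    name: str
    builder: Callable[[ModelParams], Protocol]
    expected_outcome: str
    description: str


def _proto(*, initial: str, stim: tuple[StimSegment, ...] = (),
           perturbations: tuple[Perturbation, ...] = ()) -> Callable[[ModelParams], Protocol]:
    def build(params: ModelParams) -> Protocol:
        return Protocol(
            stim_segments=stim,
            perturbations=perturbations,
            t_end=DEFAULT_T_END,
            initial=initial,
        )

    return build


PROTOCOL_REGISTRY: dict[str, NamedProtocol] = {
    np_.name: np_
    for np_ in (
        NamedProtocol(
            "zip",
            _proto(
                initial=UP,
                perturbations=(
                    Perturbation("clamp_variable", 0.0, 60.0, "p", 0.0),
                ),
            ),
            DOWN,
            "ZIP wash-in on a potentiated synapse: clamp P = 0 for 60 min",
        ),
        NamedProtocol(
            "exogenous_pkmz",
            _proto(
                initial=DOWN,
                perturbations=(
                    Perturbation("clamp_variable", 0.0, 5.0, "p", 10.0),
                ),
            ),
            UP,
            "perfusion of exogenous kinase: clamp P = 10 for 5 min",
        ),
        NamedProtocol(
            "psi_only",
            _proto(
                initial=UP,
                perturbations=(
                    Perturbation("set_parameter", 0.0, 540.0, "j1", 0.0),
                ),
            ),
            UP,
            "protein-synthesis inhibitor alone: j1 = 0 for 540 min",
        ),
        NamedProtocol(
            "actin_inhibitor_stim",
            _proto(
                initial=DOWN,
                stim=(_LTP_STIM,),
                perturbations=(
                    Perturbation("set_parameter", 0.0, 60.0, "j2", 0.0),
                    Perturbation("set_parameter", 0.0, 60.0, "j3", 0.0),
                ),
            ),
            DOWN,
            "LTP stimulus under an actin assembly inhibitor (j2 = j3 = 0)",
        ),
        NamedProtocol(
            "control_stim",
            _proto(initial=DOWN, stim=(_LTP_STIM,)),
            UP,
            "LTP stimulus alone (control for the inhibitor protocols)",
        ),
        NamedProtocol(
            "reactivation_psi",
            _proto(
                initial=UP,
                perturbations=(
                    Perturbation("clamp_variable", 0.0, 10.0, "p", 0.0),
                    Perturbation("set_parameter", 0.0, 540.0, "j1", 0.0),
                ),
            ),
            DOWN,
            "reactivation under protein-synthesis inhibition",
        ),
        NamedProtocol(
            "reactivation_only",
            _proto(
                initial=UP,
                perturbations=(
                    Perturbation("clamp_variable", 0.0, 10.0, "p", 0.0),
                ),
            ),
            UP,
            "reactivation alone: brief P = 0 clamp, synthesis intact",
        ),
        NamedProtocol(
            "stabilizer_weak_stim",
            _proto(
                initial=DOWN,
                stim=(_WEAK_STIM,),
                perturbations=(
                    Perturbation("remove_factin_decay", 0.0, 60.0),
                ),
            ),
            UP,
            "weak stimulus with an F-actin stabilizer (no F-actin decay)",
        ),
        NamedProtocol(
            "weak_stim_control",
            _proto(initial=DOWN, stim=(_WEAK_STIM,)),
            DOWN,
            "weak stimulus alone (control for the stabilizer)",
        ),
    )
}


def run_outcome(
    protocol: Protocol,
    params: ModelParams,
    sample_dt: float = 1.0,
    max_doublings: int = 3,
) -> tuple[Trajectory, str]:
    """Simulate and classify, doubling the horizon on slow relaxation.

    Near-separatrix trajectories suffer critical slowing; up to
    ``max_doublings`` horizon doublings are attempted before the
    relaxation failure propagates.
    """
    traj = simulate(protocol, params, sample_dt=sample_dt)
    for _ in range(max_doublings):
        try:
            return traj, classify_outcome(traj, params)
        except RelaxationError:
            protocol = protocol.with_t_end(2.0 * protocol.t_end)
            traj = simulate(protocol, params, sample_dt=sample_dt)
    return traj, classify_outcome(traj, params)


def run_named(
    name: str,
    params: ModelParams | None = None,
    sample_dt: float = 1.0,
) -> tuple[Trajectory, str]:
    """Run a registered protocol; returns (trajectory, UP/DOWN outcome)."""
    if params is None:
        params = ModelParams()
    if name not in PROTOCOL_REGISTRY:
        raise KeyError(
            f"unknown protocol {name!r}; registry: {sorted(PROTOCOL_REGISTRY)}"
        )
    return run_outcome(PROTOCOL_REGISTRY[name].builder(params), params,
                       sample_dt=sample_dt)


# -- stimulus-response analyses -----------------------------------------


@dataclasses.dataclass(frozen=True)
class ResponseGrid:
    """UP/DOWN outcome per (stimulus strength, duration) cell."""

    strengths: np.ndarray
    durations: np.ndarray
    outcomes: np.ndarray  # shape (n_durations, n_strengths), dtype object

    def write_tsv(self, path: str | Path) -> None:
        header = "duration\\strength\t" + "\t".join(
            repr(float(s)) for s in self.strengths
        )
        lines = [header]
        for d, row in zip(self.durations, self.outcomes):
            lines.append(repr(float(d)) + "\t" + "\t".join(row))
        Path(path).write_text("\n".join(lines) + "\n")


def _pulse_protocol(strength: float, duration: float,
                    t_end: float = DEFAULT_T_END) -> Protocol:
    return Protocol(
        stim_segments=(StimSegment(0.0, duration, strength),),
        t_end=max(t_end, duration),
        initial=DOWN,
    )


def response_grid(
    strengths: Sequence[float] | None = None,
    durations: Sequence[float] | None = None,
    params: ModelParams | None = None,
    sample_dt: float = 50.0,
) -> ResponseGrid:
    """Classify a square pulse from rest over a strength x duration grid.

    Default axes span strengths 1-200 (log-spaced) and durations 1-120
    min, covering the weak/intermediate/strong exemplar pulses.
    """
    if params is None:
        params = ModelParams()
    if strengths is None:
        strengths = np.geomspace(1.0, 200.0, 40)
    if durations is None:
        durations = np.linspace(1.0, 120.0, 40)
    strengths = np.asarray(strengths, dtype=float)
    durations = np.asarray(durations, dtype=float)
    if np.any(strengths <= 0) or np.any(durations <= 0):
        raise ValueError("grid axes must be positive")
    if np.any(np.diff(strengths) <= 0) or np.any(np.diff(durations) <= 0):
        raise ValueError("grid axes must be sorted ascending")
    outcomes = np.empty((len(durations), len(strengths)), dtype=object)
    for i, duration in enumerate(durations):
        for k, strength in enumerate(strengths):
            _, outcome = run_outcome(
                _pulse_protocol(float(strength), float(duration)),
                params,
                sample_dt=sample_dt,
            )
            outcomes[i, k] = outcome
    return ResponseGrid(strengths, durations, outcomes)


def stim_threshold(
    mrna_total: float | None = None,
    params: ModelParams | None = None,
    duration: float = 30.0,
    bracket: tuple[float, float] = (0.5, 200.0),
    rel_tol: float = 1e-3,
    sample_dt: float = 50.0,
) -> float:
    """Smallest 30-min pulse strength that switches the system UP.

    Returns 0.0 when no DOWN state exists (the system is already UP
    without stimulation), ``math.inf`` when no UP attractor exists (no
    pulse can switch it, e.g. at zero mRNA), and otherwise bisects the
    pulse strength to relative tolerance ``rel_tol``.
    """
    if params is None:
        params = ModelParams()
    if mrna_total is not None:
        if mrna_total < 0:
            raise ValueError("mrna_total must be >= 0")
        params = params.replace(mrna_total=mrna_total)
    stable = [e for e in bifurcation.find_equilibria(params) if e.is_stable]
    if not any(e.p > P_THRESHOLD for e in stable):
        return math.inf
    if not any(e.p <= P_THRESHOLD for e in stable):
        return 0.0

    def outcome_at(strength: float) -> str:
        _, outcome = run_outcome(
            _pulse_protocol(strength, duration), params, sample_dt=sample_dt
        )
        return outcome

    lo, hi = bracket
    if outcome_at(lo) == UP:
        raise ValueError(f"bracket low end {lo} already switches the system")
    if outcome_at(hi) == DOWN:
        return math.inf
    while hi - lo > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if outcome_at(mid) == UP:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


@dataclasses.dataclass(frozen=True)
class ThresholdCurve:
    """Switching threshold of a 30-min pulse versus total mRNA pool."""

    mrna: np.ndarray
    threshold: np.ndarray

    def write_tsv(self, path: str | Path) -> None:
        lines = ["mrna_total\tthreshold"]
        for m, s in zip(self.mrna, self.threshold):
            lines.append(f"{float(m)!r}\t{float(s)!r}")
        Path(path).write_text("\n".join(lines) + "\n")


def threshold_curve(
    m_values: Sequence[float],
    params: ModelParams | None = None,
    **kwargs,
) -> ThresholdCurve:
    """stim_threshold per mRNA pool value; decreasing where finite."""
    if params is None:
        params = ModelParams()
    m_values = np.asarray(list(m_values), dtype=float)
    thresholds = np.array(
        [stim_threshold(float(m), params, **kwargs) for m in m_values]
    )
    return ThresholdCurve(m_values, thresholds)
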