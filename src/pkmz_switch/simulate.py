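"""Time integration under piecewise stimulus schedules and perturbations.

A :class:`Protocol` is a list of square-wave stimulus segments plus a
list of timed perturbations: variable clamps (e.g. ZIP as a P = 0
clamp, exogenous kinase perfusion as a P = 10 clamp), temporary
parameter overrides (protein-synthesis inhibition as j1 = 0, actin
assembly inhibition as j2 = j3 = 0), and removal of the F-actin decay
term (an F-actin stabilizer such as phalloidin).

Integration restarts at every segment/perturbation boundary, so the
stiff-capable adaptive stepper never smooths across a discontinuity.
During a clamp the variable's ODE is dropped and the clamped value is
what every coupled equation sees; on release integration resumes from
the clamped value.
"""

from __future__ import annotations

import bisect
import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
from scipy.integrate import solve_ivp

from . import bifurcation
from .dynamics import SystemState, rhs, steady_epsc_of_p
from .params import PARAM_NAMES, ModelParams

__all__ = [
    "StimSegment",
    "Perturbation",
    "Protocol",
    "Trajectory",
    "IntegrationError",
    "RelaxationError",
    "AmbiguousOutcomeError",
    "simulate",
    "classify_outcome",
    "initial_state",
    "UP",
    "DOWN",
]

UP = "UP"
DOWN = "DOWN"

_VAR_INDEX = {"p": 0, "f": 1, "r": 2, "epsc": 3}

#: variables stay inside the unit box under the unperturbed dynamics, but
#: exogenous clamps (e.g. P = 10) may release the state outside it
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10

#: default horizon for outcome classification, well past the slowest
#: relaxation (PKMzeta turnover, tau1 = 1500 min)
DEFAULT_T_END = 20_000.0

#: UP/DOWN decision threshold on final P; any value strictly between the
#: saddle and the UP state is equivalent once the trajectory has relaxed
P_THRESHOLD = 0.3

RELAX_TOL = 1e-9  # |dP/dt| per minute at the final sample


class IntegrationError(RuntimeError):
    """Adaptive stepping failed (step-size collapse) at a given time."""


class RelaxationError(RuntimeError):
    """Trajectory had not relaxed when an outcome was requested."""


class AmbiguousOutcomeError(RuntimeError):
    """Trajectory relaxed onto an unstable equilibrium (the separatrix)."""


@dataclasses.dataclass(frozen=True)
class StimSegment:
    """A square-wave stimulus: Stim(t) = strength on [t_start, t_end)."""

    t_start: float
    t_end: float
    strength: float

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError("stim segment requires t_start < t_end")
        if self.strength < 0:
            raise ValueError("stim strength must be >= 0")


@dataclasses.dataclass(frozen=True)
class Perturbation:
    """A timed manipulation active on [t_start, t_end).

    kind = "clamp_variable": hold variable ``target`` at ``value``.
    kind = "set_parameter":  override parameter ``target`` with ``value``.
    kind = "remove_factin_decay": drop the -F decay term from the
    F-actin equation (``target``/``value`` unused).
    """

    kind: str
    t_start: float
    t_end: float
    target: str | None = None
    value: float | None = None

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError("perturbation requires t_start < t_end")
        if self.kind == "clamp_variable":
            if self.target not in _VAR_INDEX:
                raise ValueError(
                    f"clamp target must be one of {sorted(_VAR_INDEX)}"
                )
            if self.value is None:
                raise ValueError("clamp_variable requires a value")
        elif self.kind == "set_parameter":
            if self.target not in PARAM_NAMES:
                raise ValueError(f"unknown parameter {self.target!r}")
            if self.value is None:
                raise ValueError("set_parameter requires a value")
        elif self.kind != "remove_factin_decay":
            raise ValueError(f"unknown perturbation kind {self.kind!r}")


@dataclasses.dataclass(frozen=True)
class Protocol:
    """Stimulus schedule + perturbations + initial condition + horizon."""

    stim_segments: tuple[StimSegment, ...] = ()
    perturbations: tuple[Perturbation, ...] = ()
    t_end: float = DEFAULT_T_END
    initial: str | SystemState = DOWN

    def __post_init__(self) -> None:
        object.__setattr__(self, "stim_segments", tuple(self.stim_segments))
        object.__setattr__(self, "perturbations", tuple(self.perturbations))
        segs = sorted(self.stim_segments, key=lambda s: s.t_start)
        for a, b in zip(segs, segs[1:]):
            if b.t_start < a.t_end:
                raise ValueError("stim segments overlap")
        latest = max(
            [s.t_end for s in self.stim_segments]
            + [p.t_end for p in self.perturbations]
            + [0.0]
        )
        if self.t_end < latest:
            raise ValueError("t_end must cover all segments and perturbations")
        if isinstance(self.initial, str) and self.initial not in (UP, DOWN):
            raise ValueError("initial must be 'UP', 'DOWN' or a SystemState")

    def with_t_end(self, t_end: float) -> "Protocol":
        return dataclasses.replace(self, t_end=t_end)

    # -- JSON interchange ------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        initial: Any
        if isinstance(self.initial, SystemState):
            initial = dataclasses.asdict(self.initial)
        else:
            initial = self.initial
        return {
            "stim": [[s.t_start, s.t_end, s.strength] for s in self.stim_segments],
            "perturbations": [
                {k: v for k, v in dataclasses.asdict(p).items() if v is not None}
                for p in self.perturbations
            ],
            "initial": initial,
            "t_end": self.t_end,
        }

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "Protocol":
        initial = data.get("initial", DOWN)
        if isinstance(initial, dict):
            initial = SystemState(**initial)
        return cls(
            stim_segments=tuple(
                StimSegment(*seg) for seg in data.get("stim", [])
            ),
            perturbations=tuple(
                Perturbation(**p) for p in data.get("perturbations", [])
            ),
            t_end=float(data.get("t_end", DEFAULT_T_END)),
            initial=initial,
        )

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "Protocol":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclasses.dataclass(frozen=True)
class Trajectory:
    """Sampled states on a time grid, with the protocol that produced them."""

    times: np.ndarray
    states: np.ndarray  # shape (n, 4): columns P, F, R, EPSC
    protocol: Protocol
    params: ModelParams

    @property
    def p(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def f(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def r(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def epsc(self) -> np.ndarray:
        return self.states[:, 3]

    @property
    def final_state(self) -> SystemState:
        return SystemState.from_array(self.states[-1])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.times,
                "P": self.p,
                "FActin": self.f,
                "RNAactive": self.r,
                "EPSC": self.epsc,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        lines = ["time\tP\tFActin\tRNAactive\tEPSC"]
        for t, row in zip(self.times, self.states):
            lines.append("\t".join(repr(float(v)) for v in (t, *row)))
        Path(path).write_text("\n".join(lines) + "\n")

    @staticmethod
    def read_tsv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
        """Read back (times, states) from the TSV dialect of write_tsv."""
        rows = [
            line.split("\t")
            for line in Path(path).read_text().strip().splitlines()[1:]
        ]
        data = np.array(rows, dtype=float)
        return data[:, 0], data[:, 1:]


# -- initial conditions --------------------------------------------------


def initial_state(
    spec: str | SystemState, params: ModelParams
) -> SystemState:
    """Resolve UP/DOWN to the corresponding stable equilibrium at basal stim.

    The EPSC coordinate is set to its closed-form fixed point at the
    equilibrium P.  Raises ValueError when the requested attractor does
    not exist at the given parameters (e.g. UP below the lower fold).
    """
    if isinstance(spec, SystemState):
        return spec
    stable = [
        e for e in bifurcation.find_equilibria(params) if e.is_stable
    ]
    if spec == DOWN:
        pool = [e for e in stable if e.p <= P_THRESHOLD]
        if not pool:
            raise ValueError("no DOWN equilibrium exists at these parameters")
        eq = min(pool, key=lambda e: e.p)
    elif spec == UP:
        pool = [e for e in stable if e.p > P_THRESHOLD]
        if not pool:
            raise ValueError("no UP equilibrium exists at these parameters")
        eq = max(pool, key=lambda e: e.p)
    else:
        raise ValueError(f"unknown initial-state spec {spec!r}")
    return SystemState(eq.p, eq.f, eq.r, float(steady_epsc_of_p(eq.p, params)))


# -- the integrator ------------------------------------------------------


def _stim_at(protocol: Protocol, params: ModelParams, t: float) -> float:
    for seg in protocol.stim_segments:
        if seg.t_start <= t < seg.t_end:
            return seg.strength
    return params.stim_basal


def _active_perturbations(
    protocol: Protocol, t: float
) -> list[Perturbation]:
    return [p for p in protocol.perturbations if p.t_start <= t < p.t_end]


def _boundaries(protocol: Protocol) -> list[float]:
    pts = {0.0, float(protocol.t_end)}
    for seg in protocol.stim_segments:
        pts.update((seg.t_start, seg.t_end))
    for pert in protocol.perturbations:
        pts.update((pert.t_start, pert.t_end))
    return sorted(t for t in pts if 0.0 <= t <= protocol.t_end)


def simulate(
    protocol: Protocol,
    params: ModelParams | None = None,
    sample_dt: float = 1.0,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the model through a protocol, sampling every ``sample_dt``."""
    if params is None:
        params = ModelParams()
    if sample_dt <= 0:
        raise ValueError("sample_dt must be > 0")
    y = initial_state(protocol.initial, params).as_array()
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite initial state")

    grid = np.arange(0.0, protocol.t_end + 0.5 * sample_dt, sample_dt)
    if grid[-1] < protocol.t_end:
        grid = np.append(grid, protocol.t_end)
    out = np.empty((len(grid), 4))
    out[0] = y
    filled = 1

    boundaries = _boundaries(protocol)
    for t_a, t_b in zip(boundaries, boundaries[1:]):
        stim = _stim_at(protocol, params, t_a)
        active = _active_perturbations(protocol, t_a)
        p_eff = params
        clamps: dict[int, float] = {}
        no_factin_decay = False
        for pert in active:
            if pert.kind == "set_parameter":
                p_eff = p_eff.replace(**{pert.target: pert.value})
            elif pert.kind == "clamp_variable":
                clamps[_VAR_INDEX[pert.target]] = float(pert.value)
            else:
                no_factin_decay = True

        for idx, value in clamps.items():
            y[idx] = value

        def rhs_interval(t: float, yv: np.ndarray) -> np.ndarray:
            yv = yv.copy()
            for idx, value in clamps.items():
                yv[idx] = value
            dy = rhs(yv, p_eff, stim)
            if no_factin_decay:
                dy[1] = (p_eff.j2 + p_eff.j3 * yv[0]) * (1.0 - yv[1]) / p_eff.tau2
            for idx in clamps:
                dy[idx] = 0.0
            return dy

        i_lo = bisect.bisect_right(grid, t_a)
        i_hi = bisect.bisect_right(grid, t_b)
        t_eval = grid[i_lo:i_hi]
        sol = solve_ivp(
            rhs_interval,
            (t_a, t_b),
            y,
            method=method,
            t_eval=t_eval if len(t_eval) else None,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationError(
                f"integration failed near t = {sol.t[-1]:.6g} min: {sol.message}"
            )
        if len(t_eval):
            out[filled : filled + len(t_eval)] = sol.y.T
            filled += len(t_eval)
        y = sol.y[:, -1].copy()
        for idx, value in clamps.items():
            y[idx] = value

    out[filled - 1] = y  # exact interval endpoint at the final grid time
    return Trajectory(grid, out, protocol, params)


def classify_outcome(
    traj: Trajectory,
    params: ModelParams | None = None,
    p_threshold: float = P_THRESHOLD,
    relax_tol: float = RELAX_TOL,
) -> str:
    """UP/DOWN classification of a relaxed trajectory by its final P.

    Raises
    ------
    RelaxationError
        If |dP/dt| at the final sample exceeds ``relax_tol`` — rerun with
        a longer horizon (near-separatrix protocols relax slowly).
    """
    if params is None:
        params = traj.params
    t_end = float(traj.times[-1])
    stim = _stim_at(traj.protocol, params, t_end)
    if _active_perturbations(traj.protocol, t_end):
        raise RelaxationError("a perturbation is still active at t_end")
    dy = rhs(traj.states[-1], params, stim)
    if abs(dy[0]) > relax_tol:
        raise RelaxationError(
            f"|dP/dt| = {abs(dy[0]):.3g} at t_end; extend t_end and rerun"
        )
    p_final = float(traj.states[-1, 0])
    eqs = bifurcation.find_equilibria(params, stim)
    nearest = min(eqs, key=lambda e: abs(e.p - p_final))
    if not nearest.is_stable and abs(nearest.p - p_final) < 1e-6:
        raise AmbiguousOutcomeError(
            f"final P = {p_final:.6g} sits on the unstable saddle"
        )
    return UP if p_final > p_threshold else DOWN
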