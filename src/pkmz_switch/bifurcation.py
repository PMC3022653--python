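"""Equilibria, stability, fold detection and two-parameter fold curves.

Every equilibrium of the three-variable system has its F and R
coordinates slaved to P through the closed-form steady-state maps, so
all equilibria are roots on [0, 1] of the scalar residual

    g(p) = j1 * R*(p) * (1 - p) - p.

Equilibrium finding therefore reduces to exhaustive sign-change
bracketing of g on a fine grid followed by root polishing — a scheme
that cannot lose branches, unlike arclength continuation.  Stability is
classified from the eigenvalues of the full 3x3 Jacobian (the sign of
g'(p) serves as an independent cross-check; both agree because the
(F, R) sub-dynamics are unconditionally stable at fixed P).

One-parameter sweeps detect saddle-node (fold) bifurcations as the
parameter values where the equilibrium count changes 1 <-> 3, refined by
bisection.  The two-parameter sweep stacks one-parameter fold locations
into the SN1/SN2 fold branches and locates the cusp where they meet.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from .dynamics import steady_f_of_p, steady_r_of_p
from .params import PARAM_NAMES, ModelParams

__all__ = [
    "Equilibrium",
    "BifurcationBranch",
    "FoldCurve",
    "scalar_residual",
    "jacobian",
    "find_equilibria",
    "bifurcation_1d",
    "slice_1d",
    "mrna_bifurcation",
    "fold_curve_2d",
    "hysteresis_sweep",
]

#: p-grid density for the exhaustive root scan; resolves the closest
#: root pairs near folds, after which brentq restores full precision.
DEFAULT_P_GRID = 10_000


def scalar_residual(p, params: ModelParams, stim: float):
    """g(p) whose roots on [0, 1] are the equilibrium P values."""
    p = np.asarray(p, dtype=float)
    return params.j1 * steady_r_of_p(p, stim, params) * (1.0 - p) - p


def jacobian(p: float, f: float, r: float, params: ModelParams, stim: float) -> np.ndarray:
    """Analytic 3x3 Jacobian of (dP/dt, dF/dt, dR/dt) at a point."""
    m = params.mrna_total
    row_p = [
        (-params.j1 * r - 1.0) / params.tau1,
        0.0,
        params.j1 * (1.0 - p) / params.tau1,
    ]
    row_f = [
        params.j3 * (1.0 - f) / params.tau2,
        (-(params.j2 + params.j3 * p) - 1.0) / params.tau2,
        0.0,
    ]
    row_r = [
        params.j4 * f * (m - r) / params.tau3,
        params.j4 * (p + stim) * (m - r) / params.tau3,
        (-params.j4 * f * (p + stim) - 1.0) / params.tau3,
    ]
    return np.array([row_p, row_f, row_r])


@dataclasses.dataclass(frozen=True)
class Equilibrium:
    """A fixed point of the (P, F, R) subsystem with its stability."""

    p: float
    f: float
    r: float
    stability: str  # "stable" | "unstable"
    eigenvalues: tuple[complex, complex, complex]

    @property
    def is_stable(self) -> bool:
        return self.stability == "stable"


def _lift(p: float, params: ModelParams, stim: float) -> Equilibrium:
    f = float(steady_f_of_p(p, params))
    r = float(steady_r_of_p(p, stim, params))
    eig = np.linalg.eigvals(jacobian(p, f, r, params, stim))
    stability = "stable" if float(np.max(eig.real)) < 0.0 else "unstable"
    return Equilibrium(p, f, r, stability, tuple(complex(v) for v in eig))


def find_equilibria(
    params: ModelParams,
    stim: float | None = None,
    n_grid: int = DEFAULT_P_GRID,
) -> list[Equilibrium]:
    """All equilibria at fixed stimulus, sorted by P.

    ``stim`` defaults to the basal stimulus; every equilibrium P lies in
    [0, 1) because the synthesis term carries a (1 - P) factor.
    """
    if stim is None:
        stim = params.stim_basal
    grid = np.linspace(0.0, 1.0, n_grid)
    g = scalar_residual(grid, params, stim)
    roots: list[float] = []
    if g[0] == 0.0:
        roots.append(0.0)
    sign = np.sign(g)
    for i in np.flatnonzero(sign[:-1] * sign[1:] < 0):
        root = brentq(
            lambda p: float(scalar_residual(p, params, stim)),
            grid[i],
            grid[i + 1],
            xtol=1e-15,
            rtol=8.9e-16,
        )
        roots.append(float(root))
    # exact grid-point roots other than the origin
    for i in np.flatnonzero(g[1:] == 0.0):
        p = float(grid[i + 1])
        if not any(abs(p - r) < 1e-12 for r in roots):
            roots.append(p)
    return [_lift(p, params, stim) for p in sorted(roots)]


# -- one-parameter sweeps ------------------------------------------------


@dataclasses.dataclass(frozen=True)
class BifurcationBranch:
    """Equilibria traced against one parameter, with detected folds.

    ``samples`` holds (parameter value, Equilibrium) pairs in sweep
    order, one pair per equilibrium at each swept value.  ``fold_points``
    are the refined parameter values where the equilibrium count changes
    between 1 and 3 (saddle-node bifurcations), sorted ascending.
    """

    parameter: str
    samples: tuple[tuple[float, Equilibrium], ...]
    fold_points: tuple[float, ...]

    def equilibria_at(self, value: float) -> list[Equilibrium]:
        return [eq for v, eq in self.samples if v == value]

    def write_tsv(self, path: str | Path, sidecar: str | Path | None = None,
                  cusp: tuple[float, float] | None = None) -> None:
        lines = ["param\tp\tf\tr\tstability"]
        for value, eq in self.samples:
            lines.append(
                f"{float(value)!r}\t{float(eq.p)!r}\t{float(eq.f)!r}"
                f"\t{float(eq.r)!r}\t{eq.stability}"
            )
        Path(path).write_text("\n".join(lines) + "\n")
        if sidecar is not None:
            payload = {
                "param_name": self.parameter,
                "folds": list(self.fold_points),
                "cusp": list(cusp) if cusp is not None else None,
            }
            Path(sidecar).write_text(json.dumps(payload, indent=2) + "\n")


def _make_setter(param_name: str) -> Callable[[ModelParams, float], ModelParams]:
    if param_name not in PARAM_NAMES:
        raise KeyError(f"unknown parameter {param_name!r}; valid: {PARAM_NAMES}")
    return lambda params, value: params.replace(**{param_name: value})


def _count(params: ModelParams, stim: float | None, n_grid: int) -> int:
    return len(find_equilibria(params, stim, n_grid))


def _refine_fold(
    setter: Callable[[ModelParams, float], ModelParams],
    params: ModelParams,
    lo: float,
    hi: float,
    stim: float | None,
    n_grid: int,
    tol: float,
) -> float:
    """Bisect the parameter on an equilibrium-count change to ``tol``."""
    count_lo = _count(setter(params, lo), stim, n_grid)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _count(setter(params, mid), stim, n_grid) == count_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def bifurcation_1d(
    param_name: str,
    param_min: float,
    param_max: float,
    params: ModelParams | None = None,
    n_steps: int = 400,
    stim: float | None = None,
    n_grid: int = DEFAULT_P_GRID,
    fold_tol: float = 1e-4,
    setter: Callable[[ModelParams, float], ModelParams] | None = None,
) -> BifurcationBranch:
    """Sweep one parameter, collecting equilibria and saddle-node folds.

    Folds are detected as grid intervals where the equilibrium count
    changes and refined by bisection to ``fold_tol`` (absolute, in
    parameter units).
    """
    if params is None:
        params = ModelParams()
    if not (math.isfinite(param_min) and math.isfinite(param_max)):
        raise ValueError("parameter range must be finite")
    if param_min >= param_max:
        raise ValueError("param_min must be < param_max")
    if setter is None:
        setter = _make_setter(param_name)
    values = np.linspace(param_min, param_max, n_steps)
    samples: list[tuple[float, Equilibrium]] = []
    counts: list[int] = []
    for value in values:
        eqs = find_equilibria(setter(params, float(value)), stim, n_grid)
        counts.append(len(eqs))
        samples.extend((float(value), eq) for eq in eqs)
    folds = [
        _refine_fold(setter, params, float(values[i]), float(values[i + 1]),
                     stim, n_grid, fold_tol)
        for i in range(len(values) - 1)
        if counts[i] != counts[i + 1]
    ]
    return BifurcationBranch(param_name, tuple(samples), tuple(sorted(folds)))


def slice_1d(
    slope_a: float,
    j2_min: float,
    j2_max: float,
    params: ModelParams | None = None,
    n_steps: int = 400,
    **kwargs,
) -> BifurcationBranch:
    """Sweep j2 with j3 slaved to slope_a * j2 (an F-actin-stabilizer axis).

    This slices the two-parameter (j2, j3) fold surface along the plane
    j3 = a * j2; ``slope_a`` = 0 pins j3 to zero (pure PKMzeta-independent
    polymerization axis).
    """
    if slope_a < 0:
        raise ValueError("slope_a must be >= 0")

    def setter(p: ModelParams, value: float) -> ModelParams:
        return p.replace(j2=value, j3=slope_a * value)

    return bifurcation_1d(
        "j2(j3=a*j2)", j2_min, j2_max, params, n_steps, setter=setter, **kwargs
    )


def mrna_bifurcation(
    m_min: float,
    m_max: float,
    params: ModelParams | None = None,
    n_steps: int = 400,
    **kwargs,
) -> BifurcationBranch:
    """Sweep the total mRNA pool M as the bifurcation parameter."""
    if m_min < 0:
        raise ValueError("mRNA pool must be >= 0")
    return bifurcation_1d("mrna_total", m_min, m_max, params, n_steps, **kwargs)


# -- two-parameter fold curve --------------------------------------------


@dataclasses.dataclass(frozen=True)
class FoldCurve:
    """The two saddle-node branches in a parameter plane, plus the cusp.

    ``sn1`` holds (param_a, param_b) points of the upper fold in
    param_a (where the DOWN state annihilates); ``sn2`` the lower fold
    (where the UP state is born).  ``cusp`` is the point where the two
    branches meet tangentially, or None if the scanned box shows no
    bistability boundary.
    """

    param_a: str
    param_b: str
    sn1: tuple[tuple[float, float], ...]
    sn2: tuple[tuple[float, float], ...]
    cusp: tuple[float, float] | None

    def write_tsv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        lines = [f"branch\t{self.param_a}\t{self.param_b}"]
        for name, pts in (("SN1", self.sn1), ("SN2", self.sn2)):
            for a, b in pts:
                lines.append(f"{name}\t{float(a)!r}\t{float(b)!r}")
        Path(path).write_text("\n".join(lines) + "\n")
        if sidecar is not None:
            payload = {
                "param_a": self.param_a,
                "param_b": self.param_b,
                "cusp": list(self.cusp) if self.cusp is not None else None,
            }
            Path(sidecar).write_text(json.dumps(payload, indent=2) + "\n")


def _folds_along_a(
    param_a: str,
    a_range: tuple[float, float],
    param_b: str,
    b_value: float,
    params: ModelParams,
    n_steps: int,
    stim: float | None,
    n_grid: int,
) -> list[float]:
    base = params.replace(**{param_b: b_value})
    branch = bifurcation_1d(
        param_a, a_range[0], a_range[1], base, n_steps, stim=stim, n_grid=n_grid
    )
    return list(branch.fold_points)


def fold_curve_2d(
    param_a: str,
    param_b: str,
    a_range: tuple[float, float],
    b_range: tuple[float, float],
    params: ModelParams | None = None,
    n_grid_b: int = 60,
    n_steps_a: int = 200,
    stim: float | None = None,
    n_grid: int = 2000,
    cusp_tol: float = 1e-3,
) -> FoldCurve:
    """Trace both saddle-node branches over a (param_a, param_b) box.

    For each param_b grid value a one-parameter sweep over param_a
    locates the folds; a two-fold slice contributes its lower fold to
    SN2 and its upper to SN1, a one-fold slice to whichever branch
    matches the equilibrium structure at the left edge.  The cusp is the
    param_b value where the bistable window in param_a collapses,
    refined by interval bisection to ``cusp_tol``.
    """
    if params is None:
        params = ModelParams()
    _make_setter(param_a), _make_setter(param_b)  # validate names
    b_values = np.linspace(b_range[0], b_range[1], n_grid_b)
    sn1: list[tuple[float, float]] = []
    sn2: list[tuple[float, float]] = []
    two_fold_bs: list[float] = []
    zero_fold_bs: list[float] = []
    for b in b_values:
        folds = _folds_along_a(
            param_a, a_range, param_b, float(b), params, n_steps_a, stim, n_grid
        )
        if len(folds) >= 2:
            sn2.append((folds[0], float(b)))
            sn1.append((folds[-1], float(b)))
            two_fold_bs.append(float(b))
        elif len(folds) == 1:
            # bistable at the left edge of the a-range -> the visible fold
            # is where the DOWN state annihilates (SN1); otherwise SN2
            left = params.replace(**{param_b: float(b), param_a: a_range[0]})
            if _count(left, stim, n_grid) == 3:
                sn1.append((folds[0], float(b)))
            else:
                sn2.append((folds[0], float(b)))
        else:
            zero_fold_bs.append(float(b))

    cusp = None
    if two_fold_bs and zero_fold_bs:
        # bracket the collapse of the bistable window along param_b
        lo_candidates = [b for b in zero_fold_bs if b < min(two_fold_bs)]
        if lo_candidates:
            lo, hi = max(lo_candidates), min(two_fold_bs)
            while hi - lo > cusp_tol:
                mid = 0.5 * (lo + hi)
                folds = _folds_along_a(
                    param_a, a_range, param_b, mid, params, n_steps_a, stim, n_grid
                )
                if len(folds) >= 2:
                    hi = mid
                else:
                    lo = mid
            folds = _folds_along_a(
                param_a, a_range, param_b, hi, params, n_steps_a, stim, n_grid
            )
            a_at_cusp = 0.5 * (folds[0] + folds[-1]) if len(folds) >= 2 else folds[0]
            cusp = (float(a_at_cusp), float(0.5 * (lo + hi)))
    return FoldCurve(param_a, param_b, tuple(sn1), tuple(sn2), cusp)


def hysteresis_sweep(
    param_name: str,
    values: Sequence[float],
    params: ModelParams | None = None,
    start: str = "lowest",
    setter: Callable[[ModelParams, float], ModelParams] | None = None,
    stim: float | None = None,
    n_grid: int = DEFAULT_P_GRID,
) -> list[tuple[float, float]]:
    """Quasi-static sweep tracking the occupied stable state.

    Follows, at each parameter value in order, the stable equilibrium
    closest in P to the previously occupied one (the adiabatic limit of
    a slow parameter ramp).  Sweeping up through a fold and back exposes
    hysteresis: the return path stays on the other branch.  Returns
    (parameter value, occupied P) pairs.
    """
    if params is None:
        params = ModelParams()
    if setter is None:
        setter = _make_setter(param_name)
    values = list(values)
    stable0 = [e for e in find_equilibria(setter(params, values[0]), stim, n_grid)
               if e.is_stable]
    current = (min if start == "lowest" else max)(stable0, key=lambda e: e.p).p
    path: list[tuple[float, float]] = []
    for value in values:
        stable = [e for e in find_equilibria(setter(params, value), stim, n_grid)
                  if e.is_stable]
        current = min(stable, key=lambda e: abs(e.p - current)).p
        path.append((float(value), float(current)))
    return path
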