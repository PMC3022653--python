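"""Vector field of the PKMzeta network and its closed-form steady-state maps.

The network couples three variables by first-order kinetics:

    tau1 dP/dt = j1 * R * (1 - P) - P
    tau2 dF/dt = (j2 + j3 * P) * (1 - F) - F
    tau3 dR/dt = j4 * F * (P + Stim(t)) * (M - R) - R

with P = [PKMzeta] protein, F = F-actin fraction, R = translationally
active mRNA, and M the total mRNA pool (default 1).  Synaptic strength is
read out by a second-order EPSC equation:

    tau4 dE/dt = j5 * (E_up - E) * P^2 / P_up^2 - E + j6

At a fixed P, each of F, R and E relaxes to a closed-form value; these
maps reduce equilibrium finding to a scalar root problem and are exposed
here for reuse by the bifurcation suite.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .params import ModelParams

__all__ = [
    "SystemState",
    "Derivatives",
    "vector_field",
    "rhs",
    "steady_f_of_p",
    "steady_r_of_p",
    "steady_epsc_of_p",
]


@dataclasses.dataclass(frozen=True)
class SystemState:
    """The four dynamic variables: (P, F-actin, active mRNA, EPSC)."""

    p: float
    f: float
    r: float
    epsc: float

    def as_array(self) -> np.ndarray:
        return np.array([self.p, self.f, self.r, self.epsc], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "SystemState":
        return cls(float(y[0]), float(y[1]), float(y[2]), float(y[3]))


@dataclasses.dataclass(frozen=True)
class Derivatives:
    """Time derivatives of the four variables, per minute."""

    dp_dt: float
    df_dt: float
    dr_dt: float
    depsc_dt: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.dp_dt, self.df_dt, self.dr_dt, self.depsc_dt], dtype=float
        )


def rhs(y: np.ndarray, params: ModelParams, stim: float) -> np.ndarray:
    """Raw right-hand side on a length-4 array (p, f, r, epsc)."""
    p, f, r, epsc = y
    dp = (params.j1 * r * (1.0 - p) - p) / params.tau1
    df = ((params.j2 + params.j3 * p) * (1.0 - f) - f) / params.tau2
    dr = (
        params.j4 * f * (p + stim) * (params.mrna_total - r) - r
    ) / params.tau3
    rho = p * p / (params.p_up * params.p_up)
    de = (params.j5 * (params.epsc_up - epsc) * rho - epsc + params.j6) / params.tau4
    return np.array([dp, df, dr, de])


def vector_field(
    state: SystemState, params: ModelParams, stim: float
) -> Derivatives:
    """Evaluate the model equations at a state under stimulus ``stim``.

    Raises
    ------
    ValueError
        If any state component or the stimulus is non-finite, or the
        stimulus is negative.
    """
    y = state.as_array()
    if not np.all(np.isfinite(y)):
        raise ValueError(f"non-finite state: {state}")
    if not np.isfinite(stim) or stim < 0:
        raise ValueError(f"stim must be finite and >= 0, got {stim!r}")
    return Derivatives(*rhs(y, params, stim))


def steady_f_of_p(p, params: ModelParams):
    """F-actin equilibrium as a function of P: (j2+j3*P)/(1+j2+j3*P)."""
    drive = params.j2 + params.j3 * np.asarray(p, dtype=float)
    return drive / (1.0 + drive)


def steady_r_of_p(p, stim: float, params: ModelParams):
    """Active-mRNA equilibrium as a function of P at fixed stimulus.

    With q = j4 * F*(P) * (P + stim), the fixed point is q*M/(1+q).
    """
    p = np.asarray(p, dtype=float)
    q = params.j4 * steady_f_of_p(p, params) * (p + stim)
    return q * params.mrna_total / (1.0 + q)


def steady_epsc_of_p(p, params: ModelParams):
    """EPSC equilibrium as a function of P.

    With rho = P^2/P_up^2, the fixed point is (j6 + j5*E_up*rho)/(1 + j5*rho).
    """
    p = np.asarray(p, dtype=float)
    rho = p * p / (params.p_up * params.p_up)
    return (params.j6 + params.j5 * params.epsc_up * rho) / (1.0 + params.j5 * rho)
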