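"""Optional matplotlib helpers (requires the ``plot`` extra)."""

from __future__ import annotations

from .bifurcation import BifurcationBranch
from .simulate import Trajectory

__all__ = ["plot_trajectory", "plot_branch"]


def plot_trajectory(traj: Trajectory, ax=None, variables=("p", "epsc")):
    """Time courses of the requested variables on one axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    labels = {"p": "[PKM$\\zeta$]", "f": "[FActin]",
              "r": "[RNA$_{active}$]", "epsc": "EPSC"}
    for var in variables:
        ax.plot(traj.times, getattr(traj, var), label=labels[var])
    ax.set_xlabel("time (min)")
    ax.legend()
    return ax


def plot_branch(branch: BifurcationBranch, ax=None):
    """Steady-state P against the swept parameter; folds marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for stability, marker in (("stable", "."), ("unstable", "x")):
        pts = [(v, eq.p) for v, eq in branch.samples if eq.stability == stability]
        if pts:
            xs, ys = zip(*pts)
            ax.plot(xs, ys, marker, ms=3, label=stability)
    for fold in branch.fold_points:
        ax.axvline(fold, color="gray", lw=0.5, ls="--")
    ax.set_xlabel(branch.parameter)
    ax.set_ylabel("steady-state [PKM$\\zeta$]")
    ax.legend()
    return ax
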