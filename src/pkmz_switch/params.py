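"""Model parameters for the PKMzeta-network bistable switch.

The model has four time constants (minutes) and six dimensionless rate
constants, plus the basal stimulus level, the EPSC readout constants and
the total mRNA pool size.  Defaults are the published reference values
for hippocampal late-phase LTP.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Any

__all__ = ["ModelParams", "PARAM_NAMES"]

#: canonical serialization order / set of recognised keys
PARAM_NAMES = (
    "tau1", "tau2", "tau3", "tau4",
    "j1", "j2", "j3", "j4", "j5", "j6",
    "stim_basal", "epsc_up", "p_up", "mrna_total",
)


@dataclasses.dataclass(frozen=True)
class ModelParams:
    """Rate constants, time constants and structural constants of the model.

    Attributes
    ----------
    tau1, tau2, tau3, tau4 : float
        Time constants (minutes) of PKMzeta turnover, actin
        polymerization, mRNA recruitment, and the EPSC readout.
    j1 : float
        PKMzeta synthesis rate relative to its decay rate.
    j2, j3 : float
        PKMzeta-independent and PKMzeta-dependent actin polymerization
        rates relative to depolymerization.
    j4 : float
        Rate of mRNA recruitment into the translational machinery
        relative to detachment.
    j5, j6 : float
        EPSC drive gain and basal EPSC level.
    stim_basal : float
        Background activity of the upstream kinases (CaMKII/PKC/MAPK)
        collapsed into Stim(t); applied whenever no stimulus segment is
        active, including during steady-state analyses.
    epsc_up : float
        EPSC amplitude of the potentiated (UP) state.
    p_up : float
        Reference UP-state PKMzeta concentration in the EPSC drive term.
        Held fixed at the default-parameter UP value; it is a constant of
        the readout, not recomputed per parameter set.
    mrna_total : float
        Total PKMzeta mRNA pool M.  The recruitment equation conserves
        this pool: active mRNA relaxes toward M, never past it.
    """

    tau1: float = 1500.0
    tau2: float = 0.5
    tau3: float = 60.0
    tau4: float = 100.0
    j1: float = 80.0
    j2: float = 0.05
    j3: float = 0.5
    j4: float = 0.16
    j5: float = 14.0
    j6: float = 0.89
    stim_basal: float = 0.003
    epsc_up: float = 2.0
    p_up: float = 0.72
    mrna_total: float = 1.0

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value!r}")
        for name in ("tau1", "tau2", "tau3", "tau4"):
            if getattr(self, name) <= 0:
                raise ValueError(f"time constant {name} must be > 0")
        for name in ("j1", "j2", "j3", "j4", "j5", "j6"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be >= 0")
        if self.stim_basal < 0:
            raise ValueError("stim_basal must be >= 0")
        if self.mrna_total < 0:
            raise ValueError("mrna_total must be >= 0")
        if self.p_up <= 0:
            raise ValueError("p_up must be > 0")

    def replace(self, **overrides: float) -> "ModelParams":
        """Return a copy with the given fields replaced (validated)."""
        unknown = set(overrides) - set(PARAM_NAMES)
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "ModelParams":
        """Build from a flat mapping; unknown keys are rejected."""
        unknown = set(data) - set(PARAM_NAMES)
        if unknown:
            raise KeyError(f"unknown parameter key(s): {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in data.items()})

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ModelParams":
        """Load from a JSON file path or a JSON string."""
        path = Path(source)
        try:
            exists = path.is_file()
        except OSError:  # e.g. embedded NUL in a JSON string
            exists = False
        text = path.read_text() if exists else str(source)
        return cls.from_dict(json.loads(text))
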