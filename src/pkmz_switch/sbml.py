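"""Export of the model as SBML Level 3 (rate-rule form).

The four dynamic quantities are encoded as non-constant parameters
governed by rate rules, the kinetic constants as constant parameters,
and Stim as a constant parameter fixed at its basal value (stimulus
schedules and perturbations are protocol-level concepts and are not
part of the exported model).
"""

from __future__ import annotations

from pathlib import Path

from .params import ModelParams

__all__ = ["to_sbml"]


def _m(expr) -> str:
    """Render a nested-tuple expression tree as content MathML.

    Trees are ("op", arg, ...) with ops plus/minus/times/divide/power,
    bare strings as symbol references and numbers as literals.
    """
    if isinstance(expr, str):
        return f"<ci> {expr} </ci>"
    if isinstance(expr, (int, float)):
        return f"<cn> {expr} </cn>"
    op, *args = expr
    body = "".join(_m(a) for a in args)
    return f"<apply><{op}/>{body}</apply>"


def _rate_rule(var: str, expr) -> str:
    return (
        f'      <rateRule variable="{var}">\n'
        '        <math xmlns="http://www.w3.org/1998/Math/MathML">\n'
        f"          {_m(expr)}\n"
        "        </math>\n"
        "      </rateRule>"
    )


def to_sbml(
    params: ModelParams | None = None,
    initial: dict[str, float] | None = None,
    path: str | Path | None = None,
    model_id: str = "pkmz_switch",
) -> str:
    """Serialize the model to an SBML L3V1 document string.

    ``initial`` maps variable names (P, FActin, RNAactive, EPSC) to
    initial values; unspecified variables start at the basal fixed
    point of the DOWN branch (all zero except EPSC = j6).
    """
    if params is None:
        params = ModelParams()
    init = {"P": 0.0, "FActin": 0.0, "RNAactive": 0.0, "EPSC": params.j6}
    if initial:
        unknown = set(initial) - set(init)
        if unknown:
            raise KeyError(f"unknown variable(s): {sorted(unknown)}")
        init.update(initial)

    constants = dict(params.to_dict(), Stim=params.stim_basal)
    param_lines = [
        f'      <parameter id="{name}" value="{value!r}" constant="true"/>'
        for name, value in constants.items()
    ]
    param_lines += [
        f'      <parameter id="{name}" value="{value!r}" constant="false"/>'
        for name, value in init.items()
    ]

    one_minus = lambda v: ("minus", 1.0, v)
    rules = [
        _rate_rule(
            "P",
            ("divide",
             ("minus", ("times", "j1", "RNAactive", one_minus("P")), "P"),
             "tau1"),
        ),
        _rate_rule(
            "FActin",
            ("divide",
             ("minus",
              ("times", ("plus", "j2", ("times", "j3", "P")),
               one_minus("FActin")),
              "FActin"),
             "tau2"),
        ),
        _rate_rule(
            "RNAactive",
            ("divide",
             ("minus",
              ("times", "j4", "FActin", ("plus", "P", "Stim"),
               ("minus", "mrna_total", "RNAactive")),
              "RNAactive"),
             "tau3"),
        ),
        _rate_rule(
            "EPSC",
            ("divide",
             ("plus",
              ("minus",
               ("divide",
                ("times", "j5", ("minus", "epsc_up", "EPSC"),
                 ("power", "P", 2)),
                ("power", "p_up", 2)),
               "EPSC"),
              "j6"),
             "tau4"),
        ),
    ]

    doc = (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        '<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" '
        'level="3" version="1">\n'
        f'  <model id="{model_id}" timeUnits="minute">\n'
        "    <listOfParameters>\n"
        + "\n".join(param_lines)
        + "\n    </listOfParameters>\n"
        "    <listOfRules>\n"
        + "\n".join(rules)
        + "\n    </listOfRules>\n"
        "  </model>\n"
        "</sbml>\n"
    )
    if path is not None:
        Path(path).write_text(doc)
    return doc
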