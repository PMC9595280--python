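"""Cardiac condition protocol: named disease/physiology sweeps.

Each condition modifies the baseline circulation in a prescribed way:

- ``reference``: healthy adult at rest (HR 70, CO 5 L/min).
- ``exercise``: CO stepped 5 -> 14 L/min in 3 L/min steps with HR
  interpolated linearly between (5 L/min, 70 bpm) and (14 L/min,
  130 bpm).
- ``aging``: ventricular passive stiffness (eed) and relaxation time
  constant (tau) both scaled by (1 + 0.02*step), step 1..6 (2%..12%).
- ``MR``/``TR``: mitral/tricuspid systolic leak, 8/10/12/14% of the
  valve area left open during ventricular contraction.
- ``MS``/``TS``: mitral/tricuspid opening area narrowed by
  50/60/70/80%.
- ``ASD``/``VSD``: atrial/ventricular septal orifice of 6/8/10/12 mm
  diameter.
- ``HFpEF``: grades I/II/III — tau +80% in all grades; eed +0%, +75%,
  +130% — applied to the left ventricle.

Mean arterial pressure is regulated to 91 mmHg in every condition;
CO and HR stay at 5 L/min and 70 bpm except during exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .hemodynamics import CirculationParams, ShuntSpec, rescale_timing

__all__ = [
    "ConditionConfig",
    "CONDITION_SWEEPS",
    "exercise_hr",
    "apply_condition",
]

#: valid severity steps per condition (0 = reference-like baseline)
CONDITION_SWEEPS = {
    "reference": [0],
    "exercise": [1, 2, 3],
    "aging": [1, 2, 3, 4, 5, 6],
    "MR": [1, 2, 3, 4],
    "TR": [1, 2, 3, 4],
    "MS": [1, 2, 3, 4],
    "TS": [1, 2, 3, 4],
    "ASD": [1, 2, 3, 4],
    "VSD": [1, 2, 3, 4],
    "HFpEF": [1, 2, 3],
}

_LEAK = {1: 0.08, 2: 0.10, 3: 0.12, 4: 0.14}
_STENOSIS = {1: 0.5, 2: 0.6, 3: 0.7, 4: 0.8}
_SHUNT_MM = {1: 6.0, 2: 8.0, 3: 10.0, 4: 12.0}
_HFPEF_EED = {1: 0.0, 2: 0.75, 3: 1.30}
_HFPEF_TAU = 0.80


def exercise_hr(co_target: float) -> float:
    """Heart rate (bpm) at a given CO target, linear 5->14 L/min maps 70->130 bpm."""
    return 70.0 + (co_target - 5.0) * (130.0 - 70.0) / (14.0 - 5.0)


@dataclass
class ConditionConfig:
    """A named cardiac condition with a severity step and operating point."""

    condition: str = "reference"
    severity_index: int = 0
    co_target: float = 5.0
    hr: float = 70.0
    map_target: float = 91.0

    def __post_init__(self) -> None:
        if self.condition not in CONDITION_SWEEPS:
            raise ValueError(f"unknown condition {self.condition!r}")
        sweep = CONDITION_SWEEPS[self.condition]
        if self.condition != "reference" and self.severity_index not in sweep:
            raise ValueError(
                f"severity {self.severity_index} outside protocol sweep "
                f"{sweep} for {self.condition}")
        if not (70.0 <= self.hr <= 130.0):
            raise ValueError("hr outside protocol range [70, 130] bpm")
        if not (5.0 <= self.co_target <= 14.0):
            raise ValueError("co_target outside protocol range [5, 14] L/min")

    @classmethod
    def make(cls, condition: str, severity_index: int = 0,
             co_target: float | None = None) -> "ConditionConfig":
        """Build a config with the protocol's HR/CO for the condition.

        ``exercise`` maps severity 1/2/3 to CO 8/11/14 L/min; any
        condition accepts an explicit ``co_target`` (exercise level)
        with HR interpolated accordingly.
        """
        if condition == "exercise" and co_target is None:
            co_target = {1: 8.0, 2: 11.0, 3: 14.0}[severity_index]
        co = 5.0 if co_target is None else float(co_target)
        return cls(condition=condition, severity_index=severity_index,
                   co_target=co, hr=exercise_hr(co))


def apply_condition(config: ConditionConfig,
                    params: CirculationParams) -> CirculationParams:
    """Return the baseline parameter set modified per the condition protocol.

    Structural changes only (valve leak/stenosis, shunt orifice,
    chamber stiffness/relaxation); the operating point (HR, CO target)
    travels in the config.  Reference and exercise leave the structure
    untouched.  Activation timing is rescaled to the config's HR.
    """
    p = replace(params)
    cond, sev = config.condition, config.severity_index
    if cond in ("reference", "exercise"):
        pass
    elif cond == "aging":
        f = 1.0 + 0.02 * sev
        p.lv = replace(p.lv, eed=p.lv.eed * f, tau=p.lv.tau * f)
        p.rv = replace(p.rv, eed=p.rv.eed * f, tau=p.rv.tau * f)
    elif cond == "MR":
        p.mv = replace(p.mv, leak_fraction=_LEAK[sev])
    elif cond == "TR":
        p.tv = replace(p.tv, leak_fraction=_LEAK[sev])
    elif cond == "MS":
        p.mv = replace(p.mv, stenosis_fraction=_STENOSIS[sev])
    elif cond == "TS":
        p.tv = replace(p.tv, stenosis_fraction=_STENOSIS[sev])
    elif cond == "ASD":
        p.shunt = ShuntSpec(location="atrial", diameter=_SHUNT_MM[sev])
    elif cond == "VSD":
        p.shunt = ShuntSpec(location="ventricular", diameter=_SHUNT_MM[sev])
    elif cond == "HFpEF":
        p.lv = replace(p.lv, eed=p.lv.eed * (1.0 + _HFPEF_EED[sev]),
                       tau=p.lv.tau * (1.0 + _HFPEF_TAU))
    else:  # pragma: no cover - guarded by ConditionConfig
        raise ValueError(f"unknown condition {cond!r}")
    return rescale_timing(p, config.hr)
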