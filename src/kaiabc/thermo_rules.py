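"""Temperature dependence of the model parameters.

Every elementary rate carries an Arrhenius-type factor
``s(dE; T, T0) = exp(-dE/(kB T) + dE/(kB T0))`` relative to the reference
temperature T0 = 30 C.  Three additional rules express the physical
hypotheses about which quantities do *not* follow the generic activation:

* Rule 1 -- thermal loosening of the CI-CII structural coupling: the
  reaction-structure coupling energies d3 and d4 are *divided* by
  s(dEf; T, T0), so higher temperature weakens the delayed negative
  feedback, enlarging amplitude and period and compensating the
  accelerated reactions.
* Rule 2 -- thermally activated KaiB fold switch: the KaiB binding rate
  carries the extra factor s(dE_gs_fs) and the unbinding rate the extra
  factor s(dE_fs_gs') on top of the generic s(dE0).
* Rule 3 -- temperature-insensitive ATPase: the hydrolysis frequency f_hyd
  and the inverse ADP lifetime 1/Delta_ADP0 are held fixed; without Rule 3
  they scale by s(dE0) like every other rate (or by s(dEa), s(dEb) when
  mutant-style ATPase activation energies are given).

The named combinations Case A (rules 1+2+3), B (1+3), C (1+2) and
D (2+3, dEf = 0) are available as presets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .model_core import ModelParameters

__all__ = [
    "KELVIN_OFFSET",
    "TemperatureModel",
    "arrhenius_factor",
    "effective_parameters",
    "case_preset",
]

KELVIN_OFFSET = 273.15

#: generic rate constants that always scale with the common activation
#: energy dE0 (the KaiB and ATPase rates are governed by Rules 2 and 3).
GENERIC_RATES = ("hA0", "fA0", "hAB", "fAB", "kp", "kdp")


def celsius_to_kelvin(T_celsius: float) -> float:
    return T_celsius + KELVIN_OFFSET


def arrhenius_factor(dE: float, T_kelvin: float, T0_kelvin: float) -> float:
    """s(dE; T, T0) = exp(-dE/(kB T) + dE/(kB T0)) with ``dE`` in kB*T0 units.

    Equals 1 at T = T0 or dE = 0 and increases with T for dE > 0.
    """
    if T_kelvin <= 0 or T0_kelvin <= 0:
        raise ValueError("temperatures must be positive (Kelvin)")
    return math.exp(dE * (1.0 - T0_kelvin / T_kelvin))


@dataclass
class TemperatureModel:
    """Temperature, reference temperature, rule flags and activation energies.

    Energies are in kB*T0 units.  ``dEa``/``dEb`` are optional mutant-style
    activation energies of the ADP release (1/Delta_ADP0) and the hydrolysis
    frequency; when set they override Rule 3 for the ATPase rates.
    """

    T_celsius: float = 30.0
    T0_celsius: float = 30.0
    rule1: bool = True
    rule2: bool = True
    rule3: bool = True
    dE0: float = 10.0        # common activation energy of the generic rates
    dEf: float = 7.0         # structural-fluctuation activation energy (Rule 1)
    dE_gs_fs: float = 10.0   # KaiB ground -> fold-switched activation (Rule 2)
    dE_fs_gs_p: float = 12.0  # reverse + binding energy, dE'_fs->gs (Rule 2)
    dEa: float = None        # optional: activation of 1/Delta_ADP0
    dEb: float = None        # optional: activation of f_hyd

    @property
    def T_kelvin(self) -> float:
        return celsius_to_kelvin(self.T_celsius)

    @property
    def T0_kelvin(self) -> float:
        return celsius_to_kelvin(self.T0_celsius)

    def at(self, T_celsius: float) -> "TemperatureModel":
        """The same rule set evaluated at another temperature."""
        return replace(self, T_celsius=T_celsius)

    def s(self, dE: float) -> float:
        return arrhenius_factor(dE, self.T_kelvin, self.T0_kelvin)


def effective_parameters(params: ModelParameters,
                         thermo: TemperatureModel) -> ModelParameters:
    """Parameter set at temperature ``thermo.T_celsius``.

    ``params`` is understood as defined at the reference temperature T0.
    """
    s0 = thermo.s(thermo.dE0)
    changes = {name: getattr(params, name) * s0 for name in GENERIC_RATES}

    # Rule 1: thermal attenuation of the structure-reaction coupling.
    if thermo.rule1:
        sf = thermo.s(thermo.dEf)
        changes["d3"] = params.d3 / sf
        changes["d4"] = params.d4 / sf

    # Rule 2: thermally activated KaiB fold switch on top of the generic
    # activation; without it KaiB kinetics follow the generic rates.
    if thermo.rule2:
        changes["hB0"] = params.hB0 * s0 * thermo.s(thermo.dE_gs_fs)
        changes["fB0"] = params.fB0 * s0 * thermo.s(thermo.dE_fs_gs_p)
    else:
        changes["hB0"] = params.hB0 * s0
        changes["fB0"] = params.fB0 * s0

    # Rule 3: temperature-insensitive ATPase (unless mutant-style
    # activation energies are given, which take precedence).
    if thermo.dEa is not None or thermo.dEb is not None:
        changes["inv_dADP0"] = params.inv_dADP0 * thermo.s(thermo.dEa or 0.0)
        changes["f_hyd"] = params.f_hyd * thermo.s(thermo.dEb or 0.0)
    elif not thermo.rule3:
        changes["inv_dADP0"] = params.inv_dADP0 * s0
        changes["f_hyd"] = params.f_hyd * s0

    return params.replace(**changes)


def case_preset(name: str, **overrides) -> TemperatureModel:
    """Named rule combinations of the temperature model.

    A = Rules 1+2+3; B = Rules 1+3 (KaiB fold energies zero); C = Rules 1+2
    (ATPase rates follow the generic activation); D = Rules 2+3 with dEf = 0
    (temperature-independent coupling).
    """
    presets = {
        "A": dict(rule1=True, rule2=True, rule3=True),
        "B": dict(rule1=True, rule2=False, rule3=True,
                  dE_gs_fs=0.0, dE_fs_gs_p=0.0),
        "C": dict(rule1=True, rule2=True, rule3=False),
        "D": dict(rule1=False, rule2=True, rule3=True, dEf=0.0),
    }
    key = name.strip().upper()
    if key not in presets:
        raise ValueError(f"unknown case {name!r}; expected one of A, B, C, D")
    kwargs = presets[key]
    kwargs.update(overrides)
    return TemperatureModel(**kwargs)
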