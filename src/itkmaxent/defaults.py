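"""Calibrated base parameters shared by the seven models.

The literature gives interaction strengths for PH domains and inositol
phosphates only in other cell types, so the base rate constants shipped here
come from the package's own calibration (:func:`itkmaxent.pipeline.calibrate`):
they are chosen so that the allosteric dimer model M3, at the moderate
stimulus (Itk0 = 100, PIP3_0 = 370, PIP2_0 = 17000 molecules), produces a
transient with peak time near 2 min, asymmetry ratio near 2, and amplitude in
the tens of molecules -- the population-level behavior measured for
PLCgamma1 phosphorylation.

Units: first-order rates per minute; second-order rates per molecule per
minute (counts convention, single well-mixed box).
"""

from __future__ import annotations

from .models import ALPHA_MODELS, ParameterSet

__all__ = ["BASE_ALPHA", "base_parameters", "DEFAULT_CALIBRATION_INIT"]

#: calibration stimulus (moderate dose): Itk0, PIP3_0, PIP2_0
DEFAULT_CALIBRATION_INIT = (100, 370, 17000)

#: default K_D ratio K_D_low / K_D_high for the allosteric dimer models
BASE_ALPHA = {"M1": 100.0, "M2": 100.0, "M3": 100.0, "M7": 25.0}

# Calibrated base rates (see pipeline.calibrate); the dimer feedback models
# share one set, the no-feedback and monomer models reuse its weak-affinity
# pair so that all models start from the same primary binding kinetics.
_K_ON_LOW = 8.0e-4
_K_OFF_LOW = 10.0
_K_ON_HIGH = 8.0e-3
_K_CAT = 6.0e-3
_K_REPLACE = 8.0e-3

_DIMER_FEEDBACK_RATES = {
    "k_on_low": _K_ON_LOW,
    "k_off_low": _K_OFF_LOW,
    "k_on_high": _K_ON_HIGH,
    "k_cat": _K_CAT,
}

_NO_FEEDBACK_RATES = {"k_on": _K_ON_LOW, "k_off": _K_OFF_LOW, "k_cat": _K_CAT}

# The monomer's single weak site needs a slower base off-rate than the
# dimer's for appreciable occupancy; 4/min puts its persistence (R in the
# tens) between the dimer feedback models and the no-feedback models.
_M4_RATES = {
    "k_on": _K_ON_LOW,
    "k_off": 4.0,
    "k_replace": _K_REPLACE,
    "k_cat": _K_CAT,
}


def base_parameters(model_id: str) -> ParameterSet:
    """Calibrated base :class:`ParameterSet` for one model."""
    if model_id in ALPHA_MODELS:
        return ParameterSet(rates=dict(_DIMER_FEEDBACK_RATES), alpha=BASE_ALPHA[model_id])
    if model_id == "M4":
        return ParameterSet(rates=dict(_M4_RATES))
    if model_id in ("M5", "M6"):
        return ParameterSet(rates=dict(_NO_FEEDBACK_RATES))
    raise ValueError(f"unknown model id {model_id!r}")
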