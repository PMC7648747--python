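"""Gestational dose adjustment: restore nonpregnant steady-state exposure.

Because sertraline kinetics are linear, the continuous dose that matches the
nonpregnant AUC24 at gestational age GA is

    dose(GA) = reference_dose * AUC24_nonpregnant / AUC24_pregnant(reference_dose)

The solver verifies this with one confirmatory simulation at the matched
dose, then rounds to a total achievable from commercial tablet strengths.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement

from .config import DrugParams, GestationalCoefficients, Physiology
from .model import Regimen, build_model_params, simulate
from .nca import nca

CONFIRMATION_TOLERANCE = 1e-3
DEFAULT_MAX_TABLETS = 3


@dataclass(frozen=True)
class DoseRecommendation:
    ga: float  # weeks
    reference_dose_mg: float
    continuous_dose_mg: float  # exact AUC-matching dose
    rounded_dose_mg: float  # nearest dose composable from tablet strengths
    achieved_auc_ratio: float  # AUC24 at rounded dose / nonpregnant AUC24


def round_to_strengths(
    continuous_mg: float,
    strengths: list[float],
    max_tablets: int = DEFAULT_MAX_TABLETS,
) -> float:
    """Nearest total achievable from at most ``max_tablets`` tablets.

    Ties round down — the conservative choice for fetal exposure.
    """
    if not strengths:
        raise ValueError("tablet strengths must be non-empty")
    achievable = {0.0}
    for k in range(1, max_tablets + 1):
        for combo in combinations_with_replacement(strengths, k):
            achievable.add(sum(combo))
    achievable.discard(0.0)
    return min(achievable, key=lambda d: (abs(d - continuous_mg), d))


def required_dose(
    drug: DrugParams,
    physiology: Physiology,
    coeffs: GestationalCoefficients,
    reference_dose_mg: float,
    ga: float,
    interval_h: float = 24.0,
    n_doses: int = 30,
    max_tablets: int = DEFAULT_MAX_TABLETS,
) -> DoseRecommendation:
    """Dose at gestational age ``ga`` matching the nonpregnant AUC24 of the
    reference dose, with a confirmatory simulation at the matched dose."""
    if not 0 <= ga <= 42:
        raise ValueError(f"ga must be in [0, 42], got {ga}")
    if reference_dose_mg <= 0:
        raise ValueError("reference dose must be > 0")

    reg_ref = Regimen(dose_mg=reference_dose_mg, interval_h=interval_h, n_doses=n_doses)
    params0 = build_model_params(drug, physiology, coeffs, 0.0)
    auc_ref = nca(simulate(params0, reg_ref)).auc24

    params_ga = build_model_params(drug, physiology, coeffs, ga)
    auc_ga = nca(simulate(params_ga, reg_ref)).auc24
    continuous = reference_dose_mg * auc_ref / auc_ga

    reg_matched = Regimen(dose_mg=continuous, interval_h=interval_h, n_doses=n_doses)
    auc_matched = nca(simulate(params_ga, reg_matched)).auc24
    ratio = auc_matched / auc_ref
    if abs(ratio - 1.0) > CONFIRMATION_TOLERANCE:
        raise RuntimeError(
            f"confirmatory simulation missed the nonpregnant exposure: "
            f"AUC ratio {ratio:.5f} (expected 1 +/- {CONFIRMATION_TOLERANCE})"
        )

    rounded = round_to_strengths(continuous, drug.tablet_strengths_mg, max_tablets)
    # dose linearity: rescaling the matched dose rescales AUC proportionally
    achieved = ratio * rounded / continuous
    return DoseRecommendation(
        ga=ga,
        reference_dose_mg=reference_dose_mg,
        continuous_dose_mg=continuous,
        rounded_dose_mg=rounded,
        achieved_auc_ratio=achieved,
    )
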