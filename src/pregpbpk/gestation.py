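"""Gestational-age scaling of physiology and plasma protein binding.

Pregnancy remodels the maternal system continuously with gestational age
(GA, weeks): body weight and cardiac output rise, plasma volume expands,
serum albumin falls (raising the unbound fraction of highly bound drugs),
a placental-fetal unit grows, and the activities of CYP3A4 and CYP2D6
increase. ``gestation_scale`` evaluates all of these at a fixed GA and
returns a physiology snapshot the PBPK engine can consume; within a
simulation the snapshot is held constant (quasi-steady gestation).
"""
from __future__ import annotations

from dataclasses import dataclass

from .config import CYP_ENZYMES, GestationalCoefficients, Physiology

#: Representative gestational ages (weeks) for trimesters 1-3 used in all
#: trimester-level summaries.
TRIMESTER_GA = {1: 7.0, 2: 20.0, 3: 34.0}


@dataclass(frozen=True)
class GestationalState:
    """Physiology evaluated at one gestational age (µg / L / h unit system)."""

    ga: float
    body_weight: float  # kg
    cardiac_output: float  # L/h
    fu: float  # fraction unbound in plasma
    volumes: dict[str, float]  # L per compartment
    flows: dict[str, float]  # L/h per compartment
    cyp_multipliers: dict[str, float]
    placental_fetal_volume: float  # L


def fu_at_ga(fu0: float, albumin_ratio: float) -> float:
    """Fraction unbound at a given relative albumin concentration.

    Binding to albumin is assumed linear and non-saturated, so the
    bound:unbound ratio scales with the albumin concentration:

        fu_preg = 1 / (1 + ((1 - fu0) / fu0) * albumin_ratio)

    ``albumin_ratio`` is pregnant/nonpregnant serum albumin; a falling
    albumin (ratio < 1) raises the unbound fraction.
    """
    if not 0 < fu0 < 1:
        raise ValueError(f"fu0 must be in (0, 1), got {fu0}")
    if not 0 < albumin_ratio <= 1.2:
        raise ValueError(f"albumin_ratio must be in (0, 1.2], got {albumin_ratio}")
    if albumin_ratio == 1.0:  # exact nonpregnant identity
        return fu0
    return 1.0 / (1.0 + (1.0 - fu0) / fu0 * albumin_ratio)


def gestation_scale(
    physiology: Physiology,
    coeffs: GestationalCoefficients,
    ga: float,
    fu0: float,
) -> GestationalState:
    """Evaluate the gestational physiology snapshot at ``ga`` weeks.

    Pregnancy-gained mass is routed by tissue type: the lumped
    placental-fetal volume plus other pregnancy-specific lean growth
    (uterus, breast, extracellular water) joins the richly perfused
    compartment, while maternal fat gain joins the slowly perfused
    compartment. Plasma volume is scaled by its expansion ratio. Gut and
    liver are left at their nonpregnant size. At GA = 0 the snapshot
    reproduces the nonpregnant parameter set exactly.
    """
    if ga < 0:
        raise ValueError(f"gestational age must be >= 0, got {ga}")

    bw0 = physiology.body_weight_kg
    co0 = physiology.cardiac_output_L_h
    gain = coeffs.body_weight_gain_kg(ga)
    body_weight = bw0 + gain
    cardiac_output = co0 * coeffs.cardiac_output_ratio(ga)

    vols0 = {k: f * bw0 for k, f in physiology.fractional_volumes.items()}
    v_pf = coeffs.placental_fetal_volume_L(ga)
    fat = coeffs.fat_gain_kg(ga)
    d_plasma = vols0["plasma"] * (coeffs.plasma_volume_ratio(ga) - 1.0)
    # lean pregnancy-specific growth beyond placenta/fetus, fat and plasma
    lean_rest = max(0.0, gain - fat - d_plasma - v_pf)
    volumes = {
        "plasma": vols0["plasma"] + d_plasma,
        "gut": vols0["gut"],
        "liver": vols0["liver"],
        "richly_perfused": vols0["richly_perfused"] + v_pf + lean_rest,
        "slowly_perfused": vols0["slowly_perfused"] + fat,
    }
    flows = {k: f * cardiac_output for k, f in physiology.fractional_flows.items()}
    cyp_multipliers = {e: coeffs.cyp_multiplier(e, ga) for e in CYP_ENZYMES}
    fu = fu_at_ga(fu0, coeffs.albumin_ratio(ga))
    return GestationalState(
        ga=ga,
        body_weight=body_weight,
        cardiac_output=cardiac_output,
        fu=fu,
        volumes=volumes,
        flows=flows,
        cyp_multipliers=cyp_multipliers,
        placental_fetal_volume=v_pf,
    )
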