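"""In vitro-in vivo extrapolation (IVIVE) of CYP-mediated hepatic clearance.

Recombinant-enzyme kinetics are scaled to whole-liver unbound intrinsic
clearance in four steps: (1) in vitro intrinsic clearance per pmol enzyme as
Vmax/S corrected for microsomal binding, (2) conversion to liver-microsome
equivalents with an inter-system extrapolation factor (ISEF), (3) scaling by
mean hepatic enzyme abundance (pmol/mg microsomal protein), and (4) organ
scaling with MPPGL (mg microsomal protein per g liver) and liver mass. The
five per-enzyme clearances sum to the total hepatic intrinsic clearance;
their shares (fm) drive how gestational changes in individual CYP activities
propagate to the total.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .config import CYP_ENZYMES, DrugParams, Physiology
from .gestation import GestationalState

_UL_MIN_TO_L_H = 60.0 / 1.0e6


@dataclass(frozen=True)
class HepaticClearance:
    """Per-enzyme and total in vivo unbound hepatic intrinsic clearance (L/h)."""

    per_enzyme: dict[str, float]
    total: float = field(init=False)
    fm: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        total = sum(self.per_enzyme.values())
        if total <= 0:
            raise ValueError("total intrinsic clearance must be positive")
        object.__setattr__(self, "total", total)
        object.__setattr__(self, "fm", {e: v / total for e, v in self.per_enzyme.items()})


def clint_recombinant(vmax: float, s: float, fu_mic: float = 1.0) -> float:
    """In vitro intrinsic clearance of one recombinant CYP (µL/min/pmol).

    Computed as Vmax (pmol/min/pmol CYP) divided by the incubation substrate
    concentration (µM), corrected for the fraction unbound in the microsomal
    incubation.
    """
    if s <= 0:
        raise ValueError(f"substrate concentration must be > 0, got {s}")
    if vmax <= 0 or not 0 < fu_mic <= 1:
        raise ValueError("vmax must be > 0 and fu_mic in (0, 1]")
    return (vmax / s) / fu_mic


def scale_to_liver(drug: DrugParams, physiology: Physiology) -> HepaticClearance:
    """Scale per-CYP in vitro kinetics to whole-liver intrinsic clearance.

    Per enzyme: CLint_vivo = (Vmax/S/fu_mic) * ISEF * abundance * MPPGL *
    liver mass, converted to L/h. All five sertraline-metabolizing CYPs must
    be present in the drug configuration.
    """
    missing = set(CYP_ENZYMES) - set(drug.cyp_kinetics)
    if missing:
        raise ValueError(f"drug configuration missing CYP enzymes: {sorted(missing)}")
    per_enzyme = {}
    for enzyme in CYP_ENZYMES:
        kin = drug.cyp_kinetics[enzyme]
        clint_ul_min_pmol = clint_recombinant(
            kin.vmax_pmol_min_pmol, drug.substrate_conc_um, drug.fu_mic
        )
        ul_min = (
            clint_ul_min_pmol
            * kin.isef
            * kin.abundance_pmol_mg
            * physiology.mppgl_mg_g
            * physiology.liver_mass_g
        )
        per_enzyme[enzyme] = ul_min * _UL_MIN_TO_L_H
    return HepaticClearance(per_enzyme=per_enzyme)


def clint_at_ga(base: HepaticClearance, state: GestationalState) -> HepaticClearance:
    """Gestationally scaled hepatic intrinsic clearance.

    Each enzyme's clearance is multiplied by its activity multiplier at the
    snapshot's gestational age; enzymes without gestational data keep a
    multiplier of 1. The total therefore scales as sum(fm_e * m_e(GA)).
    """
    per_enzyme = {
        e: v * state.cyp_multipliers.get(e, 1.0) for e, v in base.per_enzyme.items()
    }
    return HepaticClearance(per_enzyme=per_enzyme)
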