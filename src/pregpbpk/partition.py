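"""Tissue:plasma partition coefficients by the tissue-composition method.

For a highly lipophilic compound the equilibrium tissue:plasma concentration
ratio is predicted from the neutral-lipid, phospholipid and water content of
tissue and plasma:

    Kp = [P*(Vnl_t + 0.3*Vph_t) + (Vw_t + 0.7*Vph_t)]
         / [P*(Vnl_p + 0.3*Vph_p) + (Vw_p + 0.7*Vph_p)] * fu_p / fu_t

with P = 10^logP. Phospholipid partitions 30% like neutral lipid and 70%
like water. Tissue binding uses the conventional estimate
fu_t = 1 / (1 + 0.5*(1 - fu_p)/fu_p) for all tissues except adipose, where
fu_t = 1. Individual-tissue predictions are volume-lumped into the model's
gut / liver / richly perfused / slowly perfused compartments and multiplied
by per-compartment adjustment factors fitted once against the nonpregnant
calibration profile.

logP (not logD) is used with no ionization correction, mirroring the use of
logP and pKa as the only lipophilicity inputs; this is a documented
simplification for an ionizable base.
"""
from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class TissueComposition:
    """Volume fractions of neutral lipid, phospholipid and water."""

    neutral_lipid: float
    phospholipid: float
    water: float

    def __post_init__(self) -> None:
        for name, v in (
            ("neutral_lipid", self.neutral_lipid),
            ("phospholipid", self.phospholipid),
            ("water", self.water),
        ):
            if not 0 <= v <= 1:
                raise ValueError(f"{name} fraction must be in [0, 1], got {v}")
        if self.neutral_lipid + self.phospholipid + self.water > 1 + 1e-9:
            raise ValueError("lipid + water fractions exceed 1")


# Standard tissue composition table (volume fractions) for the reference
# adult human, as used with the tissue-composition partitioning method.
TISSUE_COMPOSITION: dict[str, TissueComposition] = {
    "plasma": TissueComposition(0.0023, 0.0013, 0.945),
    "adipose": TissueComposition(0.79, 0.002, 0.18),
    "bone": TissueComposition(0.074, 0.0011, 0.439),
    "brain": TissueComposition(0.051, 0.0565, 0.77),
    "gut": TissueComposition(0.0487, 0.0163, 0.718),
    "heart": TissueComposition(0.0115, 0.0166, 0.758),
    "kidney": TissueComposition(0.0207, 0.0162, 0.783),
    "liver": TissueComposition(0.0348, 0.0252, 0.751),
    "lung": TissueComposition(0.003, 0.009, 0.811),
    "muscle": TissueComposition(0.0238, 0.0072, 0.76),
    "skin": TissueComposition(0.0284, 0.0111, 0.718),
    "spleen": TissueComposition(0.0201, 0.0198, 0.788),
}

# Reference-female organ volumes (L) used as lumping weights.
RICHLY_PERFUSED_TISSUES = {"brain": 1.3, "heart": 0.25, "kidney": 0.275, "lung": 0.95, "spleen": 0.13}
SLOWLY_PERFUSED_TISSUES = {"muscle": 17.5, "skin": 2.3, "adipose": 19.0, "bone": 3.2}


@dataclass(frozen=True)
class PartitionSet:
    """Per-compartment Kp values with their calibration adjustment factors."""

    kp: dict[str, float]
    adjustment: dict[str, float]

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.kp.values()):
            raise ValueError("all Kp values must be > 0")


def _tissue_fu(fu_p: float, tissue: str) -> float:
    if tissue == "adipose":
        return 1.0
    return 1.0 / (1.0 + 0.5 * (1.0 - fu_p) / fu_p)


def kp_poulin_haddad(
    logp: float,
    fu0: float,
    composition: dict[str, TissueComposition] | None = None,
    tissue: str = "muscle",
    fu_tissue: float | None = None,
) -> float:
    """Tissue:plasma partition coefficient for one tissue (dimensionless).

    ``fu_tissue`` overrides the conventional tissue-binding estimate
    (useful for oracle checks); by default adipose uses fu_t = 1 and all
    other tissues the half-plasma-binding convention.
    """
    comp = TISSUE_COMPOSITION if composition is None else composition
    if tissue not in comp:
        raise KeyError(f"no composition defined for tissue {tissue!r}")
    if "plasma" not in comp:
        raise KeyError("composition table must define 'plasma'")
    p = 10.0**logp
    t, pl = comp[tissue], comp["plasma"]
    num = p * (t.neutral_lipid + 0.3 * t.phospholipid) + (t.water + 0.7 * t.phospholipid)
    den = p * (pl.neutral_lipid + 0.3 * pl.phospholipid) + (pl.water + 0.7 * pl.phospholipid)
    fu_t = _tissue_fu(fu0, tissue) if fu_tissue is None else fu_tissue
    return num / den * fu0 / fu_t


def lumped_kp(kp_by_tissue: dict[str, float], volumes: dict[str, float]) -> float:
    """Volume-weighted aggregate Kp of a lumped compartment.

    Preserves the total partitioned amount: sum(Kp_i * V_i) = Kp_lump * V_lump.
    """
    total_v = sum(volumes.values())
    return sum(kp_by_tissue[t] * v for t, v in volumes.items()) / total_v


def build_partition_set(
    logp: float,
    fu0: float,
    adjustment: dict[str, float] | None = None,
) -> PartitionSet:
    """Raw lumped partition coefficients for the model's four tissue
    compartments, optionally multiplied by calibration adjustment factors."""
    kp_tissue = {t: kp_poulin_haddad(logp, fu0, tissue=t) for t in TISSUE_COMPOSITION if t != "plasma"}
    kp = {
        "gut": kp_tissue["gut"],
        "liver": kp_tissue["liver"],
        "richly_perfused": lumped_kp(kp_tissue, RICHLY_PERFUSED_TISSUES),
        "slowly_perfused": lumped_kp(kp_tissue, SLOWLY_PERFUSED_TISSUES),
    }
    raw = PartitionSet(kp=kp, adjustment={k: 1.0 for k in kp})
    if adjustment is None:
        return raw
    return apply_adjustment(raw, adjustment)


def apply_adjustment(kp_raw: PartitionSet, factors: dict[str, float]) -> PartitionSet:
    """Element-wise rescaling of Kp by per-compartment calibration factors."""
    if any(f <= 0 for f in factors.values()):
        raise ValueError("adjustment factors must be > 0")
    kp = {k: v * factors.get(k, 1.0) for k, v in kp_raw.kp.items()}
    adjustment = {k: kp_raw.adjustment.get(k, 1.0) * factors.get(k, 1.0) for k in kp_raw.kp}
    return replace(kp_raw, kp=kp, adjustment=adjustment)
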