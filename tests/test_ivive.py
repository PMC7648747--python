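"""IVIVE chain: recombinant kinetics -> whole-liver intrinsic clearance."""
import numpy as np
import pytest

import pregpbpk as pk
from pregpbpk.config import CYP_ENZYMES


def test_clint_recombinant_unit_arithmetic():
    assert pk.clint_recombinant(1.0, 0.5, 1.0) == 2.0
    # halving microsomal binding doubles the unbound intrinsic clearance
    assert pk.clint_recombinant(1.0, 0.5, 0.5) == 2 * pk.clint_recombinant(1.0, 0.5, 1.0)
    with pytest.raises(ValueError):
        pk.clint_recombinant(1.0, 0.0, 1.0)


def test_equal_kinetics_give_equal_shares(drug, physiology):
    kin = {
        e: drug.cyp_kinetics[e].model_copy(
            update={"vmax_pmol_min_pmol": 2.0, "isef": 0.5, "abundance_pmol_mg": 50.0}
        )
        for e in CYP_ENZYMES
    }
    clearance = pk.scale_to_liver(drug.model_copy(update={"cyp_kinetics": kin}), physiology)
    for e in CYP_ENZYMES:
        assert clearance.fm[e] == pytest.approx(0.2, rel=1e-12)


def test_missing_enzyme_rejected(drug, physiology):
    kin = {e: drug.cyp_kinetics[e] for e in CYP_ENZYMES if e != "CYP2D6"}
    with pytest.raises(ValueError, match="CYP2D6"):
        pk.scale_to_liver(drug.model_copy(update={"cyp_kinetics": kin}), physiology)


def test_packaged_fm_shares(drug, physiology):
    """CYP3A4 dominates sertraline metabolism (73% of total intrinsic
    clearance), followed by 2B6/2C9/2C19/2D6 at 9/8/7/3%."""
    clearance = pk.scale_to_liver(drug, physiology)
    expected = {"CYP3A4": 73.0, "CYP2B6": 9.0, "CYP2C9": 8.0, "CYP2C19": 7.0, "CYP2D6": 3.0}
    for enzyme, pct in expected.items():
        assert 100 * clearance.fm[enzyme] == pytest.approx(pct, abs=1.0)
    assert sum(clearance.fm.values()) == pytest.approx(1.0, abs=1e-9)


def test_chain_matches_single_expression_oracle(drug, physiology):
    """The module's staged computation equals a one-line recomputation."""
    clearance = pk.scale_to_liver(drug, physiology)
    for enzyme, kin in drug.cyp_kinetics.items():
        direct = (
            (kin.vmax_pmol_min_pmol / drug.substrate_conc_um / drug.fu_mic)
            * kin.isef
            * kin.abundance_pmol_mg
            * physiology.mppgl_mg_g
            * physiology.liver_mass_g
            * 60.0
            / 1e6
        )
        assert clearance.per_enzyme[enzyme] == pytest.approx(direct, rel=1e-9)
    assert clearance.total == pytest.approx(sum(clearance.per_enzyme.values()), rel=1e-12)


def test_gestational_clearance_trajectory(drug, physiology, coeffs):
    """Total hepatic intrinsic clearance rises ~11/37/63% at GA 10/20/30 via
    the CYP3A4 and CYP2D6 activity increases alone."""
    base = pk.scale_to_liver(drug, physiology)
    state0 = pk.gestation_scale(physiology, coeffs, 0.0, drug.fu0)
    assert pk.clint_at_ga(base, state0).total == pytest.approx(base.total, rel=1e-12)
    expected = {10.0: 1.11, 20.0: 1.37, 30.0: 1.63}
    for ga, ratio in expected.items():
        state = pk.gestation_scale(physiology, coeffs, ga, drug.fu0)
        scaled = pk.clint_at_ga(base, state)
        assert scaled.total / base.total == pytest.approx(ratio, abs=0.05)
        assert sum(scaled.fm.values()) == pytest.approx(1.0, abs=1e-9)
        # only enzymes with gestational data move
        for e in ("CYP2B6", "CYP2C9", "CYP2C19"):
            assert scaled.per_enzyme[e] == base.per_enzyme[e]


def test_clearance_nondecreasing_in_ga(drug, physiology, coeffs):
    base = pk.scale_to_liver(drug, physiology)
    totals = [
        pk.clint_at_ga(base, pk.gestation_scale(physiology, coeffs, g, drug.fu0)).total
        for g in np.linspace(0, 40, 81)
    ]
    assert np.all(np.diff(totals) >= 0)
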