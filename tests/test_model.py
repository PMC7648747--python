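"""PBPK ODE engine: absorption kinetics, linearity, mass balance, oracles."""
import dataclasses

import numpy as np
import pytest
from scipy.linalg import expm

import pregpbpk as pk
from pregpbpk.model import _coefficient_matrix, derivatives
from pregpbpk.nca import percent_change


@pytest.fixture(scope="module")
def params0(configs):
    drug, phys, coeffs = configs
    return pk.build_model_params(drug, phys, coeffs, 0.0)


def test_ka_t_limits():
    assert pk.ka_t(0.0, 0.4, 2.5) == 0.0
    assert pk.ka_t(1e4, 0.4, 2.5) == pytest.approx(0.4, rel=1e-12)
    assert pk.ka_t(2.5, 0.4, 2.5) == pytest.approx(0.4 * (1 - np.exp(-1)), rel=1e-12)
    with pytest.raises(ValueError):
        pk.ka_t(1.0, 0.4, 0.0)
    with pytest.raises(ValueError):
        pk.ka_t(-1.0, 0.4, 2.5)


def test_zero_state_has_zero_derivatives(params0):
    dydt = derivatives(np.zeros(8), 5.0, params0, 0.0)
    assert np.all(dydt == 0.0)


def test_zero_dose_gives_zero_concentrations(params0):
    out = pk.simulate(params0, pk.Regimen(dose_mg=0.0, n_doses=3))
    assert np.all(out.conc == 0.0)


def test_matrix_exponential_oracle(params0):
    """With biliary clearance off and an effectively constant absorption rate
    the system is linear time-invariant; the simulated single-dose plasma
    curve must match the matrix-exponential solution."""
    p = dataclasses.replace(params0, cl_bile=0.0, tau_a=1e-6)
    reg = pk.Regimen(dose_mg=200.0, n_doses=1)
    out = pk.simulate(p, reg, washout_h=48.0)

    a = _coefficient_matrix(p, ka=p.ka_max)
    y0 = np.zeros(8)
    y0[0] = 200.0 * 1000.0
    oracle = np.array([(expm(a * t) @ y0)[4] / p.v_plasma for t in out.times])
    scale = oracle.max()
    np.testing.assert_allclose(out.conc, oracle, atol=1e-4 * scale, rtol=1e-4)


def test_equilibration_to_partition_coefficients(params0):
    """With no elimination every tissue equilibrates to C_tissue/C_plasma = Kp."""
    p = dataclasses.replace(params0, clint_u=0.0, cl_bile=0.0)
    out = pk.simulate(p, pk.Regimen(dose_mg=100.0, n_doses=1, interval_h=24.0), washout_h=2000.0)
    final = out.amounts[-1]
    c_pl = final[4] / p.v_plasma
    assert final[4] > 0
    for idx, (v, kp) in {
        2: (p.v_gut, p.kp_gut),
        3: (p.v_liver, p.kp_liver),
        5: (p.v_rich, p.kp_rich),
        6: (p.v_slow, p.kp_slow),
    }.items():
        assert final[idx] / v / c_pl == pytest.approx(kp, rel=1e-6)


def test_mass_balance(baseline_sim):
    """Administered dose is fully accounted for by compartments + metabolized."""
    assert baseline_sim.mass_balance_error().max() <= 1e-3


def test_dose_linearity(configs):
    """Doubling the dose doubles Cmax and AUC24; gestational percent changes
    are dose-invariant (linear kinetics across the 50-200 mg range)."""
    drug, phys, coeffs = configs
    results = {}
    for ga in (0.0, 34.0):
        params = pk.build_model_params(drug, phys, coeffs, ga)
        for dose in (50.0, 100.0):
            out = pk.simulate(params, pk.Regimen(dose_mg=dose, n_doses=10), washout_h=48.0)
            results[(ga, dose)] = pk.nca(out)
    for ga in (0.0, 34.0):
        lo, hi = results[(ga, 50.0)], results[(ga, 100.0)]
        assert hi.cmax / lo.cmax == pytest.approx(2.0, rel=1e-6)
        assert hi.auc24 / lo.auc24 == pytest.approx(2.0, rel=1e-6)
    for dose in (50.0, 100.0):
        pc = percent_change(results[(34.0, dose)], results[(0.0, dose)])
        pc_other = percent_change(results[(34.0, 150.0 - dose)], results[(0.0, 150.0 - dose)])
        assert pc["auc24"] == pytest.approx(pc_other["auc24"], rel=1e-6, abs=1e-6)
        assert pc["cmax"] == pytest.approx(pc_other["cmax"], rel=1e-6, abs=1e-6)


def test_superposition_with_time_invariant_absorption(params0):
    """With constant Ka the multi-dose curve is the sum of shifted single-dose
    curves (the enterohepatic loop preserves linearity)."""
    p = dataclasses.replace(params0, tau_a=1e-6)
    n, tau = 5, 24.0
    multi = pk.simulate(p, pk.Regimen(dose_mg=100.0, interval_h=tau, n_doses=n), grid_dt=0.25)
    single = pk.simulate(
        p, pk.Regimen(dose_mg=100.0, interval_h=tau, n_doses=1), washout_h=n * tau, grid_dt=0.25
    )
    t_last = (n - 1) * tau
    mask = multi.times >= t_last
    t_eval = multi.times[mask]
    summed = np.zeros_like(t_eval)
    for k in range(n):
        shifted = t_eval - k * tau
        summed += np.interp(shifted, single.times, single.conc, left=0.0)
    np.testing.assert_allclose(multi.conc[mask], summed, rtol=2e-5, atol=1e-6 * summed.max())


def test_accumulation_consistent_with_half_life(baseline_sim, baseline_nca, configs):
    """The steady-state accumulation ratio agrees with the single-compartment
    prediction 1/(1 - 2^(-tau/t_half)) from the simulated terminal half-life."""
    drug, phys, coeffs = configs
    params = pk.build_model_params(drug, phys, coeffs, 0.0)
    first = pk.nca(pk.simulate(params, pk.Regimen(dose_mg=200.0, n_doses=1), washout_h=48.0))
    racc_sim = baseline_nca.auc24 / first.auc24
    racc_pred = 1.0 / (1.0 - 2.0 ** (-24.0 / baseline_nca.t_half))
    assert racc_sim == pytest.approx(racc_pred, rel=0.15)
    assert racc_sim > 1.5  # pronounced accumulation for a ~26 h half-life drug


def test_pregnancy_lowers_exposure(baseline_nca, ga34_sim):
    """Third-trimester simulation shows lower Cmax and AUC24 than nonpregnancy."""
    res34 = pk.nca(ga34_sim)
    assert res34.cmax < baseline_nca.cmax
    assert res34.auc24 < baseline_nca.auc24


def test_invalid_regimen_rejected():
    with pytest.raises(ValueError):
        pk.Regimen(dose_mg=-1.0)
    with pytest.raises(ValueError):
        pk.Regimen(dose_mg=100.0, interval_h=0.0)
    with pytest.raises(ValueError):
        pk.Regimen(dose_mg=100.0, n_doses=0)


def test_nonnegative_states(baseline_sim):
    assert baseline_sim.amounts.min() >= 0.0
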