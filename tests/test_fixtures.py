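"""Synthetic observed datasets: structure, noise model, closed-loop identity."""
import numpy as np
import pytest

import pregpbpk as pk
from pregpbpk.evaluation import EvalPair
from pregpbpk.fixtures import CALIBRATION_SCHEDULE_H


def test_zero_noise_points_lie_on_model_curve(configs):
    drug, phys, coeffs = configs
    ds = pk.make_calibration_like(drug, phys, coeffs, n_subjects=2, noise_cv=0.0, seed=1)
    reg = pk.Regimen(dose_mg=200.0, n_doses=30)
    out = pk.simulate(pk.build_model_params(drug, phys, coeffs, 0.0), reg, washout_h=49.0)
    truth = np.interp(
        reg.last_dose_time + np.asarray(CALIBRATION_SCHEDULE_H), out.times, out.conc
    )
    for _, grp in ds.data.groupby("subject"):
        np.testing.assert_allclose(grp["conc_ug_per_L"].to_numpy(), truth, rtol=1e-9)


def test_seeded_csv_is_byte_identical(configs, tmp_path):
    drug, phys, coeffs = configs
    a, b = tmp_path / "a.csv", tmp_path / "b.csv"
    pk.make_calibration_like(drug, phys, coeffs, n_subjects=3, noise_cv=0.2, seed=9).to_csv(a)
    pk.make_calibration_like(drug, phys, coeffs, n_subjects=3, noise_cv=0.2, seed=9).to_csv(b)
    assert a.read_bytes() == b.read_bytes()


def test_noise_cv_is_realized(configs):
    """With 20% multiplicative noise and 11 subjects the per-timepoint sample
    CV lands in the n-limited [0.1, 0.3] band."""
    drug, phys, coeffs = configs
    ds = pk.make_calibration_like(drug, phys, coeffs, n_subjects=11, noise_cv=0.2, seed=4)
    cv = ds.data.groupby("time_h")["conc_ug_per_L"].agg(lambda x: x.std() / x.mean())
    assert cv.between(0.1, 0.3).mean() >= 0.8  # most timepoints in band
    assert 0.1 <= cv.mean() <= 0.3


def test_verification_closed_loop_is_exact_at_zero_noise(configs):
    """Evaluating the model against its own noise-free synthetic summaries
    gives AFE = AAFE = 1."""
    drug, phys, coeffs = configs
    ds = pk.make_verification_like(
        drug, phys, coeffs, doses_mg=(50.0, 100.0), n_third_trimester=1, noise_cv=0.0, seed=2
    )
    prs = []
    for row in ds.data.itertuples():
        params = pk.build_model_params(drug, phys, coeffs, row.ga_weeks)
        res = pk.nca(pk.simulate(params, pk.Regimen(dose_mg=row.dose_mg, n_doses=30)))
        prs.append(EvalPair(predicted=res.cmax, observed=row.cmax_ug_per_L))
        prs.append(EvalPair(predicted=res.auc24, observed=row.auc24_ug_h_per_L))
    assert pk.afe(prs) == pytest.approx(1.0, rel=1e-9)
    assert pk.aafe(prs) == pytest.approx(1.0, rel=1e-9)


def test_verification_noise_bounds_aafe(configs):
    """30% lognormal noise produces an AAFE around 1.3 (fold-error scale)."""
    drug, phys, coeffs = configs
    ds = pk.make_verification_like(
        drug, phys, coeffs, doses_mg=(50.0, 100.0, 150.0), n_third_trimester=2, noise_cv=0.3, seed=8
    )
    prs = []
    for row in ds.data.itertuples():
        params = pk.build_model_params(drug, phys, coeffs, row.ga_weeks)
        res = pk.nca(pk.simulate(params, pk.Regimen(dose_mg=row.dose_mg, n_doses=30)))
        prs.append(EvalPair(predicted=res.cmax, observed=row.cmax_ug_per_L))
        prs.append(EvalPair(predicted=res.auc24, observed=row.auc24_ug_h_per_L))
    assert 1.1 <= pk.aafe(prs) <= 1.7


def test_exposure_declines_between_visits(configs):
    """Second-to-third-trimester Cmax and AUC24 decline at a fixed dose."""
    drug, phys, coeffs = configs
    ds = pk.make_verification_like(
        drug, phys, coeffs, doses_mg=(100.0, 100.0, 100.0, 100.0),
        n_third_trimester=4, noise_cv=0.0, seed=3,
    )
    mean = ds.data.groupby("trimester")[["cmax_ug_per_L", "auc24_ug_h_per_L"]].mean()
    assert mean.loc["T3", "cmax_ug_per_L"] < mean.loc["T2", "cmax_ug_per_L"]
    assert mean.loc["T3", "auc24_ug_h_per_L"] < mean.loc["T2", "auc24_ug_h_per_L"]


def test_negative_noise_rejected(configs):
    drug, phys, coeffs = configs
    with pytest.raises(ValueError):
        pk.make_calibration_like(drug, phys, coeffs, noise_cv=-0.1)
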