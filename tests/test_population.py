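"""Monte Carlo sampling: distribution families, truncation, renormalization."""
import numpy as np
import pandas as pd
import pytest

import pregpbpk as pk
from pregpbpk.population import DistributionSpec, default_distributions, sample_parameters


def test_vanishing_cv_collapses_to_mean():
    spec = DistributionSpec("x", "lognormal", 2.0, 1e-9)
    draws = spec.draw(np.random.default_rng(0), 1000)
    np.testing.assert_allclose(draws, 2.0, rtol=1e-7)


def test_lognormal_sample_mean_and_truncation():
    spec = DistributionSpec("x", "lognormal", 1.0, 0.3)
    draws = spec.draw(np.random.default_rng(1), 10_000)
    assert abs(draws.mean() - 1.0) < 0.02
    lo, hi = spec.bounds
    assert draws.min() >= lo and draws.max() <= hi


def test_truncation_never_violated_at_scale():
    rng = np.random.default_rng(2)
    for family in ("lognormal", "normal"):
        spec = DistributionSpec("x", family, 1.0, 0.3)
        draws = spec.draw(rng, 100_000)
        lo, hi = spec.bounds
        assert ((draws >= lo) & (draws <= hi)).all()


def test_infeasible_spec_rejected():
    with pytest.raises(ValueError):
        DistributionSpec("x", "normal", 1.0, -0.1)
    with pytest.raises(ValueError):
        DistributionSpec("x", "normal", 0.0, 0.3)


def test_flow_fractions_renormalized(drug, physiology):
    specs = default_distributions(drug, physiology)
    frame = sample_parameters(specs, 200, seed=3)
    fq = frame[[c for c in frame if c.startswith("fq_")]]
    np.testing.assert_allclose(fq.sum(axis=1), 1.0, atol=1e-12)
    fv = frame[[c for c in frame if c.startswith("fv_")]]
    nominal = sum(physiology.fractional_volumes.values())
    np.testing.assert_allclose(fv.sum(axis=1), nominal, atol=1e-12)


def test_seeded_sampling_is_reproducible(drug, physiology):
    specs = default_distributions(drug, physiology)
    a = sample_parameters(specs, 50, seed=7)
    b = sample_parameters(specs, 50, seed=7)
    pd.testing.assert_frame_equal(a, b)


def test_monte_carlo_seeded_bitwise_reproducible(configs):
    drug, phys, coeffs = configs
    reg = pk.Regimen(dose_mg=200.0, n_doses=10)
    a = pk.monte_carlo(drug, phys, coeffs, reg, ga=0.0, n=3, seed=11, washout_h=48.0)
    b = pk.monte_carlo(drug, phys, coeffs, reg, ga=0.0, n=3, seed=11, washout_h=48.0)
    pd.testing.assert_frame_equal(a.percentiles, b.percentiles)
    assert a.median_nca == b.median_nca


def test_degenerate_cv_bands_collapse(configs):
    """With vanishing variability the population bands sit on the
    deterministic curve."""
    drug, phys, coeffs = configs
    specs = [
        DistributionSpec(s.param, s.family, s.mean, 1e-9, group=s.group)
        for s in default_distributions(drug, phys)
    ]
    reg = pk.Regimen(dose_mg=200.0, n_doses=10)
    mc = pk.monte_carlo(drug, phys, coeffs, reg, ga=0.0, n=4, seed=5, washout_h=48.0, specs=specs)
    width = (mc.percentiles["p97.5"] - mc.percentiles["p2.5"]).abs().max()
    assert width <= 1e-4 * mc.percentiles["p50"].max()
    det = pk.simulate(pk.build_model_params(drug, phys, coeffs, 0.0), reg, washout_h=48.0)
    det_last = det.conc[det.times >= reg.last_dose_time]
    np.testing.assert_allclose(mc.percentiles["p50"], det_last, rtol=1e-5)
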