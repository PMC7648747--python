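"""Synthetic observed datasets with the structure of the clinical studies.

Two study shapes are emulated so that every stage of the workflow (loading,
calibration, evaluation) is testable without external data:

* a calibration-like study — nonpregnant subjects on 200 mg daily for 30
  days, with serial plasma samples after the last dose;
* a verification-like study — pregnant subjects on various daily doses
  (25-200 mg), with Cmax/AUC24 summaries at a second-trimester (22-26 weeks)
  and a third-trimester (30-34 weeks) visit.

"Observations" are model predictions perturbed by multiplicative lognormal
noise with a chosen CV, so the generating parameters are known exactly and
closed-loop recovery can be asserted.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DrugParams, GestationalCoefficients, Physiology
from .gestation import gestation_scale
from .model import Regimen, build_model_params, simulate
from .nca import nca

#: Serial sampling schedule, hours after the last dose.
CALIBRATION_SCHEDULE_H = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0, 12.0, 16.0, 24.0, 36.0, 48.0, 72.0)
#: Visit windows (weeks) for the two pregnancy study visits.
TRIMESTER2_WINDOW = (22.0, 26.0)
TRIMESTER3_WINDOW = (30.0, 34.0)


@dataclass(frozen=True)
class ObservedDataset:
    """A synthetic observed dataset plus its generation metadata."""

    data: pd.DataFrame
    kind: str  # "concentration" or "summary"
    dose_mg: float | None
    n_doses: int
    noise_cv: float
    seed: int

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False, float_format="%.6g")


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=size)


def make_calibration_like(
    drug: DrugParams,
    physiology: Physiology,
    coeffs: GestationalCoefficients,
    n_subjects: int = 11,
    dose_mg: float = 200.0,
    n_doses: int = 30,
    noise_cv: float = 0.2,
    seed: int = 0,
    schedule_h: tuple[float, ...] = CALIBRATION_SCHEDULE_H,
) -> ObservedDataset:
    """Steady-state concentration-time points for nonpregnant subjects.

    The true model is simulated once; each subject's samples are the true
    curve at the study schedule times multiplied by lognormal noise.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    regimen = Regimen(dose_mg=dose_mg, n_doses=n_doses)
    params = build_model_params(drug, physiology, coeffs, 0.0)
    out = simulate(params, regimen, washout_h=max(schedule_h) - regimen.interval_h + 1.0)
    t_abs = regimen.last_dose_time + np.asarray(schedule_h)
    truth = np.interp(t_abs, out.times, out.conc)

    rows = []
    for subj in range(1, n_subjects + 1):
        noisy = truth * _lognormal_noise(rng, noise_cv, len(truth))
        for t, c in zip(schedule_h, noisy):
            rows.append({"subject": f"S{subj:02d}", "time_h": t, "conc_ug_per_L": c})
    return ObservedDataset(
        data=pd.DataFrame(rows),
        kind="concentration",
        dose_mg=dose_mg,
        n_doses=n_doses,
        noise_cv=noise_cv,
        seed=seed,
    )


def make_verification_like(
    drug: DrugParams,
    physiology: Physiology,
    coeffs: GestationalCoefficients,
    doses_mg: tuple[float, ...] = (25.0, 50.0, 50.0, 100.0, 100.0, 150.0, 200.0, 200.0),
    n_third_trimester: int = 6,
    n_doses: int = 30,
    noise_cv: float = 0.3,
    seed: int = 0,
) -> ObservedDataset:
    """Per-subject Cmax/AUC24 summaries at two pregnancy visits.

    All ``len(doses_mg)`` subjects contribute a second-trimester visit; the
    first ``n_third_trimester`` also contribute a third-trimester visit
    (mirroring the 8-and-6-subject structure of the verification study).
    Reported body weight is the gestational weight at the visit.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for i, dose in enumerate(doses_mg):
        subj = f"P{i + 1:02d}"
        visits = [("T2", rng.uniform(*TRIMESTER2_WINDOW))]
        if i < n_third_trimester:
            visits.append(("T3", rng.uniform(*TRIMESTER3_WINDOW)))
        for label, ga in visits:
            regimen = Regimen(dose_mg=dose, n_doses=n_doses)
            params = build_model_params(drug, physiology, coeffs, ga)
            res = nca(simulate(params, regimen))
            noise = _lognormal_noise(rng, noise_cv, 2)
            state = gestation_scale(physiology, coeffs, ga, drug.fu0)
            rows.append(
                {
                    "subject": subj,
                    "trimester": label,
                    "ga_weeks": ga,
                    "dose_mg": dose,
                    "body_weight_kg": state.body_weight,
                    "cmax_ug_per_L": res.cmax * noise[0],
                    "auc24_ug_h_per_L": res.auc24 * noise[1],
                }
            )
    return ObservedDataset(
        data=pd.DataFrame(rows),
        kind="summary",
        dose_mg=None,
        n_doses=n_doses,
        noise_cv=noise_cv,
        seed=seed,
    )
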