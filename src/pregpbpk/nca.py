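"""Non-compartmental analysis of steady-state concentration-time profiles.

Metrics are computed over the final dosing interval: Cmax/Tmax by grid
maximum, AUC24 by the linear trapezoid, the terminal rate constant by
log-linear regression on the washout segment (points at least 12 h after the
last Tmax, minimum 5 points), CL/F as dose/AUC over the interval at steady
state, and Vd/F as CL/F divided by the terminal rate constant.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import MG_TO_UG, SimulationOutput

#: Start of the terminal regression window, hours after the last Tmax.
LAMBDA_Z_LAG_H = 12.0
MIN_LAMBDA_Z_POINTS = 5
MIN_LAMBDA_Z_R2 = 0.95


@dataclass(frozen=True)
class NCAResult:
    cmax: float  # µg/L
    tmax: float  # h after the last dose
    auc24: float  # µg·h/L over the final dosing interval
    t_half: float  # h
    cl_f: float  # L/h
    vd_f: float  # L
    lambda_z: float  # 1/h
    lambda_z_r2: float
    t_half_reliable: bool

    def as_dict(self) -> dict[str, float]:
        return {
            "cmax": self.cmax,
            "tmax": self.tmax,
            "auc24": self.auc24,
            "t_half": self.t_half,
            "cl_f": self.cl_f,
            "vd_f": self.vd_f,
        }


def nca_from_arrays(
    times: np.ndarray,
    conc: np.ndarray,
    t_last_dose: float,
    interval: float,
    dose_mg: float,
) -> NCAResult:
    """NCA on an arbitrary sampled profile (times in h, conc in µg/L)."""
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    win = (times >= t_last_dose) & (times <= t_last_dose + interval)
    if win.sum() < 3:
        raise ValueError("profile must cover the final dosing interval")
    t_win, c_win = times[win], conc[win]
    i_max = int(np.argmax(c_win))
    cmax = float(c_win[i_max])
    tmax = float(t_win[i_max] - t_last_dose)
    auc = float(np.trapezoid(c_win, t_win))

    tail = times >= t_last_dose + tmax + LAMBDA_Z_LAG_H
    lam, r2, reliable = np.nan, np.nan, False
    t_tail, c_tail = times[tail], conc[tail]
    pos = c_tail > 0
    if pos.sum() >= MIN_LAMBDA_Z_POINTS:
        fit = stats.linregress(t_tail[pos], np.log(c_tail[pos]))
        lam = -float(fit.slope)
        r2 = float(fit.rvalue**2)
        reliable = lam > 0 and r2 >= MIN_LAMBDA_Z_R2
    if not reliable:
        warnings.warn(
            "terminal slope unreliable (need >= 5 positive points >= 12 h "
            f"post-Tmax with r^2 >= {MIN_LAMBDA_Z_R2}); t_half flagged",
            stacklevel=2,
        )
    t_half = float(np.log(2) / lam) if lam and lam > 0 else np.nan
    cl_f = dose_mg * MG_TO_UG / auc if auc > 0 else np.nan
    vd_f = cl_f / lam if lam and lam > 0 else np.nan
    return NCAResult(
        cmax=cmax,
        tmax=tmax,
        auc24=auc,
        t_half=t_half,
        cl_f=float(cl_f),
        vd_f=float(vd_f),
        lambda_z=float(lam),
        lambda_z_r2=float(r2),
        t_half_reliable=reliable,
    )


def nca(profile: SimulationOutput, interval: float | None = None, dose_mg: float | None = None) -> NCAResult:
    """NCA of a simulated profile over its final dosing interval.

    The simulation should extend at least ~48 h past the final interval when
    a reliable terminal half-life is required.
    """
    reg = profile.regimen
    return nca_from_arrays(
        profile.times,
        profile.conc,
        t_last_dose=reg.last_dose_time,
        interval=reg.interval_h if interval is None else interval,
        dose_mg=reg.dose_mg if dose_mg is None else dose_mg,
    )


def percent_change(preg: NCAResult, nonpreg: NCAResult) -> dict[str, float]:
    """Per-metric percent change, 100 * (pregnant - nonpregnant) / nonpregnant."""
    out = {}
    for key, ref in nonpreg.as_dict().items():
        val = preg.as_dict()[key]
        if ref == 0 or not np.isfinite(ref):
            raise ZeroDivisionError(f"nonpregnant {key} is zero or non-finite")
        out[key] = 100.0 * (val - ref) / ref
    return out
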