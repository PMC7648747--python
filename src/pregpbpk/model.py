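"""Five-tissue perfusion-limited PBPK engine with oral dosing.

Compartments: gut lumen and gallbladder (transit, no blood flow), gut tissue,
liver, plasma, and lumped richly / slowly perfused tissues. Oral drug leaves
the lumen with a time-dependent first-order absorption rate constant

    Ka(t) = ka_max * (1 - exp(-t_since_dose / tau_a))

whose clock resets at every dose event — a two-parameter description of slow,
dissolution-limited uptake. The liver receives hepatic-arterial plus gut
venous blood; elimination is purely metabolic, driven by the unbound liver
venous-equilibrium concentration (CLint_u * fu * C_liver / Kp_liver). A
parallel biliary route secretes drug into the gallbladder, which empties
continuously into the lumen (first-order), closing the enterohepatic loop.
Renal clearance is negligible for sertraline and is not modeled.

The system is linear in the amounts, so doubling the dose doubles every
concentration (superposition holds), and at periodic steady state the
apparent oral clearance reduces exactly to CL/F = fu * CLint_u.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from scipy.integrate import odeint

from .config import DrugParams, GestationalCoefficients, Physiology
from .gestation import GestationalState, gestation_scale
from .ivive import clint_at_ga, scale_to_liver
from .partition import build_partition_set

STATE_NAMES = (
    "gut_lumen",
    "gallbladder",
    "gut",
    "liver",
    "plasma",
    "richly_perfused",
    "slowly_perfused",
    "metabolized",
)
N_STATES = len(STATE_NAMES)
MG_TO_UG = 1000.0


@dataclass(frozen=True)
class Regimen:
    """Repeated oral dosing schedule."""

    dose_mg: float
    interval_h: float = 24.0
    n_doses: int = 30
    start_h: float = 0.0

    def __post_init__(self) -> None:
        if self.dose_mg < 0:
            raise ValueError("dose_mg must be >= 0")
        if self.interval_h <= 0 or self.n_doses < 1:
            raise ValueError("interval_h must be > 0 and n_doses >= 1")

    @property
    def dose_times(self) -> np.ndarray:
        return self.start_h + self.interval_h * np.arange(self.n_doses)

    @property
    def last_dose_time(self) -> float:
        return self.start_h + self.interval_h * (self.n_doses - 1)


@dataclass(frozen=True)
class ModelParams:
    """Fully assembled coefficients of the ODE system (µg / L / h)."""

    v_plasma: float
    v_gut: float
    v_liver: float
    v_rich: float
    v_slow: float
    q_gut: float
    q_liver_arterial: float
    q_rich: float
    q_slow: float
    kp_gut: float
    kp_liver: float
    kp_rich: float
    kp_slow: float
    fu: float
    clint_u: float  # unbound hepatic intrinsic clearance, L/h
    cl_bile: float  # unbound biliary intrinsic clearance, L/h
    k_empty: float  # gallbladder emptying rate, 1/h
    ka_max: float  # asymptotic absorption rate, 1/h
    tau_a: float  # dissolution time constant, h
    ga: float = 0.0
    body_weight: float = float("nan")

    def scaled(self, **factors: float) -> "ModelParams":
        """Return a copy with named fields multiplied by the given factors."""
        updates = {}
        for name, f in factors.items():
            updates[name] = getattr(self, name) * f
        return dc_replace(self, **updates)


@dataclass(frozen=True)
class SimulationOutput:
    """Amounts per compartment and plasma concentration on a time grid."""

    times: np.ndarray  # h
    amounts: np.ndarray  # (n_times, 8) µg
    params: ModelParams
    regimen: Regimen
    dose_total_ug: float

    @property
    def conc(self) -> np.ndarray:
        """Total plasma concentration, µg/L."""
        return self.amounts[:, 4] / self.params.v_plasma

    def mass_balance_error(self) -> np.ndarray:
        """|administered - accounted| as a fraction of the administered dose."""
        administered = np.zeros_like(self.times)
        for td in self.regimen.dose_times:
            administered += np.where(self.times >= td - 1e-12, self.regimen.dose_mg * MG_TO_UG, 0.0)
        accounted = self.amounts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            err = np.abs(administered - accounted) / np.where(administered > 0, administered, np.inf)
        return err


class IntegrationError(RuntimeError):
    """The ODE solver failed or produced a meaningfully negative state."""


def ka_t(t_since_dose: float, ka_max: float, tau_a: float) -> float:
    """Time-dependent absorption rate constant, 1/h.

    Zero at the dose instant (nothing has dissolved yet) and saturating to
    ka_max with time constant tau_a.
    """
    if tau_a <= 0:
        raise ValueError(f"tau_a must be > 0, got {tau_a}")
    if t_since_dose < 0:
        raise ValueError("t_since_dose must be >= 0")
    return ka_max * (1.0 - math.exp(-t_since_dose / tau_a))


def _coefficient_matrix(p: ModelParams, ka: float) -> np.ndarray:
    """System matrix A(ka) with d(amounts)/dt = A @ amounts."""
    a = np.zeros((N_STATES, N_STATES))
    q_h = p.q_gut + p.q_liver_arterial
    co = q_h + p.q_rich + p.q_slow
    kl = 1.0 / (p.v_liver * p.kp_liver)
    kg = 1.0 / (p.v_gut * p.kp_gut)
    # lumen
    a[0, 0] = -ka
    a[0, 1] = p.k_empty
    # gallbladder: biliary secretion from unbound liver venous concentration
    a[1, 3] = p.cl_bile * p.fu * kl
    a[1, 1] = -p.k_empty
    # gut tissue
    a[2, 0] = ka
    a[2, 4] = p.q_gut / p.v_plasma
    a[2, 2] = -p.q_gut * kg
    # liver
    a[3, 4] = p.q_liver_arterial / p.v_plasma
    a[3, 2] = p.q_gut * kg
    a[3, 3] = -(q_h + (p.clint_u + p.cl_bile) * p.fu) * kl
    # plasma
    a[4, 3] = q_h * kl
    a[4, 5] = p.q_rich / (p.v_rich * p.kp_rich)
    a[4, 6] = p.q_slow / (p.v_slow * p.kp_slow)
    a[4, 4] = -co / p.v_plasma
    # richly perfused
    a[5, 4] = p.q_rich / p.v_plasma
    a[5, 5] = -p.q_rich / (p.v_rich * p.kp_rich)
    # slowly perfused
    a[6, 4] = p.q_slow / p.v_plasma
    a[6, 6] = -p.q_slow / (p.v_slow * p.kp_slow)
    # cumulative metabolized
    a[7, 3] = p.clint_u * p.fu * kl
    return a


def derivatives(state: np.ndarray, t: float, params: ModelParams, t_dose: float) -> np.ndarray:
    """Right-hand side of the PBPK system at time t (h since simulation start).

    ``t_dose`` is the time of the most recent dose; it anchors the absorption
    clock. Fluxes between perfused tissues follow Q_i * (C_plasma - C_i/Kp_i).
    """
    ka = ka_t(max(t - t_dose, 0.0), params.ka_max, params.tau_a)
    lumen, gall, gut, liver, plasma, rich, slow, _ = state
    p = params
    c_pl = plasma / p.v_plasma
    cv_gut = gut / (p.v_gut * p.kp_gut)
    cv_liv = liver / (p.v_liver * p.kp_liver)
    cv_rich = rich / (p.v_rich * p.kp_rich)
    cv_slow = slow / (p.v_slow * p.kp_slow)
    q_h = p.q_gut + p.q_liver_arterial
    absorbed = ka * lumen
    bile = p.cl_bile * p.fu * cv_liv
    met = p.clint_u * p.fu * cv_liv
    emptied = p.k_empty * gall
    return np.array(
        [
            emptied - absorbed,
            bile - emptied,
            absorbed + p.q_gut * (c_pl - cv_gut),
            p.q_liver_arterial * c_pl + p.q_gut * cv_gut - q_h * cv_liv - met - bile,
            q_h * cv_liv + p.q_rich * cv_rich + p.q_slow * cv_slow
            - (q_h + p.q_rich + p.q_slow) * c_pl,
            p.q_rich * (c_pl - cv_rich),
            p.q_slow * (c_pl - cv_slow),
            met,
        ]
    )


def _segment_times(t0: float, t1: float, outputs: np.ndarray) -> np.ndarray:
    inner = outputs[(outputs > t0) & (outputs <= t1)]
    ts = np.concatenate(([t0], inner))
    if ts[-1] < t1:
        ts = np.append(ts, t1)
    return ts


def simulate(
    params: ModelParams,
    regimen: Regimen,
    washout_h: float = 0.0,
    grid_dt: float = 0.25,
    coarse_dt: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SimulationOutput:
    """Integrate the dosing regimen plus optional washout.

    The solver (LSODA, stiff-capable, adaptive) restarts at every dose event,
    where the dose is added to the gut lumen and the absorption clock resets.
    Output is sampled at ``coarse_dt`` before the final dosing interval and at
    ``grid_dt`` (default 0.25 h) from the last dose to the end of washout.
    """
    dose_ug = regimen.dose_mg * MG_TO_UG
    dose_times = regimen.dose_times
    t_last = regimen.last_dose_time
    t_end = t_last + regimen.interval_h + washout_h

    coarse = np.arange(regimen.start_h, t_last, coarse_dt)
    fine = t_last + np.arange(0.0, regimen.interval_h + washout_h + grid_dt / 2, grid_dt)
    out_times = np.unique(np.concatenate((coarse, fine, dose_times, [t_end])))
    out_times = out_times[(out_times >= regimen.start_h) & (out_times <= t_end)]

    y = np.zeros(N_STATES)
    times_acc: list[np.ndarray] = []
    amounts_acc: list[np.ndarray] = []
    base = _coefficient_matrix(params, ka=0.0)
    inv_tau = 1.0 / params.tau_a

    def jac(state: np.ndarray, t: float, params_: ModelParams, t_dose: float) -> np.ndarray:
        ka = params.ka_max * (1.0 - math.exp(-max(t - t_dose, 0.0) * inv_tau))
        a = base.copy()
        a[0, 0] = -ka
        a[2, 0] = ka
        return a

    segment_bounds = np.concatenate((dose_times, [t_end]))
    for k in range(len(dose_times)):
        y[0] += dose_ug
        t0, t1 = segment_bounds[k], segment_bounds[k + 1]
        if t1 <= t0:
            continue
        ts = _segment_times(t0, t1, out_times)
        sol, info = odeint(
            derivatives,
            y,
            ts,
            args=(params, t0),
            Dfun=jac,
            rtol=rtol,
            atol=atol,
            mxstep=20000,
            full_output=True,
        )
        if info["message"] != "Integration successful.":
            raise IntegrationError(
                f"solver failed in segment starting at t={t0} h: {info['message']} "
                f"(last accepted time {info['tcur'][-1]:.3f} h)"
            )
        y = sol[-1]
        keep = np.isin(ts, out_times)
        if k + 1 < len(dose_times):
            # record dose-instant values post-dose (from the next segment)
            keep &= ts != t1
        times_acc.append(ts[keep])
        amounts_acc.append(sol[keep])

    times = np.concatenate(times_acc)
    amounts = np.vstack(amounts_acc)
    times, idx = np.unique(times, return_index=True)
    amounts = amounts[idx]

    total = regimen.n_doses * dose_ug
    if total > 0 and amounts.min() < -1e-6 * total:
        raise IntegrationError(
            f"negative compartment amount {amounts.min():.3e} µg "
            f"(dose total {total:.3e} µg); integration diverged"
        )
    np.clip(amounts, 0.0, None, out=amounts)
    return SimulationOutput(
        times=times, amounts=amounts, params=params, regimen=regimen, dose_total_ug=total
    )


def build_model_params(
    drug: DrugParams,
    physiology: Physiology,
    coeffs: GestationalCoefficients,
    ga: float = 0.0,
    param_factors: dict[str, float] | None = None,
) -> ModelParams:
    """Assemble ODE coefficients for one gestational-age snapshot.

    Runs the full parameterization chain: gestational physiology scaling,
    IVIVE with gestational CYP activity multipliers and the frozen
    calibration scalar, and tissue-composition partition coefficients with
    their frozen adjustment factors. ``param_factors`` applies multiplicative
    perturbations (Monte Carlo or sensitivity) to the drug-level parameters:
    keys fu0, clint, cl_bile, k_empty, ka_max, tau_a, and kp_<compartment>.
    """
    f = dict(param_factors or {})
    fu0 = drug.fu0 * f.pop("fu0", 1.0)
    if not 0 < fu0 < 1:
        raise ValueError(f"perturbed fu0 out of (0, 1): {fu0}")
    state = gestation_scale(physiology, coeffs, ga, fu0)
    clearance = clint_at_ga(scale_to_liver(drug, physiology), state)
    kp = build_partition_set(drug.logp, drug.fu0, drug.calibration.kp_adjustment)
    params = ModelParams(
        v_plasma=state.volumes["plasma"],
        v_gut=state.volumes["gut"],
        v_liver=state.volumes["liver"],
        v_rich=state.volumes["richly_perfused"],
        v_slow=state.volumes["slowly_perfused"],
        q_gut=state.flows["gut"],
        q_liver_arterial=state.flows["liver_arterial"],
        q_rich=state.flows["richly_perfused"],
        q_slow=state.flows["slowly_perfused"],
        kp_gut=kp.kp["gut"] * f.pop("kp_gut", 1.0),
        kp_liver=kp.kp["liver"] * f.pop("kp_liver", 1.0),
        kp_rich=kp.kp["richly_perfused"] * f.pop("kp_richly_perfused", 1.0),
        kp_slow=kp.kp["slowly_perfused"] * f.pop("kp_slowly_perfused", 1.0),
        fu=state.fu,
        clint_u=clearance.total * drug.calibration.clint_scalar * f.pop("clint", 1.0),
        cl_bile=drug.enterohepatic.cl_bile_L_h * f.pop("cl_bile", 1.0),
        k_empty=drug.enterohepatic.k_empty_per_h * f.pop("k_empty", 1.0),
        ka_max=drug.absorption.ka_max_per_h * f.pop("ka_max", 1.0),
        tau_a=drug.absorption.tau_a_h * f.pop("tau_a", 1.0),
        ga=ga,
        body_weight=state.body_weight,
    )
    if f:
        raise ValueError(f"unknown param_factors keys: {sorted(f)}")
    return params
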