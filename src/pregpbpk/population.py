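"""Monte Carlo population simulation with truncated parameter distributions.

Inter-subject variability and parameter uncertainty are propagated by
sampling model parameters from truncated distributions: lognormal for
drug-specific parameters (partition coefficients, absorption and elimination
constants, fraction unbound) and for body weight and cardiac output, normal
for the other physiological parameters. Default coefficients of variation are
20% for partition coefficients and 30% for physiological, absorption and
elimination parameters. Draws are rejected and redrawn outside the 2.5th and
97.5th percentiles of their family (rejection keeps the distribution shape,
unlike clipping), and fractional tissue volumes / blood flows are rescaled
per draw so their sums match the reference physiology (flows sum to 1).

Gestational trajectories themselves are not sampled: every virtual subject
experiences the same pregnancy-related changes applied to her sampled
nonpregnant baseline.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .config import DrugParams, GestationalCoefficients, Physiology
from .model import Regimen, build_model_params, simulate
from .nca import NCAResult, nca, nca_from_arrays

CV_PARTITION = 0.20
CV_PHYSIOLOGY = 0.30
CV_KINETIC = 0.30
CV_FU = 0.15  # experimentally measured plasma binding varies less

MAX_FAILURE_FRACTION = 0.05


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution for one parameter, truncated at the family's
    2.5th/97.5th percentiles."""

    param: str
    family: Literal["lognormal", "normal"]
    mean: float
    cv: float
    group: str | None = None  # renormalization group ("volumes" | "flows")
    bounds: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        if self.cv <= 0:
            raise ValueError(f"{self.param}: cv must be > 0, got {self.cv}")
        if self.mean <= 0:
            raise ValueError(f"{self.param}: mean must be > 0, got {self.mean}")
        dist = self._frozen()
        lo, hi = dist.ppf(0.025), dist.ppf(0.975)
        if not lo < self.mean < hi:
            raise ValueError(f"{self.param}: infeasible truncation bounds ({lo}, {hi})")
        object.__setattr__(self, "bounds", (float(lo), float(hi)))

    def _frozen(self):
        if self.family == "lognormal":
            sigma2 = np.log1p(self.cv**2)
            mu = np.log(self.mean) - sigma2 / 2.0
            return stats.lognorm(s=np.sqrt(sigma2), scale=np.exp(mu))
        return stats.norm(loc=self.mean, scale=self.cv * self.mean)

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Rejection-sample ``size`` values inside the truncation bounds."""
        dist = self._frozen()
        lo, hi = self.bounds
        out = np.empty(size)
        filled = 0
        while filled < size:
            vals = dist.rvs(size=size - filled, random_state=rng)
            ok = vals[(vals >= lo) & (vals <= hi)]
            out[filled : filled + len(ok)] = ok
            filled += len(ok)
        return out


def default_distributions(drug: DrugParams, physiology: Physiology) -> list[DistributionSpec]:
    """The packaged sampling plan for the sensitive model parameters."""
    specs: list[DistributionSpec] = [
        DistributionSpec("body_weight_kg", "lognormal", physiology.body_weight_kg, CV_PHYSIOLOGY),
        DistributionSpec("cardiac_output_L_h", "lognormal", physiology.cardiac_output_L_h, CV_PHYSIOLOGY),
    ]
    for comp, frac in physiology.fractional_volumes.items():
        specs.append(DistributionSpec(f"fv_{comp}", "normal", frac, CV_PHYSIOLOGY, group="volumes"))
    for comp, frac in physiology.fractional_flows.items():
        specs.append(DistributionSpec(f"fq_{comp}", "normal", frac, CV_PHYSIOLOGY, group="flows"))
    for comp in ("gut", "liver", "richly_perfused", "slowly_perfused"):
        specs.append(DistributionSpec(f"kp_{comp}", "lognormal", 1.0, CV_PARTITION))
    for name in ("clint", "ka_max", "tau_a", "cl_bile", "k_empty"):
        specs.append(DistributionSpec(name, "lognormal", 1.0, CV_KINETIC))
    specs.append(DistributionSpec("fu0", "lognormal", 1.0, CV_FU))
    return specs


def sample_parameters(
    specs: list[DistributionSpec], n: int, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Draw ``n`` parameter sets; fractional volume/flow groups are rescaled
    so each draw preserves the nominal group sum (flows sum to 1)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = {spec.param: spec.draw(rng, n) for spec in specs}
    frame = pd.DataFrame(draws)
    for group in ("volumes", "flows"):
        members = [s.param for s in specs if s.group == group]
        if not members:
            continue
        nominal = sum(s.mean for s in specs if s.group == group)
        total = frame[members].sum(axis=1)
        frame[members] = frame[members].mul(nominal / total, axis=0)
    return frame


def _perturbed_inputs(
    row: pd.Series, drug: DrugParams, physiology: Physiology
) -> tuple[Physiology, dict[str, float]]:
    phys_update: dict = {}
    if "body_weight_kg" in row:
        phys_update["body_weight_kg"] = float(row["body_weight_kg"])
    if "cardiac_output_L_h" in row:
        phys_update["cardiac_output_L_h"] = float(row["cardiac_output_L_h"])
    fv = {
        k: float(row[f"fv_{k}"]) if f"fv_{k}" in row else v
        for k, v in physiology.fractional_volumes.items()
    }
    fq = {
        k: float(row[f"fq_{k}"]) if f"fq_{k}" in row else v
        for k, v in physiology.fractional_flows.items()
    }
    phys = physiology.model_copy(
        update={**phys_update, "fractional_volumes": fv, "fractional_flows": fq}
    )
    Physiology.model_validate(phys.model_dump())
    factor_names = (
        "fu0", "clint", "ka_max", "tau_a", "cl_bile", "k_empty",
        "kp_gut", "kp_liver", "kp_richly_perfused", "kp_slowly_perfused",
    )
    factors = {}
    for name in factor_names:
        if name in row:
            factors[name] = float(row[name])
    return phys, factors


@dataclass(frozen=True)
class MonteCarloResult:
    """Population simulation summary over the final dosing interval."""

    times: np.ndarray  # h since last dose
    percentiles: pd.DataFrame  # columns p2.5, p50, p97.5 (µg/L)
    median_nca: NCAResult  # NCA of the median predicted curve
    iteration_nca: pd.DataFrame  # one NCA row per iteration
    parameters: pd.DataFrame  # sampled parameter sets actually used
    n_failed: int
    seed: int


def monte_carlo(
    drug: DrugParams,
    physiology: Physiology,
    coeffs: GestationalCoefficients,
    regimen: Regimen,
    ga: float = 0.0,
    n: int = 1000,
    seed: int = 0,
    washout_h: float = 72.0,
    specs: list[DistributionSpec] | None = None,
) -> MonteCarloResult:
    """Run ``n`` seeded population iterations at one gestational age.

    Returns pointwise 2.5th/50th/97.5th percentile plasma concentrations over
    the final dosing interval plus washout, per-iteration NCA, and the NCA of
    the median predicted curve. Failed iterations are resampled, up to 5% of n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    specs = default_distributions(drug, physiology) if specs is None else specs

    t_rel = None
    curves: list[np.ndarray] = []
    nca_rows: list[dict] = []
    used_rows: list[pd.Series] = []
    n_failed = 0
    max_failures = max(1, int(np.ceil(MAX_FAILURE_FRACTION * n)))
    while len(curves) < n:
        batch = sample_parameters(specs, n - len(curves), rng)
        for _, row in batch.iterrows():
            try:
                phys_i, factors = _perturbed_inputs(row, drug, physiology)
                params = build_model_params(drug, phys_i, coeffs, ga, param_factors=factors)
                out = simulate(params, regimen, washout_h=washout_h)
                res = nca(out)
            except Exception:
                n_failed += 1
                if n_failed > max_failures:
                    raise RuntimeError(
                        f"more than {max_failures} failed Monte Carlo iterations"
                    )
                continue
            mask = out.times >= regimen.last_dose_time
            if t_rel is None:
                t_rel = out.times[mask] - regimen.last_dose_time
            curves.append(out.conc[mask])
            nca_rows.append(res.as_dict())
            used_rows.append(row)

    conc = np.vstack(curves)
    lo, med, hi = np.percentile(conc, [2.5, 50.0, 97.5], axis=0)
    percentiles = pd.DataFrame({"time_h": t_rel, "p2.5": lo, "p50": med, "p97.5": hi})
    median_nca = nca_from_arrays(
        t_rel, med, t_last_dose=0.0, interval=regimen.interval_h, dose_mg=regimen.dose_mg
    )
    return MonteCarloResult(
        times=t_rel,
        percentiles=percentiles,
        median_nca=median_nca,
        iteration_nca=pd.DataFrame(nca_rows),
        parameters=pd.DataFrame(used_rows).reset_index(drop=True),
        n_failed=n_failed,
        seed=seed,
    )
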