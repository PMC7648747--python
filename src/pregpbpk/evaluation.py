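"""Predictive-performance metrics: fold-error bias and precision.

Bias is the average fold error AFE = 10^(mean log10(pred/obs)): values below
1 indicate systematic underprediction. Precision is the absolute average fold
error AAFE = 10^(mean |log10(pred/obs)|), always >= 1. A prediction is
"within twofold" when 0.5 <= pred/obs <= 2 (closed bounds).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class EvalPair:
    predicted: float
    observed: float
    subject: str = ""
    metric: str = ""
    trimester: str = ""

    def __post_init__(self) -> None:
        if self.predicted <= 0 or self.observed <= 0:
            raise ValueError("predicted and observed must be > 0 (log metrics)")


@dataclass(frozen=True)
class EvalSummary:
    afe: float
    aafe: float
    twofold_fraction: float
    n: int


def _ratios(pairs: list[EvalPair]) -> np.ndarray:
    if not pairs:
        raise ValueError("need at least one predicted/observed pair")
    return np.array([p.predicted / p.observed for p in pairs])


def afe(pairs: list[EvalPair]) -> float:
    """Average fold error (geometric mean of predicted/observed)."""
    return float(10 ** np.mean(np.log10(_ratios(pairs))))


def aafe(pairs: list[EvalPair]) -> float:
    """Absolute average fold error; 1 is perfect, always >= AFE when AFE >= 1."""
    return float(10 ** np.mean(np.abs(np.log10(_ratios(pairs)))))


def twofold_flags(pairs: list[EvalPair]) -> tuple[list[bool], float]:
    """Per-pair within-twofold flags (0.5 <= ratio <= 2, inclusive) and their
    fraction."""
    r = _ratios(pairs)
    flags = [(0.5 <= x <= 2.0) for x in r]
    return flags, float(np.mean(flags))


def evaluate(pairs: list[EvalPair]) -> EvalSummary:
    flags, frac = twofold_flags(pairs)
    return EvalSummary(afe=afe(pairs), aafe=aafe(pairs), twofold_fraction=frac, n=len(pairs))


def evaluate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Evaluate a tidy table with columns predicted, observed and (optionally)
    metric; returns one summary row per metric."""
    if "metric" not in frame:
        frame = frame.assign(metric="all")
    rows = []
    for metric, grp in frame.groupby("metric"):
        pairs = [
            EvalPair(predicted=r.predicted, observed=r.observed, metric=str(metric))
            for r in grp.itertuples()
        ]
        s = evaluate(pairs)
        rows.append(
            {"metric": metric, "afe": s.afe, "aafe": s.aafe,
             "twofold_fraction": s.twofold_fraction, "n": s.n}
        )
    return pd.DataFrame(rows)
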