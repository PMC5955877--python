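"""geNorm expression-stability engine.

For a complete samples x targets matrix of relative quantities Q the engine
computes, per target, the average expression stability

    M_j = mean over k != j of V_jk,
    V_jk = sd over samples of log2(Q_j / Q_k)   (sample sd, n-1 denominator),

then ranks targets by stepwise exclusion: the target with the highest current
M is removed and M recomputed on the reduced set until two remain (which a
pairwise measure cannot separate — they are reported tied). Normalization
factors are per-sample geometric means of the selected targets' quantities,
and the pairwise variation V_n/n+1 between factors built from the n and n+1
most stable targets indicates whether adding a target is worthwhile; the
smallest n with V_n/n+1 below 0.15 is the recommended target count. M below
0.5 / 0.2 marks high / very high stability.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import QuantityMatrix

__all__ = [
    "GeNormError",
    "StabilityConfig",
    "StabilityResult",
    "pairwise_variation",
    "m_value",
    "m_values",
    "rank_stepwise",
    "normalization_factor",
    "v_curve",
    "optimal_target_count",
    "classify_stability",
    "analyze_stability",
    "write_stability_tables",
]


class GeNormError(ValueError):
    pass


@dataclass(frozen=True)
class StabilityConfig:
    """Stability thresholds: M < m_high is 'high', M < m_very_high is 'very
    high' stability; V below v_cutoff means no further target is needed."""

    m_high: float = 0.5
    m_very_high: float = 0.2
    v_cutoff: float = 0.15

    def __post_init__(self) -> None:
        if not 0 < self.m_very_high < self.m_high:
            raise GeNormError("need 0 < m_very_high < m_high")
        if self.v_cutoff <= 0:
            raise GeNormError("v_cutoff must be positive")


@dataclass
class StabilityResult:
    m_values: dict[str, float]              # first-pass M per target
    elimination_order: list[tuple[str, float]]  # least stable first, M at elimination
    ranked_targets: list[str]               # most stable first; final two tied
    v_series: dict[int, float]              # n -> V_n/n+1
    optimal_n: int
    optimal_n_flag: str | None
    classes: dict[str, str]                 # from first-pass M
    config: StabilityConfig = field(default_factory=StabilityConfig)


def _log2q(q: QuantityMatrix) -> np.ndarray:
    arr = np.log2(q.quantities)
    if not np.all(np.isfinite(arr)):
        raise GeNormError("quantities must be finite and positive")
    return arr


def pairwise_variation(q: QuantityMatrix, j: str, k: str) -> float:
    """V_jk: sample standard deviation of log2(Q_j / Q_k) across samples."""
    if j == k:
        raise GeNormError("pairwise variation requires two distinct targets")
    if len(q.sample_ids) < 2:
        raise GeNormError("need at least 2 samples")
    lq = _log2q(q)
    jj, kk = q.target_ids.index(j), q.target_ids.index(k)
    return float(np.std(lq[:, jj] - lq[:, kk], ddof=1))


def _m_from_log(lq: np.ndarray) -> np.ndarray:
    """First-pass M for every column of a log2-quantity matrix."""
    n, t = lq.shape
    if t < 2:
        raise GeNormError("need at least 2 targets for M")
    if n < 2:
        raise GeNormError("need at least 2 samples for M")
    # V matrix of all pairwise log-ratio sds
    diff = lq[:, :, None] - lq[:, None, :]          # samples x t x t
    v = np.std(diff, axis=0, ddof=1)
    return v.sum(axis=1) / (t - 1)                  # diagonal contributes 0


def m_value(q: QuantityMatrix, j: str) -> float:
    """Average stability M_j: mean of V_jk over all other targets k."""
    if len(q.target_ids) < 2:
        raise GeNormError("M undefined for a single-target matrix")
    return float(_m_from_log(_log2q(q))[q.target_ids.index(j)])


def m_values(q: QuantityMatrix) -> dict[str, float]:
    m = _m_from_log(_log2q(q))
    return dict(zip(q.target_ids, m.tolist()))


def rank_stepwise(q: QuantityMatrix) -> tuple[list[tuple[str, float]], list[str]]:
    """Stepwise-exclusion ranking.

    Repeatedly removes the target with the highest current M (ties broken by
    target id, the lexicographically later id removed first) and recomputes M
    on the reduced set. The final pair shares one M value and is ordered
    lexicographically among the most-stable ranks. Returns
    (elimination_order with M at each step, ranked_targets most-stable-first).
    """
    if len(q.target_ids) < 3:
        raise GeNormError("stepwise ranking needs at least 3 targets")
    if len(q.sample_ids) < 2:
        raise GeNormError("stepwise ranking needs at least 2 samples")
    lq = _log2q(q)
    remaining = list(q.target_ids)
    cols = {t: i for i, t in enumerate(q.target_ids)}
    elimination: list[tuple[str, float]] = []
    while len(remaining) > 2:
        m = _m_from_log(lq[:, [cols[t] for t in remaining]])
        worst = max(zip(m, remaining), key=lambda mt: (mt[0], mt[1]))
        elimination.append((worst[1], float(worst[0])))
        remaining.remove(worst[1])
    last_m = float(_m_from_log(lq[:, [cols[t] for t in remaining]])[0])
    a, b = sorted(remaining)
    elimination.append((b, last_m))
    elimination.append((a, last_m))
    ranked = [t for t, _ in reversed(elimination)]
    return elimination, ranked


def normalization_factor(q: QuantityMatrix, targets: Sequence[str]) -> np.ndarray:
    """Per-sample geometric mean of the selected targets' quantities."""
    if not targets:
        raise GeNormError("normalization factor needs at least one target")
    sub = q.subset(targets)
    if np.any(sub <= 0):
        raise GeNormError("quantities must be positive")
    return np.exp(np.mean(np.log(sub), axis=1))


def v_curve(q: QuantityMatrix, ranked_targets: Sequence[str]) -> dict[int, float]:
    """V_n/n+1 for n = 2..T-1: sd of log2(NF_n / NF_{n+1}) across samples."""
    t = len(ranked_targets)
    if t < 3:
        raise GeNormError("V series needs at least 3 ranked targets")
    out: dict[int, float] = {}
    for n in range(2, t):
        nf_n = normalization_factor(q, ranked_targets[:n])
        nf_n1 = normalization_factor(q, ranked_targets[: n + 1])
        out[n] = float(np.std(np.log2(nf_n / nf_n1), ddof=1))
    return out


def optimal_target_count(
    v_series: dict[int, float], cutoff: float = 0.15
) -> tuple[int, str | None]:
    """Smallest n with V_n/n+1 below the cutoff; falls back to all targets.

    When no V drops below the cutoff, returns T (the full target count
    implied by the series) together with an advisory flag.
    """
    if not v_series:
        raise GeNormError("empty V series")
    for n in sorted(v_series):
        if v_series[n] < cutoff:
            return n, None
    return max(v_series) + 1, "no V below cutoff"


def classify_stability(m: float, config: StabilityConfig | None = None) -> str:
    config = config or StabilityConfig()
    if m < 0:
        raise GeNormError("M cannot be negative")
    if m < config.m_very_high:
        return "very_high"
    if m < config.m_high:
        return "high"
    return "unstable"


def analyze_stability(
    q: QuantityMatrix, config: StabilityConfig | None = None
) -> StabilityResult:
    """Full geNorm pass: first-pass M, stepwise ranking, V series, optimal n,
    and stability classes (from first-pass M)."""
    config = config or StabilityConfig()
    first_pass = m_values(q)
    elimination, ranked = rank_stepwise(q)
    v = v_curve(q, ranked)
    optimal_n, flag = optimal_target_count(v, config.v_cutoff)
    classes = {t: classify_stability(m, config) for t, m in first_pass.items()}
    return StabilityResult(first_pass, elimination, ranked, v, optimal_n, flag, classes, config)


def write_stability_tables(result: StabilityResult, prefix: str | Path) -> None:
    """Write the per-target table, the V table, and a JSON summary.

    ``prefix`` gains suffixes ``.targets.tsv``, ``.v.tsv`` and ``.json``.
    """
    prefix = Path(prefix)
    elim_m = dict(result.elimination_order)
    rank = {t: i + 1 for i, t in enumerate(result.ranked_targets)}
    rows = [
        {
            "target": t,
            "M_first_pass": result.m_values[t],
            "rank": rank[t],
            "M_at_elimination": elim_m[t],
            "class": result.classes[t],
        }
        for t in result.ranked_targets
    ]
    pd.DataFrame(rows).to_csv(prefix.with_suffix(".targets.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [{"n": n, "V": v} for n, v in sorted(result.v_series.items())]
    ).to_csv(prefix.with_suffix(".v.tsv"), sep="\t", index=False)
    summary = {
        "ranked_targets": result.ranked_targets,
        "optimal_n": result.optimal_n,
        "optimal_n_flag": result.optimal_n_flag,
        "thresholds": {
            "m_high": result.config.m_high,
            "m_very_high": result.config.m_very_high,
            "v_cutoff": result.config.v_cutoff,
        },
    }
    prefix.with_suffix(".json").write_text(json.dumps(summary, indent=2) + "\n")
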