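"""Cross-experiment consensus ranking of reference targets.

Per-experiment stability rankings (targets ordered by geNorm M-value) are
combined into a single consensus order that minimizes the summed Spearman
footrule distance

    f(c) = sum over lists L, targets t of w_L(t) * |pos_c(t) - pos_L(t)|

with 1-based positions and optional per-list weights derived from the
stability scores by min-max normalization (weighted mode is the default, the
unweighted footrule the verifiable fallback). Small universes (<= 9 targets)
are solved exactly by enumeration; larger ones by a cross-entropy Monte Carlo
search over permutations driven by a position-probability matrix.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RankAggError",
    "RankedList",
    "CeConfig",
    "ConsensusRanking",
    "objective_of",
    "aggregate_exhaustive",
    "aggregate_ce",
    "mean_rank_positions",
    "stability_box_summary",
    "read_ranking_table",
    "write_consensus",
]

EXHAUSTIVE_LIMIT = 9


class RankAggError(ValueError):
    pass


@dataclass(frozen=True)
class RankedList:
    """One experiment's ranking, most stable target first.

    ``scores`` (target -> stability measure, lower = more stable) must be
    non-decreasing along the ordering when supplied.
    """

    experiment_id: str
    ordering: tuple[str, ...]
    scores: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if len(set(self.ordering)) != len(self.ordering):
            raise RankAggError(f"duplicate targets in list {self.experiment_id}")
        if self.scores is not None:
            if set(self.scores) != set(self.ordering):
                raise RankAggError(
                    f"scores and ordering disagree on targets in {self.experiment_id}"
                )
            s = [self.scores[t] for t in self.ordering]
            if any(b < a - 1e-12 for a, b in zip(s, s[1:])):
                raise RankAggError(
                    f"ordering of {self.experiment_id} inconsistent with scores"
                )

    def positions(self) -> dict[str, int]:
        return {t: i + 1 for i, t in enumerate(self.ordering)}


def _universe(lists: Sequence[RankedList]) -> list[str]:
    if len(lists) < 1:
        raise RankAggError("need at least one ranked list")
    universe = set(lists[0].ordering)
    for lst in lists[1:]:
        if set(lst.ordering) != universe:
            raise RankAggError(
                f"list {lst.experiment_id} does not rank the shared target universe"
            )
    return sorted(universe)


def _weights(lst: RankedList, distance: str, universe: Sequence[str]) -> np.ndarray:
    if distance == "footrule":
        return np.ones(len(universe))
    if distance != "weighted_footrule":
        raise RankAggError(f"unknown distance {distance!r}")
    if lst.scores is None:
        raise RankAggError(
            f"weighted footrule needs scores on list {lst.experiment_id}"
        )
    s = np.array([lst.scores[t] for t in universe], dtype=float)
    span = s.max() - s.min()
    if span == 0:
        return np.ones(len(universe))
    return (s - s.min()) / span


def objective_of(
    candidate: Sequence[str],
    lists: Sequence[RankedList],
    distance: str = "weighted_footrule",
) -> float:
    """Summed (weighted) footrule distance of a candidate ordering."""
    universe = _universe(lists)
    if sorted(candidate) != universe:
        raise RankAggError("candidate is not a permutation of the target universe")
    cand_pos = {t: i + 1 for i, t in enumerate(candidate)}
    total = 0.0
    for lst in lists:
        w = _weights(lst, distance, universe)
        pos = lst.positions()
        total += sum(
            wi * abs(cand_pos[t] - pos[t]) for wi, t in zip(w, universe)
        )
    return float(total)


def mean_rank_positions(lists: Sequence[RankedList]) -> dict[str, float]:
    """Arithmetic mean of each target's 1-based rank across experiments."""
    universe = _universe(lists)
    out = {}
    for t in universe:
        out[t] = float(np.mean([lst.positions()[t] for lst in lists]))
    return out


@dataclass(frozen=True)
class CeConfig:
    """Cross-entropy search settings; sample_size defaults to 10*k^2."""

    sample_size: int | None = None
    elite_fraction: float = 0.1
    smoothing: float = 0.25
    max_iterations: int = 100
    convergence_patience: int = 15

    def __post_init__(self) -> None:
        if self.sample_size is not None and self.sample_size < 2:
            raise RankAggError("sample_size must be >= 2")
        if not 0 < self.elite_fraction < 1:
            raise RankAggError("elite_fraction must be in (0, 1)")
        if not 0 < self.smoothing <= 1:
            raise RankAggError("smoothing must be in (0, 1]")
        if self.max_iterations < 1 or self.convergence_patience < 1:
            raise RankAggError("iteration counts must be positive")


@dataclass
class ConsensusRanking:
    ordering: tuple[str, ...]
    objective: float
    method: str  # exhaustive | cross_entropy
    mean_rank: dict[str, float]
    distance: str
    seed: int | None = None
    config: CeConfig | None = None
    iterations: int | None = None


def aggregate_exhaustive(
    lists: Sequence[RankedList], distance: str = "weighted_footrule"
) -> ConsensusRanking:
    """Global minimum over all permutations (universe of at most 9 targets).

    Ties on the objective are broken by mean rank, then lexicographically.
    """
    universe = _universe(lists)
    k = len(universe)
    if k > EXHAUSTIVE_LIMIT:
        raise RankAggError(
            f"universe of {k} targets too large for enumeration "
            f"(limit {EXHAUSTIVE_LIMIT}); use aggregate_ce"
        )
    mean_rank = mean_rank_positions(lists)
    best: tuple[float, list[tuple[float, str]], tuple[str, ...]] | None = None
    for perm in itertools.permutations(universe):
        obj = objective_of(perm, lists, distance)
        key = (obj, [(mean_rank[t], t) for t in perm], perm)
        if best is None or key < best:
            best = key
    assert best is not None
    return ConsensusRanking(best[2], best[0], "exhaustive", mean_rank, distance)


def _sample_permutations(
    p: np.ndarray, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample permutations position-by-position without replacement from a
    position-probability matrix p (positions x targets)."""
    k = p.shape[0]
    avail = np.ones((size, k), dtype=bool)
    perms = np.empty((size, k), dtype=np.int64)
    rows = np.arange(size)
    for pos in range(k):
        w = p[pos][None, :] * avail
        tot = w.sum(axis=1, keepdims=True)
        w = np.where(tot > 0, w, avail.astype(float))
        w = w / w.sum(axis=1, keepdims=True)
        cum = np.cumsum(w, axis=1)
        u = rng.random((size, 1))
        choice = np.minimum((u > cum).sum(axis=1), k - 1)
        perms[:, pos] = choice
        avail[rows, choice] = False
    return perms


def aggregate_ce(
    lists: Sequence[RankedList],
    distance: str = "weighted_footrule",
    config: CeConfig | None = None,
    seed: int | None = None,
) -> ConsensusRanking:
    """Cross-entropy Monte Carlo minimization of the aggregation objective.

    A k x k position-probability matrix starts uniform; each iteration samples
    ``sample_size`` permutations from it, keeps the ``elite_fraction`` with the
    lowest objective, and relaxes the matrix toward the elite's positional
    frequencies with the ``smoothing`` learning rate. Search stops after
    ``convergence_patience`` iterations without improving the best-ever
    objective, or at ``max_iterations``. Identical seeds give identical
    results.
    """
    if len(lists) < 2:
        raise RankAggError("cross-entropy aggregation needs at least 2 lists")
    config = config or CeConfig()
    universe = _universe(lists)
    k = len(universe)
    size = config.sample_size or 10 * k * k
    rng = np.random.default_rng(seed)

    # Precompute per-list positions and weights over the sorted universe.
    pos = np.array([[lst.positions()[t] for t in universe] for lst in lists])
    wts = np.array([_weights(lst, distance, universe) for lst in lists])

    def batch_objective(perms: np.ndarray) -> np.ndarray:
        inv = np.empty_like(perms)
        rows = np.arange(perms.shape[0])[:, None]
        inv[rows, perms] = np.arange(1, k + 1)[None, :]
        # inv[s, t] = 1-based position of target t in sample s
        return np.einsum("lt,slt->s", wts, np.abs(inv[:, None, :] - pos[None, :, :]))

    p = np.full((k, k), 1.0 / k)
    n_elite = max(1, math.ceil(size * config.elite_fraction))
    best_obj = math.inf
    best_perm: np.ndarray | None = None
    stall = 0
    iterations = 0
    for iterations in range(1, config.max_iterations + 1):
        perms = _sample_permutations(p, size, rng)
        objs = batch_objective(perms)
        order = np.argsort(objs, kind="stable")
        if objs[order[0]] < best_obj - 1e-12:
            best_obj = float(objs[order[0]])
            best_perm = perms[order[0]].copy()
            stall = 0
        else:
            stall += 1
        elite = perms[order[:n_elite]]
        freq = np.zeros((k, k))
        for pos_i in range(k):
            counts = np.bincount(elite[:, pos_i], minlength=k)
            freq[pos_i] = counts / n_elite
        p = (1 - config.smoothing) * p + config.smoothing * freq
        if stall >= config.convergence_patience:
            break
    assert best_perm is not None
    ordering = tuple(universe[i] for i in best_perm)
    return ConsensusRanking(
        ordering,
        best_obj,
        "cross_entropy",
        mean_rank_positions(lists),
        distance,
        seed=seed,
        config=config,
        iterations=iterations,
    )


def aggregate(
    lists: Sequence[RankedList],
    distance: str = "weighted_footrule",
    config: CeConfig | None = None,
    seed: int | None = None,
) -> ConsensusRanking:
    """Exhaustive when the universe permits it, cross-entropy otherwise."""
    if len(_universe(lists)) <= EXHAUSTIVE_LIMIT:
        return aggregate_exhaustive(lists, distance)
    return aggregate_ce(lists, distance, config, seed)


def stability_box_summary(lists: Sequence[RankedList]) -> pd.DataFrame:
    """Per-target box summary of stability scores across experiments:
    quartiles (linear-interpolation definition), median, and outliers beyond
    1.5 x IQR from the box."""
    universe = _universe(lists)
    rows = []
    for t in universe:
        vals = np.array([lst.scores[t] for lst in lists if lst.scores is not None])
        if vals.size == 0:
            raise RankAggError("box summary needs scores on the lists")
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        outliers = vals[(vals < q1 - 1.5 * iqr) | (vals > q3 + 1.5 * iqr)]
        rows.append(
            {
                "target": t,
                "q1": q1,
                "median": med,
                "q3": q3,
                "outliers": ";".join(repr(v) for v in sorted(outliers)),
            }
        )
    return pd.DataFrame(rows)


def read_ranking_table(path: str | Path) -> list[RankedList]:
    """Read per-experiment rankings from TSV columns experiment,target,rank,M."""
    df = pd.read_csv(path, sep="\t")
    required = {"experiment", "target", "rank"}
    if not required.issubset(df.columns):
        raise RankAggError(f"ranking table needs columns {sorted(required)}")
    out = []
    for exp, grp in df.groupby("experiment", sort=False):
        grp = grp.sort_values("rank")
        scores = (
            dict(zip(grp["target"], grp["M"].astype(float))) if "M" in grp else None
        )
        out.append(RankedList(str(exp), tuple(grp["target"]), scores))
    return out


def write_consensus(result: ConsensusRanking, path: str | Path) -> None:
    payload = {
        "ordering": list(result.ordering),
        "objective": result.objective,
        "method": result.method,
        "distance": result.distance,
        "seed": result.seed,
        "mean_rank": result.mean_rank,
        "config": asdict(result.config) if result.config else None,
        "iterations": result.iterations,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
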