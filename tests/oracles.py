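"""Independent straight-line oracles used to cross-check the package.

These deliberately avoid the library's vectorized code paths: plain Python
loops, the statistics module, and itertools enumeration only.
"""

from __future__ import annotations

import itertools
import math
import statistics


def oracle_pairwise_v(qj: list[float], qk: list[float]) -> float:
    ratios = [math.log2(a / b) for a, b in zip(qj, qk)]
    return statistics.stdev(ratios)


def oracle_m(quantities: dict[str, list[float]], j: str) -> float:
    vs = [oracle_pairwise_v(quantities[j], quantities[k]) for k in quantities if k != j]
    return sum(vs) / len(vs)


def oracle_rank_stepwise(
    quantities: dict[str, list[float]],
) -> tuple[list[tuple[str, float]], list[str]]:
    """Stepwise exclusion with the same tie-break contract: highest M first,
    ties resolved by removing the lexicographically later id."""
    remaining = dict(quantities)
    elimination: list[tuple[str, float]] = []
    while len(remaining) > 2:
        ms = {t: oracle_m(remaining, t) for t in remaining}
        worst = max(ms, key=lambda t: (ms[t], t))
        elimination.append((worst, ms[worst]))
        del remaining[worst]
    a, b = sorted(remaining)
    last = oracle_pairwise_v(remaining[a], remaining[b])
    elimination.append((b, last))
    elimination.append((a, last))
    return elimination, [t for t, _ in reversed(elimination)]


def oracle_nf(quantities: dict[str, list[float]], targets: list[str]) -> list[float]:
    n = len(quantities[targets[0]])
    out = []
    for i in range(n):
        prod = 1.0
        for t in targets:
            prod *= quantities[t][i]
        out.append(prod ** (1.0 / len(targets)))
    return out


def oracle_v_series(
    quantities: dict[str, list[float]], ranked: list[str]
) -> dict[int, float]:
    out = {}
    for n in range(2, len(ranked)):
        nf_n = oracle_nf(quantities, ranked[:n])
        nf_n1 = oracle_nf(quantities, ranked[: n + 1])
        out[n] = statistics.stdev(
            [math.log2(a / b) for a, b in zip(nf_n, nf_n1)]
        )
    return out


def oracle_footrule(
    candidate: list[str],
    lists: list[tuple[list[str], dict[str, float] | None]],
    weighted: bool = False,
) -> float:
    """Hand-enumeration objective: lists are (ordering, scores-or-None)."""
    cand_pos = {t: i + 1 for i, t in enumerate(candidate)}
    total = 0.0
    for ordering, scores in lists:
        pos = {t: i + 1 for i, t in enumerate(ordering)}
        for t in ordering:
            if weighted:
                vals = list(scores.values())
                span = max(vals) - min(vals)
                w = 1.0 if span == 0 else (scores[t] - min(vals)) / span
            else:
                w = 1.0
            total += w * abs(cand_pos[t] - pos[t])
    return total


def oracle_best_permutation(
    lists: list[tuple[list[str], dict[str, float] | None]],
    weighted: bool = False,
) -> tuple[float, list[list[str]]]:
    """Global minimum objective and every minimizing permutation."""
    universe = sorted(lists[0][0])
    best = math.inf
    argmins: list[list[str]] = []
    for perm in itertools.permutations(universe):
        obj = oracle_footrule(list(perm), lists, weighted)
        if obj < best - 1e-12:
            best = obj
            argmins = [list(perm)]
        elif abs(obj - best) <= 1e-12:
            argmins.append(list(perm))
    return best, argmins
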