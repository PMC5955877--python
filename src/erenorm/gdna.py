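"""Genomic-DNA carryover assessment from paired +RT/-RT reactions.

Because repetitive-element assays cannot avoid genomic templates, residual
gDNA after DNase treatment is quantified by running each sample with (+RT)
and without (-RT) reverse transcription. Per sample

    dCq = mean(-RT Cq over targets) - mean(+RT Cq over targets)

and the residual gDNA signal fraction is 2**(-dCq) (e.g. dCq = 11.64 cycles
-> 0.031%). A -RT reaction that never amplifies is censored at the
instrument's cycle ceiling (the substituted value is a lower bound on the
true dCq) and the sample is excluded from the confidence interval.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import CqMatrix

__all__ = [
    "GdnaError",
    "RtControlSet",
    "DeltaCqResult",
    "GdnaReport",
    "delta_cq",
    "residual_fraction",
    "round_sig",
    "summarize",
    "write_gdna_report",
]


class GdnaError(ValueError):
    pass


@dataclass
class RtControlSet:
    """Paired +RT / -RT Cq matrices over the same samples and targets."""

    plus_rt: CqMatrix
    minus_rt: CqMatrix

    def __post_init__(self) -> None:
        if self.plus_rt.sample_ids != self.minus_rt.sample_ids:
            raise GdnaError("+RT and -RT sample sets differ")
        if self.plus_rt.target_ids != self.minus_rt.target_ids:
            raise GdnaError("+RT and -RT target sets differ")

    @property
    def max_cycles(self) -> float:
        return self.minus_rt.max_cycles


@dataclass
class DeltaCqResult:
    per_sample: dict[str, float]
    censored: set[str]


def delta_cq(
    controls: RtControlSet,
    targets: Sequence[str] | None = None,
    per_target: bool = False,
) -> DeltaCqResult:
    """Per-sample dCq between -RT and +RT reactions over a target subset.

    Default is average-then-subtract (difference of per-sample mean Cq);
    ``per_target=True`` averages per-target differences instead — the two
    coincide whenever the same targets are detected in both conditions. A
    -RT non-detect contributes the cycle ceiling and censors the sample; a
    +RT non-detect invalidates the comparison and is rejected.
    """
    shared = controls.plus_rt.target_ids
    targets = list(targets) if targets is not None else list(shared)
    if not targets:
        raise GdnaError("empty target subset")
    unknown = [t for t in targets if t not in shared]
    if unknown:
        raise GdnaError(f"targets not shared by both matrices: {unknown}")
    idx = [shared.index(t) for t in targets]
    plus, minus = controls.plus_rt, controls.minus_rt
    per_sample: dict[str, float] = {}
    censored: set[str] = set()
    for i, sample in enumerate(plus.sample_ids):
        for j in idx:
            if plus.missing_mask[i, j]:
                raise GdnaError(
                    f"+RT non-detect at sample {sample!r}, target {shared[j]!r}"
                )
        minus_vals = []
        for j in idx:
            if minus.missing_mask[i, j]:
                minus_vals.append(controls.max_cycles)
                censored.add(sample)
            else:
                minus_vals.append(minus.values[i, j])
        plus_vals = [plus.values[i, j] for j in idx]
        if per_target:
            d = float(np.mean([m - p for m, p in zip(minus_vals, plus_vals)]))
        else:
            d = float(np.mean(minus_vals) - np.mean(plus_vals))
        per_sample[sample] = d
    return DeltaCqResult(per_sample, censored)


def residual_fraction(delta: float) -> float:
    """Residual gDNA signal as a percentage: 100 * 2**(-delta).

    A negative dCq (more signal without RT than with) yields > 100% and
    should be treated as a failed DNase treatment.
    """
    return 100.0 * 2.0 ** (-delta)


def round_sig(x: float, digits: int = 2) -> float:
    """Round to ``digits`` significant figures (presentation helper)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + digits - 1)


@dataclass
class GdnaReport:
    per_sample_delta: dict[str, float]
    mean_delta: float
    ci95: tuple[float, float] | None
    range: tuple[float, float]
    per_sample_residual_percent: dict[str, float]
    mean_residual_percent: float
    censored_samples: tuple[str, ...]
    mean_is_lower_bound: bool = False
    ci_method: str = "t-distribution, n-1 df, two-sided 95%"


def summarize(delta: DeltaCqResult | Mapping[str, float]) -> GdnaReport:
    """Mean dCq with a two-sided 95% t-interval over uncensored samples.

    The min/max range covers all samples (censored included, at their
    conservative ceiling-substituted values). With every sample censored the
    mean is reported as a lower bound only.
    """
    if isinstance(delta, DeltaCqResult):
        per_sample, censored = delta.per_sample, delta.censored
    else:
        per_sample, censored = dict(delta), set()
    if not per_sample:
        raise GdnaError("no samples")
    all_vals = np.array(list(per_sample.values()))
    uncensored = np.array([d for s, d in per_sample.items() if s not in censored])
    if uncensored.size == 0:
        mean = float(all_vals.min())
        ci = None
        lower_bound = True
    else:
        mean = float(uncensored.mean())
        lower_bound = False
        if uncensored.size >= 2:
            half = float(
                stats.t.ppf(0.975, uncensored.size - 1)
                * uncensored.std(ddof=1)
                / math.sqrt(uncensored.size)
            )
            ci = (mean - half, mean + half)
        else:
            ci = None
    residuals = {s: residual_fraction(d) for s, d in per_sample.items()}
    return GdnaReport(
        per_sample_delta=dict(per_sample),
        mean_delta=mean,
        ci95=ci,
        range=(float(all_vals.min()), float(all_vals.max())),
        per_sample_residual_percent=residuals,
        mean_residual_percent=residual_fraction(mean),
        censored_samples=tuple(sorted(censored)),
        mean_is_lower_bound=lower_bound,
    )


def write_gdna_report(report: GdnaReport, prefix: str | Path) -> None:
    """Write the per-sample TSV and the JSON summary (``.tsv`` / ``.json``)."""
    prefix = Path(prefix)
    rows = [
        {
            "sample": s,
            "delta_cq": d,
            "residual_percent": report.per_sample_residual_percent[s],
            "censored": s in report.censored_samples,
        }
        for s, d in report.per_sample_delta.items()
    ]
    pd.DataFrame(rows).to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False)
    summary = {
        "mean_delta_cq": report.mean_delta,
        "mean_is_lower_bound": report.mean_is_lower_bound,
        "ci95": list(report.ci95) if report.ci95 else None,
        "ci_method": report.ci_method,
        "range": list(report.range),
        "mean_residual_percent": report.mean_residual_percent,
        "mean_residual_percent_2sf": round_sig(report.mean_residual_percent, 2),
        "censored_samples": list(report.censored_samples),
    }
    prefix.with_suffix(".json").write_text(json.dumps(summary, indent=2) + "\n")
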