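"""Seeded generators emulating the statistical structure of an ERE
reference-target study.

The Cq model treats each sample's total mRNA fraction as a shared shift:

    Cq_ij = baseline_j - s_i - delta_{g(i),j} - eta_ij - eps_ij

with s_i ~ N(0, sigma_s^2) the per-sample abundance shift common to every
target (the quantity normalization removes), delta a fixed condition effect,
eta_ij ~ N(0, tau_j^2) the target's biological instability, and eps_ij ~
N(0, sigma_eps^2) technical noise. A truly stable reference target has
tau = 0 and no condition effects: its Cq moves only with the shared shift.
Companion generators produce paired -RT controls with a controlled genomic
DNA fraction, dilution series of known efficiency, and transcript sets with
embedded (optionally mutated/antisense) primer-site cassettes. All
generators are pure functions of (design, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .data_model import CqMatrix
from .efficiency import DilutionSeries
from .gdna import RtControlSet
from .screen import PrimerPair, revcomp

__all__ = [
    "SimulationError",
    "TargetSpec",
    "ExperimentDesign",
    "GroundTruth",
    "generate_cq",
    "generate_rt_pairs",
    "InsertionRecord",
    "generate_transcriptome",
    "generate_dilution_series",
    "write_fasta",
]


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class TargetSpec:
    """One simulated assay: baseline Cq (cycles), instability sd tau
    (cycles), and fixed per-condition effects (cycles)."""

    target_id: str
    baseline_cq: float
    instability_sd: float = 0.0
    group_effects: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.instability_sd < 0:
            raise SimulationError(f"negative instability sd on {self.target_id}")
        if not 5.0 < self.baseline_cq < 38.0:
            raise SimulationError(
                f"baseline Cq {self.baseline_cq} of {self.target_id} outside (5, 38)"
            )

    @property
    def is_stable(self) -> bool:
        return self.instability_sd == 0 and not any(self.group_effects.values())


@dataclass(frozen=True)
class ExperimentDesign:
    n_samples: int
    targets: tuple[TargetSpec, ...]
    groups: Mapping[str, str] | None = None  # sample id -> condition label
    global_shift_sd: float = 1.0
    noise_sd: float = 0.1
    max_cycles: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise SimulationError("need at least 2 samples")
        if not self.targets:
            raise SimulationError("need at least 1 target")
        ids = [t.target_id for t in self.targets]
        if len(set(ids)) != len(ids):
            raise SimulationError("duplicate target ids in design")
        if self.global_shift_sd < 0:
            raise SimulationError("global_shift_sd must be >= 0")
        if self.noise_sd <= 0:
            raise SimulationError("noise_sd must be > 0")

    def sample_ids(self) -> list[str]:
        if self.groups is not None:
            return list(self.groups)
        return [f"s{i + 1:02d}" for i in range(self.n_samples)]


@dataclass
class GroundTruth:
    stable_targets: frozenset[str]
    sample_shifts: dict[str, float]
    realized_effects: np.ndarray  # samples x targets: delta + eta (cycles)
    clipped_cells: list[tuple[str, str]]


def generate_cq(design: ExperimentDesign) -> tuple[CqMatrix, GroundTruth]:
    """Draw one Cq matrix from the shared-shift model; same seed, same data.

    Values falling outside (1, max_cycles) are clipped and the affected cells
    reported in the ground truth (never silently).
    """
    rng = np.random.default_rng(design.seed)
    samples = design.sample_ids()
    if len(samples) != design.n_samples:
        raise SimulationError("groups mapping size differs from n_samples")
    targets = design.targets
    n, t = design.n_samples, len(targets)
    shifts = rng.normal(0.0, design.global_shift_sd, size=n)
    eta = np.column_stack(
        [rng.normal(0.0, spec.instability_sd, size=n) for spec in targets]
    )
    eps = rng.normal(0.0, design.noise_sd, size=(n, t))
    delta = np.zeros((n, t))
    if design.groups is not None:
        for i, s in enumerate(samples):
            cond = design.groups[s]
            for j, spec in enumerate(targets):
                delta[i, j] = spec.group_effects.get(cond, 0.0)
    baseline = np.array([spec.baseline_cq for spec in targets])
    cq = baseline[None, :] - shifts[:, None] - delta - eta - eps
    clipped = np.clip(cq, 1.0 + 1e-9, design.max_cycles)
    clipped_cells = [
        (samples[i], targets[j].target_id)
        for i, j in zip(*np.nonzero(clipped != cq))
    ]
    matrix = CqMatrix(
        samples,
        [spec.target_id for spec in targets],
        clipped,
        np.zeros((n, t), dtype=bool),
        design.max_cycles,
    )
    truth = GroundTruth(
        stable_targets=frozenset(s.target_id for s in targets if s.is_stable),
        sample_shifts=dict(zip(samples, shifts.tolist())),
        realized_effects=delta + eta,
        clipped_cells=clipped_cells,
    )
    return matrix, truth


def generate_rt_pairs(
    cq: CqMatrix,
    gdna_fraction: Mapping[str, float] | float,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> RtControlSet:
    """Emulate paired -RT controls: a sample with genomic-DNA signal fraction
    f amplifies -log2(f) cycles later without reverse transcription.

    -RT values pushed past the cycle ceiling become non-detects (censoring).
    """
    if isinstance(gdna_fraction, Mapping):
        fractions = {s: gdna_fraction[s] for s in cq.sample_ids}
    else:
        fractions = {s: float(gdna_fraction) for s in cq.sample_ids}
    for s, f in fractions.items():
        if not 0.0 < f < 1.0:
            raise SimulationError(f"gDNA fraction {f} of sample {s} outside (0, 1)")
    rng = np.random.default_rng(seed)
    shift = np.array([-np.log2(fractions[s]) for s in cq.sample_ids])
    minus = cq.values + shift[:, None] + rng.normal(0.0, noise_sd, size=cq.shape)
    mask = cq.missing_mask | (minus > cq.max_cycles)
    minus = np.where(mask, np.nan, minus)
    minus_matrix = CqMatrix(
        list(cq.sample_ids), list(cq.target_ids), minus, mask, cq.max_cycles
    )
    return RtControlSet(plus_rt=cq, minus_rt=minus_matrix)


@dataclass(frozen=True)
class InsertionRecord:
    transcript_id: str
    position: int  # cassette start, 0-based on the final transcript
    orientation: str  # '+' or '-'
    mismatch_forward: int
    mismatch_reverse: int
    three_prime_intact: bool  # both primers' 3'-terminal bases unmutated


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def generate_transcriptome(
    n_transcripts: int,
    pair: PrimerPair,
    length_range: tuple[int, int] = (500, 2000),
    spacer_length: int = 80,
    insertion_prob: float = 0.5,
    per_base_mutation_rate: float = 0.0,
    antisense_prob: float = 0.0,
    seed: int = 0,
) -> tuple[dict[str, str], list[InsertionRecord]]:
    """Random transcripts, a fraction carrying a primer-site cassette.

    The cassette is forward primer + random spacer + reverse-complemented
    reverse primer — the footprint of a real amplicon. Each cassette base
    mutates independently at ``per_base_mutation_rate`` (always to a different
    base), the whole cassette is reverse-complemented with probability
    ``antisense_prob``, and every insertion is recorded with its realized
    mismatch counts per primer site so predicted counts can be checked
    against construction ground truth.
    """
    for name, p in (
        ("insertion_prob", insertion_prob),
        ("per_base_mutation_rate", per_base_mutation_rate),
        ("antisense_prob", antisense_prob),
    ):
        if not 0.0 <= p <= 1.0:
            raise SimulationError(f"{name} outside [0, 1]")
    lo, hi = length_range
    cassette_len = len(pair.forward) + spacer_length + len(pair.reverse)
    if cassette_len > lo:
        raise SimulationError(
            f"cassette of {cassette_len} nt exceeds minimum transcript length {lo}"
        )
    rng = np.random.default_rng(seed)
    fwd = np.frombuffer(pair.forward.encode(), dtype=np.uint8)
    rev_site = np.frombuffer(revcomp(pair.reverse).encode(), dtype=np.uint8)
    transcripts: dict[str, str] = {}
    records: list[InsertionRecord] = []
    lf, lr = len(pair.forward), len(pair.reverse)
    for i in range(n_transcripts):
        tid = f"tx{i + 1:04d}"
        length = int(rng.integers(lo, hi + 1))
        backbone = _random_seq(rng, length)
        if rng.random() < insertion_prob:
            spacer = _random_seq(rng, spacer_length)
            cassette = np.concatenate([fwd, spacer, rev_site])
            mutated = rng.random(cassette.size) < per_base_mutation_rate
            for pos in np.flatnonzero(mutated):
                others = _BASES[_BASES != cassette[pos]]
                cassette[pos] = rng.choice(others)
            mm_f = int(mutated[:lf].sum())
            mm_r = int(mutated[-lr:].sum())
            # 3' termini: last base of the forward site, first base of the
            # reverse-complemented reverse site.
            intact = not (mutated[lf - 1] or mutated[cassette.size - lr])
            orientation = "+"
            if rng.random() < antisense_prob:
                cassette = np.frombuffer(
                    revcomp(cassette.tobytes().decode()).encode(), dtype=np.uint8
                )
                orientation = "-"
            pos = int(rng.integers(0, length - cassette.size + 1))
            seq = np.concatenate([backbone[:pos], cassette, backbone[pos + cassette.size :]])
            records.append(
                InsertionRecord(tid, pos, orientation, mm_f, mm_r, intact)
            )
            transcripts[tid] = seq.tobytes().decode()
        else:
            transcripts[tid] = backbone.tobytes().decode()
    return transcripts, records


def generate_dilution_series(
    true_efficiency_percent: float = 100.0,
    n_points: int = 6,
    dilution_factor: float = 4.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    max_input: float = 10.0,
    intercept_cq: float = 20.0,
    target_id: str = "assay",
) -> DilutionSeries:
    """Dilution series with known efficiency: Cq = intercept - log10(input)/log10(a).

    Defaults mirror a 6-point quarter-dilution design starting at 10 µg.
    """
    if not 50.0 < true_efficiency_percent < 150.0:
        raise SimulationError("true efficiency outside (50, 150)%")
    if n_points < 3 or dilution_factor <= 1:
        raise SimulationError("need >= 3 points and dilution factor > 1")
    rng = np.random.default_rng(seed)
    a = 1.0 + true_efficiency_percent / 100.0
    inputs = max_input / dilution_factor ** np.arange(n_points)
    log_inputs = np.log10(inputs)
    cq = intercept_cq - log_inputs / np.log10(a) + rng.normal(0.0, noise_sd, n_points)
    return DilutionSeries(
        target_id,
        tuple(log_inputs.tolist()),
        tuple(cq.tolist()),
        n_points=n_points,
        dilution_factor=dilution_factor,
    )


def write_fasta(transcripts: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tid, seq in transcripts.items():
            fh.write(f">{tid}\n")
            for start in range(0, len(seq), 70):
                fh.write(seq[start : start + 70] + "\n")
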