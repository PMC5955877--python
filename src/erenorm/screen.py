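"""Candidate repeat-assay screening: consensus conservation and
mismatch-tolerant in-silico PCR over a transcript set.

A repeat family qualifies as a normalization candidate when its copies are
well conserved against the family consensus (mean identity at least 97% by
default) and its primer pair is predicted to amplify an adequate number of
expressed transcripts (at least 30 by default; more is considered better, so
there is no upper gate). Predicted amplicons require both primers to match by
Hamming distance (no indels) within a mismatch cap, with the 3'-terminal base
of each primer matching exactly — a mismatch there blocks polymerase
extension — and a product length inside a configurable window. Both strands
are searched; coordinates are 0-based half-open on the input transcript.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "ScreenError",
    "PrimerPair",
    "RepeatFamily",
    "Amplicon",
    "ScreenResult",
    "conservation_rate",
    "find_amplicons",
    "count_expressed_targets",
    "screen_assay",
    "read_fasta",
    "read_alignment_fasta",
    "read_primer_table",
    "write_screen_table",
    "write_amplicon_bed",
]

_ALPHABET = set("ACGT")


class ScreenError(ValueError):
    pass


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class PrimerPair:
    """A qPCR primer pair; both sequences as synthesized (5'->3')."""

    assay_id: str
    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for name, seq in (("forward", self.forward), ("reverse", self.reverse)):
            up = seq.upper()
            if set(up) - _ALPHABET:
                raise ScreenError(
                    f"{name} primer of {self.assay_id} contains non-ACGT characters"
                )
            if not 15 <= len(up) <= 35:
                raise ScreenError(
                    f"{name} primer of {self.assay_id} length {len(up)} outside 15-35 nt"
                )
        object.__setattr__(self, "forward", self.forward.upper())
        object.__setattr__(self, "reverse", self.reverse.upper())


@dataclass(frozen=True)
class RepeatFamily:
    """A repeat family: gapped consensus plus copies aligned to it.

    Copies arrive pre-aligned (same column count as the consensus); alignment
    construction is upstream of this package.
    """

    family_id: str
    consensus: str
    copies: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.copies:
            raise ScreenError(f"family {self.family_id} has no copies")
        n_cols = len(self.consensus)
        for i, copy in enumerate(self.copies):
            if len(copy) != n_cols:
                raise ScreenError(
                    f"copy {i} of {self.family_id} has {len(copy)} columns, "
                    f"consensus has {n_cols}"
                )


def conservation_rate(family: RepeatFamily) -> float:
    """Mean percent identity of the copies to the consensus.

    Identity per copy = matching columns / consensus non-gap columns; a gap in
    the copy counts as a mismatch.
    """
    consensus = family.consensus.upper()
    cols = [i for i, c in enumerate(consensus) if c != "-"]
    if not cols:
        raise ScreenError(f"consensus of {family.family_id} is all gaps")
    identities = []
    for copy in family.copies:
        up = copy.upper()
        matches = sum(1 for i in cols if up[i] == consensus[i])
        identities.append(matches / len(cols))
    return 100.0 * float(np.mean(identities))


@dataclass(frozen=True)
class Amplicon:
    """Predicted product: 0-based half-open template coordinates."""

    start: int
    end: int
    orientation: str  # '+' sense, '-' antisense
    mismatch_forward: int
    mismatch_reverse: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _site_mismatches(template: np.ndarray, probe: np.ndarray) -> np.ndarray:
    """Hamming mismatch count of the probe at every template offset."""
    if probe.size > template.size:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(template, probe.size)
    return (windows != probe[None, :]).sum(axis=1)


def _find_sense(
    template: np.ndarray,
    pair: PrimerPair,
    cap: int,
    amplicon_range: tuple[int, int],
    pair_total: bool,
) -> list[tuple[int, int, int, int]]:
    """(start, end, mm_f, mm_r) for sense-orientation products."""
    fwd = _encode(pair.forward)
    rev_site = _encode(revcomp(pair.reverse))
    mm_f = _site_mismatches(template, fwd)
    mm_r = _site_mismatches(template, rev_site)
    if mm_f.size == 0 or mm_r.size == 0:
        return []
    # 3'-terminal base exact: last base of the forward site, first base of the
    # reverse-complemented reverse site (the reverse primer's 3' end).
    f_ok = (template[fwd.size - 1 :][: mm_f.size] == fwd[-1]) & (mm_f <= cap)
    r_ok = (template[: mm_r.size] == rev_site[0]) & (mm_r <= cap)
    f_pos = np.flatnonzero(f_ok)
    r_pos = np.flatnonzero(r_ok)
    lo, hi = amplicon_range
    out = []
    for i in f_pos:
        for j in r_pos:
            if j < i + fwd.size:
                continue  # primers may not overlap
            length = j + rev_site.size - i
            if length < lo or length > hi:
                continue
            if pair_total and mm_f[i] + mm_r[j] > cap:
                continue
            out.append((int(i), int(j + rev_site.size), int(mm_f[i]), int(mm_r[j])))
    return out


def find_amplicons(
    transcript: str,
    pair: PrimerPair,
    max_mismatch_per_primer: int = 3,
    amplicon_range: tuple[int, int] = (50, 1000),
    pair_total: bool = False,
) -> list[Amplicon]:
    """Predict PCR products of a primer pair on one transcript.

    Matching is Hamming-only (no indels) with at most ``max_mismatch_per_primer``
    mismatches per primer (or, with ``pair_total=True``, summed across the
    pair) and an exactly matching 3'-terminal base for each primer. Both
    orientations are searched; antisense products carry orientation '-' with
    coordinates mapped back onto the input strand.
    """
    if max_mismatch_per_primer < 0:
        raise ScreenError("mismatch cap must be >= 0")
    lo, hi = amplicon_range
    if lo <= 0 or hi < lo:
        raise ScreenError(f"invalid amplicon range {amplicon_range}")
    seq = transcript.upper()
    template = _encode(seq)
    cap = max_mismatch_per_primer
    hits = [
        Amplicon(s, e, "+", mf, mr)
        for s, e, mf, mr in _find_sense(template, pair, cap, amplicon_range, pair_total)
    ]
    rc = _encode(revcomp(seq))
    n = len(seq)
    hits += [
        Amplicon(n - e, n - s, "-", mf, mr)
        for s, e, mf, mr in _find_sense(rc, pair, cap, amplicon_range, pair_total)
    ]
    return sorted(hits, key=lambda a: (a.start, a.end, a.orientation))


def count_expressed_targets(
    transcripts: Mapping[str, str],
    pair: PrimerPair,
    caps: Sequence[int] = (3, 2),
    amplicon_range: tuple[int, int] = (50, 1000),
    pair_total: bool = False,
) -> dict[int, int]:
    """Per mismatch cap, the number of distinct transcripts with >= 1
    predicted amplicon (each transcript counts once regardless of
    multiplicity)."""
    if not transcripts:
        raise ScreenError("empty transcript set")
    counts = {}
    max_cap = max(caps)
    # One search at the loosest cap; tighter caps filter its hits.
    hits_per_transcript = {
        tid: find_amplicons(seq, pair, max_cap, amplicon_range, pair_total)
        for tid, seq in transcripts.items()
    }
    for cap in caps:
        n = 0
        for hits in hits_per_transcript.values():
            if pair_total:
                ok = any(a.mismatch_forward + a.mismatch_reverse <= cap for a in hits)
            else:
                ok = any(
                    max(a.mismatch_forward, a.mismatch_reverse) <= cap for a in hits
                )
            n += ok
        counts[cap] = n
    return counts


@dataclass(frozen=True)
class ScreenResult:
    assay_id: str
    conservation_rate: float
    n_targets: dict[int, int]
    conservation_pass: bool
    adequacy_pass: bool


def screen_assay(
    family: RepeatFamily,
    pair: PrimerPair,
    transcripts: Mapping[str, str],
    conservation_threshold: float = 97.0,
    min_hits: int = 30,
    caps: Sequence[int] = (3, 2),
    amplicon_range: tuple[int, int] = (50, 1000),
    pair_total: bool = False,
) -> ScreenResult:
    """Combined screen: conservation gate plus target-count adequacy gate.

    Adequacy is judged at the loosest mismatch cap and has no upper bound
    (a very high predicted target count is an asset, not a defect).
    """
    rate = conservation_rate(family)
    counts = count_expressed_targets(transcripts, pair, caps, amplicon_range, pair_total)
    return ScreenResult(
        assay_id=pair.assay_id,
        conservation_rate=rate,
        n_targets=counts,
        conservation_pass=rate >= conservation_threshold,
        adequacy_pass=counts[max(caps)] >= min_hits,
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_alignment_fasta(path: str | Path, family_id: str | None = None) -> RepeatFamily:
    """Read a gapped alignment FASTA whose first record is the consensus."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise ScreenError("alignment FASTA needs a consensus plus >= 1 copy")
    consensus = records[0]
    return RepeatFamily(
        family_id or consensus.id,
        str(consensus.seq),
        tuple(str(r.seq) for r in records[1:]),
    )


def read_primer_table(path: str | Path) -> list[PrimerPair]:
    """Read primer pairs from TSV columns assay, forward, reverse."""
    df = pd.read_csv(path, sep="\t")
    required = {"assay", "forward", "reverse"}
    if not required.issubset(df.columns):
        raise ScreenError(f"primer table needs columns {sorted(required)}")
    return [
        PrimerPair(str(r.assay), str(r.forward), str(r.reverse))
        for r in df.itertuples(index=False)
    ]


def write_screen_table(results: Iterable[ScreenResult], path: str | Path) -> None:
    rows = []
    for r in results:
        row = {"assay": r.assay_id, "conservation_rate": r.conservation_rate}
        for cap in sorted(r.n_targets, reverse=True):
            row[f"n_targets_cap{cap}"] = r.n_targets[cap]
        row["conservation_pass"] = r.conservation_pass
        row["adequacy_pass"] = r.adequacy_pass
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_amplicon_bed(
    hits: Mapping[str, Sequence[Amplicon]], assay_id: str, path: str | Path
) -> None:
    """BED-like TSV: transcript, start, end, assay, orientation (0-based
    half-open)."""
    rows = [
        {
            "transcript": tid,
            "start": a.start,
            "end": a.end,
            "assay": assay_id,
            "orientation": a.orientation,
        }
        for tid, amps in hits.items()
        for a in amps
    ]
    pd.DataFrame(rows, columns=["transcript", "start", "end", "assay", "orientation"]).to_csv(
        path, sep="\t", index=False
    )
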