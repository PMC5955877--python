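"""Core qPCR data containers and the Cq -> relative-quantity transform.

Quantification cycles (Cq) are read from long or wide tabular text into a
replicate-level table, collapsed (mean on the Cq scale) into a sample x target
matrix, and converted to relative quantities ``Q = a ** (minCq - Cq)`` with the
assay-specific amplification factor ``a`` (default 2, i.e. perfect doubling).
The quantity matrix is the input to the geNorm stability engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CqTableError",
    "ReplicateTable",
    "CqMatrix",
    "QuantityMatrix",
    "AssayEfficiency",
    "read_cq_table",
    "write_replicate_table",
    "collapse_replicates",
    "write_qc_flags",
    "to_relative_quantities",
    "NON_DETECT_TOKENS",
]

#: Cell contents (lower-cased, stripped) that denote a reaction that never
#: crossed the fluorescence threshold. Anything else non-numeric is an error.
NON_DETECT_TOKENS = frozenset({"", "na", "n/a", "nd", "nan", "undetermined", "undet", "-"})

LONG_COLUMNS = ("sample", "target", "replicate", "cq")


class CqTableError(ValueError):
    """Raised for malformed Cq tables or invalid matrix contents."""


def _sep_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def _parse_cq_cell(raw: object, line_no: int) -> float:
    """Parse one Cq cell; NaN encodes a non-detect."""
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return math.nan
    text = str(raw).strip()
    if text.lower() in NON_DETECT_TOKENS:
        return math.nan
    try:
        return float(text)
    except ValueError:
        raise CqTableError(
            f"unparseable Cq value {text!r} at line {line_no}"
        ) from None


@dataclass(frozen=True)
class ReplicateTable:
    """Well-level Cq records: one row per (sample, target, replicate).

    ``cq`` is NaN for non-detects. The (sample, target, replicate) triple is
    unique; violation is rejected at construction.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise CqTableError(f"replicate table missing columns: {missing}")
        dup = df.duplicated(subset=["sample", "target", "replicate"])
        if dup.any():
            row = df.loc[dup.idxmax()]
            raise CqTableError(
                "duplicate (sample, target, replicate) triple: "
                f"({row['sample']}, {row['target']}, {row['replicate']})"
            )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.records["sample"]))

    @property
    def target_ids(self) -> list[str]:
        return list(dict.fromkeys(self.records["target"]))


def read_cq_table(path: str | Path, layout: str = "long") -> ReplicateTable:
    """Read a Cq table (CSV/TSV sniffed from extension) into a ReplicateTable.

    Long layout has columns ``sample,target,replicate,cq``; wide layout has a
    first column ``sample`` and one column per target, repeated sample rows
    encoding successive replicates. Conventional non-detect tokens
    (``Undetermined``, ``NA``, ``ND``, empty, ``-``) become NaN records; any
    other non-numeric cell is rejected with its line number.
    """
    path = Path(path)
    if not path.exists():
        raise CqTableError(f"no such Cq table: {path}")
    sep = _sep_for(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df.columns = [str(c).strip().lower() for c in df.columns]
    if layout == "long":
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise CqTableError(f"long layout requires columns {LONG_COLUMNS}, missing {missing}")
        records = pd.DataFrame(
            {
                "sample": df["sample"].str.strip(),
                "target": df["target"].str.strip(),
                "replicate": df["replicate"].astype(int),
                "cq": [
                    _parse_cq_cell(v, i + 2)  # +2: header line and 1-based numbering
                    for i, v in enumerate(df["cq"])
                ],
            }
        )
    elif layout == "wide":
        if df.columns[0] != "sample":
            raise CqTableError("wide layout requires first column 'sample'")
        targets = list(df.columns[1:])
        if not targets:
            raise CqTableError("wide layout has no target columns")
        rows: list[tuple[str, str, int, float]] = []
        rep_counter: dict[str, int] = {}
        for i, row in enumerate(df.itertuples(index=False)):
            sample = str(row[0]).strip()
            rep_counter[sample] = rep_counter.get(sample, 0) + 1
            rep = rep_counter[sample]
            for j, target in enumerate(targets):
                rows.append((sample, target, rep, _parse_cq_cell(row[j + 1], i + 2)))
        records = pd.DataFrame(rows, columns=list(LONG_COLUMNS))
    else:
        raise CqTableError(f"unknown layout {layout!r}; expected 'long' or 'wide'")
    return ReplicateTable(records)


def write_replicate_table(table: ReplicateTable, path: str | Path, layout: str = "long") -> None:
    """Write a ReplicateTable back to disk in either layout.

    Floats are written with Python repr so decimal inputs round-trip exactly;
    non-detects are written as ``NA``.
    """
    path = Path(path)
    sep = _sep_for(path)
    df = table.records
    if layout == "long":
        out = df.copy()
        out["cq"] = [("NA" if math.isnan(v) else repr(float(v))) for v in out["cq"]]
        out.to_csv(path, sep=sep, index=False)
    elif layout == "wide":
        targets = list(dict.fromkeys(df["target"]))
        lines = [sep.join(["sample", *targets])]
        for (sample, _rep), grp in df.groupby(["sample", "replicate"], sort=False):
            by_target = dict(zip(grp["target"], grp["cq"]))
            cells = [
                "NA" if math.isnan(by_target.get(t, math.nan)) else repr(float(by_target[t]))
                for t in targets
            ]
            lines.append(sep.join([str(sample), *cells]))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise CqTableError(f"unknown layout {layout!r}")


@dataclass
class CqMatrix:
    """Samples x targets matrix of quantification cycles.

    ``missing_mask`` marks non-detects; present values must lie in
    (0, max_cycles]. ``qc_flags`` (optional) carries the replicate-spread QC
    listing produced by :func:`collapse_replicates`.
    """

    sample_ids: list[str]
    target_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray
    max_cycles: float = 40.0
    qc_flags: pd.DataFrame | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise CqTableError("duplicate sample ids")
        if len(set(self.target_ids)) != len(self.target_ids):
            raise CqTableError("duplicate target ids")
        shape = (len(self.sample_ids), len(self.target_ids))
        if self.values.shape != shape or self.missing_mask.shape != shape:
            raise CqTableError(
                f"shape mismatch: ids imply {shape}, values {self.values.shape}, "
                f"mask {self.missing_mask.shape}"
            )
        present = self.values[~self.missing_mask]
        if present.size and (np.any(present <= 0) or np.any(present > self.max_cycles)):
            raise CqTableError(f"Cq values outside (0, {self.max_cycles}]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def complete(self) -> bool:
        return not self.missing_mask.any()

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=self.target_ids)
        return df.mask(pd.DataFrame(self.missing_mask, index=df.index, columns=df.columns))

    def to_replicate_table(self) -> ReplicateTable:
        """Re-encode as a single-replicate table (replicate index 1)."""
        rows = [
            (s, t, 1, math.nan if self.missing_mask[i, j] else self.values[i, j])
            for i, s in enumerate(self.sample_ids)
            for j, t in enumerate(self.target_ids)
        ]
        return ReplicateTable(pd.DataFrame(rows, columns=list(LONG_COLUMNS)))

    def write(self, path: str | Path, layout: str = "long") -> None:
        write_replicate_table(self.to_replicate_table(), path, layout=layout)

    def drop(self, samples: Iterable[str] = (), targets: Iterable[str] = ()) -> "CqMatrix":
        """Return a copy without the named samples/targets (pre-filter helper)."""
        samples, targets = set(samples), set(targets)
        keep_s = [i for i, s in enumerate(self.sample_ids) if s not in samples]
        keep_t = [j for j, t in enumerate(self.target_ids) if t not in targets]
        return CqMatrix(
            [self.sample_ids[i] for i in keep_s],
            [self.target_ids[j] for j in keep_t],
            self.values[np.ix_(keep_s, keep_t)],
            self.missing_mask[np.ix_(keep_s, keep_t)],
            self.max_cycles,
        )


def collapse_replicates(table: ReplicateTable, max_spread: float = 0.5) -> CqMatrix:
    """Average technical replicates on the Cq scale into a CqMatrix.

    A cell is a non-detect only when every replicate is a non-detect;
    otherwise detected replicates are averaged. Cells whose detected-replicate
    range exceeds ``max_spread`` cycles are flagged in the attached
    ``qc_flags`` listing but still averaged.
    """
    if max_spread <= 0:
        raise CqTableError("max_spread must be positive")
    if len(table) == 0:
        raise CqTableError("empty replicate table")
    samples = table.sample_ids
    targets = table.target_ids
    values = np.full((len(samples), len(targets)), np.nan)
    mask = np.ones((len(samples), len(targets)), dtype=bool)
    qc_rows = []
    s_idx = {s: i for i, s in enumerate(samples)}
    t_idx = {t: j for j, t in enumerate(targets)}
    for (sample, target), grp in table.records.groupby(["sample", "target"], sort=False):
        detected = grp["cq"].dropna().to_numpy()
        i, j = s_idx[sample], t_idx[target]
        if detected.size:
            values[i, j] = detected.mean()
            mask[i, j] = False
            rng = float(detected.max() - detected.min()) if detected.size > 1 else 0.0
            qc_rows.append((sample, target, rng, rng > max_spread))
        else:
            qc_rows.append((sample, target, math.nan, False))
    qc = pd.DataFrame(qc_rows, columns=["sample", "target", "range", "flag"])
    return CqMatrix(samples, targets, values, mask, qc_flags=qc)


def write_qc_flags(matrix: CqMatrix, path: str | Path) -> None:
    if matrix.qc_flags is None:
        raise CqTableError("matrix carries no QC listing (not produced by collapse_replicates)")
    matrix.qc_flags.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class AssayEfficiency:
    """Amplification efficiency of one assay; 100% means perfect doubling."""

    target_id: str
    efficiency_percent: float

    def __post_init__(self) -> None:
        if not 0.0 < self.amplification_factor - 1.0 < 2.0:
            raise CqTableError(
                f"amplification factor {self.amplification_factor} outside (1, 3) "
                f"for {self.target_id}"
            )

    @property
    def amplification_factor(self) -> float:
        return 1.0 + self.efficiency_percent / 100.0


@dataclass
class QuantityMatrix:
    """Relative quantities Q in (0, 1]; per target the max over samples is 1."""

    sample_ids: list[str]
    target_ids: list[str]
    quantities: np.ndarray

    def __post_init__(self) -> None:
        self.quantities = np.asarray(self.quantities, dtype=float)
        shape = (len(self.sample_ids), len(self.target_ids))
        if self.quantities.shape != shape:
            raise CqTableError(f"quantity shape {self.quantities.shape} != {shape}")
        if np.any(~np.isfinite(self.quantities)) or np.any(self.quantities <= 0):
            raise CqTableError("quantities must be finite and > 0")
        col_max = self.quantities.max(axis=0)
        if not np.allclose(col_max, 1.0, rtol=0, atol=1e-9):
            raise CqTableError("per-target maximum quantity must equal 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.quantities.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.quantities, index=self.sample_ids, columns=self.target_ids)

    def subset(self, targets: Iterable[str]) -> np.ndarray:
        idx = [self.target_ids.index(t) for t in targets]
        return self.quantities[:, idx]


def to_relative_quantities(
    cq: CqMatrix,
    efficiencies: Mapping[str, AssayEfficiency] | None = None,
) -> QuantityMatrix:
    """Transform Cq to relative quantities ``Q_ij = a_j ** (minCq_j - Cq_ij)``.

    ``minCq_j`` is the per-target minimum across samples, so the most abundant
    sample gets Q = 1. Targets absent from ``efficiencies`` use amplification
    factor 2 (100% efficiency). Non-detects are rejected: drop the offending
    sample or target first (see :meth:`CqMatrix.drop`).
    """
    if not cq.complete:
        i, j = np.argwhere(cq.missing_mask)[0]
        raise CqTableError(
            f"non-detect at sample {cq.sample_ids[i]!r}, target {cq.target_ids[j]!r}: "
            "drop the sample or target before computing quantities"
        )
    factors = np.array(
        [
            efficiencies[t].amplification_factor if efficiencies and t in efficiencies else 2.0
            for t in cq.target_ids
        ]
    )
    min_cq = cq.values.min(axis=0)
    q = factors[None, :] ** (min_cq[None, :] - cq.values)
    return QuantityMatrix(list(cq.sample_ids), list(cq.target_ids), q)
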