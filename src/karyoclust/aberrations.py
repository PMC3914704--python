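"""Aberration identities, frequency aggregation and metaphase-matrix construction.

Two granularities are used deliberately.  Within a cell line, the unit is the
*entry*: the multiplicity-resolved token (``-18`` and ``-18x2`` are distinct
per-metaphase states).  Across cell lines, the unit is the *identity*:
multiplicity is collapsed so the same aberration matches between lines
(``-18`` and ``-18x2`` are both "loss of 18").

A composite karyotype records how many metaphases carry each entry but not
which ones; :func:`expand_composite` draws a per-metaphase binary matrix
uniformly at random subject to the recorded counts (multiplicity variants of
one identity mutually exclusive per metaphase, different identities
independent), reproducibly from a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .iscn import AberrationEvent, KaryotypeRecord, ValidationError, parse_event

__all__ = [
    "AberrationIdentity",
    "FrequencyTable",
    "MetaphaseMatrix",
    "normalize_identity",
    "aggregate_frequencies",
    "build_frequency_table",
    "expand_composite",
    "matrix_from_metaphases",
]


@dataclass(frozen=True, order=True)
class AberrationIdentity:
    """Normalized key for matching aberrations across entries and lines.

    Numerical: ``kind="numerical"``, ``key=(direction, chromosome)``.
    Structural: ``kind="structural"``, ``key`` = canonical event text with the
    multiplicity suffix stripped.
    """

    kind: str
    key: tuple[str, str] | str

    @property
    def label(self) -> str:
        if self.kind == "numerical":
            direction, chrom = self.key
            return ("+" if direction == "gain" else "-") + chrom
        return str(self.key)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def normalize_identity(event: AberrationEvent) -> AberrationIdentity:
    """Collapse an event to its identity (multiplicity and cell count ignored)."""
    if event.category in ("gain", "loss"):
        return AberrationIdentity("numerical", (event.category, event.chromosomes[0]))
    return AberrationIdentity("structural", event.core())


def identity_from_label(label: str) -> AberrationIdentity:
    """Inverse of :attr:`AberrationIdentity.label` (parses the canonical text)."""
    return normalize_identity(parse_event(label, mode="strict"))


def aggregate_frequencies(record: KaryotypeRecord,
                          mode: str = "lenient",
                          ) -> dict[AberrationIdentity, tuple[int, float]]:
    """Metaphase counts and fractions per identity.

    Sums cell counts over all multiplicity variants of each identity, capped
    at the composite count (a cap is a warning in lenient mode, an error in
    strict mode — variants are mutually exclusive states of one metaphase, so
    an uncapped sum above ``cp`` indicates an inconsistent karyotype).
    """
    cells: dict[AberrationIdentity, int] = {}
    for ev in record.events:
        ident = normalize_identity(ev)
        cells[ident] = cells.get(ident, 0) + ev.cell_count
    out: dict[AberrationIdentity, tuple[int, float]] = {}
    for ident, n in cells.items():
        if n > record.composite_count:
            msg = (f"{record.source_label or 'record'}: identity {ident.label} counted "
                   f"in {n} of {record.composite_count} metaphases; capping")
            if mode == "strict":
                raise ValidationError(msg)
            warnings.warn(msg)
            n = record.composite_count
        out[ident] = (n, n / record.composite_count)
    return out


def clonal_identities(record: KaryotypeRecord) -> set[AberrationIdentity]:
    """Identities carried by every metaphase of the record."""
    return {ident for ident, (n, _) in aggregate_frequencies(record).items()
            if n == record.composite_count}


# ---------------------------------------------------------------------------
# cross-line frequency table


class FrequencyTable:
    """Identities x cell-lines matrix of metaphase fractions in [0, 1].

    Thin wrapper around a :class:`pandas.DataFrame` keeping the row index as
    :class:`AberrationIdentity` objects and the columns as line labels.
    """

    def __init__(self, frame: pd.DataFrame):
        vals = frame.to_numpy(dtype=float)
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
            raise ValidationError("frequencies must lie in [0, 1]")
        self.frame = frame

    @property
    def identities(self) -> list[AberrationIdentity]:
        return list(self.frame.index)

    @property
    def lines(self) -> list[str]:
        return list(self.frame.columns)

    def value(self, identity: AberrationIdentity, line: str) -> float:
        return float(self.frame.loc[identity, line])

    def to_labeled_frame(self) -> pd.DataFrame:
        """The same table with string row labels (for writing)."""
        out = self.frame.copy()
        out.index = [ident.label for ident in self.frame.index]
        out.index.name = "identity"
        return out

    def write_tsv(self, path: str | Path, precision: int = 4) -> None:
        self.to_labeled_frame().to_csv(path, sep="\t", float_format=f"%.{precision}f")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "FrequencyTable":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        frame.index = [identity_from_label(l) for l in frame.index]
        return cls(frame)


def build_frequency_table(records: Iterable[KaryotypeRecord]) -> FrequencyTable:
    """Union of identities across records; an identity absent from a line is 0."""
    records = list(records)
    if len(records) < 2:
        raise ValidationError("frequency table needs at least 2 records")
    labels = [r.source_label for r in records]
    if len(set(labels)) != len(labels):
        raise ValidationError(f"duplicate record labels: {labels}")
    columns = {r.source_label: {i: f for i, (_, f) in aggregate_frequencies(r).items()}
               for r in records}
    identities = sorted({i for col in columns.values() for i in col})
    frame = pd.DataFrame(
        {lab: [columns[lab].get(i, 0.0) for i in identities] for lab in labels},
        index=identities)
    return FrequencyTable(frame)


# ---------------------------------------------------------------------------
# metaphase matrices


class MetaphaseMatrix:
    """Binary metaphases x aberration-entries matrix.

    Rows are metaphase labels, columns multiplicity-resolved entry labels;
    a cell is 1 when that metaphase carries that entry.
    """

    def __init__(self, frame: pd.DataFrame):
        vals = frame.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValidationError("metaphase matrix must be binary")
        self.frame = frame.astype(int)

    @property
    def metaphases(self) -> list[str]:
        return list(self.frame.index)

    @property
    def entries(self) -> list[str]:
        return list(self.frame.columns)

    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    def entry_counts(self) -> dict[str, int]:
        return {c: int(n) for c, n in self.frame.sum(axis=0).items()}

    def write_tsv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out.index.name = "metaphase"
        out.to_csv(path, sep="\t")

    def write_mtx(self, path: str | Path) -> None:
        """Sparse triples (1-based row, col, value) with a header comment."""
        rows, cols = np.nonzero(self.values())
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("%%MatrixMarket matrix coordinate integer general\n")
            fh.write(f"{len(self.metaphases)} {len(self.entries)} {len(rows)}\n")
            for r, c in zip(rows, cols):
                fh.write(f"{r + 1} {c + 1} 1\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "MetaphaseMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


def expand_composite(record: KaryotypeRecord, seed: int) -> MetaphaseMatrix:
    """Reconstruct a per-metaphase binary matrix consistent with a composite.

    For each entry, exactly ``cell_count`` of the ``composite_count`` rows
    carry it; multiplicity variants of one identity occupy disjoint row sets
    (a metaphase lost a chromosome once *or* twice); different identities are
    assigned independently, uniformly at random.  The composite notation does
    not record the true assignment, so this is a frequency-constrained draw,
    reproducible from ``seed`` — not a reconstruction of the observed cells.
    """
    rng = np.random.default_rng(seed)
    n = record.composite_count
    rows = [f"M_{i + 1}" for i in range(n)]
    groups: dict[AberrationIdentity, list[AberrationEvent]] = {}
    order: list[str] = []
    for ev in record.events:
        ident = normalize_identity(ev)
        groups.setdefault(ident, []).append(ev)
    data: dict[str, np.ndarray] = {}
    for ident, events in groups.items():
        total = sum(ev.cell_count for ev in events)
        if total > n:
            raise ValidationError(
                f"identity {ident.label}: variant cell counts sum to {total} > "
                f"composite count {n}")
        perm = rng.permutation(n)
        offset = 0
        for ev in events:
            col = np.zeros(n, dtype=int)
            col[perm[offset:offset + ev.cell_count]] = 1
            offset += ev.cell_count
            label = ev.entry_label()
            if label in data:  # duplicated printed entry: merge disjoint row sets
                data[label] = data[label] | col
            else:
                data[label] = col
                order.append(label)
    frame = pd.DataFrame({label: data[label] for label in order}, index=rows)
    return MetaphaseMatrix(frame)


def matrix_from_metaphases(records: Iterable[KaryotypeRecord]) -> MetaphaseMatrix:
    """Stack single-metaphase records into a binary matrix (rows in input order)."""
    records = list(records)
    if not records:
        raise ValidationError("no metaphase records given")
    for r in records:
        if r.composite_count != 1:
            raise ValidationError(
                f"{r.source_label or 'record'} is composite (cp{r.composite_count}), "
                "expected single metaphases")
    order: list[str] = []
    seen: set[str] = set()
    for r in records:
        for ev in r.events:
            label = ev.entry_label()
            if label not in seen:
                seen.add(label)
                order.append(label)
    rows = [r.source_label or f"M_{i + 1}" for i, r in enumerate(records)]
    mat = np.zeros((len(records), len(order)), dtype=int)
    col = {label: j for j, label in enumerate(order)}
    for i, r in enumerate(records):
        for ev in r.events:
            mat[i, col[ev.entry_label()]] = 1
    return MetaphaseMatrix(pd.DataFrame(mat, index=rows, columns=order))
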