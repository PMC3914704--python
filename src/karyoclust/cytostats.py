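"""Per-line cytogenetic summary statistics.

Covers the counts a cytogeneticist reports from a composite karyotype:
distinct numerical/structural aberration counts, per-chromosome gain/loss and
structural-subtype tallies, nullisomy frequencies under the ploidy baseline,
and aberrations shared across lines above a frequency threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .aberrations import (AberrationIdentity, FrequencyTable,
                          aggregate_frequencies, normalize_identity)
from .iscn import CHROMOSOMES, KaryotypeRecord, ValidationError

__all__ = [
    "ChromosomeProfile",
    "unique_counts",
    "nullisomy_fraction",
    "chromosome_profile",
    "shared_identities",
    "round_percent",
]

#: autosomes plus X, in karyogram order; Y is omitted for these female-derived lines
#: unless it actually occurs in an event.
_DEFAULT_CHROMS = tuple(str(i) for i in range(1, 23)) + ("X",)


def round_percent(fraction: float, decimals: int = 1) -> float:
    """Percentage at fixed precision using round-half-even (numpy/python default)."""
    return round(100.0 * fraction, decimals)


def unique_counts(record: KaryotypeRecord) -> tuple[int, int]:
    """(n_numerical, n_structural) distinct identities, multiplicity collapsed.

    A numerical identity is a (direction, chromosome) pair; a structural
    identity is the canonical event text.  Invariant under event reordering
    and under adding further multiplicity variants of an existing identity.
    """
    idents = {normalize_identity(ev) for ev in record.events}
    n_num = sum(1 for i in idents if i.kind == "numerical")
    return n_num, len(idents) - n_num


def nullisomy_fraction(record: KaryotypeRecord, chromosome: str) -> float:
    """Fraction of metaphases with *no* copy of ``chromosome``.

    Under a ploidy baseline of ``p`` (from ``<pn>``), nullisomy is a loss
    event with multiplicity ``p`` — all copies lost, e.g. ``-20x4`` under
    ``<4n>``.
    """
    if record.header is None or record.header.ploidy_baseline is None:
        raise ValidationError("nullisomy needs a modal header with a ploidy baseline")
    p = record.header.ploidy_baseline
    cells = sum(ev.cell_count for ev in record.events
                if ev.category == "loss" and ev.chromosomes[0] == chromosome
                and ev.multiplicity == p)
    return cells / record.composite_count


@dataclass(frozen=True)
class ChromosomeProfile:
    """Per-chromosome aberration involvement for one cell line."""

    gains_present: dict[str, bool]
    losses_present: dict[str, bool]
    structural_subtype_counts: dict[str, dict[str, int]]

    @property
    def chromosomes(self) -> list[str]:
        return list(self.gains_present)

    def structurally_affected(self) -> set[str]:
        return {c for c, counts in self.structural_subtype_counts.items()
                if sum(counts.values()) > 0}

    def structurally_unaffected(self) -> set[str]:
        return set(self.chromosomes) - self.structurally_affected()


def _structural_evidence(record: KaryotypeRecord) -> dict[str, list[str | None]]:
    """Breakpoint evidence per chromosome over distinct structural identities.

    For every op of every distinct structural identity, each listed chromosome
    contributes its positionally aligned band (``None`` when the op carries no
    band group or the group is shorter than the chromosome list).
    """
    evidence: dict[str, list[str | None]] = {}
    seen: set[str] = set()
    for ev in record.events:
        if ev.category != "structural":
            continue
        core = ev.core()
        if core in seen:
            continue
        seen.add(core)
        for op in ev.op_chain:
            bands = op.bands or ()
            for i, chrom in enumerate(op.chromosomes):
                band = bands[i] if i < len(bands) else None
                evidence.setdefault(chrom, []).append(band)
    return evidence


def chromosome_profile(record: KaryotypeRecord, rule: str = "localized",
                       chromosomes: Iterable[str] | None = None) -> ChromosomeProfile:
    """Per-chromosome gains/losses flags and structural subtype tallies.

    ``rule`` decides when a chromosome counts as structurally affected:

    - ``"localized"`` (default): it appears in some op with an at least
      partially localized breakpoint (band other than the wholly-unknown
      ``?``), or it appears in two or more ops.  A single appearance with a
      completely unknown breakpoint is treated as unconfirmed involvement.
    - ``"any"``: any appearance in a structural event counts.
    - ``"derived"``: only the first-listed (derived) chromosome of the event.

    Subtype tallies count distinct entries (multiplicity collapsed) whose
    derived chromosome is the given one.
    """
    if rule not in ("localized", "any", "derived"):
        raise ValueError(f"unknown rule {rule!r}")
    if chromosomes is None:
        present = {c for ev in record.events for c in ev.chromosomes}
        chroms = list(_DEFAULT_CHROMS) + (["Y"] if "Y" in present else [])
    else:
        chroms = [c for c in chromosomes]
        if not set(chroms) <= set(CHROMOSOMES):
            raise ValidationError(f"unknown chromosome in {chroms}")

    gains = {c: False for c in chroms}
    losses = {c: False for c in chroms}
    subtype_counts: dict[str, dict[str, int]] = {c: {} for c in chroms}
    seen: set[str] = set()
    for ev in record.events:
        if ev.category == "gain":
            gains.setdefault(ev.chromosomes[0], False)
            gains[ev.chromosomes[0]] = True
        elif ev.category == "loss":
            losses.setdefault(ev.chromosomes[0], False)
            losses[ev.chromosomes[0]] = True
        elif ev.core() not in seen:
            seen.add(ev.core())
            derived = ev.chromosomes[0]
            counts = subtype_counts.setdefault(derived, {})
            counts[ev.subtype] = counts.get(ev.subtype, 0) + 1

    if rule != "derived":
        evidence = _structural_evidence(record)
        for chrom, bands in evidence.items():
            counts = subtype_counts.setdefault(chrom, {})
            if sum(counts.values()) > 0:
                continue
            affected = (any(b is not None and b != "?" for b in bands)
                        if rule == "localized" else True) or len(bands) >= 2
            if rule == "any":
                affected = True
            if affected and chrom in chroms:
                counts["partner"] = len(bands)

    # restrict to requested chromosomes
    return ChromosomeProfile(
        gains_present={c: gains.get(c, False) for c in chroms},
        losses_present={c: losses.get(c, False) for c in chroms},
        structural_subtype_counts={c: subtype_counts.get(c, {}) for c in chroms},
    )


def shared_identities(table: FrequencyTable, lines: Iterable[str] | None = None,
                      min_fraction: float = 0.5,
                      kind: str | None = None) -> set[AberrationIdentity]:
    """Identities at frequency >= ``min_fraction`` in *every* named line.

    With ``min_fraction == 0`` the condition is presence (> 0) in every line.
    ``kind`` optionally restricts to ``"numerical"`` or ``"structural"``.
    """
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must lie in [0, 1]")
    lines = list(table.lines) if lines is None else list(lines)
    unknown = set(lines) - set(table.lines)
    if unknown:
        raise ValidationError(f"unknown line label(s): {sorted(unknown)}")
    out = set()
    for ident in table.identities:
        if kind is not None and ident.kind != kind:
            continue
        vals = [table.value(ident, line) for line in lines]
        if min_fraction == 0:
            ok = all(v > 0 for v in vals)
        else:
            ok = all(v >= min_fraction for v in vals)
        if ok:
            out.add(ident)
    return out


def summary(record: KaryotypeRecord) -> dict:
    """JSON-ready per-line summary: unique counts, clonal set, nullisomies."""
    n_num, n_struct = unique_counts(record)
    freqs = aggregate_frequencies(record)
    clonal = sorted(i.label for i, (n, _) in freqs.items()
                    if n == record.composite_count)
    nullisomies = {}
    if record.header is not None and record.header.ploidy_baseline is not None:
        for c in _DEFAULT_CHROMS:
            f = nullisomy_fraction(record, c)
            if f > 0:
                nullisomies[c] = round_percent(f)
    profile = chromosome_profile(record)
    return {
        "label": record.source_label,
        "composite_count": record.composite_count,
        "n_numerical": n_num,
        "n_structural": n_struct,
        "clonal_identities": clonal,
        "nullisomy_percent": nullisomies,
        "structurally_unaffected": sorted(profile.structurally_unaffected(),
                                          key=lambda c: (len(c), c)),
    }
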