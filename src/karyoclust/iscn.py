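"""Parser and serializer for the ISCN 2013 subset used in tumor composite karyotypes.

A composite karyotype summarizes N analyzed metaphases in one string, e.g. ::

    76~88<4n>,-X[11],-Xx2[8],+7[26],der(6)t(6;17;16)(q25;q21;?)[26],...[cp26]

Each comma-separated token is one aberration: numerical gains/losses (``+7``,
``-18x4``) or structural rearrangements (``der``, ``del``, ``dup``, ``add``,
``dic``, ``ins``, ``i``, ``t``), optionally with a multiplicity suffix ``xN``
and a bracketed count ``[N]`` of metaphases carrying it.  The trailing
``[cpN]`` gives the number of metaphases pooled into the composite.

Two parsing modes are offered.  ``strict`` accepts only well-formed notation.
``lenient`` additionally repairs the irregularities that occur in published
tables — commas for semicolons inside ``t(...)``, ``(5)`` where ``[5]`` was
meant, stray whitespace, missing separators between tokens, a multiplier with
a missing ``x`` — and records every repair applied.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "ParseError",
    "ValidationError",
    "Op",
    "ModalHeader",
    "AberrationEvent",
    "KaryotypeRecord",
    "parse_event",
    "parse_karyotype",
    "serialize",
    "serialize_event",
    "load_karyotypes",
    "table1_records",
    "record_to_dict",
    "record_to_json",
]

CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")
_CHROM_ORDER = {c: i for i, c in enumerate(("X", "Y") + tuple(str(i) for i in range(1, 23)))}

#: structural keywords, longest-match first ("ins" before "i", "der" before "d...").
_KEYWORDS = ("der", "del", "dup", "add", "dic", "ins", "i", "t")

_SUBTYPE = {"der": "der", "del": "del", "dup": "dup", "add": "add",
            "dic": "dic", "ins": "ins", "i": "iso", "t": "trans"}
_KEYWORD_OF_SUBTYPE = {v: k for k, v in _SUBTYPE.items()}


class ParseError(ValueError):
    """Malformed ISCN text; the message names the offending token."""


class ValidationError(ValueError):
    """Well-formed ISCN whose content violates a record-level constraint."""


@dataclass(frozen=True)
class Op:
    """One constituent operation of a structural event, e.g. ``t(8;16)(q?;q11.2)``."""

    keyword: str
    chromosomes: tuple[str, ...]
    bands: tuple[str, ...] | None = None

    def iscn(self) -> str:
        s = f"{self.keyword}({';'.join(self.chromosomes)})"
        if self.bands is not None:
            s += f"({';'.join(self.bands)})"
        return s


@dataclass(frozen=True)
class ModalHeader:
    """Modal chromosome-count range and ploidy baseline, e.g. ``76~88<4n>``."""

    count_low: int
    count_high: int
    ploidy_baseline: int | None = None
    approximate_flag: bool = False

    def __post_init__(self) -> None:
        if self.count_low > self.count_high:
            raise ValidationError(
                f"modal range inverted: {self.count_low} > {self.count_high}")
        if self.ploidy_baseline is not None and self.ploidy_baseline not in (2, 3, 4):
            raise ValidationError(f"unsupported ploidy baseline {self.ploidy_baseline}n")

    @property
    def reference_count(self) -> int | None:
        """Haploid-multiple reference count (``ploidy_baseline * 23``)."""
        return None if self.ploidy_baseline is None else 23 * self.ploidy_baseline

    def iscn(self) -> str:
        s = str(self.count_low) if self.count_low == self.count_high \
            else f"{self.count_low}~{self.count_high}"
        if self.ploidy_baseline is not None:
            s += f"<{self.ploidy_baseline}n{'+/-' if self.approximate_flag else ''}>"
        return s


@dataclass(frozen=True)
class AberrationEvent:
    """One parsed aberration token.

    ``category`` is ``gain``/``loss`` for numerical events (exactly one
    chromosome, no op chain) or ``structural``; structural events carry the
    full ``op_chain`` of constituent operations, positionally aligned
    breakpoints preserved (``?`` = unknown).  ``multiplicity`` is the ``xN``
    copy multiplier and ``cell_count`` the ``[N]`` metaphase count.
    """

    category: str
    subtype: str
    chromosomes: tuple[str, ...]
    op_chain: tuple[Op, ...]
    multiplicity: int = 1
    cell_count: int = 1
    raw_text: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.category in ("gain", "loss"):
            if len(self.chromosomes) != 1 or self.subtype != "none" or self.op_chain:
                raise ValidationError(f"malformed numerical event: {self.raw_text or self}")
        elif self.category == "structural":
            if self.subtype == "none" or not self.op_chain:
                raise ValidationError(f"structural event without subtype: {self.raw_text or self}")
        else:
            raise ValidationError(f"unknown category {self.category!r}")
        if self.multiplicity < 1 or self.cell_count < 1:
            raise ValidationError(f"multiplicity/cell_count must be >= 1: {self.raw_text or self}")

    @property
    def breakpoint_groups(self) -> tuple[tuple[str, ...], ...]:
        """Band groups of the constituent ops, in op order (band-less ops skipped)."""
        return tuple(op.bands for op in self.op_chain if op.bands is not None)

    def core(self) -> str:
        """Canonical text without multiplicity or cell count (the identity core)."""
        if self.category == "gain":
            return f"+{self.chromosomes[0]}"
        if self.category == "loss":
            return f"-{self.chromosomes[0]}"
        return "".join(op.iscn() for op in self.op_chain)

    def entry_label(self) -> str:
        """Multiplicity-resolved label, e.g. ``-18x2`` (no cell count)."""
        return self.core() + (f"x{self.multiplicity}" if self.multiplicity > 1 else "")

    def iscn(self, with_cell_count: bool = True) -> str:
        s = self.entry_label()
        if with_cell_count:
            s += f"[{self.cell_count}]"
        return s


@dataclass(frozen=True)
class KaryotypeRecord:
    """A parsed karyotype: modal header, sex tokens, ordered events, ``[cpN]``."""

    header: ModalHeader | None
    sex_tokens: tuple[str, ...]
    events: tuple[AberrationEvent, ...]
    composite_count: int = 1
    source_label: str = ""
    repairs: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.composite_count < 1:
            raise ValidationError("composite count must be >= 1")
        for ev in self.events:
            if ev.cell_count > self.composite_count:
                raise ValidationError(
                    f"{self.source_label or 'record'}: event {ev.iscn()} cell count "
                    f"{ev.cell_count} exceeds composite count {self.composite_count}")


# ---------------------------------------------------------------------------
# event-level parsing


def _split_list(content: str, token: str, mode: str, repairs: list[str]) -> tuple[str, ...]:
    if "," in content:
        if mode == "strict":
            raise ParseError(f"comma used for semicolon in {token!r}")
        repairs.append(f"{token}: ',' -> ';' inside parentheses")
        content = content.replace(",", ";")
    parts = tuple(p for p in content.split(";"))
    if any(p == "" for p in parts):
        raise ParseError(f"empty list element in {token!r}")
    return parts


def _check_chroms(chroms: Iterable[str], token: str) -> None:
    for c in chroms:
        if c not in CHROMOSOMES:
            raise ParseError(f"unknown chromosome designator {c!r} in {token!r}")


def parse_event(token: str, mode: str = "lenient",
                _repairs: list[str] | None = None) -> AberrationEvent:
    """Parse a single aberration token into an :class:`AberrationEvent`.

    Raises :class:`ParseError` for malformed tokens; in ``strict`` mode any
    notational irregularity is an error, in ``lenient`` mode it is repaired.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"unknown mode {mode!r}")
    repairs: list[str] = [] if _repairs is None else _repairs
    raw = token
    t = re.sub(r"\s+", "", token)
    if t != token:
        if mode == "strict":
            raise ParseError(f"whitespace inside token {token!r}")
        repairs.append(f"{raw!r}: stripped internal whitespace")
    if not t:
        raise ParseError("empty aberration token")

    m = re.fullmatch(r"([+-])([0-9]{1,2}|X|Y)(?:x(\d+))?(?:\[(\d+)\])?", t)
    if m:
        sign, chrom, mult, count = m.groups()
        _check_chroms([chrom], raw)
        return AberrationEvent(
            category="gain" if sign == "+" else "loss", subtype="none",
            chromosomes=(chrom,), op_chain=(),
            multiplicity=int(mult) if mult else 1,
            cell_count=int(count) if count else 1, raw_text=raw)
    if t[0] in "+-":
        raise ParseError(f"malformed numerical token {raw!r}")

    ops: list[Op] = []
    pos = 0
    while pos < len(t):
        kw = next((k for k in _KEYWORDS
                   if t.startswith(k, pos) and t.startswith("(", pos + len(k))), None)
        if kw is None:
            break
        pos += len(kw)
        groups: list[str] = []
        while pos < len(t) and t[pos] == "(" and len(groups) < 2:
            close = t.find(")", pos)
            if close < 0:
                raise ParseError(f"unbalanced parentheses in {raw!r}")
            groups.append(t[pos + 1:close])
            pos = close + 1
        chroms = _split_list(groups[0], raw, mode, repairs)
        bands = _split_list(groups[1], raw, mode, repairs) if len(groups) > 1 else None
        _check_chroms(chroms, raw)
        ops.append(Op(kw, chroms, bands))
    if not ops:
        raise ParseError(f"unknown subtype keyword in {raw!r}")

    rest = t[pos:]
    mult, count = 1, 1
    m = re.fullmatch(r"(?:x(\d+))?(?:\[(\d+)\])?", rest)
    if m:
        mult = int(m.group(1)) if m.group(1) else 1
        count = int(m.group(2)) if m.group(2) else 1
    elif mode == "lenient" and re.fullmatch(r"\((\d+)\)", rest):
        count = int(rest[1:-1])
        repairs.append(f"{raw!r}: trailing ({count}) read as cell count [{count}]")
    elif mode == "lenient" and re.fullmatch(r"(\d+)(?:\[(\d+)\])?", rest):
        m = re.fullmatch(r"(\d+)(?:\[(\d+)\])?", rest)
        mult = int(m.group(1))
        count = int(m.group(2)) if m.group(2) else 1
        repairs.append(f"{raw!r}: bare multiplier {mult} read as x{mult}")
    else:
        raise ParseError(f"trailing text {rest!r} in token {raw!r}")

    head = ops[0]
    chromosomes = list(head.chromosomes)
    for op in ops[1:]:
        for c in op.chromosomes:
            if c not in chromosomes:
                chromosomes.append(c)
    return AberrationEvent(
        category="structural", subtype=_SUBTYPE[ops[0].keyword],
        chromosomes=tuple(chromosomes), op_chain=tuple(ops),
        multiplicity=mult, cell_count=count, raw_text=raw)


# ---------------------------------------------------------------------------
# karyotype-level parsing

_HEADER_RE = re.compile(r"(\d+)(?:~(\d+))?(?:<(\d)n(\+/-|±)?>)?(?=,|$)")
_CP_RE = re.compile(r"\[cp(\d+)\]$")


def _split_tokens(s: str, mode: str, repairs: list[str]) -> list[str]:
    tokens, depth, start = [], 0, 0
    i = 0
    while i < len(s):
        ch = s[i]
        if ch in "([":
            depth += 1
        elif ch in ")]":
            depth -= 1
            if depth < 0:
                raise ParseError(f"unbalanced brackets near ...{s[max(0, i - 12):i + 1]!r}")
            if ch == "]" and depth == 0 and i + 1 < len(s) and s[i + 1] != ",":
                # missing separator between tokens, e.g. "-1[22]-1x2[2]"
                if mode == "strict":
                    raise ParseError(f"missing separator after ...{s[start:i + 1]!r}")
                repairs.append(f"inserted separator after {s[start:i + 1]!r}")
                tokens.append(s[start:i + 1])
                start = i + 1
                i += 1
                continue
        elif ch == "," and depth == 0:
            tokens.append(s[start:i])
            start = i + 1
        i += 1
    if depth != 0:
        raise ParseError(f"unbalanced parentheses/brackets in {s!r}")
    if start < len(s):
        tokens.append(s[start:])
    return [tok for tok in tokens if tok != ""]


def parse_karyotype(text: str, mode: str = "lenient",
                    source_label: str = "") -> KaryotypeRecord:
    """Parse a full ISCN karyotype string into a :class:`KaryotypeRecord`.

    Handles an optional modal header (``76~88<4n>``), leading sex-chromosome
    tokens, the comma-separated event tokens, and a trailing ``[cpN]``
    composite count (absent for a single-metaphase karyotype).
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"unknown mode {mode!r}")
    repairs: list[str] = []
    s = re.sub(r"\s+", "", text)
    if s != text.strip() or text != text.strip():
        if mode == "strict" and re.search(r"\S\s+\S", text.strip()):
            raise ParseError(f"stray whitespace in {source_label or text!r}")
        if re.search(r"\S\s+\S", text.strip()):
            repairs.append("stripped stray whitespace")
    if not s:
        raise ParseError("empty karyotype string")

    composite_count = 1
    m = _CP_RE.search(s)
    if m:
        composite_count = int(m.group(1))
        s = s[:m.start()]
        s = s.rstrip(",")

    header = None
    if s and s[0].isdigit():
        m = _HEADER_RE.match(s)
        if not m:
            raise ParseError(f"malformed modal header in {source_label or s!r}")
        low = int(m.group(1))
        high = int(m.group(2)) if m.group(2) else low
        ploidy = int(m.group(3)) if m.group(3) else None
        header = ModalHeader(low, high, ploidy, approximate_flag=bool(m.group(4)))
        s = s[m.end():].lstrip(",")

    tokens = _split_tokens(s, mode, repairs)
    sex_tokens: list[str] = []
    while tokens and re.fullmatch(r"[XY]+", tokens[0]):
        sex_tokens.append(tokens.pop(0))

    events = tuple(parse_event(tok, mode, _repairs=repairs) for tok in tokens)
    return KaryotypeRecord(header=header, sex_tokens=tuple(sex_tokens),
                           events=events, composite_count=composite_count,
                           source_label=source_label, repairs=tuple(repairs))


# ---------------------------------------------------------------------------
# serialization

def serialize_event(event: AberrationEvent, with_cell_count: bool = True) -> str:
    return event.iscn(with_cell_count=with_cell_count)


def serialize(record: KaryotypeRecord) -> str:
    """Render a record back to canonical ISCN text.

    The output re-parses in strict mode to an event-wise equal record
    (lenient repairs are normalized away).  Per-event cell counts and the
    ``[cpN]`` suffix are emitted only for composite records.
    """
    composite = record.composite_count > 1
    parts: list[str] = []
    if record.header is not None:
        parts.append(record.header.iscn())
    parts.extend(record.sex_tokens)
    parts.extend(ev.iscn(with_cell_count=composite) for ev in record.events)
    if not parts:
        parts.append("46" if record.header is None else record.header.iscn())
    s = ",".join(parts)
    if composite:
        s += f"[cp{record.composite_count}]"
    return s


def record_to_dict(record: KaryotypeRecord) -> dict:
    """Stable JSON-ready rendering of a record (events in input order)."""
    return {
        "source_label": record.source_label,
        "header": None if record.header is None else {
            "count_low": record.header.count_low,
            "count_high": record.header.count_high,
            "ploidy_baseline": record.header.ploidy_baseline,
            "approximate_flag": record.header.approximate_flag,
        },
        "sex_tokens": list(record.sex_tokens),
        "composite_count": record.composite_count,
        "events": [
            {
                "category": ev.category,
                "subtype": ev.subtype,
                "chromosomes": list(ev.chromosomes),
                "breakpoint_groups": [list(g) for g in ev.breakpoint_groups],
                "op_chain": [op.iscn() for op in ev.op_chain],
                "multiplicity": ev.multiplicity,
                "cell_count": ev.cell_count,
                "iscn": ev.iscn(),
            }
            for ev in record.events
        ],
        "repairs": list(record.repairs),
    }


def record_to_json(record: KaryotypeRecord, **kwargs) -> str:
    kwargs.setdefault("sort_keys", True)
    kwargs.setdefault("indent", 2)
    return json.dumps(record_to_dict(record), **kwargs)


# ---------------------------------------------------------------------------
# file input

def load_karyotypes(path: str | Path, mode: str = "lenient") -> list[KaryotypeRecord]:
    """Read a UTF-8 karyotype file: one karyotype per line, optionally
    ``label<TAB>karyotype``.  Blank lines and ``#`` comment lines are skipped.
    """
    records = []
    text = Path(path).read_text(encoding="utf-8")
    for i, line in enumerate(text.splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "\t" in line:
            label, karyo = line.split("\t", 1)
        else:
            label, karyo = f"karyotype_{i + 1}", line
        records.append(parse_karyotype(karyo, mode=mode, source_label=label.strip()))
    if not records:
        raise ValidationError(f"no karyotypes found in {path}")
    return records


def table1_path() -> Path:
    """Path to the bundled cell-line composite-karyotype fixture."""
    return Path(str(resources.files("karyoclust.data") / "table1_karyotypes.txt"))


def table1_records(mode: str = "lenient") -> list[KaryotypeRecord]:
    """The four bundled breast-cancer cell-line records (MCF7, T47D, BT474, SKBR3)."""
    return load_karyotypes(table1_path(), mode=mode)
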