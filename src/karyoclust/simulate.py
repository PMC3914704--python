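"""Synthetic metaphase-karyotype generator with known clonal structure.

Emulates what a cytogeneticist sees when karyotyping 20-odd metaphases of an
established tumor line: a clonal core of aberrations carried by every cell,
optional subclones carrying private aberrations in a fraction of cells, and
sporadic single-cell noise aberrations.  Ground truth (which metaphase
belongs to which subclone) is returned alongside, so clustering recovery can
be scored.  The default regime for demonstrations is clones-absent (clonal
core + sporadic noise): discrete subclones are the exception, not the rule,
in long-established lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .aberrations import MetaphaseMatrix, normalize_identity
from .iscn import (_CHROM_ORDER, AberrationEvent, KaryotypeRecord, ModalHeader,
                   ValidationError, parse_event)

__all__ = ["CellLineSpec", "generate_line", "compose_composite",
           "records_from_matrix"]


def _as_event(template: str | AberrationEvent) -> AberrationEvent:
    ev = template if isinstance(template, AberrationEvent) \
        else parse_event(template, mode="strict")
    return replace(ev, cell_count=1)


@dataclass(frozen=True)
class CellLineSpec:
    """Parameters of one simulated cell line.

    ``clonal_events`` are carried by every metaphase.  Each subclone is a
    ``(name, events, fraction)`` triple: its private events appear together in
    a random metaphase subset of expected size ``fraction * n`` (one binomial
    draw per subclone; with ``disjoint_subclones`` each metaphase belongs to
    at most one subclone).  ``noise_rate`` is the Poisson mean of sporadic
    per-metaphase aberrations drawn from a catalog of simple valid events.
    ``multiplicity_profile`` optionally maps a numerical event label (e.g.
    ``"-18"``) to a ``{multiplicity: probability}`` distribution sampled per
    carrying metaphase.
    """

    n_metaphases: int
    ploidy_baseline: int = 2
    clonal_events: tuple = ()
    subclones: tuple = ()
    disjoint_subclones: bool = False
    noise_rate: float = 0.0
    multiplicity_profile: dict | None = None
    seed: int = 0
    label: str = "SIM"

    def __post_init__(self) -> None:
        if self.n_metaphases < 2:
            raise ValidationError("need at least 2 metaphases")
        if self.ploidy_baseline not in (2, 3, 4):
            raise ValidationError("ploidy baseline must be 2, 3 or 4")
        if self.noise_rate < 0:
            raise ValidationError("noise_rate must be >= 0")
        fracs = [f for _, _, f in self.subclones]
        if any(not 0 < f < 1 for f in fracs):
            raise ValidationError("subclone fractions must lie in (0, 1)")
        if self.disjoint_subclones and sum(fracs) > 1:
            raise ValidationError("disjoint subclone fractions must sum to <= 1")
        if not self.clonal_events and not self.subclones and self.noise_rate == 0:
            raise ValidationError(
                "degenerate spec: no clonal events, no subclones, no noise")


def _noise_catalog(used: set, rng: np.random.Generator) -> list[AberrationEvent]:
    """Simple valid events (numerical plus small del/dup) not colliding with ``used``."""
    catalog = []
    bands = ["p11", "p13", "p15", "q11", "q13", "q21", "q23", "q25"]
    for c in [str(i) for i in range(1, 23)] + ["X"]:
        for tok in (f"+{c}", f"-{c}",
                    f"del({c})({rng.choice(bands)})",
                    f"dup({c})({rng.choice(bands[:4])}{rng.choice(bands[4:])})"):
            ev = _as_event(tok)
            if normalize_identity(ev) not in used:
                catalog.append(ev)
    return catalog


def _sort_key(ev: AberrationEvent):
    return (_CHROM_ORDER[ev.chromosomes[0]],
            0 if ev.category != "structural" else 1,
            ev.core(), ev.multiplicity)


def _chromosome_count(events: Sequence[AberrationEvent], ploidy: int) -> int:
    n = 23 * ploidy
    for ev in events:
        if ev.category == "gain":
            n += ev.multiplicity
        elif ev.category == "loss":
            n -= ev.multiplicity
    return n


def generate_line(spec: CellLineSpec,
                  ) -> tuple[list[KaryotypeRecord], dict[str, str]]:
    """Draw the metaphases of one simulated line.

    Returns single-metaphase records (composite count 1) and the ground-truth
    subclone label per metaphase (``"base"``, a subclone name, or a ``+``-join
    for overlapping membership).  Reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_metaphases
    clonal = [_as_event(t) for t in spec.clonal_events]
    subclones = [(name, [_as_event(t) for t in events], float(frac))
                 for name, events, frac in spec.subclones]

    membership = np.zeros((n, len(subclones)), dtype=bool)
    if spec.disjoint_subclones and subclones:
        probs = [f for _, _, f in subclones]
        probs.append(max(0.0, 1.0 - sum(probs)))
        draw = rng.choice(len(subclones) + 1, size=n, p=np.array(probs) / sum(probs))
        for s in range(len(subclones)):
            membership[:, s] = draw == s
    else:
        for s, (_, _, frac) in enumerate(subclones):
            membership[:, s] = rng.random(n) < frac

    used = {normalize_identity(ev) for ev in clonal}
    used |= {normalize_identity(ev) for _, evs, _ in subclones for ev in evs}
    catalog = _noise_catalog(used, rng) if spec.noise_rate > 0 else []

    profile = spec.multiplicity_profile or {}

    def with_multiplicity(ev: AberrationEvent) -> AberrationEvent:
        dist = profile.get(ev.core())
        if not dist:
            return ev
        mults = sorted(dist)
        p = np.array([dist[m] for m in mults], dtype=float)
        return replace(ev, multiplicity=int(rng.choice(mults, p=p / p.sum())))

    records, truth = [], {}
    for i in range(n):
        name = f"{spec.label}_M{i + 1}"
        events = [with_multiplicity(ev) for ev in clonal]
        members = [subclones[s][0] for s in range(len(subclones)) if membership[i, s]]
        for s in range(len(subclones)):
            if membership[i, s]:
                events.extend(with_multiplicity(ev) for ev in subclones[s][1])
        if catalog:
            k = min(rng.poisson(spec.noise_rate), len(catalog))
            if k:
                events.extend(catalog[j] for j in
                              rng.choice(len(catalog), size=k, replace=False))
        events.sort(key=_sort_key)
        count = _chromosome_count(events, spec.ploidy_baseline)
        header = ModalHeader(count, count, spec.ploidy_baseline)
        records.append(KaryotypeRecord(
            header=header, sex_tokens=(), events=tuple(events),
            composite_count=1, source_label=name))
        truth[name] = "+".join(members) if members else "base"
    return records, truth


def compose_composite(metaphases: Sequence[KaryotypeRecord],
                      label: str = "") -> KaryotypeRecord:
    """Pool single-metaphase records into one composite (``[cpN]``) record.

    One event entry per (identity, multiplicity) pair with the number of
    carrying metaphases as cell count; the modal header spans the chromosome
    counts implied by the pooled events.
    """
    metaphases = list(metaphases)
    if not metaphases:
        raise ValidationError("no metaphases to compose")
    ploidies = {r.header.ploidy_baseline if r.header else None for r in metaphases}
    if len(ploidies) != 1:
        raise ValidationError(f"mixed ploidy baselines: {ploidies}")
    ploidy = ploidies.pop()
    for r in metaphases:
        if r.composite_count != 1:
            raise ValidationError("compose_composite expects single-metaphase records")

    counts: dict[str, int] = {}
    rep: dict[str, AberrationEvent] = {}
    for r in metaphases:
        for ev in r.events:
            key = ev.entry_label()
            counts[key] = counts.get(key, 0) + 1
            rep.setdefault(key, ev)
    events = sorted((replace(rep[k], cell_count=c) for k, c in counts.items()),
                    key=_sort_key)
    if ploidy is not None:
        per_cell = [_chromosome_count(r.events, ploidy) for r in metaphases]
        header = ModalHeader(min(per_cell), max(per_cell), ploidy)
    else:
        header = None
    return KaryotypeRecord(
        header=header, sex_tokens=metaphases[0].sex_tokens, events=tuple(events),
        composite_count=len(metaphases),
        source_label=label or (metaphases[0].source_label.rsplit("_M", 1)[0]
                               if metaphases[0].source_label else ""))


def records_from_matrix(matrix: MetaphaseMatrix, ploidy_baseline: int | None = None,
                        ) -> list[KaryotypeRecord]:
    """Turn a binary metaphase matrix back into single-metaphase records.

    Column labels must be canonical entry labels (they are, for matrices built
    by this package).  Used to close the expand -> compose round trip.
    """
    entry_events = {label: _as_event(label) for label in matrix.entries}
    header = None if ploidy_baseline is None else \
        ModalHeader(23 * ploidy_baseline, 23 * ploidy_baseline, ploidy_baseline)
    records = []
    for name, row in matrix.frame.iterrows():
        events = sorted((entry_events[c] for c in matrix.entries if row[c]),
                        key=_sort_key)
        if header is not None:
            count = _chromosome_count(events, ploidy_baseline)
            rec_header = ModalHeader(count, count, ploidy_baseline)
        else:
            rec_header = None
        records.append(KaryotypeRecord(header=rec_header, sex_tokens=(),
                                       events=tuple(events), composite_count=1,
                                       source_label=str(name)))
    return records
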