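"""Approximate motif search over unique peptides and event aggregation.

The scanner slides each motif over every window of a peptide and reports one
*event* per window whose Hamming distance to the motif matches the requested
mode. Overlapping windows are each reported, and a peptide may contribute
several events for one motif — event counting deliberately mirrors ELISA-style
site counting rather than peptide presence/absence.

Three modes are exposed:

* ``perfect`` — Hamming distance 0;
* ``one_mismatch`` — distance exactly 1 (the default mismatch semantics;
  note that exact-distance counts can be *below* perfect counts);
* ``at_most_one`` — distance 0 or 1, provided for sensitivity analysis.

Only substitutions count as mismatches (fixed-length windows; no indels),
and I/L are distinct residues with no Q/E deamidation equivalence.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

from .ingest import UniquePeptideSet
from .motifs import MotifCategory, MotifDatabase, MotifRecord

__all__ = [
    "MatchMode",
    "MatchEvent",
    "EventCountTable",
    "FlourComparison",
    "UNDEFINED_RATIO",
    "scan_peptide",
    "scan_oracle",
    "count_events",
    "compare_flours",
    "write_event_table",
    "read_event_table",
    "write_events_long",
]


class MatchMode(str, enum.Enum):
    PERFECT = "perfect"
    ONE_MISMATCH = "one_mismatch"
    AT_MOST_ONE = "at_most_one"

    @classmethod
    def coerce(cls, value: Union[str, "MatchMode"]) -> "MatchMode":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).replace("-", "_"))
        except ValueError:
            raise ValueError(
                f"unknown match mode {value!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


#: The two modes reported in the aggregated count table.
REPORT_MODES = (MatchMode.PERFECT, MatchMode.ONE_MISMATCH)


@dataclass(frozen=True)
class MatchEvent:
    """One motif occurrence in one peptide.

    ``offset`` is the 0-based start of the match window within the peptide
    (windows are half-open ``[offset, offset + len(motif))``).
    ``mismatch_position`` is the 0-based position within the motif of the
    single substitution, present iff ``mismatches == 1``.
    """

    peptide_sequence: str
    motif_id: str
    offset: int
    mismatches: int
    mismatch_position: int | None = None

    def __post_init__(self) -> None:
        if self.mismatches not in (0, 1):
            raise ValueError("mismatches must be 0 or 1")
        if (self.mismatch_position is None) != (self.mismatches == 0):
            raise ValueError(
                "mismatch_position must be present iff mismatches == 1"
            )


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def scan_peptide(
    peptide: str,
    motif: MotifRecord,
    mode: Union[str, MatchMode] = MatchMode.PERFECT,
) -> list[MatchEvent]:
    """Find all windows of ``peptide`` matching ``motif`` under ``mode``.

    Every window position is examined, so overlapping matches are each
    reported; events come back ordered by offset. A motif longer than the
    peptide yields no events.
    """
    mode = MatchMode.coerce(mode)
    m = len(motif.sequence)
    if m > len(peptide) or m == 0:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(_encode(peptide), m)
    diff = windows != _encode(motif.sequence)
    nmm = diff.sum(axis=1)
    if mode is MatchMode.PERFECT:
        keep = nmm == 0
    elif mode is MatchMode.ONE_MISMATCH:
        keep = nmm == 1
    else:
        keep = nmm <= 1
    events: list[MatchEvent] = []
    for off in np.flatnonzero(keep):
        k = int(nmm[off])
        events.append(
            MatchEvent(
                peptide_sequence=peptide,
                motif_id=motif.motif_id,
                offset=int(off),
                mismatches=k,
                mismatch_position=int(np.argmax(diff[off])) if k == 1 else None,
            )
        )
    return events


def scan_oracle(
    peptide: str,
    motif: MotifRecord,
    mode: Union[str, MatchMode] = MatchMode.PERFECT,
) -> list[MatchEvent]:
    """Brute-force reference scanner: enumerate every window and literally
    count mismatching positions. Definitionally correct and deliberately
    independent of :func:`scan_peptide`; intended for testing."""
    mode = MatchMode.coerce(mode)
    mseq = motif.sequence
    events: list[MatchEvent] = []
    for off in range(len(peptide) - len(mseq) + 1):
        bad = [i for i in range(len(mseq)) if peptide[off + i] != mseq[i]]
        if mode is MatchMode.PERFECT:
            ok = len(bad) == 0
        elif mode is MatchMode.ONE_MISMATCH:
            ok = len(bad) == 1
        else:
            ok = len(bad) <= 1
        if ok:
            events.append(
                MatchEvent(
                    peptide_sequence=peptide,
                    motif_id=motif.motif_id,
                    offset=off,
                    mismatches=len(bad),
                    mismatch_position=bad[0] if len(bad) == 1 else None,
                )
            )
    return events


@dataclass
class EventCountTable:
    """Category x mode event counts for one sample.

    All six categories are present for both reported modes (zeros allowed).
    """

    sample_label: str
    counts: dict[tuple[MotifCategory, MatchMode], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cat in MotifCategory:
            for mode in REPORT_MODES:
                self.counts.setdefault((cat, mode), 0)
        for key, v in self.counts.items():
            if v < 0:
                raise ValueError(f"negative count for {key}")

    def get(self, category: Union[str, MotifCategory], mode: Union[str, MatchMode]) -> int:
        return self.counts[(MotifCategory.coerce(category), MatchMode.coerce(mode))]


def count_events(
    upset: UniquePeptideSet,
    db: MotifDatabase,
    mode: Union[str, MatchMode, None] = None,
    scanner=scan_peptide,
) -> tuple[EventCountTable, list[MatchEvent]]:
    """Aggregate motif events over a unique peptide set.

    For each category the count is the total number of events summed over
    every (unique peptide, motif of that category) pair — a peptide may
    contribute many events, overlapping events included, and two motifs of
    the same category matching the same window both count.

    ``mode=None`` fills both reported modes; a single mode fills only that
    column (the other stays zero). Returns the table and the full per-event
    list for auditing.
    """
    modes = REPORT_MODES if mode is None else (MatchMode.coerce(mode),)
    counts: dict[tuple[MotifCategory, MatchMode], int] = {}
    all_events: list[MatchEvent] = []
    for md in modes:
        if md not in REPORT_MODES:
            raise ValueError(
                "count tables report the perfect and one_mismatch modes"
            )
        for motif in db:
            for pep in upset:
                evts = scanner(pep, motif, md)
                counts[(motif.category, md)] = counts.get(
                    (motif.category, md), 0
                ) + len(evts)
                all_events.extend(evts)
    return EventCountTable(sample_label=upset.sample_label, counts=counts), all_events


#: Sentinel carried for a fold-ratio whose comparator count is zero.
UNDEFINED_RATIO = None


def _round1(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class FlourComparison:
    """Per-category fold-ratios (reference / comparator) for one mode.

    ``ratios`` holds the ratio rounded half-up to one decimal (the reporting
    convention); ``exact_ratios`` keeps full precision. A zero comparator
    count yields the ``UNDEFINED_RATIO`` sentinel (``None``), never a number.
    """

    reference_label: str
    comparator_label: str
    mode: MatchMode
    ratios: dict[MotifCategory, float | None] = field(default_factory=dict)
    exact_ratios: dict[MotifCategory, float | None] = field(default_factory=dict)


def compare_flours(
    reference: EventCountTable,
    comparator: EventCountTable,
    mode: Union[str, MatchMode] = MatchMode.PERFECT,
) -> FlourComparison:
    """Per-category fold-ratio of reference over comparator event counts."""
    mode = MatchMode.coerce(mode)
    ratios: dict[MotifCategory, float | None] = {}
    exact: dict[MotifCategory, float | None] = {}
    for cat in MotifCategory:
        num = reference.get(cat, mode)
        den = comparator.get(cat, mode)
        if den == 0:
            ratios[cat] = exact[cat] = UNDEFINED_RATIO
        else:
            exact[cat] = num / den
            ratios[cat] = _round1(num / den)
    return FlourComparison(
        reference_label=reference.sample_label,
        comparator_label=comparator.sample_label,
        mode=mode,
        ratios=ratios,
        exact_ratios=exact,
    )


# --- tabular I/O ------------------------------------------------------------


def write_event_table(
    table: EventCountTable,
    path: Union[str, Path],
    header_lines: Sequence[str] = (),
) -> None:
    """Write a count table as TSV: rows = categories, columns = modes."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(f"# sample: {table.sample_label}\n")
        fh.write("category\t" + "\t".join(m.value for m in REPORT_MODES) + "\n")
        for cat in MotifCategory:
            row = "\t".join(str(table.get(cat, m)) for m in REPORT_MODES)
            fh.write(f"{cat.value}\t{row}\n")


def read_event_table(path: Union[str, Path]) -> EventCountTable:
    """Read a count table written by :func:`write_event_table`."""
    path = Path(path)
    sample = path.stem
    counts: dict[tuple[MotifCategory, MatchMode], int] = {}
    with path.open("r", encoding="utf-8") as fh:
        header: list[str] | None = None
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("#"):
                body = line.lstrip("# ")
                if body.startswith("sample:"):
                    sample = body.split(":", 1)[1].strip()
                continue
            if not line.strip():
                continue
            fields = line.split("\t")
            if header is None:
                if fields[0] != "category":
                    raise ValueError(f"{path}: expected 'category' header column")
                header = fields[1:]
                continue
            cat = MotifCategory.coerce(fields[0])
            for mode_name, value in zip(header, fields[1:]):
                counts[(cat, MatchMode.coerce(mode_name))] = int(value)
    if header is None:
        raise ValueError(f"{path}: no header row")
    return EventCountTable(sample_label=sample, counts=counts)


def write_events_long(
    events: Iterable[MatchEvent],
    path: Union[str, Path],
    header_lines: Sequence[str] = (),
) -> None:
    """Write the per-event audit TSV (peptide, motif, offset, mismatches)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("peptide\tmotif_id\toffset\tmismatches\tmismatch_position\n")
        for e in events:
            mp = "" if e.mismatch_position is None else str(e.mismatch_position)
            fh.write(
                f"{e.peptide_sequence}\t{e.motif_id}\t{e.offset}\t{e.mismatches}\t{mp}\n"
            )
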