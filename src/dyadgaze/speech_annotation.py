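"""Speech segments, dialogue acts, validation and pair synchronization.

Two schemes:

* :class:`SpeechSegment` — contiguous intervals carrying one of the 14
  speech tags (see :mod:`dyadgaze.vocab`);
* :class:`DialogueActUnit` — ISO 24617-2 dialogue acts, read from a
  DiAML-MultiTab-style delimited table with unique unit ids, dimension,
  communicative function, optional qualifiers, ISO 24617-8 rhetorical
  relations, and functional/feedback dependences referencing other units.

Pair recordings run on independent clocks; a shared beep marker anchors a
rigid time offset (:func:`synchronize_pair` / :func:`apply_offset`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .vocab import (
    DIMENSIONS,
    RHETORICAL_RELATIONS,
    SPEECH_TAGS,
    UNSEEN_IN_CORPUS,
    function_allowed_in,
)

#: Segment boundary granularity of the audio segmenter, ms (lint-only).
SEGMENT_RESOLUTION_MS = 10.0

#: Sub-field delimiter inside multi-valued DiAML-MultiTab cells.
MULTI_DELIM = ";"


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class SpeechSegment:
    sender: str
    tag: str
    start_ms: float
    end_ms: float

    def __post_init__(self) -> None:
        if self.tag not in SPEECH_TAGS:
            raise AnnotationError(f"unknown speech tag {self.tag!r}")
        if not self.start_ms < self.end_ms:
            raise AnnotationError(
                f"segment must have start < end, got [{self.start_ms}, {self.end_ms})"
            )

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


@dataclass(frozen=True)
class DialogueActUnit:
    """One dialogue act in DiAML-MultiTab terms."""

    unit_id: str
    sender: str
    word_intervals: tuple[tuple[float, float], ...]
    dimension: str
    communicative_function: str
    certainty: str = ""
    sentiment: str = ""
    rhetorical_relations: tuple[tuple[str, int], ...] = field(default_factory=tuple)
    functional_dependences: tuple[str, ...] = field(default_factory=tuple)
    feedback_dependences: tuple[str, ...] = field(default_factory=tuple)


def unit_interval(unit: DialogueActUnit) -> tuple[float, float]:
    """Time span of a dialogue act: the concatenation of its word intervals."""
    if not unit.word_intervals:
        raise AnnotationError(f"unit {unit.unit_id} has no word intervals")
    return (
        min(s for s, _ in unit.word_intervals),
        max(e for _, e in unit.word_intervals),
    )


# --- segment I/O ----------------------------------------------------------

SEGMENT_COLUMNS = ("sender", "tag", "start_ms", "end_ms")


def _check_segments(segments: list[SpeechSegment]) -> None:
    by_sender: dict[str, list[SpeechSegment]] = {}
    for seg in segments:
        by_sender.setdefault(seg.sender, []).append(seg)
    for sender, segs in by_sender.items():
        segs = sorted(segs, key=lambda s: s.start_ms)
        for a, b in zip(segs[:-1], segs[1:]):
            if b.start_ms < a.end_ms:
                raise AnnotationError(
                    f"overlapping segments for sender {sender!r}: "
                    f"[{a.start_ms}, {a.end_ms}) and [{b.start_ms}, {b.end_ms})"
                )


def read_segments(path: str | Path) -> list[SpeechSegment]:
    """Read a tab-delimited speech segment table; rejects overlaps."""
    path = Path(path)
    if path.stat().st_size == 0:
        return []
    df = pd.read_csv(path, sep="\t")
    segments = [
        SpeechSegment(
            sender=str(row.sender),
            tag=row.tag,
            start_ms=float(row.start_ms),
            end_ms=float(row.end_ms),
        )
        for row in df.itertuples(index=False)
    ]
    _check_segments(segments)
    return segments


def write_segments(segments: list[SpeechSegment], path: str | Path) -> None:
    _check_segments(segments)
    df = pd.DataFrame(
        [(s.sender, s.tag, s.start_ms, s.end_ms) for s in segments],
        columns=list(SEGMENT_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


def lint_segments(segments: list[SpeechSegment]) -> list[str]:
    """Non-fatal quality warnings (e.g. boundaries off the 10 ms grid)."""
    warnings = []
    for seg in segments:
        for name, v in (("start", seg.start_ms), ("end", seg.end_ms)):
            if abs(v / SEGMENT_RESOLUTION_MS - round(v / SEGMENT_RESOLUTION_MS)) > 1e-9:
                warnings.append(
                    f"{seg.sender} {seg.tag!r} {name} {v} ms is off the "
                    f"{SEGMENT_RESOLUTION_MS:g} ms segmentation grid"
                )
    return warnings


# --- dialogue act I/O -----------------------------------------------------

DIALOGUE_ACT_COLUMNS = (
    "unit_id",
    "sender",
    "word_intervals",
    "dimension",
    "communicative_function",
    "certainty",
    "sentiment",
    "rhetorical_relations",
    "functional_dependences",
    "feedback_dependences",
)


def _parse_intervals(cell: str) -> tuple[tuple[float, float], ...]:
    if not cell:
        return ()
    out = []
    for token in cell.split(MULTI_DELIM):
        s, e = token.split("-")
        out.append((float(s), float(e)))
    return tuple(out)


def _fmt_intervals(intervals) -> str:
    return MULTI_DELIM.join(f"{s:g}-{e:g}" for s, e in intervals)


def _parse_rrs(cell: str) -> tuple[tuple[str, int], ...]:
    if not cell:
        return ()
    out = []
    for token in cell.split(MULTI_DELIM):
        rel, arg = token.rsplit(":", 1)
        out.append((rel, int(arg)))
    return tuple(out)


def read_dialogue_acts(path: str | Path) -> list[DialogueActUnit]:
    """Read a DiAML-MultiTab-style tab-delimited dialogue act table.

    One unit per row; multi-valued cells (word intervals, rhetorical
    relations, dependences) are ``;``-delimited.  Raises
    :class:`AnnotationError` on duplicate unit ids or unknown dimensions,
    naming the offending row.
    """
    df = pd.read_csv(Path(path), sep="\t", keep_default_na=False, dtype=str)
    units: list[DialogueActUnit] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        if row.unit_id in seen:
            raise AnnotationError(f"row {i}: duplicate unit_id {row.unit_id!r}")
        seen.add(row.unit_id)
        if row.dimension not in DIMENSIONS:
            raise AnnotationError(
                f"row {i} (unit {row.unit_id!r}): unknown dimension {row.dimension!r}"
            )
        units.append(
            DialogueActUnit(
                unit_id=row.unit_id,
                sender=row.sender,
                word_intervals=_parse_intervals(row.word_intervals),
                dimension=row.dimension,
                communicative_function=row.communicative_function,
                certainty=row.certainty,
                sentiment=row.sentiment,
                rhetorical_relations=_parse_rrs(row.rhetorical_relations),
                functional_dependences=tuple(
                    t for t in row.functional_dependences.split(MULTI_DELIM) if t
                ),
                feedback_dependences=tuple(
                    t for t in row.feedback_dependences.split(MULTI_DELIM) if t
                ),
            )
        )
    return units


def write_dialogue_acts(units: list[DialogueActUnit], path: str | Path) -> None:
    rows = [
        (
            u.unit_id,
            u.sender,
            _fmt_intervals(u.word_intervals),
            u.dimension,
            u.communicative_function,
            u.certainty,
            u.sentiment,
            MULTI_DELIM.join(f"{rel}:{arg}" for rel, arg in u.rhetorical_relations),
            MULTI_DELIM.join(u.functional_dependences),
            MULTI_DELIM.join(u.feedback_dependences),
        )
        for u in units
    ]
    pd.DataFrame(rows, columns=list(DIALOGUE_ACT_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_dialogue_acts(units: list[DialogueActUnit]) -> ValidationReport:
    """Consistency checks on a dialogue act table.

    Violations: duplicate unit ids; unresolved dependence references;
    a dimension-specific communicative function annotated outside its home
    dimension; rhetorical-relation labels outside the 18-label DR-Core set.
    Warnings: functions flagged as unseen in the interview corpus.
    """
    report = ValidationReport()
    ids: set[str] = set()
    for u in units:
        if u.unit_id in ids:
            report.violations.append(f"duplicate unit_id {u.unit_id!r}")
        ids.add(u.unit_id)
    for u in units:
        if not function_allowed_in(u.communicative_function, u.dimension):
            report.violations.append(
                f"unit {u.unit_id!r}: function {u.communicative_function!r} "
                f"is not admissible under dimension {u.dimension!r}"
            )
        if u.communicative_function in UNSEEN_IN_CORPUS:
            report.warnings.append(
                f"unit {u.unit_id!r}: function {u.communicative_function!r} "
                "unseen in corpus"
            )
        for rel, _arg in u.rhetorical_relations:
            if rel not in RHETORICAL_RELATIONS:
                report.violations.append(
                    f"unit {u.unit_id!r}: rhetorical relation {rel!r} is not "
                    "in the DR-Core set"
                )
        for ref in u.functional_dependences + u.feedback_dependences:
            if ref not in ids:
                report.violations.append(
                    f"unit {u.unit_id!r}: dependence reference {ref!r} "
                    "does not resolve"
                )
    return report


# --- synchronization ------------------------------------------------------


@dataclass(frozen=True)
class SyncOffset:
    """Recording B clock minus recording A clock, ms."""

    offset_ms: float


def synchronize_pair(beep_a_ms: float, beep_b_ms: float) -> SyncOffset:
    """Offset aligning recording B's clock onto recording A's.

    Both recordings captured the same physical beep; the offset is the
    difference of its timestamps.
    """
    return SyncOffset(offset_ms=float(beep_b_ms) - float(beep_a_ms))


def apply_offset(obj, offset: SyncOffset):
    """Rigidly shift timestamps by ``-offset_ms`` (B-clock -> A-clock).

    Accepts a list of :class:`SpeechSegment`, a gaze sample DataFrame with
    a ``t_ms`` column, or a bare float timestamp; returns the same kind.
    """
    d = offset.offset_ms
    if isinstance(obj, (int, float)):
        return obj - d
    if isinstance(obj, pd.DataFrame):
        out = obj.copy()
        out["t_ms"] = out["t_ms"] - d
        return out
    return [
        replace(seg, start_ms=seg.start_ms - d, end_ms=seg.end_ms - d) for seg in obj
    ]


# --- boundary re-segmentation --------------------------------------------


def merge_segment_boundaries(
    segments_a: list[SpeechSegment], segments_b: list[SpeechSegment]
) -> tuple[list[SpeechSegment], list[SpeechSegment]]:
    """Re-cut both recordings at the union of all boundary times.

    Each output segment inherits the tag and sender of the input segment
    containing it; no output interval crosses any input boundary.  Total
    annotated duration per tag is preserved exactly.
    """
    boundaries = sorted(
        {b for seg in segments_a + segments_b for b in (seg.start_ms, seg.end_ms)}
    )

    def recut(segments: list[SpeechSegment]) -> list[SpeechSegment]:
        out = []
        for seg in sorted(segments, key=lambda s: s.start_ms):
            cuts = [seg.start_ms]
            cuts += [b for b in boundaries if seg.start_ms < b < seg.end_ms]
            cuts.append(seg.end_ms)
            for s, e in zip(cuts[:-1], cuts[1:]):
                out.append(replace(seg, start_ms=s, end_ms=e))
        return out

    return recut(segments_a), recut(segments_b)
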