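"""Hierarchical annotation I/O and sequence derivation.

Vocalizations are annotated on three Praat TextGrid interval tiers named (by
default) ``combination``, ``call`` and ``segment``.  A combination is a run of
calls separated by short silences (<= ~0.5 s); a call is a run of segments
separated by very short silences (<= 0.025 s); segments carry one of four
hand-label classes after relabeling: DS (down sweep), LH (long high), NL
(noisy line), SH (short high).

This module reads and writes long-format TextGrids, enforces the nesting
invariants, and derives the labeled sequences that the transition analysis
consumes.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.io import wavfile

from vocalcomb.errors import (
    FormatError,
    HierarchyError,
    LabelError,
    OrderingError,
    VocalcombError,
)

SEGMENT_CLASSES = ("DS", "LH", "NL", "SH")
#: Low-sample hand-label classes folded into acoustically overlapping classes.
DEFAULT_RELABELING = {"HL": "LH", "US": "SH"}
LEVELS = ("segment", "call", "combination")
DEFAULT_TIER_NAMES = {"segment": "segment", "call": "call", "combination": "combination"}

CALL_GROUPS = ("LH-containing", "lone-NL", "other")

#: Tolerance (s) when testing whether a segment lies inside a call, to absorb
#: annotation rounding.
CONTAINMENT_TOL = 1e-3
#: Overlaps up to this (s) between consecutive units on a tier are repaired by
#: truncating the earlier unit; larger overlaps are format errors.
OVERLAP_TOL = 1e-3


@dataclass(frozen=True)
class RecordingMeta:
    """Per-recording metadata used as cluster-evaluation predictors."""

    recording_id: str
    individual_id: str
    group_id: str
    site: str
    sex: str
    sample_rate: int = 44100
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        for name in ("recording_id", "individual_id", "group_id"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")


@dataclass(frozen=True, order=True)
class VocalUnit:
    """One labeled, time-bounded unit on one combinatorial level."""

    start: float
    end: float
    label: str
    level: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid unit times [{self.start}, {self.end}]")
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class AnnotationSet:
    """Three-tier annotation hierarchy for one recording."""

    meta: RecordingMeta
    units: dict[str, list[VocalUnit]] = field(
        default_factory=lambda: {lv: [] for lv in LEVELS}
    )

    def __post_init__(self) -> None:
        for lv in LEVELS:
            self.units.setdefault(lv, [])

    def level(self, level: str) -> list[VocalUnit]:
        if level not in LEVELS:
            raise ValueError(f"unknown level {level!r}")
        return self.units[level]

    def validate(self, containment_tol: float = CONTAINMENT_TOL) -> None:
        """Raise if the nesting invariants are violated."""
        for lv in LEVELS:
            us = self.units[lv]
            if us != sorted(us, key=lambda u: u.start):
                raise OrderingError(f"{lv} tier not sorted by start")
            for a, b in zip(us, us[1:]):
                if a.end > b.start + 1e-9:
                    raise OrderingError(
                        f"{lv} tier overlap at {b.start:.4f}s "
                        f"({self.meta.recording_id})"
                    )
        for seg in self.units["segment"]:
            owners = [
                c
                for c in self.units["call"]
                if c.start - containment_tol <= seg.start
                and seg.end <= c.end + containment_tol
            ]
            if len(owners) != 1:
                raise HierarchyError(
                    f"segment at {seg.start:.4f}s contained by {len(owners)} "
                    f"calls ({self.meta.recording_id})"
                )
        for call in self.units["call"]:
            owners = [
                c
                for c in self.units["combination"]
                if c.start - containment_tol <= call.start
                and call.end <= c.end + containment_tol
            ]
            if len(owners) > 1:
                raise HierarchyError(
                    f"call at {call.start:.4f}s inside {len(owners)} combinations"
                )
        for comb in self.units["combination"]:
            n = len(self._children(comb, "call", containment_tol))
            if n < 2:
                raise HierarchyError(
                    f"combination at {comb.start:.4f}s has {n} call(s); needs >= 2"
                )

    def _children(
        self, parent: VocalUnit, level: str, tol: float = CONTAINMENT_TOL
    ) -> list[VocalUnit]:
        return [
            u
            for u in self.units[level]
            if parent.start - tol <= u.start and u.end <= parent.end + tol
        ]

    def calls_of(self, combination: VocalUnit) -> list[VocalUnit]:
        return self._children(combination, "call")

    def segments_of(self, call: VocalUnit) -> list[VocalUnit]:
        return self._children(call, "segment")

    def call_of_segment(self, segment: VocalUnit) -> VocalUnit:
        for c in self.units["call"]:
            if (
                c.start - CONTAINMENT_TOL <= segment.start
                and segment.end <= c.end + CONTAINMENT_TOL
            ):
                return c
        raise HierarchyError(f"orphan segment at {segment.start:.4f}s")


@dataclass
class GapStatistics:
    """Summary of silent gaps between consecutive units inside their parent."""

    level: str  # "between-call" | "between-segment"
    gaps: list[float]
    mean: float
    sd: float
    max: float

    @classmethod
    def from_gaps(cls, level: str, gaps: Sequence[float]) -> "GapStatistics":
        arr = np.asarray(gaps, dtype=float)
        if arr.size and arr.min() < -1e-9:
            raise ValueError("negative gap")
        return cls(
            level=level,
            gaps=list(arr),
            mean=float(arr.mean()) if arr.size else math.nan,
            sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            max=float(arr.max()) if arr.size else math.nan,
        )


# ---------------------------------------------------------------------------
# TextGrid read / write (long text format)
# ---------------------------------------------------------------------------

_NUM_RE = re.compile(r"(xmin|xmax)\s*=\s*([-\d.eE+]+)")
_TEXT_RE = re.compile(r'(?:text|name)\s*=\s*"((?:[^"]|"")*)"')


def _parse_textgrid_tiers(text: str) -> dict[str, list[tuple[float, float, str]]]:
    """Return {tier_name: [(xmin, xmax, label), ...]} from a long TextGrid."""
    tiers: dict[str, list[tuple[float, float, str]]] = {}
    chunks = re.split(r"item\s*\[\d+\]\s*:", text)
    for chunk in chunks[1:]:
        if '"IntervalTier"' not in chunk:
            continue
        m = re.search(r'name\s*=\s*"((?:[^"]|"")*)"', chunk)
        if not m:
            raise FormatError("IntervalTier without a name")
        name = m.group(1).replace('""', '"')
        intervals: list[tuple[float, float, str]] = []
        for ichunk in re.split(r"intervals\s*\[\d+\]\s*:", chunk)[1:]:
            nums = dict(_NUM_RE.findall(ichunk))
            tm = re.search(r'text\s*=\s*"((?:[^"]|"")*)"', ichunk)
            if "xmin" not in nums or "xmax" not in nums or tm is None:
                raise FormatError(f"malformed interval in tier {name!r}")
            xmin, xmax = float(nums["xmin"]), float(nums["xmax"])
            label = tm.group(1).replace('""', '"')
            if xmax <= xmin and label.strip():
                raise FormatError(
                    f"interval with end <= start in tier {name!r} at {xmin}"
                )
            intervals.append((xmin, xmax, label))
        tiers[name] = intervals
    return tiers


def _repair_overlaps(units: list[VocalUnit], tol: float = OVERLAP_TOL) -> list[VocalUnit]:
    """Truncate the earlier unit when consecutive units overlap by <= tol.

    Mirrors the annotation convention for intersecting boundaries at segment
    transitions: each boundary is placed where the intersection ceases.
    """
    units = sorted(units, key=lambda u: u.start)
    out: list[VocalUnit] = []
    for u in units:
        if out and out[-1].end > u.start:
            overlap = out[-1].end - u.start
            if overlap > tol:
                raise FormatError(
                    f"{u.level} overlap of {overlap:.4f}s at {u.start:.4f}s"
                )
            out[-1] = replace(out[-1], end=u.start)
        out.append(u)
    return out


def read_textgrid(
    path: str | Path,
    meta: RecordingMeta,
    tier_names: Mapping[str, str] | None = None,
    validate: bool = True,
) -> AnnotationSet:
    """Read a long-format Praat TextGrid into an :class:`AnnotationSet`.

    Empty-label intervals (silences / fillers) are skipped.  ``tier_names``
    maps level -> tier name when the file uses non-default tier names.
    """
    tier_names = dict(DEFAULT_TIER_NAMES, **(tier_names or {}))
    text = Path(path).read_text()
    tiers = _parse_textgrid_tiers(text)
    units: dict[str, list[VocalUnit]] = {}
    for level in LEVELS:
        tname = tier_names[level]
        if tname not in tiers:
            raise HierarchyError(
                f"TextGrid {path} lacks tier {tname!r} for level {level!r} "
                f"(found: {sorted(tiers)})"
            )
        lvl_units = [
            VocalUnit(start=a, end=b, label=lab.strip(), level=level)
            for a, b, lab in tiers[tname]
            if lab.strip()
        ]
        units[level] = _repair_overlaps(lvl_units)
    ann = AnnotationSet(meta=meta, units=units)
    if validate:
        ann.validate()
    return ann


def _format_tier(name: str, units: list[VocalUnit], xmin: float, xmax: float) -> str:
    # Praat interval tiers are contiguous: emit empty filler intervals in gaps.
    intervals: list[tuple[float, float, str]] = []
    cursor = xmin
    for u in units:
        if u.start > cursor:
            intervals.append((cursor, u.start, ""))
        intervals.append((u.start, u.end, u.label))
        cursor = u.end
    if cursor < xmax:
        intervals.append((cursor, xmax, ""))
    if not intervals:
        intervals = [(xmin, xmax, "")]
    lines = [
        '        class = "IntervalTier"',
        f'        name = "{name}"',
        f"        xmin = {xmin:.6f}",
        f"        xmax = {xmax:.6f}",
        f"        intervals: size = {len(intervals)}",
    ]
    for i, (a, b, lab) in enumerate(intervals, 1):
        lines += [
            f"        intervals [{i}]:",
            f"            xmin = {a:.6f}",
            f"            xmax = {b:.6f}",
            f'            text = "{lab.replace(chr(34), chr(34) * 2)}"',
        ]
    return "\n".join(lines)


def write_textgrid(
    ann: AnnotationSet,
    path: str | Path,
    tier_names: Mapping[str, str] | None = None,
    xmax: float | None = None,
) -> Path:
    """Write a long-format Praat TextGrid; refuses invariant-violating input."""
    ann.validate()
    tier_names = dict(DEFAULT_TIER_NAMES, **(tier_names or {}))
    all_units = [u for us in ann.units.values() for u in us]
    tmax = xmax if xmax is not None else (max((u.end for u in all_units), default=1.0))
    parts = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        "xmin = 0.000000",
        f"xmax = {tmax:.6f}",
        "tiers? <exists>",
        f"size = {len(LEVELS)}",
        "item []:",
    ]
    # combination, call, segment ordering: coarse to fine, like hand annotation
    for i, level in enumerate(("combination", "call", "segment"), 1):
        parts.append(f"    item [{i}]:")
        parts.append(_format_tier(tier_names[level], ann.units[level], 0.0, tmax))
    out = Path(path)
    out.write_text("\n".join(parts) + "\n")
    return out


# ---------------------------------------------------------------------------
# WAV + metadata sidecar
# ---------------------------------------------------------------------------


def read_wav(path: str | Path) -> tuple[int, np.ndarray]:
    """Read a mono 16-bit PCM WAV; returns (sample_rate, float64 in [-1, 1])."""
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise FormatError(f"{path}: expected mono audio, got shape {data.shape}")
    if data.dtype == np.int16:
        data = data.astype(np.float64) / 32768.0
    else:
        data = data.astype(np.float64)
    return int(rate), data


def write_wav(path: str | Path, rate: int, signal: np.ndarray) -> Path:
    """Write float signal in [-1, 1] as 16-bit PCM mono WAV."""
    clipped = np.clip(np.asarray(signal, dtype=np.float64), -1.0, 1.0)
    wavfile.write(str(path), rate, (clipped * 32767.0).astype(np.int16))
    return Path(path)


METADATA_COLUMNS = ("recording_id", "individual_id", "group_id", "site", "sex")


def read_metadata_csv(path: str | Path) -> dict[str, RecordingMeta]:
    """Read the sidecar metadata CSV keyed by recording_id."""
    out: dict[str, RecordingMeta] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            meta = RecordingMeta(
                recording_id=row["recording_id"],
                individual_id=row["individual_id"],
                group_id=row["group_id"],
                site=row["site"],
                sex=row["sex"],
                sample_rate=int(row.get("sample_rate", 44100) or 44100),
                bit_depth=int(row.get("bit_depth", 16) or 16),
            )
            out[meta.recording_id] = meta
    return out


def write_metadata_csv(metas: Iterable[RecordingMeta], path: str | Path) -> Path:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(METADATA_COLUMNS + ("sample_rate", "bit_depth"))
        for m in metas:
            w.writerow(
                [m.recording_id, m.individual_id, m.group_id, m.site, m.sex,
                 m.sample_rate, m.bit_depth]
            )
    return Path(path)


# ---------------------------------------------------------------------------
# Relabeling, grouping, sequence derivation
# ---------------------------------------------------------------------------


def relabel_segments(
    ann: AnnotationSet,
    mapping: Mapping[str, str] | None = None,
    strict: bool = False,
) -> AnnotationSet:
    """Apply a segment-label mapping (default folds HL->LH and US->SH).

    Unmapped labels pass through unless ``strict``, in which case any label
    outside ``mapping`` raises :class:`LabelError`.
    """
    mapping = DEFAULT_RELABELING if mapping is None else dict(mapping)
    new_segments = []
    for u in ann.units["segment"]:
        if u.label in mapping:
            new_segments.append(replace(u, label=mapping[u.label]))
        elif strict:
            raise LabelError(f"unmapped segment label {u.label!r}")
        else:
            new_segments.append(u)
    units = dict(ann.units)
    units["segment"] = new_segments
    return AnnotationSet(meta=ann.meta, units=units)


def group_into_combinations(
    calls: Sequence[VocalUnit],
    threshold: float = 0.5,
    tolerance: float = 0.15,
) -> list[VocalUnit]:
    """Merge runs of calls separated by gaps <= threshold (+ tolerance).

    The base silence criterion is 0.5 s; the tolerance admits the small
    deviations above it observed in real data (gaps up to ~0.6 s still joined,
    while discrete calls and combinations sit > 1 s apart).  Runs of a single
    call yield no combination (a combination needs >= 2 calls).
    """
    calls = list(calls)
    for a, b in zip(calls, calls[1:]):
        if b.start < a.start:
            raise OrderingError("calls must be sorted by start time")
        if b.start < a.end - 1e-9:
            raise OrderingError(f"overlapping calls at {b.start:.4f}s")
    cutoff = threshold + tolerance
    combos: list[VocalUnit] = []
    run: list[VocalUnit] = []
    for c in calls:
        if run and (c.start - run[-1].end) > cutoff:
            if len(run) > 1:
                combos.append(
                    VocalUnit(run[0].start, run[-1].end, f"C{len(combos) + 1}",
                              "combination")
                )
            run = []
        run.append(c)
    if len(run) > 1:
        combos.append(
            VocalUnit(run[0].start, run[-1].end, f"C{len(combos) + 1}", "combination")
        )
    return combos


def derive_sequences(
    ann: AnnotationSet,
    level: str,
    call_labeler: Callable[[Sequence[str]], str] | None = None,
) -> list[list[str]]:
    """Derive ordered label sequences at one combinatorial level.

    ``level="segment"``: one sequence of segment labels per call.
    ``level="call"``: one sequence of call labels per combination, where each
    call is labeled by ``call_labeler`` applied to its segment labels
    (default: the three broad call groups via :func:`assign_call_group`).
    """
    if level == "segment":
        for seg in ann.units["segment"]:
            ann.call_of_segment(seg)  # raises HierarchyError on orphans
        return [
            [s.label for s in ann.segments_of(call)]
            for call in ann.units["call"]
            if ann.segments_of(call)
        ]
    if level == "call":
        labeler = call_labeler or assign_call_group
        seqs = []
        for comb in ann.units["combination"]:
            calls = ann.calls_of(comb)
            if not calls:
                raise HierarchyError(
                    f"combination at {comb.start:.4f}s contains no calls"
                )
            seqs.append(
                [labeler([s.label for s in ann.segments_of(c)]) for c in calls]
            )
        return seqs
    raise ValueError(f"level must be 'segment' or 'call', got {level!r}")


def gap_statistics(
    ann_list: Sequence[AnnotationSet], level: str
) -> GapStatistics:
    """Silent gaps between consecutive units of a level inside their parent.

    ``level="between-call"`` pools gaps between consecutive calls within each
    combination (not across discrete calls); ``level="between-segment"`` pools
    gaps between consecutive segments within each call.
    """
    if not ann_list:
        raise ValueError("need at least one annotated recording")
    gaps: list[float] = []
    if level == "between-call":
        parents, childof = "combination", AnnotationSet.calls_of
    elif level == "between-segment":
        parents, childof = "call", AnnotationSet.segments_of
    else:
        raise ValueError(f"unknown gap level {level!r}")
    found_parent = False
    for ann in ann_list:
        for parent in ann.units[parents]:
            found_parent = True
            kids = childof(ann, parent)
            gaps.extend(max(0.0, b.start - a.end) for a, b in zip(kids, kids[1:]))
    if not found_parent:
        raise HierarchyError(f"no parent units for {level} gap statistics")
    return GapStatistics.from_gaps(level, gaps)


def simplify_call_label(segment_labels: Sequence[str]) -> str:
    """Collapse consecutive duplicate segment labels and join with '-'.

    A call of three SH segments followed by an LH becomes ``"SH-LH"``;
    non-adjacent repeats are kept (``[DS, SH, DS]`` -> ``"DS-SH-DS"``).
    """
    labels = list(segment_labels)
    if not labels:
        raise ValueError("empty segment label sequence")
    out = [labels[0]]
    for lab in labels[1:]:
        if lab != out[-1]:
            out.append(lab)
    return "-".join(out)


def assign_call_group(segment_labels: Sequence[str]) -> str:
    """Assign one of the three broad call groups from a call's segment labels.

    (i) calls containing an LH segment anywhere; (ii) lone-NL calls (a single
    NL segment making up the whole call); (iii) everything else (lone DS/SH,
    or any mix of DS/SH/NL).  The partition is exhaustive and exclusive.
    """
    labels = list(segment_labels)
    if not labels:
        raise ValueError("empty segment label sequence")
    for lab in labels:
        if lab not in SEGMENT_CLASSES:
            raise LabelError(f"unknown segment label {lab!r}")
    if "LH" in labels:
        return "LH-containing"
    if labels == ["NL"]:
        return "lone-NL"
    return "other"


def assign_position_category(
    ann: AnnotationSet, segment_class: str
) -> list[tuple[VocalUnit, str]]:
    """Positional category for every instance of one segment class.

    LH contrasts segments that directly precede a DS within their call with
    segments that end the call or solely comprise it; NL contrasts lone
    segments (the call is just the NL) with segments combined with others.
    DS and SH get the generic next-label context (no within-class contrast was
    established for them).  Returns (unit, category) pairs in corpus order.
    """
    if segment_class not in SEGMENT_CLASSES:
        raise LabelError(f"unknown segment class {segment_class!r}")
    out: list[tuple[VocalUnit, str]] = []
    for call in ann.units["call"]:
        segs = ann.segments_of(call)
        for i, seg in enumerate(segs):
            if seg.label != segment_class:
                continue
            nxt = segs[i + 1].label if i + 1 < len(segs) else None
            if segment_class == "LH":
                if nxt == "DS":
                    cat = "precedes-DS"
                elif nxt is None:
                    cat = "call-final-or-lone"
                else:
                    cat = "other"
            elif segment_class == "NL":
                cat = "lone" if len(segs) == 1 else "combined"
            else:
                cat = "lone" if len(segs) == 1 else (
                    f"precedes-{nxt}" if nxt else "call-final"
                )
            out.append((seg, cat))
    return out
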