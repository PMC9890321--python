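"""Synthetic WAV + TextGrid corpora with known combinatorial ground truth.

The generator emulates the structure of a non-song combinatorial repertoire:
four acoustically distinct segment classes — DS (descending frequency
sweep), LH (long high tone), NL (band-limited noise), SH (short high tone) —
combined into calls of 1-7 segments by a configurable first-order chain, and
calls combined into combinations of 2-5 calls by a configurable chain over
the three broad call groups.  Inter-segment silences are <= 0.025 s,
inter-call silences within combinations <= 0.5 s, and inter-combination
silences > 1 s, so threshold-based segmentation recovers the ground truth
exactly.  Audio is rendered at 44.1 kHz / 16-bit mono; every corpus carries
a manifest from which all realized counts are recomputable.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

from vocalcomb.annotation_io import (
    AnnotationSet,
    RecordingMeta,
    VocalUnit,
    assign_call_group,
    write_metadata_csv,
    write_textgrid,
    write_wav,
)
from vocalcomb.errors import LabelError, SpecError
from vocalcomb.transitions import SequenceCorpus, TransitionMatrix, count_transitions

SEGMENT_ALPHABET = ("DS", "LH", "NL", "SH")
CALL_GROUP_ALPHABET = ("LH-containing", "lone-NL", "other")

#: Default within-call chain: the observed segment-to-segment transition
#: probabilities of the study system (LH only ever to DS; NL mostly to DS;
#: DS mostly to SH; SH to everything, rarely NL).
DEFAULT_SEGMENT_TRANSITION: dict[str, dict[str, float]] = {
    "DS": {"DS": 0.07, "LH": 0.18, "NL": 0.0, "SH": 0.75},
    "LH": {"DS": 1.0},
    "NL": {"DS": 0.8, "SH": 0.2},
    "SH": {"DS": 0.49, "LH": 0.23, "NL": 0.01, "SH": 0.27},
}

#: Default between-call chain over the three broad call groups.
DEFAULT_CALL_GROUP_TRANSITION: dict[str, dict[str, float]] = {
    "other": {"LH-containing": 0.65, "lone-NL": 0.01, "other": 0.34},
    "lone-NL": {"other": 1.0},
    "LH-containing": {"LH-containing": 0.33, "other": 0.67},
}

#: Sequence-initial distributions.  Both chains rarely transition *into* NL /
#: lone-NL, yet those classes are well represented in the corpus the chains
#: were estimated from — they must therefore occur predominantly
#: sequence-initially.  These defaults make the realized class composition
#: resemble that corpus (segment shares roughly DS 35%, LH 15%, NL 13%,
#: SH 32%).
DEFAULT_SEGMENT_INITIAL: dict[str, float] = {
    "DS": 0.35, "LH": 0.05, "NL": 0.25, "SH": 0.35,
}
DEFAULT_CALL_GROUP_INITIAL: dict[str, float] = {
    "LH-containing": 0.20, "lone-NL": 0.25, "other": 0.55,
}

#: Length distributions: decaying weights over the admissible ranges, giving
#: mean call length ~2.5 segments and mean combination length ~2.6 calls,
#: near the per-unit means of the reference corpus (1333/561 and 561/222).
DEFAULT_CALL_LENGTH_WEIGHTS = (0.35, 0.25, 0.16, 0.10, 0.07, 0.04, 0.03)
DEFAULT_COMBINATION_LENGTH_WEIGHTS = (0.6, 0.25, 0.1, 0.05)


@dataclass(frozen=True)
class ClassAcoustics:
    """Rendering parameters for one segment class."""

    kind: str  # "sweep" | "tone" | "noise"
    duration: float
    amplitude: float = 0.7
    freq: float = 0.0  # tone center (Hz)
    f_start: float = 0.0  # sweep start (Hz)
    f_end: float = 0.0  # sweep end (Hz)
    band: tuple[float, float] = (0.0, 0.0)  # noise band (Hz)
    duration_jitter: float = 0.1  # multiplicative, uniform +-
    freq_jitter: float = 0.03  # multiplicative, uniform +-


#: Invented class acoustics, well separated inside the 0.4-8 kHz analysis band.
DEFAULT_ACOUSTICS: dict[str, ClassAcoustics] = {
    "DS": ClassAcoustics(kind="sweep", f_start=6500.0, f_end=2000.0, duration=0.15),
    "LH": ClassAcoustics(kind="tone", freq=2800.0, duration=0.30),
    "NL": ClassAcoustics(kind="noise", band=(1000.0, 4000.0), duration=0.18,
                         amplitude=0.6),
    "SH": ClassAcoustics(kind="tone", freq=5200.0, duration=0.07),
}


def _probs_to_matrix(
    table: Mapping[str, Mapping[str, float]], alphabet: Sequence[str]
) -> np.ndarray:
    m = np.zeros((len(alphabet), len(alphabet)))
    idx = {a: i for i, a in enumerate(alphabet)}
    for src, row in table.items():
        for dst, p in row.items():
            m[idx[src], idx[dst]] = p
    sums = m.sum(axis=1)
    bad = [alphabet[i] for i in range(len(alphabet))
           if sums[i] > 0 and abs(sums[i] - 1) > 1e-9]
    if bad:
        raise SpecError(f"non-stochastic transition rows for {bad}")
    return m


def stationary_distribution(probs: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic chain (power iteration);
    states with no outgoing transitions are excluded from the support."""
    active = probs.sum(axis=1) > 0
    if not active.any():
        raise SpecError("chain has no transitions")
    p = probs[np.ix_(active, active)]
    p = p / p.sum(axis=1, keepdims=True)
    v = np.full(p.shape[0], 1.0 / p.shape[0])
    for _ in range(10_000):
        nv = v @ p
        if np.abs(nv - v).max() < 1e-12:
            v = nv
            break
        v = nv
    out = np.zeros(probs.shape[0])
    out[active] = v / v.sum()
    return out


@dataclass
class GeneratorSpec:
    """A stated world: the structural and acoustic parameters of a corpus."""

    segment_transition: dict[str, dict[str, float]] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_SEGMENT_TRANSITION)
    )
    call_group_transition: dict[str, dict[str, float]] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_CALL_GROUP_TRANSITION)
    )
    initial_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SEGMENT_INITIAL)
    )
    call_group_initial: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CALL_GROUP_INITIAL)
    )
    call_length_range: tuple[int, int] = (1, 7)
    combination_length_range: tuple[int, int] = (2, 5)
    call_length_weights: tuple[float, ...] = DEFAULT_CALL_LENGTH_WEIGHTS
    combination_length_weights: tuple[float, ...] = DEFAULT_COMBINATION_LENGTH_WEIGHTS
    gap_segment: float = 0.02
    gap_call: float = 0.3
    gap_combination: float = 1.5
    n_combinations: int = 222
    n_individuals: int = 8
    n_groups: int = 4
    sample_rate: int = 44100
    seed: int = 0
    acoustics: dict[str, ClassAcoustics] = field(
        default_factory=lambda: dict(DEFAULT_ACOUSTICS)
    )
    #: individual index -> relative sampling weight; used to emulate
    #: over-represented callers for testing the subsampling guard
    individual_weights: dict[int, float] | None = None
    #: when True, each call's segments are rejection-sampled to match its
    #: group drawn from the call-group chain; when False, calls are sampled
    #: straight from the segment chain (groups become emergent), so realized
    #: segment-transition frequencies are unbiased estimates of the chain
    condition_calls_on_group: bool = True

    def validate(self) -> None:
        if not (self.gap_segment < self.gap_call < self.gap_combination):
            raise SpecError("gaps must be ordered segment < call < combination")
        if self.gap_segment > 0.025:
            raise SpecError("inter-segment silence must be <= 0.025 s")
        if self.gap_call > 0.5:
            raise SpecError("within-combination inter-call silence must be <= 0.5 s")
        if self.gap_combination <= 1.0:
            raise SpecError("inter-combination silence must be > 1 s")
        lo, hi = self.call_length_range
        if not (1 <= lo <= hi <= 7):
            raise SpecError("call lengths must lie in [1, 7]")
        if len(self.call_length_weights) != hi - lo + 1:
            raise SpecError("call_length_weights must cover call_length_range")
        lo, hi = self.combination_length_range
        if not (2 <= lo <= hi <= 5):
            raise SpecError("combination lengths must lie in [2, 5]")
        if len(self.combination_length_weights) != hi - lo + 1:
            raise SpecError(
                "combination_length_weights must cover combination_length_range"
            )
        nyq = self.sample_rate / 2
        for lab, ac in self.acoustics.items():
            top = max(ac.freq, ac.f_start, ac.f_end, ac.band[1])
            if top >= nyq:
                raise SpecError(f"class {lab}: frequency {top} above Nyquist {nyq}")
        _probs_to_matrix(self.segment_transition, SEGMENT_ALPHABET)
        _probs_to_matrix(self.call_group_transition, CALL_GROUP_ALPHABET)


# ---------------------------------------------------------------------------
# Manifest (ground truth)
# ---------------------------------------------------------------------------


@dataclass
class SegmentGT:
    label: str
    start: float
    end: float
    overrides: dict = field(default_factory=dict)


@dataclass
class CallGT:
    group: str
    segments: list[SegmentGT]

    @property
    def start(self) -> float:
        return self.segments[0].start

    @property
    def end(self) -> float:
        return self.segments[-1].end

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.segments]


@dataclass
class ComboGT:
    calls: list[CallGT]

    @property
    def start(self) -> float:
        return self.calls[0].start

    @property
    def end(self) -> float:
        return self.calls[-1].end


@dataclass
class RecordingGT:
    meta: RecordingMeta
    combinations: list[ComboGT]


@dataclass
class CorpusManifest:
    """Self-consistent ground truth for a rendered corpus."""

    recordings: list[RecordingGT]
    gap_segment: float
    gap_call: float
    gap_combination: float
    seed: int

    @property
    def n_combinations(self) -> int:
        return sum(len(r.combinations) for r in self.recordings)

    @property
    def n_calls(self) -> int:
        return sum(len(c.calls) for r in self.recordings for c in r.combinations)

    @property
    def n_segments(self) -> int:
        return sum(
            len(call.segments)
            for r in self.recordings
            for c in r.combinations
            for call in c.calls
        )

    def segment_sequences(self) -> list[list[str]]:
        return [
            call.labels
            for r in self.recordings
            for c in r.combinations
            for call in c.calls
        ]

    def call_group_sequences(self) -> list[list[str]]:
        return [
            [call.group for call in c.calls]
            for r in self.recordings
            for c in r.combinations
        ]

    def realized_segment_counts(self) -> TransitionMatrix:
        return count_transitions(
            SequenceCorpus(self.segment_sequences(), SEGMENT_ALPHABET, "segment")
        )

    def realized_call_counts(self) -> TransitionMatrix:
        return count_transitions(
            SequenceCorpus(self.call_group_sequences(), CALL_GROUP_ALPHABET, "call")
        )

    def to_annotations(self) -> list[AnnotationSet]:
        """Ground-truth AnnotationSets (no file round trip)."""
        out = []
        for rec in self.recordings:
            units = {"segment": [], "call": [], "combination": []}
            for combo in rec.combinations:
                units["combination"].append(
                    VocalUnit(combo.start, combo.end, "combination", "combination")
                )
                for call in combo.calls:
                    units["call"].append(
                        VocalUnit(call.start, call.end, call.group, "call")
                    )
                    for seg in call.segments:
                        units["segment"].append(
                            VocalUnit(seg.start, seg.end, seg.label, "segment")
                        )
            out.append(AnnotationSet(meta=rec.meta, units=units))
        return out

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "gap_segment": self.gap_segment,
            "gap_call": self.gap_call,
            "gap_combination": self.gap_combination,
            "seed": self.seed,
            "recordings": [
                {
                    "meta": asdict(r.meta),
                    "combinations": [
                        {
                            "calls": [
                                {
                                    "group": call.group,
                                    "segments": [asdict(s) for s in call.segments],
                                }
                                for call in c.calls
                            ]
                        }
                        for c in r.combinations
                    ],
                }
                for r in self.recordings
            ],
        }
        p = Path(path)
        p.write_text(json.dumps(payload, indent=1))
        return p

    @classmethod
    def from_json(cls, path: str | Path) -> "CorpusManifest":
        payload = json.loads(Path(path).read_text())
        recs = []
        for r in payload["recordings"]:
            combos = [
                ComboGT(calls=[
                    CallGT(
                        group=call["group"],
                        segments=[SegmentGT(**s) for s in call["segments"]],
                    )
                    for call in c["calls"]
                ])
                for c in r["combinations"]
            ]
            recs.append(RecordingGT(meta=RecordingMeta(**r["meta"]), combinations=combos))
        return cls(
            recordings=recs,
            gap_segment=payload["gap_segment"],
            gap_call=payload["gap_call"],
            gap_combination=payload["gap_combination"],
            seed=payload["seed"],
        )


# ---------------------------------------------------------------------------
# Sequence sampling
# ---------------------------------------------------------------------------


def _sample_chain(
    probs: np.ndarray,
    initial: np.ndarray,
    length: int,
    alphabet: Sequence[str],
    rng: np.random.Generator,
) -> list[str]:
    states = [int(rng.choice(len(alphabet), p=initial))]
    for _ in range(length - 1):
        row = probs[states[-1]]
        if row.sum() == 0:
            raise SpecError(
                f"state {alphabet[states[-1]]!r} is absorbing with no outgoing "
                f"transitions; cannot reach length {length}"
            )
        states.append(int(rng.choice(len(alphabet), p=row)))
    return [alphabet[s] for s in states]


def _sample_call_segments(
    group: str,
    seg_probs: np.ndarray,
    seg_initial: np.ndarray,
    spec: GeneratorSpec,
    rng: np.random.Generator,
    max_tries: int = 2000,
) -> list[str]:
    """Segment labels for one call, conditioned on its broad group."""
    if group == "lone-NL":
        return ["NL"]
    lo, hi = spec.call_length_range
    lengths = np.arange(lo, hi + 1)
    w = np.asarray(spec.call_length_weights, dtype=float)
    w = w / w.sum()
    for _ in range(max_tries):
        length = int(rng.choice(lengths, p=w))
        labels = _sample_chain(seg_probs, seg_initial, length, SEGMENT_ALPHABET, rng)
        if assign_call_group(labels) == group:
            return labels
    raise SpecError(
        f"segment chain cannot produce a {group!r} call within {max_tries} tries"
    )


def _make_individuals(spec: GeneratorSpec) -> list[RecordingMeta]:
    metas = []
    for i in range(spec.n_individuals):
        g = i % spec.n_groups
        metas.append(RecordingMeta(
            recording_id=f"rec{i:02d}",
            individual_id=f"ind{i:02d}",
            group_id=f"grp{g:02d}",
            site="site A" if g < (spec.n_groups + 1) // 2 else "site B",
            sex="F" if i % 2 == 0 else "M",
            sample_rate=spec.sample_rate,
            bit_depth=16,
        ))
    return metas


def sample_sequences(spec: GeneratorSpec) -> CorpusManifest:
    """Draw a ground-truth corpus: call-group sequences per combination from
    the between-call chain, segment sequences per call from the within-call
    chain (conditioned on the call's group), with unit times laid out on the
    sample grid using the spec's fixed gap regime."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    seg_probs = _probs_to_matrix(spec.segment_transition, SEGMENT_ALPHABET)
    grp_probs = _probs_to_matrix(spec.call_group_transition, CALL_GROUP_ALPHABET)
    seg_initial = np.array(
        [spec.initial_distribution.get(a, 0.0) for a in SEGMENT_ALPHABET]
    )
    seg_initial = seg_initial / seg_initial.sum()
    grp_initial = np.array(
        [spec.call_group_initial.get(a, 0.0) for a in CALL_GROUP_ALPHABET]
    )
    grp_initial = grp_initial / grp_initial.sum()

    metas = _make_individuals(spec)
    weights = np.ones(spec.n_individuals)
    if spec.individual_weights:
        for i, w in spec.individual_weights.items():
            weights[i] = w
    weights = weights / weights.sum()

    sr = spec.sample_rate

    def q(x: float) -> float:  # quantize to the sample grid
        return round(x * sr) / sr

    per_individual: list[list[ComboGT]] = [[] for _ in metas]
    for _ in range(spec.n_combinations):
        owner = int(rng.choice(spec.n_individuals, p=weights))
        lo, hi = spec.combination_length_range
        cw = np.asarray(spec.combination_length_weights, dtype=float)
        n_calls = int(rng.choice(np.arange(lo, hi + 1), p=cw / cw.sum()))
        if spec.condition_calls_on_group:
            groups = _sample_chain(
                grp_probs, grp_initial, n_calls, CALL_GROUP_ALPHABET, rng
            )
        else:
            groups = [None] * n_calls
        calls = []
        for g in groups:
            if g is None:
                clo, chi = spec.call_length_range
                w = np.asarray(spec.call_length_weights, dtype=float)
                length = int(rng.choice(np.arange(clo, chi + 1), p=w / w.sum()))
                labels = _sample_chain(
                    seg_probs, seg_initial, length, SEGMENT_ALPHABET, rng
                )
                g = assign_call_group(labels)
            else:
                labels = _sample_call_segments(g, seg_probs, seg_initial, spec, rng)
            segs = []
            for lab in labels:
                ac = spec.acoustics[lab]
                dur = ac.duration * (
                    1 + ac.duration_jitter * float(rng.uniform(-1, 1))
                )
                fshift = 0.0
                base = ac.freq or ac.f_start or ac.band[1]
                if ac.freq_jitter:
                    fshift = base * ac.freq_jitter * float(rng.uniform(-1, 1))
                segs.append(SegmentGT(
                    label=lab, start=0.0, end=q(max(dur, 0.02)),
                    overrides={"freq_shift": fshift} if fshift else {},
                ))
            calls.append(CallGT(group=g, segments=segs))
        per_individual[owner].append(ComboGT(calls=calls))

    # lay out absolute times per recording (one recording per individual)
    recordings = []
    for meta, combos in zip(metas, per_individual):
        t = q(0.1)
        for combo in combos:
            for ci, call in enumerate(combo.calls):
                if ci > 0:
                    t = q(t + spec.gap_call)
                for si, seg in enumerate(call.segments):
                    if si > 0:
                        t = q(t + spec.gap_segment)
                    dur = seg.end  # stored as duration until now
                    seg.start = t
                    seg.end = q(t + dur)
                    t = seg.end
            t = q(t + spec.gap_combination)
        recordings.append(RecordingGT(meta=meta, combinations=combos))

    return CorpusManifest(
        recordings=recordings,
        gap_segment=spec.gap_segment,
        gap_call=spec.gap_call,
        gap_combination=spec.gap_combination,
        seed=spec.seed,
    )


# ---------------------------------------------------------------------------
# Audio rendering
# ---------------------------------------------------------------------------


def _ramp(n: int, sr: int, ms: float = 5.0) -> np.ndarray:
    k = min(int(sr * ms / 1000), n // 2)
    env = np.ones(n)
    if k > 0:
        ramp = 0.5 * (1 - np.cos(np.linspace(0, np.pi, k)))
        env[:k] = ramp
        env[-k:] = ramp[::-1]
    return env


def render_segment(
    label: str,
    ac: ClassAcoustics,
    n_samples: int,
    sample_rate: int,
    rng: np.random.Generator,
    overrides: Mapping | None = None,
) -> np.ndarray:
    """Synthesize one segment waveform (sweep, tone, or band-limited noise)."""
    ov = dict(overrides or {})
    fshift = float(ov.get("freq_shift", 0.0))
    amp = ac.amplitude * float(ov.get("amp_scale", 1.0))
    t = np.arange(n_samples) / sample_rate
    if ac.kind == "tone":
        x = np.sin(2 * np.pi * (ac.freq + fshift) * t)
    elif ac.kind == "sweep":
        f = np.linspace(ac.f_start + fshift, ac.f_end + fshift, n_samples)
        phase = 2 * np.pi * np.cumsum(f) / sample_rate
        x = np.sin(phase)
    elif ac.kind == "noise":
        lo, hi = ac.band[0] + fshift, ac.band[1] + fshift
        sos = sps.butter(4, [lo, hi], btype="bandpass", fs=sample_rate, output="sos")
        x = sps.sosfilt(sos, rng.standard_normal(n_samples))
        peak = np.abs(x).max()
        if peak > 0:
            x = x / peak
    else:
        raise LabelError(f"unknown acoustic kind {ac.kind!r} for class {label!r}")
    return amp * x * _ramp(n_samples, sample_rate)


def render_audio(
    manifest: CorpusManifest,
    spec: GeneratorSpec,
    outdir: str | Path,
) -> dict[str, Path]:
    """Render the corpus to WAV + TextGrid (+ metadata CSV and manifest JSON).

    Deterministic: identical (manifest, spec) produce byte-identical files.
    Returns {recording_id: wav_path} plus 'metadata' and 'manifest' entries.
    """
    spec.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed + 1)  # noise realizations only
    sr = spec.sample_rate
    paths: dict[str, Path] = {}
    for rec in manifest.recordings:
        segs = [
            s for c in rec.combinations for call in c.calls for s in call.segments
        ]
        total = (max((s.end for s in segs), default=0.5) + 0.1)
        x = np.zeros(int(round(total * sr)))
        for seg in segs:
            i0 = int(round(seg.start * sr))
            i1 = int(round(seg.end * sr))
            x[i0:i1] = render_segment(
                seg.label, spec.acoustics[seg.label], i1 - i0, sr, rng, seg.overrides
            )
        wav_path = outdir / f"{rec.meta.recording_id}.wav"
        write_wav(wav_path, sr, x)
        paths[rec.meta.recording_id] = wav_path
    for ann in manifest.to_annotations():
        write_textgrid(ann, outdir / f"{ann.meta.recording_id}.TextGrid")
    paths["metadata"] = write_metadata_csv(
        [r.meta for r in manifest.recordings], outdir / "metadata.csv"
    )
    paths["manifest"] = manifest.to_json(outdir / "manifest.json")
    return paths


def generate_corpus(spec: GeneratorSpec, outdir: str | Path) -> CorpusManifest:
    """Convenience: sample sequences and render the full corpus to disk."""
    manifest = sample_sequences(spec)
    render_audio(manifest, spec, outdir)
    return manifest


# ---------------------------------------------------------------------------
# Coarticulation injection
# ---------------------------------------------------------------------------


def position_category_of(call: CallGT, index: int) -> str:
    """Positional category of segment ``index`` within a ground-truth call,
    using the same rules as the annotation-side classifier."""
    seg = call.segments[index]
    nxt = call.segments[index + 1].label if index + 1 < len(call.segments) else None
    if seg.label == "LH":
        if nxt == "DS":
            return "precedes-DS"
        return "call-final-or-lone" if nxt is None else "other"
    if seg.label == "NL":
        return "lone" if len(call.segments) == 1 else "combined"
    if len(call.segments) == 1:
        return "lone"
    return f"precedes-{nxt}" if nxt else "call-final"


def inject_coarticulation(
    manifest: CorpusManifest,
    rule: Mapping[tuple[str, str], Mapping[str, float]],
) -> CorpusManifest:
    """Apply position-dependent acoustic shifts to matching segments.

    ``rule`` maps (segment class, position category) to parameter shifts:
    ``freq_shift`` (Hz, added) and/or ``amp_scale`` (multiplied).  Returns a
    deep-copied manifest; an empty rule returns an identical copy.
    """
    for (cls, _), shifts in rule.items():
        if cls not in SEGMENT_ALPHABET:
            raise LabelError(f"unknown segment class {cls!r} in rule")
        unknown = set(shifts) - {"freq_shift", "amp_scale"}
        if unknown:
            raise LabelError(f"unknown acoustic parameters {unknown}")
    out = copy.deepcopy(manifest)
    for rec in out.recordings:
        for combo in rec.combinations:
            for call in combo.calls:
                for i, seg in enumerate(call.segments):
                    cat = position_category_of(call, i)
                    shifts = rule.get((seg.label, cat))
                    if not shifts:
                        continue
                    if "freq_shift" in shifts:
                        seg.overrides["freq_shift"] = (
                            seg.overrides.get("freq_shift", 0.0)
                            + shifts["freq_shift"]
                        )
                    if "amp_scale" in shifts:
                        seg.overrides["amp_scale"] = (
                            seg.overrides.get("amp_scale", 1.0) * shifts["amp_scale"]
                        )
    return out
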