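"""Standardized spectrograms for latent-space projection.

Each annotated vocal unit is converted to a fixed-size 64x64 log-mel
spectrogram: band-pass filter (Butterworth, 0.4-8 kHz, zero-phase), magnitude
STFT, mel filterbank over the same band, logarithmic amplitude compression,
log-duration time rescaling (so a unit's displayed width is proportional to
the log of its duration relative to the longest unit in the dataset), and
right zero-padding to the uniform size that the projection requires.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from vocalcomb.annotation_io import (
    AnnotationSet,
    VocalUnit,
    assign_call_group,
    assign_position_category,
    read_wav,
    simplify_call_label,
)
from vocalcomb.errors import ConfigError, DegenerateUnitError

logger = logging.getLogger(__name__)

N_FEATURES = 64 * 64
FEATURE_COLUMNS = [f"f{i:04d}" for i in range(N_FEATURES)]


@dataclass(frozen=True)
class PreprocessConfig:
    """Spectrogram standardization parameters.

    The analysis band (0.4-8 kHz) covers the spectral content of the
    vocalizations; STFT window/hop and the amplitude floor are exposed
    because they are method choices, not measurements.
    """

    band_low: float = 400.0
    band_high: float = 8000.0
    filter_order: int = 5
    window_length: int = 512
    hop_length: int = 128
    n_mel: int = 64
    out_freq_bins: int = 64
    out_time_bins: int = 64
    log_floor: float = 1e-4
    #: anchor duration (s) for the log time-rescale; widths are proportional
    #: to log(duration / anchor) and the dataset's longest unit spans all
    #: out_time_bins columns
    duration_anchor: float = 1e-3

    def validate(self, sample_rate: int) -> None:
        nyquist = sample_rate / 2
        if not (0 < self.band_low < self.band_high < nyquist):
            raise ConfigError(
                f"need 0 < band_low < band_high < Nyquist ({nyquist} Hz); "
                f"got [{self.band_low}, {self.band_high}]"
            )
        if self.n_mel != self.out_freq_bins:
            raise ConfigError("n_mel must equal out_freq_bins")


def bandpass(signal: np.ndarray, sample_rate: int, cfg: PreprocessConfig) -> np.ndarray:
    """Zero-phase Butterworth band-pass; length preserved."""
    cfg.validate(sample_rate)
    sos = sps.butter(
        cfg.filter_order, [cfg.band_low, cfg.band_high],
        btype="bandpass", fs=sample_rate, output="sos",
    )
    return sps.sosfiltfilt(sos, np.asarray(signal, dtype=np.float64))


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(cfg: PreprocessConfig, sample_rate: int) -> np.ndarray:
    """Triangular mel filterbank (n_mel x n_fft_bins) over the analysis band."""
    n_fft = cfg.window_length
    fft_freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate)
    mel_pts = np.linspace(
        _hz_to_mel(cfg.band_low), _hz_to_mel(cfg.band_high), cfg.n_mel + 2
    )
    hz_pts = _mel_to_hz(mel_pts)
    fb = np.zeros((cfg.n_mel, fft_freqs.size))
    for i in range(cfg.n_mel):
        lo, ctr, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (fft_freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - ctr, 1e-12)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def mel_center_frequencies(cfg: PreprocessConfig) -> np.ndarray:
    """Center frequency (Hz) of each mel band."""
    mel_pts = np.linspace(
        _hz_to_mel(cfg.band_low), _hz_to_mel(cfg.band_high), cfg.n_mel + 2
    )
    return _mel_to_hz(mel_pts)[1:-1]


def time_support_width(
    duration: float, max_duration: float, cfg: PreprocessConfig
) -> float:
    """Continuous time-support width (columns) of a unit: proportional to
    log-duration, in [1, out_time_bins]; the dataset's longest unit fills
    all columns.  Kept continuous so spectrogram distance varies smoothly
    with duration (a rounded width would make two near-identical units
    differ by a whole zero-vs-signal column)."""
    if max_duration <= 0:
        raise ConfigError("max_duration must be positive")
    d0 = cfg.duration_anchor
    denom = np.log(max(max_duration, d0 * (1 + 1e-9)) / d0)
    frac = np.log(max(duration, d0) / d0) / denom
    return float(np.clip(frac * cfg.out_time_bins, 1.0, cfg.out_time_bins))


def time_support_bins(duration: float, max_duration: float, cfg: PreprocessConfig) -> int:
    """Number of (possibly partial) time columns a unit occupies."""
    return int(np.ceil(time_support_width(duration, max_duration, cfg) - 1e-9))


def _place_time_support(spec: np.ndarray, width: float, out_bins: int) -> np.ndarray:
    """Resample spectrogram columns onto a fractional support of ``width``
    target columns; the column straddling the support edge is scaled by its
    coverage so the representation is continuous in duration."""
    t = spec.shape[1]
    out = np.zeros((spec.shape[0], out_bins))
    n_cols = int(np.ceil(width - 1e-9))
    # source position for target column u: centre of u mapped into [0, t-1]
    for u in range(n_cols):
        coverage = min(1.0, width - u)
        pos = min((u + 0.5) / width * (t - 1), t - 1.0) if t > 1 else 0.0
        lo = int(np.floor(pos))
        hi = min(lo + 1, t - 1)
        fr = pos - lo
        out[:, u] = (spec[:, lo] * (1 - fr) + spec[:, hi] * fr) * coverage
    return out


@dataclass
class SpectrogramMatrix:
    """64x64 standardized log-mel spectrogram of one vocal unit."""

    values: np.ndarray
    unit_ref: str
    duration: float

    def __post_init__(self) -> None:
        if self.values.shape != (64, 64):
            raise ValueError(f"expected 64x64, got {self.values.shape}")


def unit_spectrogram(
    signal: np.ndarray,
    sample_rate: int,
    unit: VocalUnit,
    cfg: PreprocessConfig,
    max_duration: float | None = None,
    unit_ref: str = "",
    prefiltered: bool = False,
) -> SpectrogramMatrix:
    """Standardized spectrogram of one unit cut from a recording.

    ``max_duration`` anchors the log time-rescale (defaults to the unit's own
    duration, which then fills all 64 columns).  Raises
    :class:`DegenerateUnitError` for units shorter than one analysis window.
    """
    cfg.validate(sample_rate)
    i0 = int(round(unit.start * sample_rate))
    i1 = int(round(unit.end * sample_rate))
    if i0 < 0 or i1 > signal.size:
        raise ValueError(
            f"unit [{unit.start}, {unit.end}]s outside signal of "
            f"{signal.size / sample_rate:.3f}s"
        )
    clip = signal[i0:i1]
    if clip.size < cfg.window_length:
        raise DegenerateUnitError(
            f"unit of {clip.size} samples shorter than window "
            f"({cfg.window_length})"
        )
    if not prefiltered:
        clip = bandpass(clip, sample_rate, cfg)
    _, _, z = sps.stft(
        clip, fs=sample_rate, window="hann", nperseg=cfg.window_length,
        noverlap=cfg.window_length - cfg.hop_length, boundary=None, padded=False,
    )
    mag = np.abs(z)
    mel = mel_filterbank(cfg, sample_rate) @ mag
    logmel = np.log1p(mel / cfg.log_floor)
    dur = unit.duration
    width = time_support_width(dur, max_duration if max_duration else dur, cfg)
    out = _place_time_support(logmel, width, cfg.out_time_bins)
    return SpectrogramMatrix(values=out, unit_ref=unit_ref, duration=dur)


def _resolve_audio(
    audio: Mapping[str, tuple[int, np.ndarray]] | str | Path,
    recording_id: str,
) -> tuple[int, np.ndarray]:
    if isinstance(audio, (str, Path)):
        path = Path(audio) / f"{recording_id}.wav"
        if not path.exists():
            raise FileNotFoundError(f"no audio for recording {recording_id!r}: {path}")
        return read_wav(path)
    if recording_id not in audio:
        raise FileNotFoundError(f"no audio for recording {recording_id!r}")
    return audio[recording_id]


def build_dataset(
    ann_list: Sequence[AnnotationSet],
    audio: Mapping[str, tuple[int, np.ndarray]] | str | Path,
    level: str,
    cfg: PreprocessConfig | None = None,
) -> pd.DataFrame:
    """Flattened 4096-feature spectrogram table for one combinatorial level.

    One row per unit (degenerate units logged and skipped), joined with all
    predictor labels: hand label, individual, group, site, sex, and the
    level-appropriate derived labels (position category for segments; call
    group and simplified label for calls).
    """
    cfg = cfg or PreprocessConfig()
    if level not in ("segment", "call"):
        raise ValueError("level must be 'segment' or 'call'")
    if not ann_list:
        logger.warning("build_dataset called with an empty corpus")
        return pd.DataFrame(columns=FEATURE_COLUMNS + ["unit_ref", "label"])

    max_dur = max(
        (u.duration for ann in ann_list for u in ann.units[level]), default=0.0
    )
    rows, meta_rows = [], []
    for ann in ann_list:
        units = ann.units[level]
        if not units:
            continue
        rate, wav = _resolve_audio(audio, ann.meta.recording_id)
        filtered = bandpass(wav, rate, cfg)
        poscat: dict[tuple[float, float], str] = {}
        if level == "segment":
            for cls in ("DS", "LH", "NL", "SH"):
                for seg, cat in assign_position_category(ann, cls):
                    poscat[(seg.start, seg.end)] = cat
        for k, unit in enumerate(units):
            ref = f"{ann.meta.recording_id}:{level}:{k}"
            try:
                spec = unit_spectrogram(
                    filtered, rate, unit, cfg, max_duration=max_dur,
                    unit_ref=ref, prefiltered=True,
                )
            except DegenerateUnitError as exc:
                logger.warning("skipping %s: %s", ref, exc)
                continue
            rows.append(spec.values.ravel())
            if level == "segment":
                label = unit.label
                extra = {"position_category": poscat.get((unit.start, unit.end), "")}
            else:
                seg_labels = [s.label for s in ann.segments_of(unit)]
                label = simplify_call_label(seg_labels)
                extra = {"call_group": assign_call_group(seg_labels)}
            meta_rows.append({
                "unit_ref": ref,
                "recording_id": ann.meta.recording_id,
                "label": label,
                "individual": ann.meta.individual_id,
                "group": ann.meta.group_id,
                "site": ann.meta.site,
                "sex": ann.meta.sex,
                "start": unit.start,
                "end": unit.end,
                "duration": unit.duration,
                **extra,
            })
    if not rows:
        logger.warning("no usable units at level %r", level)
        return pd.DataFrame(columns=FEATURE_COLUMNS + ["unit_ref", "label"])
    feats = pd.DataFrame(
        np.asarray(rows, dtype=np.float32), columns=FEATURE_COLUMNS
    )
    meta = pd.DataFrame(meta_rows)
    return pd.concat([feats, meta], axis=1)


def feature_matrix(df: pd.DataFrame) -> np.ndarray:
    """Extract the 4096-column feature block from a spectrogram table."""
    return df[FEATURE_COLUMNS].to_numpy(dtype=np.float64)
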