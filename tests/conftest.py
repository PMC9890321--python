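"""Shared fixtures: hand-built annotation sets and rendered synthetic corpora.

The rendered corpora are session-scoped because audio synthesis plus
spectrogram extraction is the expensive part of the suite; every test that
needs a realistic corpus shares these.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pytest

from vocalcomb.annotation_io import AnnotationSet, RecordingMeta, VocalUnit
from vocalcomb.pipeline import load_corpus
from vocalcomb.synthetic_data import GeneratorSpec, render_audio, sample_sequences

warnings.filterwarnings("ignore", message=".*n_jobs.*random_state.*")
warnings.filterwarnings("ignore", message=".*force_all_finite.*")


@pytest.fixture()
def meta() -> RecordingMeta:
    return RecordingMeta(
        recording_id="recA", individual_id="ind1", group_id="g1",
        site="site A", sex="F",
    )


@pytest.fixture()
def tiny_annotation(meta) -> AnnotationSet:
    """One combination of two calls: [NL, DS] then [LH, DS]."""
    seg = [
        VocalUnit(0.10, 0.25, "NL", "segment"),
        VocalUnit(0.27, 0.40, "DS", "segment"),
        VocalUnit(0.70, 0.95, "LH", "segment"),
        VocalUnit(0.97, 1.10, "DS", "segment"),
    ]
    call = [
        VocalUnit(0.10, 0.40, "c1", "call"),
        VocalUnit(0.70, 1.10, "c2", "call"),
    ]
    comb = [VocalUnit(0.10, 1.10, "C1", "combination")]
    ann = AnnotationSet(
        meta=meta, units={"segment": seg, "call": call, "combination": comb}
    )
    ann.validate()
    return ann


@pytest.fixture(scope="session")
def small_spec() -> GeneratorSpec:
    return GeneratorSpec(seed=11, n_combinations=30)


@pytest.fixture(scope="session")
def small_corpus(small_spec, tmp_path_factory):
    """(manifest, corpus directory, parsed annotations) for a 30-combination
    rendered corpus — shared across the suite."""
    outdir = tmp_path_factory.mktemp("corpus_small")
    manifest = sample_sequences(small_spec)
    render_audio(manifest, small_spec, outdir)
    anns = load_corpus(outdir)
    return manifest, Path(outdir), anns


@pytest.fixture(scope="session")
def segment_table(small_corpus, small_spec):
    from vocalcomb.preprocess import PreprocessConfig, build_dataset

    _, outdir, anns = small_corpus
    return build_dataset(anns, outdir, "segment", PreprocessConfig())


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
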