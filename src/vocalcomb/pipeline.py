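"""Full-pipeline orchestration: ingest -> subsample -> preprocess ->
project/evaluate -> transition tests, from a single config, with a results
bundle whose every number is traceable to a stage and a seed."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from vocalcomb import annotation_io as aio
from vocalcomb.annotation_io import AnnotationSet, read_metadata_csv, read_textgrid
from vocalcomb.embedding_eval import (
    balanced_subsample,
    evaluate_predictors,
    per_individual_counts,
    permuted_label_test,
    project,
)
from vocalcomb.errors import VocalcombError
from vocalcomb.preprocess import PreprocessConfig, build_dataset
from vocalcomb.transitions import (
    SequenceCorpus,
    export_transition_graph,
    permutation_test,
)

logger = logging.getLogger(__name__)

DEFAULT_PREDICTORS = ("label", "individual", "group", "site", "sex")


@dataclass
class PipelineConfig:
    """Everything a full run needs; serializable to/from YAML."""

    data_dir: str
    output_dir: str
    combination_threshold: float = 0.5
    combination_tolerance: float = 0.15
    individual_cap: int | None = None
    per_individual_caps: dict[str, int] = field(default_factory=dict)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    umap_seed: int = 0
    umap_params: dict = field(default_factory=dict)
    n_perm: int = 1
    n_iter: int = 10_000
    alpha: float = 0.05
    subsample_seed: int = 0
    balanced: bool = False
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS
    min_within_class_rows: int = 30
    render_graphs: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "preprocess" in raw:
            raw["preprocess"] = PreprocessConfig(**raw["preprocess"])
        if "predictors" in raw:
            raw["predictors"] = tuple(raw["predictors"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def load_corpus(data_dir: str | Path) -> list[AnnotationSet]:
    """Read metadata.csv plus one TextGrid per recording from a directory."""
    data_dir = Path(data_dir)
    meta_path = data_dir / "metadata.csv"
    if not meta_path.exists():
        raise VocalcombError(f"ingest: no metadata.csv in {data_dir}")
    metas = read_metadata_csv(meta_path)
    anns = []
    for rid, meta in sorted(metas.items()):
        tg = data_dir / f"{rid}.TextGrid"
        if not tg.exists():
            raise VocalcombError(f"ingest: missing TextGrid for {rid}: {tg}")
        anns.append(read_textgrid(tg, meta))
    return anns


def cap_overrepresented(
    ann_list: Sequence[AnnotationSet],
    cap: int | dict[str, int],
    seed: int = 0,
) -> list[AnnotationSet]:
    """Randomly downsample combinations of over-represented individuals.

    ``cap`` is either one ceiling for everyone or a per-individual mapping.
    Dropping a combination also drops its calls and segments.  Selection is
    seeded and individuals at or below their cap are untouched.
    """
    if isinstance(cap, int) and cap < 1:
        raise ValueError("cap must be >= 1")
    rng = np.random.default_rng(seed)
    by_ind: dict[str, list[tuple[int, int]]] = {}
    for ai, ann in enumerate(ann_list):
        for ci, _ in enumerate(ann.units["combination"]):
            by_ind.setdefault(ann.meta.individual_id, []).append((ai, ci))
    drop: set[tuple[int, int]] = set()
    for ind, combos in sorted(by_ind.items()):
        ind_cap = cap.get(ind) if isinstance(cap, dict) else cap
        if ind_cap is None or len(combos) <= ind_cap:
            continue
        keep_idx = rng.choice(len(combos), size=ind_cap, replace=False)
        keep = {combos[i] for i in keep_idx}
        drop.update(set(combos) - keep)
    out = []
    for ai, ann in enumerate(ann_list):
        combos = [
            c for ci, c in enumerate(ann.units["combination"])
            if (ai, ci) not in drop
        ]
        tol = aio.CONTAINMENT_TOL
        calls = [
            u for u in ann.units["call"]
            if any(c.start - tol <= u.start and u.end <= c.end + tol for c in combos)
        ]
        segs = [
            u for u in ann.units["segment"]
            if any(c.start - tol <= u.start and u.end <= c.end + tol for c in calls)
        ]
        out.append(AnnotationSet(
            meta=ann.meta,
            units={"segment": segs, "call": calls, "combination": combos},
        ))
    return out


def _within_class_evaluations(
    seg_df: pd.DataFrame, cfg: PipelineConfig
) -> pd.DataFrame:
    """Per segment class, project the class's spectrograms alone and ask how
    well the position category explains the layout."""
    rows = []
    for cls in ("LH", "NL", "DS", "SH"):
        sub = seg_df[seg_df["label"] == cls]
        cats = sub["position_category"]
        counts = cats.value_counts()
        if len(sub) < cfg.min_within_class_rows or (counts >= 2).sum() < 2:
            continue
        usable = sub[cats.isin(counts[counts >= 2].index)]
        try:
            emb = project(usable, seed=cfg.umap_seed, params=cfg.umap_params)
            res = permuted_label_test(
                emb, usable["position_category"].to_numpy(),
                n_perm=cfg.n_perm, seed=cfg.umap_seed, predictor="position_category",
            )
        except VocalcombError as exc:
            logger.warning("within-class %s skipped: %s", cls, exc)
            continue
        rows.append({
            "segment_class": cls, "predictor": "position_category",
            "S": res.S, "H": res.H, "df": res.df, "p": res.p, "n": res.n,
        })
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write the results bundle to cfg.output_dir.

    Bundle: gap statistics, segment- and call-level cluster evaluations,
    within-class position-category evaluations, segment and call-group
    transition tests, and a manifest of every seed and parameter used.
    Stage failures abort with a stage-named diagnostic.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": cfg.to_dict()}

    def stage(name):
        logger.info("stage: %s", name)
        return name

    try:
        stage("ingest")
        anns = load_corpus(cfg.data_dir)
        anns = [aio.relabel_segments(a) for a in anns]
    except (OSError, VocalcombError) as exc:
        raise VocalcombError(f"ingest: {exc}") from exc

    if cfg.individual_cap or cfg.per_individual_caps:
        stage("subsample")
        cap = cfg.per_individual_caps or cfg.individual_cap
        anns = cap_overrepresented(anns, cap, seed=cfg.subsample_seed)

    stage("gaps")
    gap_report = {}
    for lv in ("between-call", "between-segment"):
        gs = aio.gap_statistics(anns, lv)
        gap_report[lv] = {
            "n": len(gs.gaps), "mean": gs.mean, "sd": gs.sd, "max": gs.max,
        }
    (out / "gap_statistics.json").write_text(json.dumps(gap_report, indent=1))
    bundle["gaps"] = gap_report

    stage("preprocess")
    seg_df = build_dataset(anns, cfg.data_dir, "segment", cfg.preprocess)
    call_df = build_dataset(anns, cfg.data_dir, "call", cfg.preprocess)
    if cfg.balanced:
        seg_df = balanced_subsample(seg_df, "label", seed=cfg.subsample_seed)

    stage("embed/evaluate")
    for name, df, extra in (
        ("segment", seg_df, []),
        ("call", call_df, ["call_group"]),
    ):
        if len(df) < 10:
            logger.warning("too few %s rows (%d); skipping evaluation", name, len(df))
            continue
        emb = project(df, seed=cfg.umap_seed, params=cfg.umap_params)
        emb.to_frame().to_csv(out / f"{name}_coords.csv", index=False)
        preds = [p for p in (*cfg.predictors, *extra) if p in df.columns]
        table = evaluate_predictors(
            emb, df, preds, n_perm=cfg.n_perm, seed=cfg.umap_seed
        )
        table.to_csv(out / f"{name}_evaluation.csv", index=False)
        per_individual_counts(df).to_csv(out / f"{name}_individual_counts.csv")
        bundle[f"{name}_evaluation"] = table

    stage("within-class")
    within = _within_class_evaluations(seg_df, cfg)
    within.to_csv(out / "within_class_evaluation.csv", index=False)
    bundle["within_class_evaluation"] = within

    stage("transitions")
    seg_seqs = [s for ann in anns for s in aio.derive_sequences(ann, "segment")]
    call_seqs = [s for ann in anns for s in aio.derive_sequences(ann, "call")]
    for name, seqs in (("segment", seg_seqs), ("call_group", call_seqs)):
        if not any(len(s) > 1 for s in seqs):
            logger.warning("no multi-unit sequences at level %s", name)
            continue
        corpus = SequenceCorpus(seqs, level=name)
        result = permutation_test(
            corpus, n_iter=cfg.n_iter, alpha=cfg.alpha, seed=cfg.umap_seed
        )
        export_transition_graph(
            result, out / f"transitions_{name}.csv",
            image_path=(out / f"transitions_{name}.png") if cfg.render_graphs else None,
        )
        bundle[f"transitions_{name}"] = result

    stage("manifest")
    manifest = {
        "seeds": {
            "umap": cfg.umap_seed,
            "subsample": cfg.subsample_seed,
            "permutation": cfg.umap_seed,
        },
        "n_iter": cfg.n_iter,
        "n_perm": cfg.n_perm,
        "counts": {
            "recordings": len(anns),
            "segments": sum(len(a.units["segment"]) for a in anns),
            "calls": sum(len(a.units["call"]) for a in anns),
            "combinations": sum(len(a.units["combination"]) for a in anns),
        },
        "config": cfg.to_dict(),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    bundle["manifest"] = manifest
    return bundle
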