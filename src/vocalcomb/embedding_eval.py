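"""Latent-space projection and predictor-wise cluster evaluation.

Spectrogram tables are projected to 2-D with UMAP (each time-frequency bin an
independent dimension; min_dist = 0 as recommended for cluster evaluation).
How well a categorical predictor — hand label, caller identity, group, site,
sex, position category — explains the layout is quantified by the mean
silhouette coefficient S over the projection, and its departure from chance
by a Kruskal-Wallis rank test comparing the per-point silhouette
coefficients under the true labels against those under randomly permuted
labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import silhouette_samples

from vocalcomb.errors import ParameterError
from vocalcomb.preprocess import FEATURE_COLUMNS, feature_matrix

DEFAULT_UMAP_PARAMS: dict = {"n_neighbors": 15, "min_dist": 0.0, "metric": "euclidean"}


@dataclass
class EmbeddingResult:
    """A 2-D embedding of a spectrogram table."""

    coords: np.ndarray
    unit_refs: list[str]
    seed: int
    params: dict

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(f"coords must be n x 2, got {self.coords.shape}")
        if len(self.unit_refs) != len(self.coords):
            raise ValueError("one unit_ref per coordinate row required")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"unit_ref": self.unit_refs, "x": self.coords[:, 0], "y": self.coords[:, 1]}
        )


@dataclass
class ClusterEvalResult:
    """Silhouette score and permuted-label rank test for one predictor."""

    predictor: str
    S: float
    per_point_silhouette: np.ndarray
    H: float = np.nan
    df: int = 0
    p: float = np.nan
    n: int = 0

    def __post_init__(self) -> None:
        self.per_point_silhouette = np.asarray(self.per_point_silhouette, float)
        if not -1.0 - 1e-9 <= self.S <= 1.0 + 1e-9:
            raise ValueError(f"S out of [-1, 1]: {self.S}")


def project(
    data: pd.DataFrame | np.ndarray,
    seed: int = 0,
    params: Mapping | None = None,
) -> EmbeddingResult:
    """Project a spectrogram table into 2-D latent space with UMAP.

    Deterministic for a given (data, seed, params): the seed is passed as
    UMAP's random_state, which forces single-threaded, reproducible layout
    optimization.
    """
    import umap  # deferred: numba compilation is slow at import time

    merged = dict(DEFAULT_UMAP_PARAMS, **(params or {}))
    if isinstance(data, pd.DataFrame):
        x = feature_matrix(data)
        refs = list(data["unit_ref"]) if "unit_ref" in data else [
            str(i) for i in range(len(data))
        ]
    else:
        x = np.asarray(data, dtype=np.float64)
        refs = [str(i) for i in range(len(x))]
    if x.shape[0] < 10:
        raise ParameterError(f"need >= 10 rows to project, got {x.shape[0]}")
    if np.isnan(x).any():
        raise ParameterError("missing values in feature matrix")
    if x.shape[0] <= merged["n_neighbors"]:
        raise ParameterError(
            f"n_neighbors ({merged['n_neighbors']}) must be < n rows ({x.shape[0]})"
        )
    reducer = umap.UMAP(n_components=2, random_state=seed, **merged)
    coords = reducer.fit_transform(x)
    return EmbeddingResult(coords=coords, unit_refs=refs, seed=seed, params=merged)


def _check_labels(labels: np.ndarray) -> None:
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ParameterError(
            "silhouette undefined for a single class; need >= 2 classes"
        )
    if (counts < 2).any():
        small = classes[counts < 2]
        raise ParameterError(f"classes with < 2 members: {list(small)}")


def silhouette_by_predictor(
    emb: EmbeddingResult, labels: Sequence, predictor: str = ""
) -> ClusterEvalResult:
    """Mean silhouette coefficient of a labeling on the 2-D coordinates."""
    labels = np.asarray(labels)
    if len(labels) != len(emb.coords):
        raise ParameterError("one label per embedded point required")
    _check_labels(labels)
    per_point = silhouette_samples(emb.coords, labels)
    return ClusterEvalResult(
        predictor=predictor,
        S=float(per_point.mean()),
        per_point_silhouette=per_point,
        n=len(labels),
    )


def permuted_label_test(
    emb: EmbeddingResult,
    labels: Sequence,
    n_perm: int = 1,
    seed: int = 0,
    predictor: str = "",
) -> ClusterEvalResult:
    """Compare true-label silhouettes against permuted-label silhouettes.

    Per-point silhouette coefficients under the true labels form one group;
    each of ``n_perm`` random label permutations contributes another.  The
    Kruskal-Wallis H statistic over the groups tests whether the true-label
    distribution differs from a chance layout.  df = (number of groups) - 1.
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    true_res = silhouette_by_predictor(emb, labels, predictor=predictor)
    labels = np.asarray(labels)
    groups = [true_res.per_point_silhouette]
    for _ in range(n_perm):
        permuted = labels[rng.permutation(len(labels))]
        groups.append(silhouette_samples(emb.coords, permuted))
    try:
        h, p = stats.kruskal(*groups)
    except ValueError:  # all values identical across groups
        h, p = 0.0, 1.0
    return ClusterEvalResult(
        predictor=predictor,
        S=true_res.S,
        per_point_silhouette=true_res.per_point_silhouette,
        H=float(h),
        df=len(groups) - 1,
        p=float(p),
        n=len(labels),
    )


def balanced_subsample(
    data: pd.DataFrame, class_column: str, seed: int = 0
) -> pd.DataFrame:
    """Downsample every class (without replacement) to the smallest class
    count; deterministic for a given seed."""
    counts = data[class_column].value_counts()
    if counts.empty:
        raise ParameterError("empty table")
    n_min = int(counts.min())
    rng = np.random.default_rng(seed)
    keep = []
    for cls, sub in data.groupby(class_column, sort=True):
        idx = np.asarray(sub.index)
        keep.append(rng.choice(idx, size=n_min, replace=False))
    return data.loc[np.concatenate(keep)]


def evaluate_predictors(
    emb: EmbeddingResult,
    data: pd.DataFrame,
    predictors: Sequence[str],
    n_perm: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Evaluation table (predictor, S, H, df, p, n) for several predictors on
    one shared projection; predictors whose labeling is degenerate (single
    class or singleton classes) are reported with NaN scores."""
    rows = []
    for k, pred in enumerate(predictors):
        labels = data[pred].to_numpy()
        try:
            res = permuted_label_test(
                emb, labels, n_perm=n_perm, seed=seed + k, predictor=pred
            )
            rows.append({
                "predictor": pred, "S": res.S, "H": res.H, "df": res.df,
                "p": res.p, "n": res.n,
            })
        except ParameterError:
            rows.append({
                "predictor": pred, "S": np.nan, "H": np.nan, "df": 0,
                "p": np.nan, "n": len(labels),
            })
    table = pd.DataFrame(rows)
    return table


def per_individual_counts(data: pd.DataFrame) -> pd.Series:
    """Row count per individual — the over-representation guard that every
    evaluation report should carry."""
    return data["individual"].value_counts()
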