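"""First-order transition analysis with frequency-preserving randomization.

Sequences of labeled vocal units (segments within calls, or calls within
combinations) are summarized by a forward transition probability matrix
``P(j | i)`` estimated from adjacent ordered pairs within sequences.  The
null model randomizes the assignment of units to sequences while preserving
both each label's total frequency and the multiset of sequence lengths, so
any sequential structure — but nothing else — is destroyed.  Per-cell
significance is the two-tailed rank of the observed probability among the
randomized draws.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from vocalcomb.errors import LabelError, ParameterError, VocalcombError


@dataclass
class SequenceCorpus:
    """A list of label sequences over a fixed alphabet at one level."""

    sequences: list[list[str]]
    alphabet: tuple[str, ...] = ()
    level: str = "segment"

    def __post_init__(self) -> None:
        self.sequences = [list(s) for s in self.sequences]
        if any(len(s) == 0 for s in self.sequences):
            raise ValueError("sequences must be non-empty")
        if not self.alphabet:
            self.alphabet = tuple(
                sorted({tok for seq in self.sequences for tok in seq})
            )
        idx = {a: i for i, a in enumerate(self.alphabet)}
        for seq in self.sequences:
            for tok in seq:
                if tok not in idx:
                    raise LabelError(f"token {tok!r} outside alphabet {self.alphabet}")

    @property
    def n_tokens(self) -> int:
        return sum(len(s) for s in self.sequences)

    def encoded(self) -> tuple[np.ndarray, np.ndarray]:
        """(flat int-coded token array, sequence lengths)."""
        idx = {a: i for i, a in enumerate(self.alphabet)}
        flat = np.fromiter(
            (idx[t] for seq in self.sequences for t in seq), dtype=np.int64,
            count=self.n_tokens,
        )
        lengths = np.fromiter((len(s) for s in self.sequences), dtype=np.int64,
                              count=len(self.sequences))
        return flat, lengths


@dataclass
class TransitionMatrix:
    """Forward transition counts and row-normalized probabilities."""

    counts: np.ndarray
    probs: np.ndarray
    alphabet: tuple[str, ...]

    @classmethod
    def from_counts(cls, counts: np.ndarray, alphabet: Sequence[str]) -> "TransitionMatrix":
        counts = np.asarray(counts, dtype=np.int64)
        return cls(counts=counts, probs=_row_normalize(counts),
                   alphabet=tuple(alphabet))

    def prob(self, src: str, dst: str) -> float:
        i, j = self.alphabet.index(src), self.alphabet.index(dst)
        return float(self.probs[i, j])


def _row_normalize(counts: np.ndarray) -> np.ndarray:
    sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(sums > 0, counts / np.where(sums > 0, sums, 1), 0.0)
    return probs


def _pair_indices(lengths: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flat indices of (preceding, following) positions of within-sequence pairs."""
    prev, nxt = [], []
    offset = 0
    for ln in lengths:
        if ln > 1:
            idx = np.arange(offset, offset + ln)
            prev.append(idx[:-1])
            nxt.append(idx[1:])
        offset += ln
    if not prev:
        z = np.empty(0, dtype=np.int64)
        return z, z
    return np.concatenate(prev), np.concatenate(nxt)


def _count_from_flat(flat: np.ndarray, prev: np.ndarray, nxt: np.ndarray,
                     n_states: int) -> np.ndarray:
    counts = np.zeros((n_states, n_states), dtype=np.int64)
    np.add.at(counts, (flat[prev], flat[nxt]), 1)
    return counts


def count_transitions(corpus: SequenceCorpus) -> TransitionMatrix:
    """Count adjacent ordered pairs within each sequence (no cross-sequence
    pairs, no start/end tokens) and row-normalize."""
    flat, lengths = corpus.encoded()
    prev, nxt = _pair_indices(lengths)
    counts = _count_from_flat(flat, prev, nxt, len(corpus.alphabet))
    return TransitionMatrix.from_counts(counts, corpus.alphabet)


def randomize_corpus(
    corpus: SequenceCorpus, seed: int | np.random.Generator = 0
) -> SequenceCorpus:
    """One frequency-preserving randomized draw.

    Tokens are reassigned to sequence slots by a uniform permutation, so the
    token multiset and the sequence-length multiset are both exactly
    preserved.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flat, lengths = corpus.encoded()
    shuffled = flat[rng.permutation(flat.size)]
    seqs, offset = [], 0
    for ln in lengths:
        seqs.append([corpus.alphabet[k] for k in shuffled[offset:offset + ln]])
        offset += ln
    return SequenceCorpus(sequences=seqs, alphabet=corpus.alphabet,
                          level=corpus.level)


@dataclass
class TransitionTestResult:
    """Observed transition matrix with per-cell Monte-Carlo significance."""

    observed: TransitionMatrix
    null_samples: np.ndarray  # (|A|, |A|, n_iter) null transition probabilities
    p_two_tailed: np.ndarray  # NaN where the cell is undefined in all draws
    significant: np.ndarray
    n_iter: int
    seed: int
    alpha: float = 0.05
    alphabet: tuple[str, ...] = field(default_factory=tuple)

    def p(self, src: str, dst: str) -> float:
        i, j = self.alphabet.index(src), self.alphabet.index(dst)
        return float(self.p_two_tailed[i, j])


def permutation_test(
    corpus: SequenceCorpus,
    n_iter: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> TransitionTestResult:
    """Monte-Carlo test of each observed transition probability.

    For each iteration the corpus is randomized by :func:`randomize_corpus`
    and transition probabilities recomputed, building a per-cell null sample.
    The two-tailed p-value is ``min(1, 2 * min(tail ranks))`` with each tail
    rank computed with add-one smoothing, ``(#{null in tail} + 1) /
    (n_iter + 1)``, so p is floored at ``1 / (n_iter + 1)``; ties between the
    observed and null values count toward both tails (conservative).  A cell
    is flagged significant when the observed probability falls outside the
    central ``1 - alpha`` interval of its null sample.  Rows whose state has
    no outgoing transition in the observed corpus nor in any draw are
    reported as NaN (not applicable).
    """
    if n_iter < 1:
        raise ParameterError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    flat, lengths = corpus.encoded()
    prev, nxt = _pair_indices(lengths)
    n_states = len(corpus.alphabet)
    observed = TransitionMatrix.from_counts(
        _count_from_flat(flat, prev, nxt, n_states), corpus.alphabet
    )

    null = np.empty((n_states, n_states, n_iter), dtype=np.float64)
    null_row_defined = np.zeros(n_states, dtype=bool)
    for it in range(n_iter):
        shuffled = flat[rng.permutation(flat.size)]
        counts = _count_from_flat(shuffled, prev, nxt, n_states)
        null[:, :, it] = _row_normalize(counts)
        null_row_defined |= counts.sum(axis=1) > 0

    obs = observed.probs[:, :, None]
    eps = 1e-12
    n_le = (null <= obs + eps).sum(axis=2)
    n_ge = (null >= obs - eps).sum(axis=2)
    tail = np.minimum(n_le, n_ge)
    p = np.minimum(1.0, 2.0 * (tail + 1) / (n_iter + 1))
    p = np.maximum(p, 1.0 / (n_iter + 1))

    lo = np.quantile(null, alpha / 2, axis=2)
    hi = np.quantile(null, 1 - alpha / 2, axis=2)
    significant = (observed.probs < lo - eps) | (observed.probs > hi + eps)

    undefined = ~(null_row_defined | (observed.counts.sum(axis=1) > 0))
    p[undefined, :] = np.nan
    significant[undefined, :] = False

    return TransitionTestResult(
        observed=observed,
        null_samples=null,
        p_two_tailed=p,
        significant=significant,
        n_iter=n_iter,
        seed=seed,
        alpha=alpha,
        alphabet=corpus.alphabet,
    )


def export_transition_graph(
    result: TransitionTestResult,
    path: str | Path,
    image_path: str | Path | None = None,
) -> Path:
    """Write the full edge list (zeros included) as CSV; optionally render a
    directed-graph figure with edge opacity proportional to probability."""
    alphabet = result.alphabet
    if not alphabet:
        raise VocalcombError("empty alphabet: nothing to export")
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["from", "to", "count", "probability", "p", "significant"])
        for i, a in enumerate(alphabet):
            for j, b in enumerate(alphabet):
                pv = result.p_two_tailed[i, j]
                w.writerow([
                    a, b,
                    int(result.observed.counts[i, j]),
                    f"{result.observed.probs[i, j]:.6f}",
                    "NA" if np.isnan(pv) else f"{pv:.6g}",
                    bool(result.significant[i, j]),
                ])
    if image_path is not None:
        _render_graph(result, Path(image_path))
    return path


def _render_graph(result: TransitionTestResult, image_path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(result.alphabet)
    for i, a in enumerate(result.alphabet):
        for j, b in enumerate(result.alphabet):
            pr = result.observed.probs[i, j]
            if pr > 0:
                g.add_edge(a, b, prob=pr, sig=bool(result.significant[i, j]))
    pos = nx.circular_layout(g)
    fig, ax = plt.subplots(figsize=(5, 5))
    nx.draw_networkx_nodes(g, pos, ax=ax, node_color="#cfe8ef", node_size=1400)
    nx.draw_networkx_labels(g, pos, ax=ax)
    for u, v, d in g.edges(data=True):
        nx.draw_networkx_edges(
            g, pos, edgelist=[(u, v)], ax=ax, alpha=max(0.15, d["prob"]),
            connectionstyle="arc3,rad=0.15", width=1 + 3 * d["prob"],
        )
        x, y = (pos[u] + pos[v]) / 2
        star = "*" if d["sig"] else ""
        ax.text(x, y, f"{d['prob']:.2f}{star}", fontsize=8, ha="center")
    ax.set_axis_off()
    fig.savefig(image_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
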