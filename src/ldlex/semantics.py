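"""Lexome semantic vectors by incremental Rescorla-Wagner learning.

Semantic vectors are the rows of a lexome-by-lexome association weight
matrix learned incrementally over a lexome-coded corpus: each sentence is
an unordered set of lexomes, and every lexome in the sentence predicts
every lexome of the lexicon (present outcomes pushed toward the asymptote,
absent ones toward zero, by the delta rule with equal saliences). A word,
in turn, is the sum of its lexomes' vectors: the vector of an inflected
word is stem vector + inflectional-function vector(s), and a monomorphemic
word's vector is identical to its single lexome's row.

Post-processing follows the standard recipe: the main diagonal (each
lexome predicting itself) is zeroed so self-prediction does not dominate
the vectors, and near-constant columns, which carry no discriminative
information, are pruned by a variance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import LdlexError

#: default column-variance pruning threshold
VARIANCE_THRESHOLD = 3.4e-8


@dataclass(frozen=True)
class Lexome:
    label: str
    kind: str = "content"  # content | inflectional | derivational

    def __post_init__(self):
        if self.kind not in {"content", "inflectional", "derivational"}:
            raise LdlexError(f"Lexome {self.label}: unknown kind {self.kind!r}")


@dataclass
class LexomeCorpus:
    """Ordered learning events; each event is a sentence's lexome set."""

    events: list[tuple[str, ...]]
    lexicon: list[Lexome] | None = None

    def __post_init__(self):
        self.events = [tuple(dict.fromkeys(e)) for e in self.events]
        if not self.events:
            raise LdlexError("LexomeCorpus: events must be non-empty")
        if self.lexicon is not None:
            known = {l.label for l in self.lexicon}
            for i, ev in enumerate(self.events):
                unknown = [l for l in ev if l not in known]
                if unknown:
                    raise LdlexError(
                        f"LexomeCorpus: unknown lexome(s) {unknown} in event {i}")

    @property
    def labels(self) -> list[str]:
        """All lexome labels in deterministic order (lexicon order, or
        first appearance in the corpus)."""
        if self.lexicon is not None:
            return [l.label for l in self.lexicon]
        seen: dict[str, None] = {}
        for ev in self.events:
            for l in ev:
                seen.setdefault(l, None)
        return list(seen)

    @classmethod
    def from_text(cls, path, inflectional_prefix: str = "@") -> "LexomeCorpus":
        """One sentence per line, whitespace-separated lexome labels;
        labels starting with the prefix are inflectional lexomes."""
        path = Path(path)
        lines = [ln.split() for ln in path.read_text(encoding="utf-8").splitlines()
                 if ln.strip()]
        corpus = cls([tuple(ln) for ln in lines])
        kinds = {
            l: ("inflectional" if l.startswith(inflectional_prefix) else "content")
            for l in corpus.labels
        }
        corpus.lexicon = [Lexome(l, kinds[l]) for l in corpus.labels]
        return corpus


@dataclass
class WeightMatrix:
    values: np.ndarray
    row_labels: list[str]
    col_labels: list[str]
    row_pos: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise LdlexError("WeightMatrix: shape inconsistent with labels")
        self.row_pos = {l: i for i, l in enumerate(self.row_labels)}

    def row(self, label: str) -> np.ndarray:
        if label not in self.row_pos:
            raise LdlexError(f"WeightMatrix: no row for lexome {label!r}")
        return self.values[self.row_pos[label]]

    def w(self, cue: str, outcome: str) -> float:
        if outcome not in self.col_labels:
            raise LdlexError(f"WeightMatrix: no column for lexome {outcome!r}")
        return float(self.row(cue)[self.col_labels.index(outcome)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels,
                            columns=self.col_labels)


def learn_rw_weights(corpus: LexomeCorpus, learning_rate: float = 0.001,
                     asymptote: float = 1.0, n_epochs: int = 1) -> WeightMatrix:
    """One (or more) incremental Rescorla-Wagner passes over the corpus.

    For every event, cues = outcomes = the sentence's lexome set (a word
    predicts the other words of its sentence and itself); every known
    lexome is an outcome, with target ``asymptote`` when present and 0 when
    absent. Weights start at zero and each active cue's weight to each
    outcome moves by ``learning_rate`` times the prediction error shared
    across outcomes. Deterministic in corpus order; order matters.
    """
    if not 0.0 < learning_rate < 1.0:
        raise LdlexError("learn_rw_weights: learning_rate must be in (0, 1)")
    if asymptote <= 0:
        raise LdlexError("learn_rw_weights: asymptote must be positive")
    labels = corpus.labels
    pos = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    W = np.zeros((n, n))
    target = np.zeros(n)
    for _ in range(n_epochs):
        for i, ev in enumerate(corpus.events):
            try:
                idx = [pos[l] for l in ev]
            except KeyError as exc:  # only reachable with a stale lexicon
                raise LdlexError(
                    f"learn_rw_weights: unknown lexome {exc} in event {i}") from None
            target[:] = 0.0
            target[idx] = asymptote
            error = target - W[idx].sum(axis=0)
            W[idx] += learning_rate * error
    return WeightMatrix(W, list(labels), list(labels))


def postprocess_weights(W: WeightMatrix,
                        variance_threshold: float = VARIANCE_THRESHOLD) -> WeightMatrix:
    """Zero the self-prediction diagonal, then prune low-variance columns.

    Variance is the population variance of each column, computed after
    diagonal zeroing; columns with variance strictly below the threshold
    are removed.
    """
    if len(W.row_labels) != len(W.col_labels):
        raise LdlexError("postprocess_weights: weight matrix must be square")
    V = W.values.copy()
    col_pos = {l: j for j, l in enumerate(W.col_labels)}
    for i, l in enumerate(W.row_labels):
        j = col_pos.get(l)
        if j is not None:
            V[i, j] = 0.0
    variances = V.var(axis=0)  # population variance
    keep = np.flatnonzero(variances >= variance_threshold)
    if keep.size == 0:
        raise LdlexError("postprocess_weights: all columns pruned")
    return WeightMatrix(V[:, keep], list(W.row_labels),
                        [W.col_labels[j] for j in keep])


def compose_word_vector(lexomes, W: WeightMatrix) -> np.ndarray:
    """Sum of the semantic (row) vectors of a word's lexomes."""
    lexomes = sorted(lexomes)
    if not lexomes:
        raise LdlexError("compose_word_vector: empty lexome set")
    return np.sum([W.row(l) for l in lexomes], axis=0)


@dataclass
class SemanticSpace:
    """Word semantic matrix: one row per inflectionally distinct reading."""

    S: np.ndarray
    word_index: list[str]

    def __post_init__(self):
        self.S = np.atleast_2d(np.asarray(self.S, dtype=float))
        if self.S.shape[0] != len(self.word_index):
            raise LdlexError("SemanticSpace: row count != index length")
        if not np.isfinite(self.S).all():
            raise LdlexError("SemanticSpace: non-finite entries")

    @property
    def dim(self) -> int:
        return self.S.shape[1]

    def __len__(self) -> int:
        return self.S.shape[0]

    def row(self, word_id: str) -> np.ndarray:
        return self.S[self.word_index.index(word_id)]


def build_semantic_space(entries, W: WeightMatrix) -> SemanticSpace:
    """Assemble S row-per-reading: ambiguous surface forms (same phones,
    different lexome sets) contribute one row each."""
    rows, ids, seen = [], [], set()
    for e in entries:
        key = (e.form.phones, frozenset(e.lexomes))
        if key in seen:
            raise LdlexError(
                f"build_semantic_space: duplicate (form, lexome-set) for {e.id}")
        seen.add(key)
        rows.append(compose_word_vector(e.lexomes, W))
        ids.append(e.id)
    return SemanticSpace(np.vstack(rows), ids)
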