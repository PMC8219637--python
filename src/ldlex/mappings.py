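"""Linear form-meaning networks estimated by multivariate least squares.

Each network is a matrix A transforming the row vectors of a source matrix
X into those of a target matrix Y (Y = XA). A is the minimum-norm
least-squares solution A = X⁻Y through the SVD-based generalized inverse;
the same mappings can also be learned incrementally with the Widrow-Hoff
delta rule. The standard registry for a lexicon comprises:

====  ==================  ==========================================
name  solves              role
====  ==================  ==========================================
J     C_o J = T_a         orthographic trigrams -> triphones
H_p   T_a H_p = S         triphones -> semantics (production check)
G     S G = T_a           semantics -> triphone support (production)
F     C_a F = S           acoustic cues -> semantics (direct route)
E     C_a E = T_a         acoustic cues -> triphones (indirect, 1st leg)
H_c   T_a H_c = S         triphones -> semantics (indirect, 2nd leg)
====  ==================  ==========================================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import LdlexError, pearson

#: relative singular-value cutoff for the generalized inverse
RCOND = 1e-10


@dataclass
class LinearMapping:
    name: str
    matrix: np.ndarray
    source_kind: str = ""
    target_kind: str = ""

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise LdlexError(f"LinearMapping {self.name}: matrix must be 2-D")
        if not np.isfinite(self.matrix).all():
            raise LdlexError(f"LinearMapping {self.name}: non-finite entries")

    @property
    def source_dim(self) -> int:
        return self.matrix.shape[0]

    @property
    def target_dim(self) -> int:
        return self.matrix.shape[1]


def estimate_mapping(X, Y, name: str = "", source_kind: str = "",
                     target_kind: str = "", rcond: float = RCOND) -> LinearMapping:
    """Minimum-norm least-squares solution of X A = Y.

    Computed with a rank-revealing SVD solver; among all minimizers of
    ||XA - Y||_F the returned A has minimal Frobenius norm.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2:
        raise LdlexError("estimate_mapping: X and Y must be 2-D")
    if X.shape[0] != Y.shape[0]:
        raise LdlexError(
            f"estimate_mapping: row-count mismatch ({X.shape[0]} vs {Y.shape[0]})")
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise LdlexError("estimate_mapping: non-finite entries in X or Y")
    A, *_ = np.linalg.lstsq(X, Y, rcond=rcond)
    return LinearMapping(name, A, source_kind, target_kind)


def apply_mapping(v, M: LinearMapping) -> np.ndarray:
    """v @ M for a single vector or row-stacked matrix of vectors."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != M.source_dim:
        raise LdlexError(
            f"apply_mapping({M.name}): input dim {v.shape[-1]} != {M.source_dim}")
    return v @ M.matrix


def widrow_hoff_step(M: LinearMapping, x, y, rate: float) -> LinearMapping:
    """One incremental delta-rule update: A += rate * x (y - xA)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape[0] != M.source_dim or y.shape[0] != M.target_dim:
        raise LdlexError(f"widrow_hoff_step({M.name}): dimension mismatch")
    if rate < 0:
        raise LdlexError("widrow_hoff_step: rate must be non-negative")
    updated = M.matrix + rate * np.outer(x, y - x @ M.matrix)
    return LinearMapping(M.name, updated, M.source_kind, M.target_kind)


def mean_row_correlation(predicted, target) -> float:
    """Mean Pearson correlation of corresponding rows (training diagnostic)."""
    predicted = np.atleast_2d(predicted)
    target = np.atleast_2d(target)
    return float(np.mean([pearson(p, t) for p, t in zip(predicted, target)]))


class MappingRegistry(dict):
    """Named mappings plus their training-reconstruction diagnostics."""

    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        self.diagnostics: pd.DataFrame | None = None


def train_lexicon_mappings(C_o, T_a, S, C_a=None, rcond: float = RCOND) -> MappingRegistry:
    """Estimate the full registry from row-aligned training matrices.

    ``C_a`` is optional: without acoustic cue vectors the comprehension
    mappings F, E, H_c are trained on the orthographic cue matrix instead,
    so both routes remain available.
    """
    C_o = np.asarray(C_o, dtype=float)
    T_a = np.asarray(T_a, dtype=float)
    S = np.asarray(S, dtype=float)
    comp = C_o if C_a is None else np.asarray(C_a, dtype=float)
    comp_kind = "letter_trigram" if C_a is None else "fbs_feature"
    n = C_o.shape[0]
    for nm, M in (("T_a", T_a), ("S", S), ("comprehension cues", comp)):
        if M.shape[0] != n:
            raise LdlexError(f"train_lexicon_mappings: {nm} row count != {n}")
    reg = MappingRegistry()
    reg["J"] = estimate_mapping(C_o, T_a, "J", "letter_trigram", "triphone", rcond)
    reg["H_p"] = estimate_mapping(T_a, S, "H_p", "triphone", "semantic", rcond)
    reg["G"] = estimate_mapping(S, T_a, "G", "semantic", "triphone", rcond)
    reg["F"] = estimate_mapping(comp, S, "F", comp_kind, "semantic", rcond)
    reg["E"] = estimate_mapping(comp, T_a, "E", comp_kind, "triphone", rcond)
    reg["H_c"] = estimate_mapping(T_a, S, "H_c", "triphone", "semantic", rcond)
    rows = []
    for name, X, Y in (("J", C_o, T_a), ("H_p", T_a, S), ("G", S, T_a),
                       ("F", comp, S), ("E", comp, T_a), ("H_c", T_a, S)):
        rows.append({
            "mapping": name,
            "mean_row_correlation": mean_row_correlation(
                apply_mapping(X, reg[name]), Y),
        })
    reg.diagnostics = pd.DataFrame(rows).set_index("mapping")
    return reg
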