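"""Comprehension routes and semantic-neighborhood measures.

Acoustic (or orthographic) cue vectors are mapped into semantic space by
two routes: the direct route in one step (ŝ₁ = c F) and the indirect
route through the triphone layer (ŝ₂ = c E H_c). Four measures locate the
resulting vector relative to the word vectors of the lexicon:

- EDNN: Euclidean distance to the nearest word vector,
- NNC:  maximum Pearson correlation with any word vector,
- ALC:  mean Pearson correlation with all word vectors,
- DRC:  correlation between the two routes' estimates.

Pearson correlation (the cosine of centered vectors) is used throughout.
The module also provides the inflectional similarity profile (Same /
Different / Uninflected comparison cells per inflectional category) and a
PCA regularization of correlated measure columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from ._utils import LdlexError, pearson, pearson_rows
from .mappings import LinearMapping, apply_mapping
from .semantics import SemanticSpace

logger = logging.getLogger("ldlex")


@dataclass
class RouteOutput:
    s1: np.ndarray  # direct route
    s2: np.ndarray  # indirect route


def comprehend_direct(c, F: LinearMapping) -> np.ndarray:
    return apply_mapping(c, F)


def comprehend_indirect(c, E: LinearMapping, H_c: LinearMapping) -> np.ndarray:
    return apply_mapping(apply_mapping(c, E), H_c)


def ednn(s_hat, space: SemanticSpace) -> float:
    """Euclidean distance from the estimated vector to its nearest word."""
    if len(space) == 0:
        raise LdlexError("ednn: empty semantic space")
    s_hat = np.asarray(s_hat, dtype=float).reshape(1, -1)
    return float(cdist(s_hat, space.S).min())


def _valid_correlations(s_hat, space: SemanticSpace) -> np.ndarray:
    r = pearson_rows(space.S, s_hat)
    bad = np.isnan(r)
    if bad.any():
        logger.info("skipped %d zero-variance word vectors", int(bad.sum()))
    r = r[~bad]
    if r.size == 0:
        raise LdlexError("all word vectors have zero variance")
    return r


def nnc(s_hat, space: SemanticSpace) -> float:
    """Maximum correlation with any word vector (nearest-neighbor angle)."""
    return float(_valid_correlations(s_hat, space).max())


def alc(s_hat, space: SemanticSpace) -> float:
    """Mean correlation with all word vectors (neighborhood density)."""
    return float(_valid_correlations(s_hat, space).mean())


def drc(s1, s2) -> float:
    """Correlation between the direct- and indirect-route estimates."""
    s1 = np.asarray(s1, dtype=float).ravel()
    s2 = np.asarray(s2, dtype=float).ravel()
    if s1.shape != s2.shape:
        raise LdlexError("drc: dimension mismatch")
    if np.ptp(s1) == 0 or np.ptp(s2) == 0:
        raise LdlexError("drc: zero-variance route vector")
    return pearson(s1, s2)


def _as_label_sets(labels) -> list[frozenset[str]]:
    out = []
    for l in labels:
        if isinstance(l, str):
            out.append(frozenset([l]))
        else:
            out.append(frozenset(l))
    return out


def inflectional_profile(vectors, labels, other_vectors=None, other_labels=None,
                         uninflected: str = "uninflected") -> pd.DataFrame:
    """Same / Different / Uninflected mean correlations per category.

    In the one-set mode (``other_vectors`` None) every item is compared
    with every *other* item of the same set (self-pairs excluded); in the
    two-set mode items are compared with the reference set (e.g.,
    pseudowords against real words). Items may carry several category
    labels and then contribute to each. A category with no Same pairs is
    emitted with n = 0 and NaN mean.
    """
    V = np.atleast_2d(np.asarray(vectors, dtype=float))
    L = _as_label_sets(labels)
    if V.shape[0] != len(L):
        raise LdlexError("inflectional_profile: labels misaligned with vectors")
    same_set = other_vectors is None
    W = V if same_set else np.atleast_2d(np.asarray(other_vectors, dtype=float))
    M = L if same_set else _as_label_sets(other_labels)
    if W.shape[0] != len(M):
        raise LdlexError("inflectional_profile: reference labels misaligned")

    # full cross-correlation matrix, centered rows
    Vc = V - V.mean(axis=1, keepdims=True)
    Wc = W - W.mean(axis=1, keepdims=True)
    nv = np.linalg.norm(Vc, axis=1)
    nw = np.linalg.norm(Wc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (Vc @ Wc.T) / np.outer(nv, nw)

    categories = sorted({c for s in L for c in s if c != uninflected})
    rows = []
    for cat in categories:
        members = [i for i, s in enumerate(L) if cat in s]
        for comparison in ("Same", "Different", "Uninflected"):
            vals = []
            for i in members:
                for j in range(W.shape[0]):
                    if same_set and i == j:
                        continue
                    if comparison == "Same":
                        hit = cat in M[j]
                    elif comparison == "Uninflected":
                        hit = uninflected in M[j]
                    else:
                        hit = (cat not in M[j]) and (uninflected not in M[j])
                    if hit and np.isfinite(R[i, j]):
                        vals.append(R[i, j])
            rows.append({
                "category": cat,
                "comparison": comparison,
                "mean_correlation": float(np.mean(vals)) if vals else float("nan"),
                "n": len(vals),
            })
    return pd.DataFrame(rows)


@dataclass
class PCAMeasures:
    loadings: pd.DataFrame            # variables x components
    scores: np.ndarray                # items x components
    variance_proportions: np.ndarray  # length k


def pca_measures(records: pd.DataFrame, variables, k: int) -> PCAMeasures:
    """PCA regularization of correlated measure columns.

    Variables are standardized (correlation-matrix PCA). Sign convention:
    the largest-magnitude loading of each component is made positive.
    """
    variables = list(variables)
    if k > len(variables):
        raise LdlexError("pca_measures: k exceeds number of variables")
    X = records[variables].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise LdlexError("pca_measures: incomplete cases present")
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        const = [v for v, s in zip(variables, sd) if s == 0]
        raise LdlexError(f"pca_measures: constant variable(s) {const}")
    Z = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Z)
    loadings = pca.components_.T.copy()  # variables x k
    for j in range(k):
        if loadings[np.abs(loadings[:, j]).argmax(), j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    cols = [f"PC{j + 1}" for j in range(k)]
    return PCAMeasures(
        loadings=pd.DataFrame(loadings, index=variables, columns=cols),
        scores=scores,
        variance_proportions=pca.explained_variance_ratio_.copy(),
    )
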