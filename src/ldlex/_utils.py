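"""Shared numerical helpers: Pearson correlations with degenerate-input policy."""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger("ldlex")


class LdlexError(ValueError):
    """Labeled error raised for contract violations."""


def pearson(u, v) -> float:
    """Pearson correlation of two vectors.

    Zero-variance inputs yield 0.0 (logged) rather than NaN, so that
    similarity maxima/means over degenerate candidates stay well defined.
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise LdlexError(f"pearson: shape mismatch {u.shape} vs {v.shape}")
    uc = u - u.mean()
    vc = v - v.mean()
    nu = np.linalg.norm(uc)
    nv = np.linalg.norm(vc)
    if nu == 0.0 or nv == 0.0:
        logger.debug("pearson: zero-variance vector, correlation recorded as 0")
        return 0.0
    return float(np.clip(np.dot(uc, vc) / (nu * nv), -1.0, 1.0))


def pearson_rows(M, v) -> np.ndarray:
    """Correlation of vector ``v`` with every row of ``M`` (vectorized).

    Rows with zero variance give NaN; a zero-variance ``v`` gives 0.0
    against every row (logged), matching :func:`pearson`.
    """
    M = np.asarray(M, dtype=float)
    v = np.asarray(v, dtype=float).ravel()
    if M.ndim != 2 or M.shape[1] != v.shape[0]:
        raise LdlexError(f"pearson_rows: shape mismatch {M.shape} vs {v.shape}")
    vc = v - v.mean()
    nv = np.linalg.norm(vc)
    Mc = M - M.mean(axis=1, keepdims=True)
    nm = np.linalg.norm(Mc, axis=1)
    if nv == 0.0:
        logger.debug("pearson_rows: zero-variance query vector, correlations = 0")
        return np.zeros(M.shape[0])
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.clip((Mc @ vc) / (nm * nv), -1.0, 1.0)
    r[nm == 0.0] = np.nan
    return r
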