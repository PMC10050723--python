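"""P component: detect correlated miRNA-CpG feature pairs.

Every miRNA feature is tested against every CpG feature with the Pearson
correlation; pairs whose |r| strictly exceeds ``alpha`` and whose two-sided
p-value (t-transform, n-2 degrees of freedom) is below ``pair_p_max`` are
emitted.  Both the sign-symmetric threshold and the p-value gate follow the
convention that a strong negative association (miRNA repression, methylation
silencing) is as informative as a positive one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_config import OmicsMatrix, TrimintError, logger


class ZeroVarianceError(TrimintError):
    """A feature vector has no variance, so Pearson correlation is undefined."""


@dataclass(frozen=True)
class FeaturePair:
    """A correlated (miRNA, CpG) pair."""

    mirna_id: str
    cpg_id: str
    r: float
    p_value: float

    @property
    def name(self) -> str:
        return f"{self.mirna_id}_{self.cpg_id}"


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson correlation with the classical t-transform p-value.

    The two-sided p-value comes from t = r * sqrt((n-2) / (1-r^2)) with n-2
    degrees of freedom.  Raises :class:`ZeroVarianceError` when either vector
    is constant, so callers can skip the feature rather than propagate NaNs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise TrimintError("pearson expects two equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise TrimintError("pearson needs at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt(np.dot(xc, xc)))
    sy = float(np.sqrt(np.dot(yc, yc)))
    if sx == 0.0 or sy == 0.0:
        raise ZeroVarianceError("constant vector has undefined correlation")
    r = float(np.dot(xc, yc) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    p = _p_from_r(np.array([r]), n)[0]
    return r, float(p)


def _p_from_r(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-values for Pearson r via the t-distribution with n-2 df."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", over="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, np.finfo(float).tiny))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def correlation_matrix(A: OmicsMatrix, B: OmicsMatrix) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs correlations between the rows of two sample-aligned matrices.

    Returns ``(R, valid)`` where ``R[i, j] = cor(A_i, B_j)`` and ``valid`` is
    an outer product mask that is False wherever either feature is constant.
    Implemented as standardize-then-crossproduct, so cost is one matrix
    product rather than a double loop.
    """
    if A.sample_ids != B.sample_ids:
        raise TrimintError("matrices must be sample-aligned (identical sample order)")
    n = A.n_samples
    Za, ok_a = _standardize_rows(A.values())
    Zb, ok_b = _standardize_rows(B.values())
    R = (Za @ Zb.T) / n
    return np.clip(R, -1.0, 1.0), np.outer(ok_a, ok_b)


def _standardize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    ok = sd[:, 0] > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (X - mu) / sd
    Z[~ok] = 0.0
    return Z, ok


def detect_pairs(
    A: OmicsMatrix,
    B: OmicsMatrix,
    alpha: float = 0.6,
    pair_p_max: float = 0.05,
) -> list[FeaturePair]:
    """Exhaustive scan of all miRNA x CpG pairs.

    Emits every pair with |r| > alpha (strict) and p < pair_p_max, sorted by
    |r| descending then (mirna_id, cpg_id) for a fully deterministic order.
    Zero-variance features are skipped with a logged count; an empty result
    is legal and logged as a warning.
    """
    R, valid = correlation_matrix(A, B)
    n_const = int(valid.size - valid.sum())
    if n_const:
        logger.info("detect_pairs: skipped %d pairs involving constant features", n_const)
    hit = valid & (np.abs(R) > alpha)
    idx = np.argwhere(hit)
    pairs: list[FeaturePair] = []
    if idx.size:
        p_values = _p_from_r(R[hit], A.n_samples)
        mirna_ids = A.feature_ids
        cpg_ids = B.feature_ids
        for (i, j), p in zip(idx, p_values):
            if p < pair_p_max:
                pairs.append(FeaturePair(mirna_ids[i], cpg_ids[j], float(R[i, j]), float(p)))
    pairs.sort(key=lambda fp: (-abs(fp.r), fp.mirna_id, fp.cpg_id))
    if not pairs:
        logger.warning("detect_pairs: no pairs passed |r| > %.3g, p < %.3g", alpha, pair_p_max)
    return pairs
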