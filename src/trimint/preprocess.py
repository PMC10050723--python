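"""Feature filters applied before pairing.

Methylation probes go through a missing-fraction filter (probes with more
than ``max_missing_fraction`` missing values are dropped, survivors are
mean-imputed), a variability filter keeping probes whose interquartile range
exceeds ``min_iqr``, and optional user-supplied exclusion lists (sex
chromosome, SNP, cross-reactive probes).  All three omics then pass a
per-feature two-sample t-test against the class labels, keeping features
with p below ``p_max``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_config import LabelTable, OmicsMatrix, TrimintError, logger


@dataclass
class FilterReport:
    """Bookkeeping for one filter stage."""

    stage: str
    features_in: int
    features_out: int
    removed_ids: list[str] = field(default_factory=list)
    notes: str = ""

    def __post_init__(self) -> None:
        assert self.features_out == self.features_in - len(self.removed_ids)


def filter_missing(
    matrix: OmicsMatrix, max_missing_fraction: float = 0.2
) -> tuple[OmicsMatrix, FilterReport]:
    """Drop features with missing fraction strictly above the threshold.

    Surviving features have their remaining missing entries imputed with the
    feature's mean over the non-missing samples.  A feature missing in every
    sample has no mean to impute and is always dropped.
    """
    if not (0 <= max_missing_fraction < 1):
        raise TrimintError("max_missing_fraction must be in [0, 1)")
    values = matrix.values()
    miss = ~np.isfinite(values)
    frac = miss.mean(axis=1)
    keep = (frac <= max_missing_fraction) & (frac < 1.0)
    removed = [fid for fid, k in zip(matrix.feature_ids, keep) if not k]
    data = matrix.data.loc[keep].copy()
    if data.size and not np.all(np.isfinite(data.to_numpy())):
        row_means = data.mean(axis=1, skipna=True)
        data = data.T.fillna(row_means).T
    out = OmicsMatrix(matrix.name, matrix.role, data)
    report = FilterReport("missing", matrix.n_features, out.n_features, removed)
    if removed or miss.any():
        logger.info(
            "missing filter on %s: removed %d/%d features, imputed %d entries",
            matrix.name, len(removed), matrix.n_features, int(miss[keep].sum()),
        )
    return out, report


def filter_iqr(matrix: OmicsMatrix, min_iqr: float = 0.1) -> tuple[OmicsMatrix, FilterReport]:
    """Keep features whose interquartile range is strictly greater than ``min_iqr``.

    Quartiles use linear interpolation between order statistics; retention of
    features near the boundary depends on this convention.
    """
    values = matrix.values()
    if values.size and not np.all(np.isfinite(values)):
        raise TrimintError("filter_iqr requires a matrix without missing values")
    if matrix.n_features == 0:
        return matrix, FilterReport("iqr", 0, 0, [])
    q75, q25 = np.percentile(values, [75, 25], axis=1)
    keep = (q75 - q25) > min_iqr
    removed = [fid for fid, k in zip(matrix.feature_ids, keep) if not k]
    out = OmicsMatrix(matrix.name, matrix.role, matrix.data.loc[keep])
    return out, FilterReport("iqr", matrix.n_features, out.n_features, removed)


def filter_exclusion(
    matrix: OmicsMatrix, blocklists: list[set[str]]
) -> tuple[OmicsMatrix, FilterReport]:
    """Remove features listed in any blocklist; unknown IDs are counted, not errors."""
    union: set[str] = set().union(*blocklists) if blocklists else set()
    present = set(matrix.feature_ids)
    removed = [fid for fid in matrix.feature_ids if fid in union]
    unknown = len(union - present)
    out = OmicsMatrix(matrix.name, matrix.role, matrix.data.drop(index=removed))
    if unknown:
        logger.info("exclusion filter on %s: %d blocklist IDs not in matrix", matrix.name, unknown)
    return out, FilterReport(
        "exclusion", matrix.n_features, out.n_features, removed,
        notes=f"unknown_blocklist_ids={unknown}",
    )


def ttest_filter(
    matrix: OmicsMatrix,
    labels: LabelTable,
    p_max: float = 0.05,
    welch: bool = True,
) -> tuple[OmicsMatrix, FilterReport]:
    """Keep features whose two-sample t-test p-value is below ``p_max``.

    Welch's unequal-variance form is the default; ``welch=False`` switches to
    the pooled-variance test.  Features constant within both classes carry no
    information and are treated as p = 1 (removed).
    """
    values = matrix.values()
    if values.size and not np.all(np.isfinite(values)):
        raise TrimintError("ttest_filter requires a matrix without missing values")
    y = labels.vector(matrix.sample_ids)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise TrimintError("ttest_filter needs >= 2 samples per class")
    if matrix.n_features == 0:
        return matrix, FilterReport("ttest", 0, 0, [])
    g1, g0 = values[:, y == 1], values[:, y == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(g1, g0, axis=1, equal_var=not welch)
    p = np.where(np.isfinite(p), p, 1.0)  # zero variance in both classes -> keep out
    keep = p < p_max
    removed = [fid for fid, k in zip(matrix.feature_ids, keep) if not k]
    out = OmicsMatrix(matrix.name, matrix.role, matrix.data.loc[keep])
    return out, FilterReport("ttest", matrix.n_features, out.n_features, removed)


def preprocess_cpg(
    matrix: OmicsMatrix,
    max_missing_fraction: float = 0.2,
    min_iqr: float = 0.1,
    blocklists: list[set[str]] | None = None,
) -> tuple[OmicsMatrix, list[FilterReport]]:
    """Convenience chain: missing-fraction filter, IQR filter, exclusion lists."""
    reports: list[FilterReport] = []
    m, rep = filter_missing(matrix, max_missing_fraction)
    reports.append(rep)
    m, rep = filter_iqr(m, min_iqr)
    reports.append(rep)
    m, rep = filter_exclusion(m, blocklists or [])
    reports.append(rep)
    return m, reports
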