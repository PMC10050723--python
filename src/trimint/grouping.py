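"""G component: build cross-omics gene groups around each miRNA-CpG pair.

A group collects every mRNA feature jointly correlated with both members of
a pair above the ``beta`` threshold.  By default the condition is applied to
the absolute correlation (a repressive miRNA-target link shows up as a
strong negative correlation); ``use_abs=False`` restores the literal signed
reading ``cor > beta``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_config import OmicsMatrix, TrimintError, logger
from .pairing import FeaturePair, _standardize_rows


@dataclass(frozen=True)
class Group:
    """A feature pair plus the mRNA features correlated with both members.

    The name is ``mirnaID_cpgID``; ``gene_ids`` is ordered by descending
    joint correlation strength min(|cor(a, c)|, |cor(c, b)|) with ID as the
    tie-break, so group contents are reproducible across runs.
    """

    pair: FeaturePair
    gene_ids: tuple[str, ...]
    beta_used: float

    @property
    def name(self) -> str:
        return self.pair.name

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def _pair_vectors(pair: FeaturePair, A: OmicsMatrix, B: OmicsMatrix) -> tuple[np.ndarray, np.ndarray]:
    if pair.mirna_id not in A.data.index:
        raise TrimintError(f"pair miRNA {pair.mirna_id!r} not in matrix {A.name!r}")
    if pair.cpg_id not in B.data.index:
        raise TrimintError(f"pair CpG {pair.cpg_id!r} not in matrix {B.name!r}")
    return (
        A.data.loc[pair.mirna_id].to_numpy(dtype=float),
        B.data.loc[pair.cpg_id].to_numpy(dtype=float),
    )


def _row_correlations(vec: np.ndarray, C: OmicsMatrix) -> np.ndarray:
    """Correlation of one vector with every row of C; NaN for constant rows."""
    n = vec.size
    Z, ok = _standardize_rows(C.values())
    v = vec - vec.mean()
    sd = v.std()
    if sd == 0:
        return np.full(C.n_features, np.nan)
    r = (Z @ (v / sd)) / n
    r = np.clip(r, -1.0, 1.0)
    r[~ok] = np.nan
    return r


def build_group(
    pair: FeaturePair,
    A: OmicsMatrix,
    B: OmicsMatrix,
    C: OmicsMatrix,
    beta: float = 0.6,
    use_abs: bool = True,
) -> Group | None:
    """Collect mRNA features correlated with both pair members above beta.

    Returns ``None`` when no gene qualifies (the pair then contributes no
    group).  Both threshold comparisons are strict.
    """
    if A.sample_ids != B.sample_ids or A.sample_ids != C.sample_ids:
        raise TrimintError("matrices must be sample-aligned")
    a, b = _pair_vectors(pair, A, B)
    r_a = _row_correlations(a, C)
    r_b = _row_correlations(b, C)
    if use_abs:
        cond = (np.abs(r_a) > beta) & (np.abs(r_b) > beta)
    else:
        cond = (r_a > beta) & (r_b > beta)
    cond &= np.isfinite(r_a) & np.isfinite(r_b)
    if not cond.any():
        return None
    strength = np.minimum(np.abs(r_a), np.abs(r_b))
    members = [(C.feature_ids[i], strength[i]) for i in np.flatnonzero(cond)]
    members.sort(key=lambda t: (-t[1], t[0]))
    return Group(pair, tuple(g for g, _ in members), beta)


def build_groups(
    pairs: list[FeaturePair],
    A: OmicsMatrix,
    B: OmicsMatrix,
    C: OmicsMatrix,
    beta: float = 0.6,
    use_abs: bool = True,
) -> list[Group]:
    """Apply :func:`build_group` to each pair, dropping pairs with no genes.

    Pair order is preserved.  Gene sets of different groups may overlap; no
    deduplication happens across groups.
    """
    groups = [g for p in pairs if (g := build_group(p, A, B, C, beta, use_abs)) is not None]
    logger.info("build_groups: %d pairs -> %d non-empty groups", len(pairs), len(groups))
    if pairs and not groups:
        logger.warning("build_groups: no pair yielded a non-empty gene set at beta=%.3g", beta)
    return groups
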