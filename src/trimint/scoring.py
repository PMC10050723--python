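"""S component: score groups by cross-validated classification performance.

Each group is scored by restricting the training expression matrix to the
group's genes and running a stratified Monte Carlo cross-validation: the
training samples are repeatedly split, a random forest is fitted on the
inner-train part and evaluated on the inner-test part, and the score is the
weighted metric mean over iterations.  All groups within one outer split are
scored on the *same* inner partitions so their scores are comparable, and
ranks follow from sorting scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .grouping import Group
from .io_config import LabelTable, OmicsMatrix, RunConfig, TrimintError, derive_seed


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier family scores groups and fits cumulative models.

    Only ``random_forest`` ships; the registry accepts additional factories
    for experimentation.  Any classifier must expose scikit-learn's
    ``fit`` / ``predict`` / ``predict_proba``.
    """

    kind: str = "random_forest"
    n_trees: int = 100
    seed: int = 0


def _make_random_forest(spec: ClassifierSpec):
    return RandomForestClassifier(
        n_estimators=spec.n_trees,
        max_features="sqrt",
        random_state=spec.seed,
        n_jobs=1,
    )


CLASSIFIER_REGISTRY = {"random_forest": _make_random_forest}


def make_classifier(spec: ClassifierSpec):
    try:
        factory = CLASSIFIER_REGISTRY[spec.kind]
    except KeyError:
        raise TrimintError(
            f"unknown classifier kind {spec.kind!r}; registered: {sorted(CLASSIFIER_REGISTRY)}"
        ) from None
    return factory(spec)


@dataclass
class ScoredGroup:
    """A group with its cross-validated score and within-split rank."""

    group: Group
    score: float
    per_iteration_scores: list[float] = field(default_factory=list)
    rank: int | None = None

    @property
    def name(self) -> str:
        return self.group.name


def stratified_split(
    y: np.ndarray, test_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One stratified train/test index split keeping >= 1 sample per class on each side."""
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        if members.size < 2:
            raise TrimintError(f"class {cls!r} has < 2 samples; cannot split")
        perm = rng.permutation(members)
        n_test = int(round(test_fraction * members.size))
        n_test = min(max(n_test, 1), members.size - 1)
        test_idx.extend(perm[:n_test])
        train_idx.extend(perm[n_test:])
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


def make_inner_splits(
    y: np.ndarray, n_iterations: int, test_fraction: float, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified Monte Carlo partitions shared by every group of one outer split.

    The construction guarantees both classes on both sides; should a drawn
    partition still degenerate it is redrawn with a derived seed (at most 10
    attempts) before failing hard.
    """
    splits = []
    for it in range(n_iterations):
        for attempt in range(10):
            rng = np.random.default_rng(derive_seed(seed, it, attempt))
            tr, te = stratified_split(y, test_fraction, rng)
            if len(set(y[tr])) == 2 and len(set(y[te])) >= 1:
                splits.append((tr, te))
                break
        else:
            raise TrimintError("could not draw a valid stratified inner split in 10 attempts")
    return splits


def _iteration_score(
    clf, X_train, y_train, X_test, y_test, weights: dict[str, float]
) -> float:
    clf.fit(X_train, y_train)
    total = sum(weights.values())
    value = 0.0
    if weights.get("accuracy", 0.0) > 0:
        acc = float(np.mean(clf.predict(X_test) == y_test))
        value += weights["accuracy"] * acc
    if weights.get("auc", 0.0) > 0:
        from .modeling import rank_auc  # local import to avoid cycle

        pos_col = list(clf.classes_).index(1)
        scores = clf.predict_proba(X_test)[:, pos_col]
        auc = rank_auc(y_test, scores)
        value += weights["auc"] * (auc if np.isfinite(auc) else 0.5)
    return value / total


def score_group(
    group: Group,
    C_train: OmicsMatrix,
    labels: LabelTable,
    cfg: RunConfig,
    seed: int,
    inner_splits: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> ScoredGroup:
    """Score one group; ``rank`` is left unset.

    ``inner_splits`` lets a caller share partitions across groups; when
    omitted they are drawn from ``seed``.
    """
    missing = [g for g in group.gene_ids if g not in C_train.data.index]
    if missing:
        raise TrimintError(f"group {group.name} genes absent from training matrix: {missing}")
    # canonicalize sample and gene order so scores do not depend on how the
    # caller happened to order columns or group members
    order = sorted(C_train.sample_ids)
    y = labels.vector(order)
    if inner_splits is None:
        inner_splits = make_inner_splits(
            y, cfg.inner_cv_iterations, cfg.inner_test_fraction, seed
        )
    X = C_train.data.loc[sorted(group.gene_ids), order].to_numpy(dtype=float).T
    per_iter: list[float] = []
    for it, (tr, te) in enumerate(inner_splits):
        clf = make_classifier(
            ClassifierSpec("random_forest", cfg.rf_trees, derive_seed(seed, 1000 + it))
        )
        per_iter.append(
            _iteration_score(clf, X[tr], y[tr], X[te], y[te], cfg.score_metric_weights)
        )
    return ScoredGroup(group, float(np.mean(per_iter)), per_iter)


def score_and_rank(
    groups: list[Group],
    C_train: OmicsMatrix,
    labels: LabelTable,
    cfg: RunConfig,
    seed: int,
) -> list[ScoredGroup]:
    """Score every group on iteration-aligned inner splits and assign ranks.

    Sorted by score descending; ties broken toward larger gene sets (more
    informative for the downstream model), then lexicographic name.  Ranks
    are 1..m.
    """
    if not groups:
        raise TrimintError("score_and_rank needs at least one group")
    y = labels.vector(sorted(C_train.sample_ids))
    inner = make_inner_splits(y, cfg.inner_cv_iterations, cfg.inner_test_fraction, seed)
    scored = [score_group(g, C_train, labels, cfg, seed, inner_splits=inner) for g in groups]
    scored.sort(key=lambda s: (-s.score, -s.group.n_genes, s.name))
    for pos, s in enumerate(scored, start=1):
        s.rank = pos
    return scored
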