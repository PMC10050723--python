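import numpy as np
import pandas as pd
import pytest

from trimint import (
    FeaturePair,
    Group,
    LabelTable,
    OmicsMatrix,
    RunConfig,
    ScoredGroup,
    SimulationSpec,
    generate,
)
from trimint.modeling import PerformanceRow
from trimint.pipeline import SplitResult


def make_matrix(values, feature_ids=None, sample_ids=None, role="mRNA", name="m"):
    values = np.asarray(values, dtype=float)
    feature_ids = feature_ids or [f"f{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{i}" for i in range(values.shape[1])]
    return OmicsMatrix(name, role, pd.DataFrame(values, index=feature_ids, columns=sample_ids))


def make_labels(n_neg, n_pos, sample_ids=None):
    sample_ids = sample_ids or [f"s{i}" for i in range(n_neg + n_pos)]
    assign = {s: ("control" if i < n_neg else "case") for i, s in enumerate(sample_ids)}
    return LabelTable(assign, "case")


def make_scored(name_pair, gene_ids, score, rank, split=None):
    mirna, cpg = name_pair
    grp = Group(FeaturePair(mirna, cpg, 0.8, 1e-6), tuple(gene_ids), 0.6)
    return ScoredGroup(grp, score, [score], rank)


def make_split_result(split_index, scored_groups, performance=None):
    return SplitResult(
        split_index=split_index,
        seed=split_index,
        scored_groups=scored_groups,
        performance=performance or [],
        n_pairs=len(scored_groups),
        n_groups=len(scored_groups),
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One draw of the default simulation: 3 modules, loading 0.8, effect 2.0."""
    return generate(SimulationSpec(seed=11))


@pytest.fixture(scope="session")
def small_dataset():
    """A cheaper fixture for pipeline-level tests."""
    spec = SimulationSpec(
        n_samples_per_class=30,
        n_modules=2,
        genes_per_module=4,
        n_background={"miRNA": 30, "CpG": 30, "mRNA": 40},
        seed=5,
    )
    return generate(spec)


@pytest.fixture
def fast_config():
    return RunConfig(
        n_outer_splits=3,
        rf_trees=25,
        inner_cv_iterations=3,
        min_group_frequency=0,
        seed=123,
    )
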