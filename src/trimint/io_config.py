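"""Input/output, core containers and run configuration.

The pipeline works on three feature-by-sample numeric matrices (miRNA
expression, CpG methylation beta values, mRNA expression) plus a two-class
sample label table.  Matrices are stored features-in-rows, the common
convention of TCGA/Xena-style exports; an ``orientation`` switch transposes
files that ship samples-in-rows.

All randomness in a run flows from one master seed: outer split ``i`` uses
``seed + i``, and every consumer inside a split derives independent child
seeds through :func:`derive_seed`.
"""

from __future__ import annotations

import dataclasses
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("trimint")

ROLES = ("miRNA", "CpG", "mRNA")

#: strings treated as a missing CpG measurement on input
MISSING_MARKERS = ("", "NA", "NaN", "nan", "N/A", "null")


class TrimintError(ValueError):
    """Raised for invalid inputs or configuration."""


@dataclass
class OmicsMatrix:
    """A named feature-by-sample numeric matrix with an omics role.

    Parameters
    ----------
    name : str
        Short identifier used in logs and output file names.
    role : str
        One of ``miRNA``, ``CpG``, ``mRNA``.
    data : pandas.DataFrame
        Features in rows, samples in columns.  Missing entries (NaN) are
        permitted only for ``role="CpG"`` before preprocessing.
    """

    name: str
    role: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise TrimintError(f"unknown omics role {self.role!r}; expected one of {ROLES}")
        dup_f = self.data.index[self.data.index.duplicated()].unique().tolist()
        if dup_f:
            raise TrimintError(f"duplicate feature IDs in matrix {self.name!r}: {dup_f}")
        dup_s = self.data.columns[self.data.columns.duplicated()].unique().tolist()
        if dup_s:
            raise TrimintError(f"duplicate sample IDs in matrix {self.name!r}: {dup_s}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise TrimintError(f"matrix {self.name!r} contains non-numeric values")
        if self.role != "CpG" and values.size and not np.all(np.isfinite(values)):
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise TrimintError(
                f"matrix {self.name!r} (role {self.role}) has a non-finite value at "
                f"feature {self.data.index[r]!r}, sample {self.data.columns[c]!r}; "
                "missing values are only allowed for CpG matrices"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_features(self, feature_ids: Sequence[str]) -> "OmicsMatrix":
        return OmicsMatrix(self.name, self.role, self.data.loc[list(feature_ids)])

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicsMatrix":
        return OmicsMatrix(self.name, self.role, self.data.loc[:, list(sample_ids)])


@dataclass
class LabelTable:
    """Sample-to-class assignment for a two-class phenotype."""

    assignments: dict[str, str]
    positive_label: str

    def __post_init__(self) -> None:
        classes = sorted(set(self.assignments.values()))
        if len(classes) != 2:
            raise TrimintError(f"exactly two classes required, found {classes}")
        if self.positive_label not in classes:
            raise TrimintError(
                f"positive_label {self.positive_label!r} not among classes {classes}"
            )
        counts = pd.Series(list(self.assignments.values())).value_counts()
        if counts.min() < 2:
            raise TrimintError(
                f"every class needs >= 2 samples for stratified splitting, got {counts.to_dict()}"
            )

    @property
    def classes(self) -> tuple[str, str]:
        labs = sorted(set(self.assignments.values()))
        return (labs[0], labs[1])

    @property
    def negative_label(self) -> str:
        a, b = self.classes
        return b if self.positive_label == a else a

    @property
    def sample_ids(self) -> list[str]:
        return list(self.assignments)

    def vector(self, sample_ids: Sequence[str]) -> np.ndarray:
        """0/1 vector (1 = positive class) aligned to ``sample_ids``."""
        return np.array(
            [1 if self.assignments[s] == self.positive_label else 0 for s in sample_ids],
            dtype=int,
        )

    def subset(self, sample_ids: Sequence[str]) -> "LabelTable":
        return LabelTable({s: self.assignments[s] for s in sample_ids}, self.positive_label)


@dataclass
class RunConfig:
    """All tunable knobs of a pipeline run.

    ``alpha`` gates the absolute Pearson correlation of miRNA-CpG pairs,
    ``beta`` the gene-to-pair correlations that populate groups.  The outer
    loop draws ``n_outer_splits`` stratified train/test splits holding out
    ``test_fraction`` of samples; per-group scores come from
    ``inner_cv_iterations`` Monte Carlo splits of the training portion.
    ``leakage_mode="global"`` applies the t-test filter and correlation scans
    to all samples (mirroring the original workflow); ``"train_only"`` keeps
    every supervised or correlation step blind to the held-out test samples.
    """

    alpha: float = 0.6
    beta: float = 0.6
    pair_p_max: float = 0.05
    ttest_p_max: float = 0.05
    n_outer_splits: int = 100
    test_fraction: float = 0.1
    inner_cv_iterations: int = 5
    inner_test_fraction: float = 0.1
    top_k_groups: int = 10
    min_group_frequency: int = 5
    rf_trees: int = 100
    score_metric_weights: dict[str, float] = field(default_factory=lambda: {"accuracy": 1.0})
    seed: int = 42
    leakage_mode: str = "global"
    use_abs_beta: bool = True
    welch: bool = True
    max_missing_fraction: float = 0.2
    min_iqr: float = 0.1
    count_top_k_only: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise TrimintError("alpha must be in (0, 1]")
        if not (0 < self.beta <= 1):
            raise TrimintError("beta must be in (0, 1]")
        if not (0 < self.test_fraction < 1):
            raise TrimintError("test_fraction must be in (0, 1)")
        if not (0 < self.inner_test_fraction < 1):
            raise TrimintError("inner_test_fraction must be in (0, 1)")
        if self.n_outer_splits < 1 or self.inner_cv_iterations < 1:
            raise TrimintError("split/iteration counts must be positive")
        if self.top_k_groups < 1 or self.rf_trees < 1:
            raise TrimintError("top_k_groups and rf_trees must be positive")
        if self.min_group_frequency < 0:
            raise TrimintError("min_group_frequency must be >= 0")
        if self.leakage_mode not in ("global", "train_only"):
            raise TrimintError("leakage_mode must be 'global' or 'train_only'")
        unknown = set(self.score_metric_weights) - {"accuracy", "auc"}
        if unknown:
            raise TrimintError(f"unknown score metrics: {sorted(unknown)}")
        if not self.score_metric_weights or sum(self.score_metric_weights.values()) <= 0:
            raise TrimintError("score_metric_weights must have positive total weight")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)


def derive_seed(master: int, *stream: int) -> int:
    """Deterministically derive a child seed below 2**31 from a master seed.

    The same (master, stream...) tuple always maps to the same child, and
    distinct tuples give statistically independent children (numpy
    SeedSequence mixing).
    """
    ss = np.random.SeedSequence([int(master) % (2**31), *[int(s) % (2**31) for s in stream]])
    return int(ss.generate_state(1, dtype=np.uint32)[0]) % (2**31)


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(
    path: str | Path,
    role: str,
    orientation: str = "features_in_rows",
    name: str | None = None,
    delimiter: str | None = None,
) -> OmicsMatrix:
    """Read a delimited-text matrix with one header row and one ID column.

    ``orientation="samples_in_rows"`` transposes the file into the canonical
    feature-by-sample layout.  Missing markers (``NA``, empty cell) are
    accepted only for ``role="CpG"``; any other non-numeric cell is a hard
    error reported with its coordinates.
    """
    path = Path(path)
    if orientation not in ("features_in_rows", "samples_in_rows"):
        raise TrimintError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(
        path,
        sep=_delimiter_for(path, delimiter),
        index_col=0,
        dtype=str,
        keep_default_na=False,
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "samples_in_rows":
        df = df.T
    missing_mask = df.isin(MISSING_MARKERS)
    numeric = df.mask(missing_mask).apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~missing_mask
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise TrimintError(
            f"non-numeric value {df.iat[r, c]!r} at feature {df.index[r]!r}, "
            f"sample {df.columns[c]!r} in {path}"
        )
    if role != "CpG" and missing_mask.to_numpy().any():
        r, c = np.argwhere(missing_mask.to_numpy())[0]
        raise TrimintError(
            f"missing value at feature {df.index[r]!r}, sample {df.columns[c]!r} in {path}; "
            "missing entries are only allowed in CpG matrices"
        )
    return OmicsMatrix(name or path.stem, role, numeric.astype(float))


def write_matrix(matrix: OmicsMatrix, path: str | Path, delimiter: str | None = None) -> None:
    """Write a matrix features-in-rows as delimited text (``NA`` for missing)."""
    path = Path(path)
    matrix.data.to_csv(
        path, sep=_delimiter_for(path, delimiter), na_rep="NA", float_format="%.10g",
        index_label="feature_id",
    )


def read_labels(path: str | Path, positive_label: str, delimiter: str | None = None) -> LabelTable:
    """Read a two-column (sample_id, label) table."""
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter), dtype=str)
    if df.shape[1] < 2:
        raise TrimintError(f"label table {path} needs two columns (sample_id, label)")
    samples = df.iloc[:, 0].astype(str)
    dup = samples[samples.duplicated()].unique().tolist()
    if dup:
        raise TrimintError(f"duplicate sample IDs in label table: {dup}")
    return LabelTable(dict(zip(samples, df.iloc[:, 1].astype(str))), positive_label)


def write_labels(labels: LabelTable, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(labels.assignments), "label": list(labels.assignments.values())}
    ).to_csv(path, sep="\t", index=False)


def read_id_list(path: str | Path) -> set[str]:
    """Read a one-ID-per-line exclusion list (blank lines and '#' comments skipped)."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def align_samples(
    matrices: Sequence[OmicsMatrix], labels: LabelTable
) -> tuple[list[OmicsMatrix], LabelTable]:
    """Restrict all matrices and labels to their common samples.

    The shared order is lexicographic, so the result does not depend on input
    file order.  Fails hard when fewer than 4 samples survive or one class
    disappears.
    """
    if not matrices:
        raise TrimintError("align_samples needs at least one matrix")
    common = set(labels.assignments)
    for m in matrices:
        common &= set(m.sample_ids)
    order = sorted(common)
    if len(order) < 4:
        raise TrimintError(
            f"only {len(order)} samples shared by all matrices and labels; need >= 4"
        )
    kept_classes = {labels.assignments[s] for s in order}
    if len(kept_classes) < 2:
        raise TrimintError(
            f"sample intersection lost a class; remaining class(es): {sorted(kept_classes)}"
        )
    sub_labels = labels.subset(order)
    return [m.subset_samples(order) for m in matrices], sub_labels


def _format_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        if np.isnan(value):
            return ""
        return f"{value:.6g}"
    if isinstance(value, (np.floating,)):
        return _format_cell(float(value))
    if isinstance(value, (np.integer,)):
        return str(int(value))
    if isinstance(value, (list, tuple)):
        return ";".join(_format_cell(v) for v in value)
    if isinstance(value, (set, frozenset)):
        return ";".join(sorted(str(v) for v in value))
    return str(value)


def write_table(
    rows: Iterable[Mapping[str, object]], path: str | Path, schema: Sequence[str]
) -> None:
    """Write records as a tab-separated table with a fixed column order.

    Floats are rendered with 6 significant digits; list-valued cells are
    semicolon-joined; missing values render as empty cells.  Row order is the
    iteration order of ``rows``, so identical inputs give byte-identical files.
    """
    buf = io.StringIO()
    buf.write("\t".join(schema) + "\n")
    for row in rows:
        missing = [c for c in schema if c not in row]
        if missing:
            raise TrimintError(f"record missing columns {missing}")
        buf.write("\t".join(_format_cell(row[c]) for c in schema) + "\n")
    Path(path).write_text(buf.getvalue())


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
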