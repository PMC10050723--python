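"""Synthetic tri-omics data with planted miRNA-CpG-gene modules.

Each module is a single latent Gaussian factor shared by one miRNA, one CpG
probe and a small gene set.  For sample ``s`` of class ``y`` the module's
latent value is ``z = effect_size * [y == positive] + N(0, 1)``, and each
planted feature is ``sign * (loading * z + sqrt(1 - loading^2) * noise_sd * N(0, 1))``
with an independently drawn sign per feature, so negative miRNA/methylation
associations occur naturally.  Background features are independent standard
normals.  With ``effect_size = 0`` the population correlation between two
features of the same module is exactly ``loading**2``, which makes pairing
and grouping thresholds analytically checkable; with a class effect the
latent variance grows and the correlation strengthens.

The CpG matrix can optionally be squashed through a logistic transform into
(0, 1) to mimic methylation beta values; this preserves association signs
but makes correlations only approximately analyzable, so unit tests keep it
off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io_config import LabelTable, OmicsMatrix, TrimintError, write_labels, write_matrix


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic dataset.

    Defaults: two classes of 60 samples, 3 planted modules of 5 genes each,
    loading 0.8 (so the null-class pair correlation is 0.64, just above the
    default pairing threshold of 0.6), class effect 2.0 latent standard
    deviations, and 200 background features per omics role.
    """

    n_samples_per_class: int = 60
    n_modules: int = 3
    genes_per_module: int = 5
    n_background: dict[str, int] = field(
        default_factory=lambda: {"miRNA": 200, "CpG": 200, "mRNA": 200}
    )
    effect_size: float = 2.0
    loading: float = 0.8
    noise_sd: float = 1.0
    cpg_bounded: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_class < 2 or self.n_modules < 0 or self.genes_per_module < 1:
            raise TrimintError("counts must be positive (>= 2 samples per class)")
        if not (0 < self.loading <= 1):
            raise TrimintError("loading must be in (0, 1]")
        if self.effect_size < 0 or self.noise_sd < 0:
            raise TrimintError("effect_size and noise_sd must be >= 0")
        if set(self.n_background) - {"miRNA", "CpG", "mRNA"}:
            raise TrimintError("n_background keys must be omics roles")


@dataclass
class PlantedModule:
    """Ground truth for one module."""

    index: int
    mirna_id: str
    cpg_id: str
    gene_ids: list[str]
    latent: np.ndarray

    @property
    def pair_name(self) -> str:
        return f"{self.mirna_id}_{self.cpg_id}"


@dataclass
class GroundTruth:
    modules: list[PlantedModule]
    class_labels: dict[str, str]
    positive_label: str

    @property
    def pair_names(self) -> set[str]:
        return {m.pair_name for m in self.modules}


POSITIVE_LABEL = "case"
NEGATIVE_LABEL = "control"


def expected_pair_correlation(loading: float) -> float:
    """Population correlation of two features sharing one unit-variance latent factor.

    Both features load with the same ``loading`` on a standard-normal latent,
    with unit total variance, giving correlation ``loading**2``.  This is the
    zero-effect-size value; a class effect adds latent variance and pushes
    the realized correlation above it.
    """
    if not (0 < loading <= 1):
        raise TrimintError("loading must be in (0, 1]")
    return loading**2


def _planted_feature(
    z: np.ndarray, loading: float, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    sign = rng.choice([-1.0, 1.0])
    eps = rng.standard_normal(z.size) * noise_sd
    return sign * (loading * z + np.sqrt(1.0 - loading**2) * eps)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate(
    spec: SimulationSpec,
) -> tuple[OmicsMatrix, OmicsMatrix, OmicsMatrix, LabelTable, GroundTruth]:
    """Draw one synthetic dataset; identical specs give identical output."""
    rng = np.random.default_rng(spec.seed)
    n = 2 * spec.n_samples_per_class
    sample_ids = [f"s{i:04d}" for i in range(n)]
    y = np.array([0] * spec.n_samples_per_class + [1] * spec.n_samples_per_class)
    labels = {
        s: (POSITIVE_LABEL if yi else NEGATIVE_LABEL) for s, yi in zip(sample_ids, y)
    }

    modules: list[PlantedModule] = []
    rows: dict[str, list[tuple[str, np.ndarray]]] = {"miRNA": [], "CpG": [], "mRNA": []}
    for m in range(spec.n_modules):
        z = spec.effect_size * y + rng.standard_normal(n)
        mirna_id = f"mirna_mod{m}"
        cpg_id = f"cg_mod{m}"
        gene_ids = [f"gene_mod{m}_{g}" for g in range(spec.genes_per_module)]
        rows["miRNA"].append((mirna_id, _planted_feature(z, spec.loading, spec.noise_sd, rng)))
        rows["CpG"].append((cpg_id, _planted_feature(z, spec.loading, spec.noise_sd, rng)))
        for gid in gene_ids:
            rows["mRNA"].append((gid, _planted_feature(z, spec.loading, spec.noise_sd, rng)))
        modules.append(PlantedModule(m, mirna_id, cpg_id, gene_ids, z))

    prefix = {"miRNA": "mirna_bg", "CpG": "cg_bg", "mRNA": "gene_bg"}
    for role in ("miRNA", "CpG", "mRNA"):
        n_bg = spec.n_background.get(role, 0)
        for i in range(n_bg):
            rows[role].append((f"{prefix[role]}{i}", rng.standard_normal(n)))

    def _matrix(role: str, name: str) -> OmicsMatrix:
        ids = [fid for fid, _ in rows[role]]
        values = (
            np.vstack([v for _, v in rows[role]])
            if rows[role]
            else np.empty((0, n))
        )
        if role == "CpG" and spec.cpg_bounded:
            values = _logistic(values)
        return OmicsMatrix(name, role, pd.DataFrame(values, index=ids, columns=sample_ids))

    A = _matrix("miRNA", "mirna")
    B = _matrix("CpG", "methylation")
    C = _matrix("mRNA", "expression")
    label_table = LabelTable(labels, POSITIVE_LABEL)
    truth = GroundTruth(modules, labels, POSITIVE_LABEL)
    return A, B, C, label_table, truth


def write_dataset(
    spec: SimulationSpec, outdir: str | Path
) -> tuple[OmicsMatrix, OmicsMatrix, OmicsMatrix, LabelTable, GroundTruth]:
    """Generate and write A.tsv, B.tsv, C.tsv, labels.tsv and truth.yaml."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    A, B, C, labels, truth = generate(spec)
    write_matrix(A, outdir / "A.tsv")
    write_matrix(B, outdir / "B.tsv")
    write_matrix(C, outdir / "C.tsv")
    write_labels(labels, outdir / "labels.tsv")
    truth_doc = {
        "positive_label": truth.positive_label,
        "modules": [
            {"mirna": m.mirna_id, "cpg": m.cpg_id, "genes": list(m.gene_ids)}
            for m in truth.modules
        ],
    }
    (outdir / "truth.yaml").write_text(yaml.safe_dump(truth_doc, sort_keys=False))
    return A, B, C, labels, truth
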