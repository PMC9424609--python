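"""Cohort ingestion, validation and the experiment manifest.

A *cohort* is one study's expression matrix (genes x samples, log2 scale)
with a binary case/control label per sample and a role in the experiment
(``training`` or ``validation``). Matrices are plain TSV with a ``gene_id``
header cell; labels are two-column TSV mapping sample ids to
``case``/``control``. The manifest is a small YAML file naming the cohort
files, their roles, and analysis options.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

ROLES = ("training", "validation")
CI_METHODS = ("bootstrap", "hanley_mcneil")


class CohortError(ValueError):
    """Raised for malformed cohort inputs."""


@dataclass
class AnalysisConfig:
    """Tunable thresholds and reproducibility knobs for a full run.

    ``es_threshold`` and ``fdr_threshold`` gate which genes are called
    differential (|pooled effect size| > 1.3 and per-direction FDR < 0.9 by
    default); ``forward_search_min_improvement`` is the minimum weighted-AUC
    gain an added gene must deliver (0 stops only when no addition strictly
    improves).
    """

    es_threshold: float = 1.3
    fdr_threshold: float = 0.9
    forward_search_min_improvement: float = 0.0
    auc_ci_method: str = "bootstrap"
    bootstrap_reps: int = 2000
    rng_seed: int = 0
    log2_already: bool = True

    def __post_init__(self) -> None:
        if not self.es_threshold > 0:
            raise ValueError("es_threshold must be > 0")
        if not 0 < self.fdr_threshold <= 1:
            raise ValueError("fdr_threshold must be in (0, 1]")
        if self.forward_search_min_improvement < 0:
            raise ValueError("forward_search_min_improvement must be >= 0")
        if self.auc_ci_method not in CI_METHODS:
            raise ValueError(f"auc_ci_method must be one of {CI_METHODS}")
        if self.bootstrap_reps < 100:
            raise ValueError("bootstrap_reps must be >= 100")


@dataclass
class Cohort:
    """One study: a log2 expression matrix plus binary labels.

    ``expression`` is genes x samples; ``labels`` is 1 for case, 0 for
    control, aligned with the matrix columns.
    """

    id: str
    expression: pd.DataFrame
    labels: pd.Series
    role: str = "training"

    def __post_init__(self) -> None:
        self.validate()

    # -- derived views ------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.expression.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expression.columns)

    @property
    def n_genes(self) -> int:
        return self.expression.shape[0]

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    @property
    def n_case(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_control(self) -> int:
        return int((self.labels == 0).sum())

    def case_matrix(self) -> pd.DataFrame:
        return self.expression.loc[:, self.labels[self.labels == 1].index]

    def control_matrix(self) -> pd.DataFrame:
        return self.expression.loc[:, self.labels[self.labels == 0].index]

    def validate(self) -> None:
        if self.role not in ROLES:
            raise CohortError(f"cohort {self.id!r}: role must be one of {ROLES}")
        if self.n_genes < 1:
            raise CohortError(f"cohort {self.id!r}: needs at least one gene")
        if self.n_samples < 2:
            raise CohortError(f"cohort {self.id!r}: needs at least two samples")
        if self.expression.index.has_duplicates:
            raise CohortError(f"cohort {self.id!r}: duplicate gene ids")
        if self.expression.columns.has_duplicates:
            raise CohortError(f"cohort {self.id!r}: duplicate sample ids")
        if len(self.labels) != self.n_samples:
            raise CohortError(f"cohort {self.id!r}: labels length != n_samples")
        if not set(self.labels.index) == set(self.expression.columns):
            raise CohortError(f"cohort {self.id!r}: label sample ids do not match matrix")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise CohortError(f"cohort {self.id!r}: labels must be 0/1")
        if self.n_case == 0 or self.n_control == 0:
            raise CohortError(
                f"cohort {self.id!r}: needs at least one case and one control"
            )
        vals = self.expression.to_numpy()
        if not np.isfinite(vals).all():
            raise CohortError(f"cohort {self.id!r}: non-finite expression values")
        # keep labels in matrix column order
        self.labels = self.labels.reindex(self.expression.columns)


def read_cohort(
    matrix_path: str | Path,
    labels_path: str | Path,
    role: str = "training",
    log2_already: bool = True,
    cohort_id: str | None = None,
) -> Cohort:
    """Read one cohort from a matrix TSV and a labels TSV.

    The matrix has a header row of sample ids (first cell ``gene_id``) and
    one row per gene. Labels map every sample id to ``case`` or ``control``.
    If ``log2_already`` is false, every value x becomes log2(x + 1).
    Duplicate gene ids are collapsed by averaging their rows.
    """
    matrix_path = Path(matrix_path)
    labels_path = Path(labels_path)
    expr = pd.read_csv(matrix_path, sep="\t", index_col=0)
    expr.index = expr.index.astype(str)
    expr.columns = expr.columns.astype(str)

    # locate non-numeric cells precisely before failing
    numeric = expr.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & expr.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise CohortError(
            f"{matrix_path}: non-numeric cell at gene {expr.index[r]!r}, "
            f"sample {expr.columns[c]!r}: {expr.iat[r, c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise CohortError(
            f"{matrix_path}: missing value at gene {numeric.index[r]!r}, "
            f"sample {numeric.columns[c]!r}"
        )
    expr = numeric.astype(float)

    if expr.index.has_duplicates:
        n_dup = int(expr.index.duplicated().sum())
        logger.info(
            "%s: collapsing %d duplicate gene id rows by averaging", matrix_path, n_dup
        )
        expr = expr.groupby(level=0, sort=False).mean()

    if not log2_already:
        if (expr.to_numpy() < 0).any():
            raise CohortError(f"{matrix_path}: negative values cannot be log2(x+1) transformed")
        expr = np.log2(expr + 1.0)

    lab = pd.read_csv(labels_path, sep="\t", dtype=str)
    required = {"sample_id", "class"}
    if not required <= set(lab.columns):
        raise CohortError(f"{labels_path}: labels file needs columns {sorted(required)}")
    lab = lab.set_index("sample_id")["class"]
    missing = [s for s in expr.columns if s not in lab.index]
    if missing:
        raise CohortError(f"{labels_path}: no label for sample {missing[0]!r}")
    unknown = set(lab.unique()) - {"case", "control"}
    if unknown:
        raise CohortError(f"{labels_path}: unknown class value {sorted(unknown)[0]!r}")
    labels = lab.reindex(expr.columns).map({"case": 1, "control": 0}).astype(int)

    cid = cohort_id or matrix_path.stem
    return Cohort(id=cid, expression=expr, labels=labels, role=role)


def write_cohort(cohort: Cohort, matrix_path: str | Path, labels_path: str | Path) -> None:
    """Write a cohort back to the TSV formats ``read_cohort`` consumes."""
    expr = cohort.expression.copy()
    expr.index.name = "gene_id"
    # repr-based float formatting keeps the read->write->read round trip exact
    expr.to_csv(matrix_path, sep="\t", float_format=None)
    lab = pd.DataFrame(
        {
            "sample_id": cohort.sample_ids,
            "class": ["case" if v == 1 else "control" for v in cohort.labels],
        }
    )
    lab.to_csv(labels_path, sep="\t", index=False)


def intersect_genes(cohorts: Sequence[Cohort]) -> list[Cohort]:
    """Restrict every cohort to the sorted intersection of gene ids."""
    if not cohorts:
        raise CohortError("need at least one cohort")
    common = set(cohorts[0].gene_ids)
    for c in cohorts[1:]:
        common &= set(c.gene_ids)
    if not common:
        raise CohortError("gene universes have empty intersection")
    order = sorted(common)
    return [
        Cohort(
            id=c.id,
            expression=c.expression.loc[order],
            labels=c.labels.copy(),
            role=c.role,
        )
        for c in cohorts
    ]


@dataclass
class Manifest:
    """Paths to cohort files, their roles, and the analysis options."""

    cohorts: list[dict] = field(default_factory=list)  # matrix, labels, role, id
    options: AnalysisConfig = field(default_factory=AnalysisConfig)
    base_dir: Path = field(default_factory=Path)

    def __post_init__(self) -> None:
        if not any(c["role"] == "training" for c in self.cohorts):
            raise CohortError("manifest needs at least one training cohort")

    def load_cohorts(self, role: str | None = None) -> list[Cohort]:
        """Read cohorts, optionally only those with the given role.

        Reading lazily per role means validation files need not exist at
        discovery time.
        """
        out = []
        for entry in self.cohorts:
            if role is not None and entry["role"] != role:
                continue
            out.append(
                read_cohort(
                    self.base_dir / entry["matrix"],
                    self.base_dir / entry["labels"],
                    role=entry["role"],
                    log2_already=self.options.log2_already,
                    cohort_id=entry.get("id"),
                )
            )
        return out


def load_manifest(path: str | Path) -> Manifest:
    """Parse a YAML manifest; relative cohort paths resolve against it."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "cohorts" not in doc:
        raise CohortError(f"{path}: manifest must be a mapping with a 'cohorts' list")
    cohorts = []
    for i, entry in enumerate(doc["cohorts"]):
        if not {"matrix", "labels", "role"} <= set(entry):
            raise CohortError(f"{path}: cohort entry {i} needs matrix, labels, role")
        if entry["role"] not in ROLES:
            raise CohortError(f"{path}: cohort entry {i}: bad role {entry['role']!r}")
        cohorts.append(dict(entry))
    opts = doc.get("options") or {}
    valid = {f.name for f in fields(AnalysisConfig)}
    unknown = set(opts) - valid
    if unknown:
        raise CohortError(f"{path}: unknown option {sorted(unknown)[0]!r}")
    config = AnalysisConfig(**opts)
    return Manifest(cohorts=cohorts, options=config, base_dir=path.parent)


def save_manifest(manifest: Manifest, path: str | Path) -> None:
    cfg = manifest.options
    doc = {
        "cohorts": manifest.cohorts,
        "options": {f.name: getattr(cfg, f.name) for f in fields(AnalysisConfig)},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def with_labels(cohort: Cohort, labels: pd.Series | np.ndarray) -> Cohort:
    """Return a copy of the cohort with replacement labels (same samples)."""
    new = pd.Series(np.asarray(labels), index=cohort.expression.columns)
    return replace(cohort, labels=new)
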