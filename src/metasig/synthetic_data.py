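"""Simulated multi-cohort case/control expression studies with known truth.

The generator mirrors the random-effects model the analysis assumes, on the
log2 scale: for cohort i, gene j, sample s,

    x_ijs = mu_j + b_ij + y_s * (delta_j + u_ij) * noise_sd + eps_ijs

where mu_j is a fixed per-gene baseline, b_ij ~ N(0, baseline_shift_sd^2) is
a cohort-specific offset, y_s is the case indicator, delta_j is the true
standardized effect of signal genes (0 for nulls), u_ij ~ N(0, tau2_true)
adds between-cohort effect heterogeneity for signal genes, and
eps ~ N(0, noise_sd^2). Because the class shift is scaled by noise_sd, each
delta_j is directly on the Hedges-g scale and comparable to the ES gate.

The default preset emulates the study design the analysis targets: three
cohorts of 36, 12 (training) and 6 (validation) samples, a few thousand
genes, a small set of large-effect signal genes, and modest between-cohort
heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_cohorts import Cohort, Manifest, save_manifest, write_cohort
from .meta_analysis import MetaGeneResult
from .signature_search import Signature


@dataclass
class SimulationSpec:
    """Parameters of one simulated multi-cohort study.

    ``true_effects`` gives the signed standardized effect per signal gene;
    left as None it alternates +delta_scale / -delta_scale. Cohort sizes are
    (n_case, n_control) pairs; roles mark which cohorts are training vs
    validation.
    """

    n_genes: int = 2000
    n_signal_genes: int = 20
    delta_scale: float = 2.0
    true_effects: Sequence[float] | None = None
    tau2_true: float = 0.25
    cohort_sizes: Sequence[tuple[int, int]] = ((18, 18), (6, 6), (3, 3))
    cohort_roles: Sequence[str] = ("training", "training", "validation")
    cohort_baseline_shift_sd: float = 0.5
    noise_sd: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0 <= self.n_signal_genes <= self.n_genes:
            raise ValueError("n_signal_genes must lie in [0, n_genes]")
        if self.tau2_true < 0:
            raise ValueError("tau2_true must be >= 0")
        if self.cohort_baseline_shift_sd < 0:
            raise ValueError("cohort_baseline_shift_sd must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if len(self.cohort_roles) != len(self.cohort_sizes):
            raise ValueError("cohort_roles length must match cohort_sizes")
        for n1, n2 in self.cohort_sizes:
            if n1 < 2 or n2 < 2:
                raise ValueError("cohort_sizes: each class needs >= 2 samples")
        if self.true_effects is not None:
            if len(self.true_effects) != self.n_signal_genes:
                raise ValueError("true_effects length must equal n_signal_genes")

    def effects(self) -> np.ndarray:
        if self.true_effects is not None:
            return np.asarray(self.true_effects, dtype=float)
        signs = np.where(np.arange(self.n_signal_genes) % 2 == 0, 1.0, -1.0)
        return signs * self.delta_scale


@dataclass
class SimulatedStudy:
    cohorts: list[Cohort]
    truth: pd.DataFrame  # gene_id, is_signal, delta, direction
    spec: SimulationSpec = field(repr=False, default=None)

    @property
    def training(self) -> list[Cohort]:
        return [c for c in self.cohorts if c.role == "training"]

    @property
    def validation(self) -> list[Cohort]:
        return [c for c in self.cohorts if c.role == "validation"]

    def signal_genes(self) -> pd.DataFrame:
        return self.truth[self.truth["is_signal"]]


def simulate_study(spec: SimulationSpec) -> SimulatedStudy:
    """Draw one study from the spec; bit-identical for the same seed."""
    rng = np.random.default_rng(spec.rng_seed)
    n_genes = spec.n_genes
    gene_ids = [f"G{j:05d}" for j in range(n_genes)]

    delta = np.zeros(n_genes)
    signal_idx = rng.choice(n_genes, size=spec.n_signal_genes, replace=False)
    signal_idx.sort()
    delta[signal_idx] = spec.effects()

    mu = rng.uniform(4.0, 12.0, size=n_genes)  # plausible log2 intensities

    cohorts = []
    for i, ((n_case, n_control), role) in enumerate(
        zip(spec.cohort_sizes, spec.cohort_roles)
    ):
        cid = f"cohort{i + 1}"
        n = n_case + n_control
        y = np.concatenate([np.ones(n_case), np.zeros(n_control)])
        b = rng.normal(0.0, spec.cohort_baseline_shift_sd, size=n_genes)
        u = np.zeros(n_genes)
        if spec.tau2_true > 0 and spec.n_signal_genes > 0:
            u[signal_idx] = rng.normal(
                0.0, np.sqrt(spec.tau2_true), size=spec.n_signal_genes
            )
        eps = rng.normal(0.0, spec.noise_sd, size=(n_genes, n))
        x = (
            (mu + b)[:, None]
            + np.outer((delta + u) * spec.noise_sd, y)
            + eps
        )
        expr = pd.DataFrame(
            x, index=gene_ids, columns=[f"{cid}_S{s:03d}" for s in range(n)]
        )
        expr.index.name = "gene_id"
        labels = pd.Series(y.astype(int), index=expr.columns)
        cohorts.append(Cohort(id=cid, expression=expr, labels=labels, role=role))

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "is_signal": delta != 0,
            "delta": delta,
            "direction": np.where(delta > 0, "up", np.where(delta < 0, "down", "none")),
        }
    )
    return SimulatedStudy(cohorts=cohorts, truth=truth, spec=spec)


def truth_recovery_report(
    study: SimulatedStudy,
    results: Sequence[MetaGeneResult],
    signature: Signature | None = None,
) -> dict:
    """How well the pipeline recovered the planted ground truth.

    Sensitivity counts signal genes flagged with the *correct* direction;
    specificity counts null genes left unflagged. Effect bias compares each
    signal gene's pooled estimate with its true delta.
    """
    if signature is not None and len(signature) == 0:
        raise ValueError("empty signature")
    truth = study.truth.set_index("gene_id")
    res_genes = {r.gene_id for r in results}
    if not res_genes <= set(truth.index):
        raise ValueError("results contain genes outside the simulated universe")

    flags = {r.gene_id: r.direction for r in results}
    es = {r.gene_id: r.pooled_es for r in results}
    tau2 = {r.gene_id: r.tau2 for r in results}

    signal = truth[truth["is_signal"]]
    nulls = truth[~truth["is_signal"]]
    correct = sum(
        flags.get(g, "none") == signal.loc[g, "direction"] for g in signal.index
    )
    sensitivity = correct / len(signal) if len(signal) else float("nan")
    true_neg = sum(flags.get(g, "none") == "none" for g in nulls.index)
    specificity = true_neg / len(nulls) if len(nulls) else float("nan")

    seen = [g for g in signal.index if g in es]
    bias = [es[g] - signal.loc[g, "delta"] for g in seen]
    # sign-aligned estimate: +delta and -delta genes both contribute +|es|
    aligned = [es[g] * np.sign(signal.loc[g, "delta"]) for g in seen]
    report = {
        "n_signal": int(len(signal)),
        "n_null": int(len(nulls)),
        "sensitivity": float(sensitivity),
        "specificity": float(specificity),
        "mean_es_bias": float(np.mean(bias)) if bias else float("nan"),
        "mean_signed_pooled_es_signal": float(np.mean(aligned)) if aligned else float("nan"),
        "median_tau2_signal": float(np.median([tau2[g] for g in seen])) if seen else float("nan"),
    }
    if signature is not None:
        sig_genes = set(signature.genes)
        report["signature_size"] = len(sig_genes)
        report["signature_within_signal"] = bool(
            sig_genes <= set(signal.index)
        )
    return report


def write_study(study: SimulatedStudy, out_dir: str | Path) -> Path:
    """Write cohort TSVs, the truth table and a ready-to-run manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for cohort in study.cohorts:
        m = out_dir / f"{cohort.id}_matrix.tsv"
        l = out_dir / f"{cohort.id}_labels.tsv"
        write_cohort(cohort, m, l)
        entries.append(
            {"matrix": m.name, "labels": l.name, "role": cohort.role, "id": cohort.id}
        )
    study.truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    manifest = Manifest(cohorts=entries, base_dir=out_dir)
    manifest.options.rng_seed = study.spec.rng_seed if study.spec else 0
    manifest_path = out_dir / "manifest.yaml"
    save_manifest(manifest, manifest_path)
    return manifest_path
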