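"""Greedy forward selection of a diagnostic gene signature.

The diagnostic *meta-score* of a sample is the mean log2 expression of the
signature's up-regulated genes minus the mean of its down-regulated genes
(mean over an empty set is 0). Forward search seeds with the single gene
whose score best separates cases from controls by sample-size-weighted AUC
across the training cohorts, then repeatedly adds the candidate giving the
largest weighted AUC, stopping when the best addition improves by no more
than ``min_improvement``. Each candidate's up/down placement is fixed by its
meta-analysis direction. Ties break by larger |pooled effect|, then gene id,
so the search is fully deterministic.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .diagnostics import ScoredCohort, auc_mann_whitney
from .io_cohorts import Cohort
from .meta_analysis import MetaGeneResult

logger = logging.getLogger(__name__)


@dataclass
class Signature:
    """Disjoint up- and down-regulated gene sets with the search trace."""

    up_genes: frozenset[str]
    down_genes: frozenset[str]
    search_trace: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.up_genes = frozenset(self.up_genes)
        self.down_genes = frozenset(self.down_genes)
        if self.up_genes & self.down_genes:
            raise ValueError("up and down gene sets must be disjoint")
        if not (self.up_genes or self.down_genes):
            raise ValueError("signature must contain at least one gene")

    @property
    def genes(self) -> frozenset[str]:
        return self.up_genes | self.down_genes

    def __len__(self) -> int:
        return len(self.genes)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "up": sorted(self.up_genes),
            "down": sorted(self.down_genes),
            "trace": [[g, a] for g, a in self.search_trace],
        }
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "Signature":
        doc = json.loads(Path(path).read_text())
        return cls(
            up_genes=frozenset(doc["up"]),
            down_genes=frozenset(doc["down"]),
            search_trace=[(g, float(a)) for g, a in doc.get("trace", [])],
        )


def meta_score(cohort: Cohort, signature: Signature) -> ScoredCohort:
    """Score each sample: mean(up genes) - mean(down genes), log2 scale.

    Signature genes absent from the cohort are excluded with a warning; if
    every signature gene is absent that is a hard error.
    """
    present = set(cohort.expression.index)
    up = sorted(signature.up_genes & present)
    down = sorted(signature.down_genes & present)
    missing = sorted(signature.genes - present)
    if missing:
        if not (up or down):
            raise KeyError(
                f"cohort {cohort.id!r}: no signature gene present (missing {missing})"
            )
        warnings.warn(
            f"cohort {cohort.id!r}: signature genes absent, excluded: {missing}",
            stacklevel=2,
        )
        logger.warning("cohort %s: excluded absent signature genes %s", cohort.id, missing)

    n = cohort.n_samples
    up_mean = cohort.expression.loc[up].mean(axis=0).to_numpy() if up else np.zeros(n)
    down_mean = (
        cohort.expression.loc[down].mean(axis=0).to_numpy() if down else np.zeros(n)
    )
    return ScoredCohort(cohort.id, up_mean - down_mean, cohort.labels.to_numpy())


def weighted_auc(signature: Signature, cohorts: Sequence[Cohort]) -> float:
    """Sample-size-weighted mean of per-cohort meta-score AUCs."""
    if not cohorts:
        raise ValueError("need at least one cohort")
    total_w = 0.0
    acc = 0.0
    for cohort in cohorts:
        scored = meta_score(cohort, signature)
        auc = auc_mann_whitney(scored.case_scores, scored.control_scores)
        acc += cohort.n_samples * auc
        total_w += cohort.n_samples
    return acc / total_w


def _extend(signature: Signature | None, gene: str, direction: str) -> Signature:
    up = set(signature.up_genes) if signature else set()
    down = set(signature.down_genes) if signature else set()
    (up if direction == "up" else down).add(gene)
    return Signature(frozenset(up), frozenset(down))


def forward_search(
    candidates: Sequence[MetaGeneResult],
    cohorts: Sequence[Cohort],
    min_improvement: float = 0.0,
) -> Signature:
    """Greedy forward selection maximizing weighted AUC.

    Candidates must carry a direction (up/down) from the meta-analysis;
    the direction is never re-optimized during the search.
    """
    cands = [c for c in candidates if c.direction in ("up", "down")]
    if not cands:
        raise ValueError("no candidates with an up/down direction")
    if min_improvement < 0:
        raise ValueError("min_improvement must be >= 0")

    # deterministic tie-break order: larger |pooled_es| first, then gene id
    by_gene = {c.gene_id: c for c in cands}
    order = sorted(by_gene.values(), key=lambda c: (-abs(c.pooled_es), c.gene_id))

    current: Signature | None = None
    current_auc = -np.inf
    trace: list[tuple[str, float]] = []
    remaining = list(order)

    while remaining:
        best_gene = None
        best_auc = -np.inf
        best_sig = None
        for cand in remaining:  # iteration order encodes the tie-break
            sig = _extend(current, cand.gene_id, cand.direction)
            auc = weighted_auc(sig, cohorts)
            if auc > best_auc:
                best_gene, best_auc, best_sig = cand, auc, sig
        if current is None:
            # seeding step: always take the best singleton
            current, current_auc = best_sig, best_auc
            trace.append((best_gene.gene_id, best_auc))
            remaining.remove(best_gene)
            continue
        if best_auc - current_auc <= min_improvement:
            break
        current, current_auc = best_sig, best_auc
        trace.append((best_gene.gene_id, best_auc))
        remaining.remove(best_gene)

    logger.info(
        "forward search selected %d genes (weighted AUC %.4f): %s",
        len(current),
        current_auc,
        " -> ".join(g for g, _ in trace),
    )
    return Signature(current.up_genes, current.down_genes, trace)


def write_scores(scored: ScoredCohort, sample_ids: Sequence[str], path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "score": scored.scores,
            "class": ["case" if y == 1 else "control" for y in scored.labels],
        }
    ).to_csv(path, sep="\t", index=False)
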