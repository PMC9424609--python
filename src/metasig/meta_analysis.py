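"""Random-effects pooling and significance filtering across cohorts.

Per gene, per-cohort Hedges' g values are pooled with the DerSimonian–Laird
method-of-moments random-effects model. Per-cohort one-sided p-values (one
per direction) are combined across cohorts with Fisher's method and adjusted
across genes with Benjamini–Hochberg, separately per direction. A gene is
called *up* when its pooled effect exceeds the ES threshold and its
up-direction FDR clears the FDR threshold; symmetrically for *down*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .effect_size import GeneEffect, cohort_effects
from .io_cohorts import AnalysisConfig, Cohort, intersect_genes

logger = logging.getLogger(__name__)

_TINY_P = np.finfo(float).tiny


class DLResult(NamedTuple):
    pooled_es: float
    se_pooled: float
    tau2: float
    Q: float
    z: float
    p_pooled: float


@dataclass(frozen=True)
class MetaGeneResult:
    gene_id: str
    k: int
    pooled_es: float
    se_pooled: float
    tau2: float
    Q: float
    z: float
    p_pooled: float
    fisher_p_up: float
    fisher_p_down: float
    fdr_up: float
    fdr_down: float
    direction: str  # up | down | none


def dersimonian_laird(effects: Sequence[tuple[float, float]]) -> DLResult:
    """DerSimonian–Laird random-effects pooling of (effect, variance) pairs.

    With fixed weights w_i = 1/v_i: Q = sum w_i (g_i - ES_FE)^2 and
    tau2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)); the pooled
    estimate then uses w*_i = 1/(v_i + tau2). A single study passes through
    with tau2 = 0.
    """
    if len(effects) == 0:
        raise ValueError("need at least one effect")
    g = np.array([e[0] for e in effects], dtype=float)
    v = np.array([e[1] for e in effects], dtype=float)
    if (v <= 0).any():
        raise ValueError("all variances must be positive")
    k = len(g)
    w = 1.0 / v
    es_fe = float(np.sum(w * g) / np.sum(w))
    q = float(np.sum(w * (g - es_fe) ** 2))
    if k >= 2:
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    else:
        tau2 = 0.0
    w_star = 1.0 / (v + tau2)
    pooled = float(np.sum(w_star * g) / np.sum(w_star))
    se = float(np.sum(w_star) ** -0.5)
    z = pooled / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return DLResult(pooled, se, tau2, q, float(z), p)


def fisher_combine(p_values: Sequence[float]) -> float:
    """Fisher's combined probability: -2 sum(ln p) ~ chi-square(2k)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if (p > 1).any() or (p < 0).any():
        raise ValueError("p-values must lie in [0, 1]")
    if (p == 0).any():
        logger.warning("clamping %d zero p-values to %.3e", int((p == 0).sum()), _TINY_P)
        p = np.clip(p, _TINY_P, 1.0)
    x2 = -2.0 * np.sum(np.log(p))
    return float(stats.chi2.sf(x2, df=2 * p.size))


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def run_meta(
    cohorts: Sequence[Cohort],
    config: AnalysisConfig | None = None,
) -> list[MetaGeneResult]:
    """Full per-gene meta-analysis over training cohorts.

    Cohorts are restricted to their common gene universe first. Genes with
    zero pooled variance in every cohort are dropped (none contribute an
    effect); genes degenerate in only some cohorts are pooled over the
    remaining ones.
    """
    config = config or AnalysisConfig()
    if not cohorts:
        raise ValueError("need at least one cohort")
    cohorts = intersect_genes(list(cohorts))

    per_gene: dict[str, list[GeneEffect]] = {g: [] for g in cohorts[0].gene_ids}
    for cohort in cohorts:
        effects, _skipped = cohort_effects(cohort)
        for eff in effects:
            per_gene[eff.gene_id].append(eff)

    genes = [g for g, effs in per_gene.items() if effs]
    dropped = len(per_gene) - len(genes)
    if dropped:
        logger.info("run_meta: dropped %d genes degenerate in every cohort", dropped)

    rows = []
    fisher_up = np.empty(len(genes))
    fisher_down = np.empty(len(genes))
    for i, gene in enumerate(genes):
        effs = per_gene[gene]
        dl = dersimonian_laird([(e.g, e.var_g) for e in effs])
        z_i = np.array([e.g / np.sqrt(e.var_g) for e in effs])
        p_up = stats.norm.sf(z_i)  # evidence the gene is elevated in cases
        p_down = stats.norm.cdf(z_i)
        fisher_up[i] = fisher_combine(p_up)
        fisher_down[i] = fisher_combine(p_down)
        rows.append((gene, len(effs), dl))

    fdr_up = benjamini_hochberg(fisher_up)
    fdr_down = benjamini_hochberg(fisher_down)

    results = []
    for i, (gene, k, dl) in enumerate(rows):
        if dl.pooled_es > config.es_threshold and fdr_up[i] < config.fdr_threshold:
            direction = "up"
        elif dl.pooled_es < -config.es_threshold and fdr_down[i] < config.fdr_threshold:
            direction = "down"
        else:
            direction = "none"
        results.append(
            MetaGeneResult(
                gene_id=gene,
                k=k,
                pooled_es=dl.pooled_es,
                se_pooled=dl.se_pooled,
                tau2=dl.tau2,
                Q=dl.Q,
                z=dl.z,
                p_pooled=dl.p_pooled,
                fisher_p_up=float(fisher_up[i]),
                fisher_p_down=float(fisher_down[i]),
                fdr_up=float(fdr_up[i]),
                fdr_down=float(fdr_down[i]),
                direction=direction,
            )
        )
    return results


def meta_table(results: Sequence[MetaGeneResult]) -> pd.DataFrame:
    """Meta-analysis results as one tidy row per gene."""
    return pd.DataFrame([r.__dict__ for r in results])


def flagged(results: Sequence[MetaGeneResult]) -> list[MetaGeneResult]:
    """Genes called differential (direction != none)."""
    return [r for r in results if r.direction != "none"]


def write_meta(results: Sequence[MetaGeneResult], path, flagged_path=None) -> None:
    table = meta_table(results)
    table.to_csv(path, sep="\t", index=False)
    if flagged_path is not None:
        table[table["direction"] != "none"].to_csv(flagged_path, sep="\t", index=False)
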