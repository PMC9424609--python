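"""ROC/AUC evaluation of diagnostic scores, with confidence intervals.

AUC is the Mann–Whitney probability that a random case scores above a random
control (ties count half). Confidence intervals are stratified percentile
bootstrap by default — it behaves sensibly at the AUC = 1 boundary — with the
Hanley–McNeil normal interval as an alternative. The summary AUC across
cohorts is the sample-size-weighted mean of per-cohort AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import mannwhitneyu, norm
from sklearn.metrics import roc_curve

from .io_cohorts import Cohort


@dataclass
class ScoredCohort:
    """Per-sample diagnostic scores with labels for one cohort."""

    cohort_id: str
    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels must have the same length")
        if not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite")

    @property
    def case_scores(self) -> np.ndarray:
        return self.scores[self.labels == 1]

    @property
    def control_scores(self) -> np.ndarray:
        return self.scores[self.labels == 0]

    @property
    def n(self) -> int:
        return self.scores.size


@dataclass
class ROCResult:
    cohort_id: str
    auc: float
    ci_low: float
    ci_high: float
    roc_points: np.ndarray  # (n, 2) array of (fpr, tpr)
    n_case: int
    n_control: int
    thresholds: np.ndarray = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "cohort_id": self.cohort_id,
            "auc": self.auc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_case": self.n_case,
            "n_control": self.n_control,
        }


def auc_mann_whitney(scores_case, scores_control) -> float:
    """AUC as the normalized Mann–Whitney U statistic (ties count 0.5)."""
    case = np.asarray(scores_case, dtype=float)
    control = np.asarray(scores_control, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValueError("both classes must be non-empty")
    u = mannwhitneyu(case, control, alternative="two-sided").statistic
    return float(u) / (case.size * control.size)


def roc_points(scores_case, scores_control) -> tuple[np.ndarray, np.ndarray]:
    """Full ROC polyline from (0,0) to (1,1) plus thresholds."""
    y = np.concatenate([np.ones(len(scores_case)), np.zeros(len(scores_control))])
    s = np.concatenate([scores_case, scores_control])
    fpr, tpr, thr = roc_curve(y, s, drop_intermediate=False)
    return np.column_stack([fpr, tpr]), thr


def _bootstrap_ci(
    scores_case: np.ndarray,
    scores_control: np.ndarray,
    reps: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    n1, n2 = scores_case.size, scores_control.size
    aucs = np.empty(reps)
    for b in range(reps):
        case_b = scores_case[rng.integers(0, n1, n1)]
        control_b = scores_control[rng.integers(0, n2, n2)]
        aucs[b] = auc_mann_whitney(case_b, control_b)
    low, high = np.percentile(aucs, [2.5, 97.5])
    return float(np.clip(low, 0, 1)), float(np.clip(high, 0, 1))


def _hanley_mcneil_ci(auc: float, n1: int, n2: int) -> tuple[float, float]:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    se2 = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n2 - 1) * (q2 - auc**2)) / (
        n1 * n2
    )
    half = norm.ppf(0.975) * np.sqrt(max(se2, 0.0))
    return float(np.clip(auc - half, 0, 1)), float(np.clip(auc + half, 0, 1))


def auc_confidence_interval(
    scores_case,
    scores_control,
    method: str = "bootstrap",
    reps: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """95% CI for the AUC, clipped to [0, 1].

    ``bootstrap`` resamples cases and controls separately (stratified), so
    no resample ever loses a class; ``hanley_mcneil`` is the classic normal
    interval.
    """
    case = np.asarray(scores_case, dtype=float)
    control = np.asarray(scores_control, dtype=float)
    if method == "bootstrap":
        if reps < 100:
            raise ValueError("bootstrap needs reps >= 100")
        rng = np.random.default_rng(seed)
        return _bootstrap_ci(case, control, reps, rng)
    if method == "hanley_mcneil":
        auc = auc_mann_whitney(case, control)
        return _hanley_mcneil_ci(auc, case.size, control.size)
    raise ValueError(f"unknown CI method {method!r}")


def roc_result(
    scored: ScoredCohort,
    ci_method: str = "bootstrap",
    reps: int = 2000,
    seed: int = 0,
) -> ROCResult:
    """Per-cohort ROC curve, AUC and CI for one scored cohort."""
    case, control = scored.case_scores, scored.control_scores
    auc = auc_mann_whitney(case, control)
    lo, hi = auc_confidence_interval(case, control, ci_method, reps, seed)
    pts, thr = roc_points(case, control)
    return ROCResult(
        cohort_id=scored.cohort_id,
        auc=auc,
        ci_low=lo,
        ci_high=hi,
        roc_points=pts,
        n_case=case.size,
        n_control=control.size,
        thresholds=thr,
    )


def summary_auc(
    scored: Sequence[ScoredCohort],
    ci_method: str = "bootstrap",
    reps: int = 2000,
    seed: int = 0,
) -> ROCResult:
    """Pooled discrimination across cohorts.

    Point estimate: sample-size-weighted mean of per-cohort AUCs. CI:
    cohort-stratified bootstrap (cases and controls resampled within each
    cohort). The attached ROC points come from the concatenated scores and
    are illustrative only; the AUC field is the weighted mean.
    """
    if not scored:
        raise ValueError("need at least one scored cohort")
    weights = np.array([s.n for s in scored], dtype=float)
    aucs = np.array([auc_mann_whitney(s.case_scores, s.control_scores) for s in scored])
    point = float(np.sum(weights * aucs) / np.sum(weights))

    if ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        boot = np.empty(reps)
        for b in range(reps):
            vals = np.empty(len(scored))
            for i, s in enumerate(scored):
                c, t = s.case_scores, s.control_scores
                vals[i] = auc_mann_whitney(
                    c[rng.integers(0, c.size, c.size)],
                    t[rng.integers(0, t.size, t.size)],
                )
            boot[b] = np.sum(weights * vals) / np.sum(weights)
        lo, hi = (float(np.clip(x, 0, 1)) for x in np.percentile(boot, [2.5, 97.5]))
    elif ci_method == "hanley_mcneil":
        n1 = sum(s.case_scores.size for s in scored)
        n2 = sum(s.control_scores.size for s in scored)
        lo, hi = _hanley_mcneil_ci(point, n1, n2)
    else:
        raise ValueError(f"unknown CI method {ci_method!r}")

    all_case = np.concatenate([s.case_scores for s in scored])
    all_control = np.concatenate([s.control_scores for s in scored])
    pts, thr = roc_points(all_case, all_control)
    return ROCResult(
        cohort_id="summary",
        auc=point,
        ci_low=lo,
        ci_high=hi,
        roc_points=pts,
        n_case=all_case.size,
        n_control=all_control.size,
        thresholds=thr,
    )


def single_gene_auc(
    gene_id: str,
    cohorts: Sequence[Cohort],
    direction: str = "up",
    ci_method: str = "bootstrap",
    reps: int = 2000,
    seed: int = 0,
) -> list[ROCResult]:
    """Evaluate one gene's expression as the diagnostic score.

    ``direction='down'`` negates the expression so that higher score still
    means case-like. Returns per-cohort results followed by the summary.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    sign = 1.0 if direction == "up" else -1.0
    scored = []
    for cohort in cohorts:
        if gene_id not in cohort.expression.index:
            raise KeyError(f"gene {gene_id!r} absent from cohort {cohort.id!r}")
        scores = sign * cohort.expression.loc[gene_id].to_numpy(dtype=float)
        scored.append(
            ScoredCohort(cohort.id, scores, cohort.labels.to_numpy())
        )
    results = [roc_result(s, ci_method, reps, seed) for s in scored]
    results.append(summary_auc(scored, ci_method, reps, seed))
    return results


def write_roc_points(result: ROCResult, path) -> None:
    import pandas as pd

    df = pd.DataFrame(result.roc_points, columns=["fpr", "tpr"])
    if result.thresholds is not None:
        df["threshold"] = result.thresholds
    df.to_csv(path, sep="\t", index=False)
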