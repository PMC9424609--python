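"""Scikit-learn estimator facade over the discovery pipeline.

``MetaSignatureClassifier.fit`` takes the usual (X, y) — samples x genes,
binary labels — plus an optional ``cohorts`` grouping vector, splits the data
into per-cohort studies, runs the random-effects meta-analysis and the greedy
forward search, and freezes the resulting signature. ``decision_function``
returns the meta-score (mean up-gene expression minus mean down-gene
expression) and ``predict`` thresholds it at the Youden-optimal cut found on
the training scores. The estimator composes with sklearn model selection and
pipelines via get_params/set_params/clone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_curve
from sklearn.utils.validation import check_is_fitted

from .io_cohorts import AnalysisConfig, Cohort
from .meta_analysis import flagged, run_meta
from .signature_search import Signature, forward_search, meta_score


class MetaSignatureClassifier(ClassifierMixin, BaseEstimator):
    """Diagnostic gene-signature classifier discovered by multi-cohort meta-analysis.

    Parameters
    ----------
    es_threshold : float, default 1.3
        Minimum |pooled Hedges' g| for a gene to become a candidate.
    fdr_threshold : float, default 0.9
        Per-direction Fisher/Benjamini-Hochberg FDR gate for candidates.
    min_improvement : float, default 0.0
        Minimum weighted-AUC gain required to add a gene during forward search.

    Attributes
    ----------
    signature_ : Signature
        Frozen up/down gene sets with the search trace.
    meta_results_ : list of MetaGeneResult
        Full per-gene meta-analysis results.
    threshold_ : float
        Decision threshold on the meta-score (Youden J on training scores).
    feature_names_in_ : ndarray of str
        Gene ids seen during fit.
    """

    def __init__(
        self,
        es_threshold: float = 1.3,
        fdr_threshold: float = 0.9,
        min_improvement: float = 0.0,
    ):
        self.es_threshold = es_threshold
        self.fdr_threshold = fdr_threshold
        self.min_improvement = min_improvement

    # -- helpers --------------------------------------------------------
    def _to_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            df = X.copy()
            df.columns = df.columns.astype(str)
            return df
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional (samples x genes)")
        return pd.DataFrame(X, columns=[f"x{j}" for j in range(X.shape[1])])

    def _make_cohorts(self, df: pd.DataFrame, y: np.ndarray, groups) -> list[Cohort]:
        if groups is None:
            groups = np.zeros(len(df), dtype=int)
        groups = np.asarray(groups)
        cohorts = []
        for gid in pd.unique(groups):
            mask = groups == gid
            sub = df.loc[mask]
            expr = sub.T
            expr.columns = [f"{gid}_s{i}" for i in range(mask.sum())]
            labels = pd.Series(y[mask].astype(int), index=expr.columns)
            cohorts.append(Cohort(id=str(gid), expression=expr, labels=labels))
        return cohorts

    # -- sklearn API ----------------------------------------------------
    def fit(self, X, y, cohorts=None):
        """Discover the signature on (X, y), optionally split by cohort.

        ``cohorts`` is a per-sample grouping vector; omitted, all samples
        form a single cohort.
        """
        df = self._to_frame(X)
        y = np.asarray(y)
        classes = np.unique(y)
        if not set(classes) <= {0, 1}:
            raise ValueError("y must be binary 0/1 (control/case)")
        if len(classes) < 2:
            raise ValueError("y must contain both classes")
        if len(y) != len(df):
            raise ValueError("X and y length mismatch")

        config = AnalysisConfig(
            es_threshold=self.es_threshold,
            fdr_threshold=self.fdr_threshold,
            forward_search_min_improvement=self.min_improvement,
        )
        cohort_list = self._make_cohorts(df, y, cohorts)
        self.meta_results_ = run_meta(cohort_list, config)
        candidates = flagged(self.meta_results_)
        if not candidates:
            raise ValueError(
                "no gene passed the ES/FDR filter; relax es_threshold/fdr_threshold"
            )
        self.signature_ = forward_search(
            candidates, cohort_list, self.min_improvement
        )
        self.classes_ = np.array([0, 1])
        self.feature_names_in_ = np.asarray(df.columns, dtype=object)
        self.n_features_in_ = df.shape[1]

        train_scores = self._scores(df)
        fpr, tpr, thr = roc_curve(y, train_scores)
        j = tpr - fpr
        self.threshold_ = float(thr[int(np.argmax(j))])
        return self

    def _scores(self, df: pd.DataFrame) -> np.ndarray:
        expr = df.T
        expr.columns = [f"s{i}" for i in range(len(df))]
        labels = pd.Series(
            np.r_[np.zeros(len(df) - 1, dtype=int), 1], index=expr.columns
        )  # placeholder labels; scoring ignores them
        cohort = Cohort(id="predict", expression=expr, labels=labels)
        return meta_score(cohort, self.signature_).scores

    def decision_function(self, X) -> np.ndarray:
        """Meta-score per sample: mean(up genes) - mean(down genes)."""
        check_is_fitted(self, "signature_")
        df = self._to_frame(X)
        missing = set(self.signature_.genes) - set(df.columns)
        if missing == set(self.signature_.genes):
            raise KeyError("no signature gene present in X")
        return self._scores(df)

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return (scores >= self.threshold_).astype(int)

    def get_signature(self) -> Signature:
        check_is_fitted(self, "signature_")
        return self.signature_
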