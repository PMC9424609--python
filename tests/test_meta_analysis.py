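import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from metasig import (
    AnalysisConfig,
    benjamini_hochberg,
    dersimonian_laird,
    fisher_combine,
    run_meta,
)
from metasig.effect_size import cohort_effects
from metasig.io_cohorts import with_labels
from metasig.meta_analysis import flagged

from conftest import make_cohort


def chi2_tail_by_integration(x2, df):
    """Independent oracle: integrate the chi-square density directly."""
    pdf = lambda t: t ** (df / 2 - 1) * math.exp(-t / 2) / (
        2 ** (df / 2) * math.gamma(df / 2)
    )
    val, _ = quad(pdf, x2, np.inf)
    return val


def bh_step_up(p):
    """Hand re-implementation of the BH step-up rule as oracle."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        adj[idx] = running
    return adj


class TestDerSimonianLaird:
    def test_single_study_passes_through(self):
        res = dersimonian_laird([(1.6, 0.88)])
        assert res.pooled_es == pytest.approx(1.6)
        assert res.tau2 == 0.0
        assert res.se_pooled == pytest.approx(math.sqrt(0.88), abs=1e-9)

    def test_homogeneous_studies_force_zero_tau2(self):
        res = dersimonian_laird([(1.0, 0.1), (1.0, 0.1)])
        assert res.Q == pytest.approx(0.0, abs=1e-12)
        assert res.tau2 == 0.0
        assert res.pooled_es == pytest.approx(1.0)
        assert res.se_pooled == pytest.approx(math.sqrt(0.05), abs=1e-9)

    def test_heterogeneous_hand_example(self):
        res = dersimonian_laird([(0.0, 0.5), (2.0, 0.5)])
        assert res.Q == pytest.approx(4.0, abs=1e-12)
        assert res.tau2 == pytest.approx(1.5, abs=1e-12)
        assert res.pooled_es == pytest.approx(1.0, abs=1e-12)
        assert res.se_pooled == pytest.approx(1.0, abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            dersimonian_laird([])
        with pytest.raises(ValueError):
            dersimonian_laird([(1.0, 0.0)])

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=-5, max_value=5),
                st.floats(min_value=0.01, max_value=5),
            ),
            min_size=1,
            max_size=8,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_pooled_es_within_range_and_fe_when_q_small(self, effects):
        res = dersimonian_laird(effects)
        gs = [g for g, _ in effects]
        assert min(gs) - 1e-9 <= res.pooled_es <= max(gs) + 1e-9
        assert res.tau2 >= 0
        if res.Q <= len(effects) - 1:
            w = np.array([1 / v for _, v in effects])
            fe = np.sum(w * gs) / np.sum(w)
            assert res.pooled_es == pytest.approx(fe, rel=1e-9, abs=1e-9)


class TestFisherCombine:
    def test_all_ones_combine_to_one(self):
        assert fisher_combine([1.0, 1.0]) == pytest.approx(1.0)

    def test_k1_identity(self):
        assert fisher_combine([0.05]) == pytest.approx(0.05, abs=1e-12)

    @pytest.mark.parametrize(
        "pvals", [[0.5, 0.5], [0.01, 0.2, 0.9], [0.001], [0.3, 0.3, 0.3, 0.3]]
    )
    def test_matches_numerical_integration_oracle(self, pvals):
        x2 = -2 * sum(math.log(p) for p in pvals)
        expected = chi2_tail_by_integration(x2, 2 * len(pvals))
        assert fisher_combine(pvals) == pytest.approx(expected, abs=1e-9)

    def test_order_invariance_and_zero_clamp(self):
        assert fisher_combine([0.1, 0.7]) == fisher_combine([0.7, 0.1])
        assert 0 <= fisher_combine([0.0, 0.5]) <= 1  # clamped, not an error
        with pytest.raises(ValueError):
            fisher_combine([1.2])

    def test_extra_null_pvalue_tracks_oracle(self):
        base = [0.02, 0.1]
        x2 = -2 * sum(math.log(p) for p in base)  # extra p=1 adds nothing to X2
        expected = chi2_tail_by_integration(x2, 2 * (len(base) + 1))
        assert fisher_combine(base + [1.0]) == pytest.approx(expected, abs=1e-9)


class TestBenjaminiHochberg:
    def test_hand_example(self):
        adj = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04], abs=1e-12)

    def test_single_value_identity(self):
        assert benjamini_hochberg([1.0]) == pytest.approx([1.0])

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40)
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_step_up_oracle_and_properties(self, p):
        adj = benjamini_hochberg(p)
        assert adj == pytest.approx(bh_step_up(p), abs=1e-12)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        assert np.all(adj <= 1 + 1e-12)
        # rank order preserved
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_thresholding_adjusted_equals_step_up_decision(self):
        """Flagging adj <= t reproduces the classic step-up rejection set."""
        rng = np.random.default_rng(0)
        p = rng.uniform(size=30)
        adj = benjamini_hochberg(p)
        m = len(p)
        order = np.argsort(p, kind="stable")
        for t in (0.05, 0.2, 0.9):
            ks = [k for k in range(1, m + 1) if p[order[k - 1]] <= k * t / m]
            rejected = set(order[: max(ks)]) if ks else set()
            assert set(np.nonzero(adj <= t)[0]) == rejected


class TestRunMeta:
    def _two_cohorts(self, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for cid in ("a", "b"):
            x = rng.normal(5, 1, (6, 12))
            x[0, :6] += 3.0  # strong up gene
            x[1, :6] -= 3.0  # strong down gene
            out.append(
                make_cohort(x, [1] * 6 + [0] * 6, cohort_id=cid)
            )
        return out

    def test_flags_planted_genes_with_direction(self):
        cohorts = self._two_cohorts()
        results = run_meta(cohorts, AnalysisConfig())
        by_gene = {r.gene_id: r for r in results}
        assert by_gene["G0"].direction == "up"
        assert by_gene["G1"].direction == "down"

    def test_es_gate_blocks_small_effects(self):
        cohorts = self._two_cohorts()
        results = run_meta(cohorts, AnalysisConfig(es_threshold=50.0))
        assert all(r.direction == "none" for r in results)

    def test_label_flip_swaps_directions(self):
        cohorts = self._two_cohorts()
        flipped = [with_labels(c, 1 - c.labels.to_numpy()) for c in cohorts]
        res = {r.gene_id: r.direction for r in run_meta(cohorts)}
        res_flipped = {r.gene_id: r.direction for r in run_meta(flipped)}
        swap = {"up": "down", "down": "up", "none": "none"}
        assert res_flipped == {g: swap[d] for g, d in res.items()}

    def test_single_cohort_reduces_to_hedges_g(self):
        (cohort, _) = self._two_cohorts()
        results = run_meta([cohort])
        effects, _ = cohort_effects(
            make_cohort(
                cohort.expression.sort_index().to_numpy(),
                cohort.labels.to_numpy(),
                gene_ids=sorted(cohort.gene_ids),
            )
        )
        by_gene = {e.gene_id: e for e in effects}
        for r in results:
            assert r.k == 1
            assert r.tau2 == 0.0
            assert r.pooled_es == pytest.approx(by_gene[r.gene_id].g, abs=1e-9)

    def test_recovery_on_simulated_study(self, default_study):
        results = run_meta(default_study.training)
        truth = default_study.truth.set_index("gene_id")
        hits = [
            r
            for r in results
            if truth.loc[r.gene_id, "is_signal"]
            and r.direction == truth.loc[r.gene_id, "direction"]
        ]
        assert len(hits) / default_study.truth["is_signal"].sum() >= 0.9
        n_flagged = len(flagged(results))
        # permissive FDR still cannot flag many nulls: the ES gate dominates
        assert n_flagged <= 2 * default_study.truth["is_signal"].sum()
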