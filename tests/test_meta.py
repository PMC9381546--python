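import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import projected_from_counts
from metaqtl.errors import DomainError
from metaqtl.meta import (
    MixtureModel,
    analyze_chromosome,
    em_fit,
    gg_cluster,
    gg_select,
    information_criteria,
    select_k,
    summarize_mqtl,
)
from metaqtl.types import GeneticMap
from oracles import best_partition_ref, block_loglik_ref, mixture_loglik_ref


class TestEmFit:
    def test_k1_closed_form_equal_sds(self):
        m = em_fit(np.array([10.0, 20.0]), np.array([1.0, 1.0]), 1)
        assert m.means[0] == pytest.approx(15.0, abs=1e-9)
        assert m.weights[0] == 1.0

    def test_k1_inverse_variance_mean(self):
        m = em_fit(np.array([10.0, 20.0]), np.array([1.0, 2.0]), 1)
        assert m.means[0] == pytest.approx(12.0, abs=1e-9)

    def test_k2_two_far_clusters(self):
        x = np.array([0.0, 0.0, 100.0, 100.0])
        s = np.ones(4)
        m = em_fit(x, s, 2, seed=0)
        assert m.means == pytest.approx([0.0, 100.0], abs=1e-6)
        assert m.weights == pytest.approx([0.5, 0.5], abs=1e-6)
        # grid oracle: no (mu1, mu2) on a fine grid beats the EM fit
        grid = np.arange(-5.0, 105.0, 0.5)
        best_grid = max(
            mixture_loglik_ref(x, s, [a, b], [0.5, 0.5])
            for a in grid[::4]
            for b in grid[::4]
        )
        assert m.logL >= best_grid - 1e-9

    def test_logl_matches_reference(self):
        rng = np.random.default_rng(5)
        x = np.sort(rng.uniform(0, 50, 8))
        s = rng.uniform(0.5, 3.0, 8)
        m = em_fit(x, s, 2, seed=1)
        assert m.logL == pytest.approx(
            mixture_loglik_ref(x, s, m.means, m.weights), abs=1e-9
        )

    def test_responsibilities_row_stochastic_and_weights_sum(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 100, 15)
        s = rng.uniform(0.5, 5.0, 15)
        m = em_fit(x, s, 3, seed=2)
        assert m.responsibilities.sum(axis=1) == pytest.approx(np.ones(15), abs=1e-9)
        assert m.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert list(m.means) == sorted(m.means)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            em_fit(np.array([1.0]), np.array([1.0]), 2)
        with pytest.raises(DomainError):
            em_fit(np.array([]), np.array([]), 1)
        with pytest.raises(DomainError):
            em_fit(np.array([1.0, 2.0]), np.array([1.0, 0.0]), 1)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 100, 12)
        s = rng.uniform(0.5, 5.0, 12)
        a = em_fit(x, s, 3, seed=11)
        b = em_fit(x, s, 3, seed=11)
        assert np.array_equal(a.means, b.means) and a.logL == b.logL


def model(logL, K, n):
    return MixtureModel(K, np.zeros(K), np.full(K, 1 / K), logL, np.zeros((n, K)), True, n)


class TestInformationCriteria:
    def test_arithmetic(self):
        row = information_criteria(model(-10.0, 1, 10))
        assert row.nu == 1
        assert row.AIC == pytest.approx(22.0)
        assert row.AIC3 == pytest.approx(23.0)
        assert row.AICc == pytest.approx(22.5)
        assert row.BIC == pytest.approx(22.3026, abs=1e-4)
        assert row.AWE == pytest.approx(27.6052, abs=1e-4)

    def test_aicc_guard(self):
        row = information_criteria(model(-10.0, 6, 10))
        assert row.nu == 11
        assert math.isinf(row.AICc)

    @given(st.integers(1, 5), st.floats(-100, 0), st.integers(12, 60))
    @settings(max_examples=50, deadline=None)
    def test_penalty_monotone_in_k(self, K, logL, n):
        small = information_criteria(model(logL, K, n))
        big = information_criteria(model(logL, K + 1, n))
        for name in ("AIC", "AICc", "AIC3", "BIC", "AWE"):
            assert big.value(name) > small.value(name)


class TestSelectK:
    def _rows(self, winners):
        """Build criteria rows so each criterion's argmin is as prescribed."""
        ks = sorted(set(winners.values()) | {1, 2, 3})
        rows = []
        for k in ks:
            row = information_criteria(model(-50.0, k, 40))
            for name, target in winners.items():
                setattr(row, name, 0.0 if k == target else 100.0 + k)
            rows.append(row)
        return rows

    def test_three_votes_win(self):
        rows = self._rows({"AIC": 2, "AICc": 2, "AIC3": 2, "BIC": 1, "AWE": 1})
        chosen, record = select_k(rows)
        assert chosen == 2 and record["rule"] == "at_least_three_of_five"

    def test_plurality_fallback_tie_smaller(self):
        rows = self._rows({"AIC": 1, "AICc": 1, "AIC3": 2, "BIC": 2, "AWE": 3})
        chosen, record = select_k(rows)
        assert chosen == 1 and record["rule"] == "plurality_fallback"

    def test_unanimous(self):
        rows = self._rows({n: 3 for n in ("AIC", "AICc", "AIC3", "BIC", "AWE")})
        chosen, _ = select_k(rows)
        assert chosen == 3

    def test_empty_table(self):
        with pytest.raises(DomainError):
            select_k([])


class TestGgCluster:
    def test_two_far_pairs(self):
        blocks, _ = gg_cluster(np.array([1.0, 2.0, 50.0, 51.0]), np.ones(4), 2)
        assert blocks == [(0, 2), (2, 4)]

    def test_k_equals_n(self):
        x = np.array([1.0, 5.0, 9.0])
        blocks, logL = gg_cluster(x, np.ones(3), 3)
        assert blocks == [(0, 1), (1, 2), (2, 3)]
        assert logL == pytest.approx(block_loglik_ref(x, np.ones(3), blocks))

    def test_k1_single_block(self):
        x = np.array([0.0, 10.0])
        s = np.array([1.0, 3.0])
        blocks, _ = gg_cluster(x, s, 1)
        assert blocks == [(0, 2)]

    def test_k_too_large(self):
        with pytest.raises(DomainError):
            gg_cluster(np.array([1.0, 2.0]), np.ones(2), 3)

    @given(st.data())
    @settings(max_examples=200, deadline=None)
    def test_matches_exhaustive_enumeration(self, data):
        n = data.draw(st.integers(2, 8))
        x = np.sort(np.array(data.draw(
            st.lists(st.floats(0, 100, allow_nan=False), min_size=n, max_size=n)
        )))
        s = np.array(data.draw(
            st.lists(st.floats(0.3, 5.0, allow_nan=False), min_size=n, max_size=n)
        ))
        k = data.draw(st.integers(1, n))
        blocks, logL = gg_cluster(x, s, k)
        ref_blocks, ref_ll = best_partition_ref(x, s, k)
        assert logL == pytest.approx(ref_ll, abs=1e-6)
        assert block_loglik_ref(x, s, blocks) == pytest.approx(ref_ll, abs=1e-6)


class TestGgSelect:
    def test_two_cluster_instance(self):
        x = np.array([10.0, 10.5, 60.0, 61.0])
        s = np.ones(4)
        chosen, blocks, record = gg_select(x, s)
        # direct criterion computation over all candidates is the oracle
        crits = {}
        for k in (1, 2, 3, 4):
            _, ll = gg_cluster(x, s, k)
            crits[k] = -2 * ll + 2 * k * math.log(4)
        assert chosen == min(crits, key=crits.get) == 2
        assert blocks == [(0, 2), (2, 4)]

    def test_single_qtl(self):
        chosen, blocks, record = gg_select(np.array([5.0]), np.array([1.0]))
        assert chosen == 1 and blocks == [(0, 1)]

    def test_four_tight_clusters_n12(self):
        x = np.sort(np.concatenate([c + np.array([0.0, 0.3, 0.6]) for c in (10, 60, 110, 160)]))
        s = np.ones(12)
        chosen, blocks, record = gg_select(x, s)
        assert chosen == 4
        assert [j - i for i, j in blocks] == [3, 3, 3, 3]
        assert record["model_label"] == "Model 4"

    def test_every_qtl_apart_label(self):
        x = np.array([0.0, 50.0, 100.0, 150.0, 200.0, 250.0])
        chosen, _, record = gg_select(x, np.full(6, 0.01))
        if chosen == 6:
            assert record["model_label"] == "Model n"


class TestSummarize:
    def test_symmetric_pair(self):
        members = projected_from_counts([10.0, 12.0], [1.0, 1.0])
        m = summarize_mqtl(members, 0.5, None, "MQTL1.1")
        assert m.position == pytest.approx(11.0)
        assert m.sigma == pytest.approx(math.sqrt(0.5), abs=1e-4)
        assert m.ci95_start == pytest.approx(11 - 1.96 * math.sqrt(0.5), abs=1e-4)
        assert m.ci95_end == pytest.approx(11 + 1.96 * math.sqrt(0.5), abs=1e-4)

    def test_single_member_identity(self):
        members = projected_from_counts([42.0], [2.0])
        m = summarize_mqtl(members, 1.0, None, "MQTL1.1")
        assert m.position == pytest.approx(42.0)
        assert m.sigma == pytest.approx(2.0)

    def test_unequal_precision(self):
        # brute-force check: position maximizes the joint Gaussian likelihood
        members = projected_from_counts([0.0, 10.0], [1.0, 3.0])
        m = summarize_mqtl(members, 1.0, None, "MQTL1.1")
        assert m.position == pytest.approx(1.0, abs=1e-9)
        assert m.sigma == pytest.approx(0.9487, abs=1e-4)
        grid = np.linspace(-2, 12, 2801)
        ll = -((0.0 - grid) ** 2) / 2 - ((10.0 - grid) ** 2) / (2 * 9)
        assert abs(grid[np.argmax(ll)] - m.position) < 0.01

    def test_marker_fields(self):
        cmap = GeneticMap("ref", [(f"m{i}", 1, float(i * 5)) for i in range(10)])
        members = projected_from_counts([21.0, 23.0], [1.0, 1.0])
        m = summarize_mqtl(members, 1.0, cmap, "MQTL1.1")
        assert m.peak_marker == "m4"  # 20 cM is nearest to 22
        assert m.flank_left == "m4"
        assert m.flank_right == "m5"


class TestAnalyzeChromosome:
    def test_mixture_branch_above_threshold(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(20, 1, 11), rng.normal(80, 1, 11)])
        # known sds exceed the realized scatter, so splitting a cluster
        # cannot pay for its extra parameters
        qtls = projected_from_counts(x, np.full(22, 2.0), chromosome=3)
        mqtls, decision = analyze_chromosome(qtls, seed=1)
        assert decision.branch == "mixture"
        assert decision.n_qtl == 22
        assert decision.chosen_k == 2
        assert sum(m.weight for m in mqtls) == pytest.approx(1.0, abs=1e-6)

    def test_contiguous_branch_at_or_below_threshold(self):
        x = np.array([5.0, 6.0, 40.0, 41.0, 80.0, 81.0, 82.0, 83.0])
        qtls = projected_from_counts(x, np.full(8, 1.0))
        mqtls, decision = analyze_chromosome(qtls)
        assert decision.branch == "contiguous"
        assert sum(m.weight for m in mqtls) == pytest.approx(1.0)

    def test_single_qtl_passthrough(self):
        qtls = projected_from_counts([33.0], [2.5])
        mqtls, decision = analyze_chromosome(qtls)
        assert len(mqtls) == 1
        assert mqtls[0].position == pytest.approx(33.0)
        assert mqtls[0].ci95_end - mqtls[0].ci95_start == pytest.approx(2 * 1.96 * 2.5)

    def test_member_partition(self):
        x = np.array([5.0, 6.0, 40.0, 41.0])
        qtls = projected_from_counts(x, np.full(4, 1.0))
        mqtls, _ = analyze_chromosome(qtls)
        all_members = sorted(sum((m.member_qtl for m in mqtls), []))
        assert all_members == sorted(q.qtl_id for q in qtls)

    def test_well_separated_recovery_under_2cm(self):
        # gap >= 5 x median sigma: K and means recover tightly
        true = np.array([30.0, 90.0, 150.0])
        hits = 0
        errs = []
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            assign = rng.integers(0, 3, 22)
            s = rng.uniform(2.0, 6.0, 22)
            x = true[assign] + rng.normal(0, s)
            qtls = projected_from_counts(x, s, chromosome=3)
            mqtls, decision = analyze_chromosome(qtls, seed=rep)
            if decision.chosen_k == 3:
                hits += 1
                mus = np.sort([m.position for m in mqtls])
                errs.extend((mus - true) ** 2)
        assert hits >= 16  # >= 80%
        assert math.sqrt(np.mean(errs)) < 2.0
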