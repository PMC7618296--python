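"""Incremental analysis, dominance frontier, PSA, CEAC and threshold sweep."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from ovatriage.decision_tree import StageShiftParams
from ovatriage.economics import (
    CEResult,
    VARIANT_PAIRS,
    ceac,
    evaluate_all_pathways,
    icer_frontier,
    incremental,
    net_benefit,
    pathway_ce,
    run_psa,
    threshold_sweep,
)
from ovatriage.decision_tree import standard_pathways

from _oracles import exhaustive_frontier

# printed per-1000 increments against current practice, used as frontier inputs
TABLE_INCREMENTS_GE50 = {
    1: (0.0, 0.0), 2: (1.48, 34_894), 3: (1.53, 39_327),
    4: (1.86, 283_225), 5: (1.86, 283_223), 6: (2.23, 304_856),
}
TABLE_INCREMENTS_UNDER50 = {
    1: (0.0, 0.0), 2: (-0.97, -33_354), 3: (-0.95, -33_455),
    4: (0.32, 258_083), 5: (0.33, 259_095), 6: (2.44, 334_595),
}


def _ce(pid, qaly, cost):
    return CEResult(
        pathway_id=pid, qalys_per_1000=qaly, lys_per_1000=0.0, costs_per_1000=cost,
        detection_rate=None, referral_rate=0.0,
    )


class TestIncremental:
    def test_identical_results_give_zeros(self):
        results = {1: _ce(1, 10.0, 100.0), 2: _ce(2, 10.0, 100.0)}
        assert incremental(results) == {1: (0.0, 0.0), 2: (0.0, 0.0)}

    def test_printed_increments_recovered_from_absolute_values(self):
        results = {
            1: _ce(1, 905.7 - 1.48, 100_000.0),
            2: _ce(2, 905.7, 100_000.0 + 34_894),
        }
        dq, dc = incremental(results)[2]
        assert dq == pytest.approx(1.48, abs=1e-9)
        assert dc == pytest.approx(34_894, abs=1e-6)

    def test_antisymmetric_under_comparator_swap(self):
        results = {1: _ce(1, 5.0, 70.0), 2: _ce(2, 9.0, 120.0)}
        d12 = incremental(results, comparator_id=1)[2]
        d21 = incremental(results, comparator_id=2)[1]
        assert d12 == (-d21[0], -d21[1])

    def test_missing_comparator_rejected(self):
        with pytest.raises(KeyError):
            incremental({2: _ce(2, 1.0, 1.0)}, comparator_id=1)


class TestFrontier:
    def test_extended_dominance_three_options(self):
        """The middle option off the convex hull is extendedly dominated."""
        fr = icer_frontier({1: (0.0, 0.0), 2: (1.0, 30_000.0), 3: (2.0, 40_000.0)})
        assert fr.extendedly_dominated == {2}
        assert fr.on_frontier == {1, 3}
        comp, icer = fr.icers[3]
        assert comp == 1 and icer == pytest.approx(20_000.0)

    def test_single_option(self):
        fr = icer_frontier({4: (1.0, 10.0)})
        assert fr.on_frontier == {4}
        assert fr.icers == {}

    def test_strict_dominance(self):
        fr = icer_frontier({1: (0.0, 0.0), 2: (-1.0, 5_000.0)})
        assert fr.dominated == {2}

    def test_exact_tie_keeps_lower_id(self):
        fr = icer_frontier({1: (0.0, 0.0), 3: (1.0, 10.0), 5: (1.0, 10.0)})
        assert 3 in fr.on_frontier
        assert 5 in fr.dominated
        assert fr.ties == {3, 5}

    @pytest.mark.parametrize(
        "rows", [TABLE_INCREMENTS_GE50, TABLE_INCREMENTS_UNDER50],
        ids=["ge50", "under50"],
    )
    def test_published_dominance_structure(self, rows):
        """Concurrent risk-model pathways are extendedly dominated in both strata."""
        fr = icer_frontier(rows, variant_pairs=VARIANT_PAIRS)
        assert {4, 5} <= fr.extendedly_dominated

    def test_variant_twins_not_compared_with_each_other(self):
        fr = icer_frontier(TABLE_INCREMENTS_GE50, variant_pairs=VARIANT_PAIRS)
        # both sequential variants sit on the frontier, each against pathway 1
        assert fr.icers[2][0] == 1
        assert fr.icers[3][0] == 1
        assert fr.icers[2][1] == pytest.approx(34_894 / 1.48)
        assert fr.icers[3][1] == pytest.approx(39_327 / 1.53)

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.floats(0, 10), st.floats(0, 1e5)),
            min_size=1, max_size=6,
        )
    )
    def test_matches_exhaustive_search(self, qc_pairs):
        """Frontier classification equals brute-force dominance search."""
        points = [(i + 1, q, c) for i, (q, c) in enumerate(qc_pairs)]
        # avoid near-degenerate geometry where tie-break conventions differ
        for i, (_, qi, ci) in enumerate(points):
            for _, qj, cj in points[i + 1:]:
                assume(abs(qi - qj) > 1e-3 and abs(ci - cj) > 1e-1)
        for a in points:
            for b in points:
                for c in points:
                    if len({a[0], b[0], c[0]}) == 3:
                        cross = (b[1] - a[1]) * (c[2] - a[2]) - (c[1] - a[1]) * (b[2] - a[2])
                        assume(abs(cross) > 1e-2)
        fr = icer_frontier({pid: (q, c) for pid, q, c in points})
        dominated, ext = exhaustive_frontier(points)
        assert fr.dominated == dominated
        assert fr.extendedly_dominated == ext
        assert fr.on_frontier == {p[0] for p in points} - dominated - ext


class TestNetBenefit:
    def test_printed_increment_cost_effective_at_30000(self):
        assert net_benefit(1.48, 34_894, 30_000) == pytest.approx(9_506.0)

    def test_zero_threshold(self):
        assert net_benefit(3.0, 250.0, 0.0) == -250.0

    def test_linear_in_threshold(self):
        nb = [net_benefit(2.0, 10_000.0, lam) for lam in (0, 10_000, 20_000)]
        assert nb[2] - nb[1] == pytest.approx(nb[1] - nb[0])

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            net_benefit(1.0, 1.0, -1.0)


class TestPSA:
    def test_same_seed_reproducible(self, profile, ge50, library_ge50):
        a = run_psa(profile, ge50, n=25, seed=7, library=library_ge50, pathway_ids=(1, 2))
        b = run_psa(profile, ge50, n=25, seed=7, library=library_ge50, pathway_ids=(1, 2))
        assert a.draws.equals(b.draws)
        assert np.array_equal(a.results[2], b.results[2])

    def test_different_seed_changes_draws(self, profile, ge50, library_ge50):
        a = run_psa(profile, ge50, n=25, seed=7, library=library_ge50, pathway_ids=(1,))
        b = run_psa(profile, ge50, n=25, seed=8, library=library_ge50, pathway_ids=(1,))
        assert not a.draws.equals(b.draws)

    def test_draws_respect_support_and_rr_mean(self, profile, ge50, library_ge50):
        psa = run_psa(profile, ge50, n=1000, seed=3, library=library_ge50, pathway_ids=(1, 2))
        sens_cols = [c for c in psa.draws.columns if c.startswith(("sens_", "spec_"))]
        for col in sens_cols:
            assert psa.draws[col].between(0.0, 1.0).all()
        rr = psa.draws["rr_late"]
        sd = rr.std()
        assert abs(rr.mean() - 0.836) < 3 * sd / np.sqrt(len(rr)) + 0.01

    def test_psa_mean_near_base_case(self, profile, ge50, library_ge50):
        """Monte-Carlo means track the deterministic base case (near-linearity)."""
        psa = run_psa(profile, ge50, n=400, seed=5, library=library_ge50, pathway_ids=(1, 2))
        dq = psa.results[2][:, 0] - psa.results[1][:, 0]
        dc = psa.results[2][:, 1] - psa.results[1][:, 1]
        base = evaluate_all_pathways(ge50, profile, library=library_ge50, pathway_ids=(1, 2))
        base_dq = base[2].qalys_per_1000 - base[1].qalys_per_1000
        base_dc = base[2].costs_per_1000 - base[1].costs_per_1000
        n = len(dq)
        assert abs(dq.mean() - base_dq) < 3 * dq.std() / np.sqrt(n) + 0.05 * abs(base_dq)
        assert abs(dc.mean() - base_dc) < 3 * dc.std() / np.sqrt(n) + 0.05 * abs(base_dc)


class TestCEAC:
    def _psa_like(self, results, n):
        from ovatriage.economics import PSAResult
        import pandas as pd

        return PSAResult(
            n_draws=n, seed=0, stratum=None, draws=pd.DataFrame(index=range(n)),
            results=results,
        )

    def test_identical_pathways_split_ties(self):
        arr = np.tile([5.0, 100.0], (10, 1))
        psa = self._psa_like({1: arr.copy(), 2: arr.copy()}, 10)
        curve = ceac(psa, [0, 10_000, 30_000])
        assert np.allclose(curve.probabilities.values, 0.5)

    def test_probabilities_partition_to_one(self, profile, ge50, library_ge50):
        psa = run_psa(profile, ge50, n=50, seed=2, library=library_ge50)
        curve = ceac(psa, np.arange(0, 50_001, 10_000))
        sums = curve.probabilities.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_dominant_pathway_has_probability_one(self):
        good = np.tile([10.0, 50.0], (8, 1))
        bad = np.tile([1.0, 500.0], (8, 1))
        psa = self._psa_like({1: bad, 2: good}, 8)
        curve = ceac(psa, [0, 20_000])
        assert np.all(curve.probabilities[2].values == 1.0)

    def test_empty_grid_rejected(self):
        psa = self._psa_like({1: np.zeros((3, 2))}, 3)
        with pytest.raises(ValueError):
            ceac(psa, [])


class TestThresholdSweep:
    def test_base_case_cell_is_exact(self, profile, ge50, library_ge50):
        """The (1%, 3%) cell reproduces the base-case comparison exactly."""
        grid = threshold_sweep(
            ge50, profile, moderate_grid=[0.01], high_grid=[0.03], library=library_ge50
        )
        base = evaluate_all_pathways(ge50, profile, library=library_ge50, pathway_ids=(1, 2))
        inc = incremental(base)[2]
        row = grid.iloc[0]
        assert row.dqaly_per_1000 == inc[0]
        assert row.dcost_per_1000 == inc[1]

    def test_cost_decreases_as_moderate_threshold_rises(self, profile, ge50, library_ge50):
        """Fewer ultrasounds and referrals as the band narrows from below."""
        grid = threshold_sweep(
            ge50, profile,
            moderate_grid=[0.008, 0.012, 0.016, 0.02, 0.024, 0.028],
            high_grid=[0.03],
            library=library_ge50,
        )
        dc = grid.sort_values("moderate")["dcost_per_1000"].to_numpy()
        assert np.all(np.diff(dc) <= 1e-9)

    def test_upper_triangle_only(self, profile, ge50, library_ge50):
        grid = threshold_sweep(
            ge50, profile, moderate_grid=[0.01, 0.03], high_grid=[0.01, 0.03],
            library=library_ge50,
        )
        assert len(grid) == 3
        assert (grid.moderate <= grid.high).all()


class TestPathwayCE:
    def test_comparator_increment_signs_ge50(self, profile, ge50, library_ge50):
        """At >=50 the risk-banded sequential pathway adds QALYs at extra cost."""
        results = evaluate_all_pathways(ge50, profile, library=library_ge50, pathway_ids=(1, 2))
        inc = incremental(results)[2]
        assert inc[0] > 0
        assert inc[1] > 0

    def test_null_stage_shift_leaves_only_referral_effects(self, profile, ge50, library_ge50):
        """With no stage shift the QALY increment is only the benign-surgery
        effect of the extra referrals, bounded by the referral-rate gap."""
        defs = standard_pathways()
        kw = dict(library=library_ge50, shift=StageShiftParams(rr_late=1.0))
        r1 = pathway_ce(defs[1], ge50, profile, **kw)
        r2 = pathway_ce(defs[2], ge50, profile, **kw)
        dq = r2.qalys_per_1000 - r1.qalys_per_1000
        refer_gap = abs(r2.referral_rate - r1.referral_rate)
        surgery_bound = 1000 * refer_gap * (0.04 + 0.008 * 40)
        assert abs(dq) <= surgery_bound

    def test_perfect_tests_equalize_health_outcomes(self, profile, ge50, library_ge50):
        """With perfect tests every pathway detects everyone and refers no one
        falsely, so health outcomes coincide; only primary-care testing costs
        can differ (concurrent pathways still scan every woman)."""

        class _Perfect:
            def lookup(self, test_id, age_group, label):
                return 1.0, 1.0

        defs = standard_pathways()
        results = [
            pathway_ce(defs[pid], ge50, profile, library=library_ge50, accuracy=_Perfect())
            for pid in (1, 2, 4, 6)
        ]
        for r in results[1:]:
            assert r.qalys_per_1000 == pytest.approx(results[0].qalys_per_1000, abs=1e-9)
            assert r.lys_per_1000 == pytest.approx(results[0].lys_per_1000, abs=1e-9)
            assert r.cost_breakdown["fp_secondary"] == 0.0
            assert r.cost_breakdown["inpatient"] == pytest.approx(
                results[0].cost_breakdown["inpatient"], abs=1e-9
            )

    def test_cost_breakdown_sums_to_total(self, profile, ge50, library_ge50):
        res = evaluate_all_pathways(ge50, profile, library=library_ge50, pathway_ids=(2,))[2]
        assert sum(res.cost_breakdown.values()) == pytest.approx(res.costs_per_1000, rel=1e-12)
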