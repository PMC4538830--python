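import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import hdxmap as hm
from hdxmap.constants import DEUTERIUM_MASS_SHIFT


def _records(da_by_timepoint, state="free", start=1, seq="GGGGGGGGGGG"):
    """Build a one-peptide record table: {timepoint: [replicate Da values]}."""
    rows = []
    for t, values in da_by_timepoint.items():
        for r, v in enumerate(values, start=1):
            rows.append(("p", state, start, start + len(seq) - 1, seq, t, r, v))
    return pd.DataFrame(rows, columns=[
        "protein_id", "state", "start", "end", "sequence",
        "timepoint_s", "replicate", "uptake_Da",
    ])


class TestPerTimepointDiff:
    def test_identical_states_zero_diff(self):
        recs = _records({3.0: [1.0, 1.1, 0.9], 30.0: [2.0, 2.2, 1.8]})
        diffs = hm.per_timepoint_diff(recs, recs.copy(), n_max=10)
        np.testing.assert_allclose(diffs["diff_pct"], 0.0, atol=1e-12)
        np.testing.assert_allclose(diffs["diff_da"], 0.0, atol=1e-12)

    def test_one_da_on_ten_amides(self):
        a = _records({3.0: [1.0, 1.0, 1.0]})
        b = _records({3.0: [2.0, 2.0, 2.0]})
        diffs = hm.per_timepoint_diff(a, b, n_max=10)
        assert diffs["diff_da"].iloc[0] == pytest.approx(1.0)
        # 1.0 Da / 1.006277 / 10 amides = +9.94 %HDX
        assert diffs["diff_pct"].iloc[0] == pytest.approx(9.94, abs=0.005)

    def test_antisymmetric_under_state_swap(self):
        a = _records({3.0: [1.0, 1.2, 0.8], 30.0: [1.4, 1.6, 1.5]})
        b = _records({3.0: [2.0, 2.1, 1.9], 30.0: [2.4, 2.3, 2.6]})
        fwd = hm.per_timepoint_diff(a, b, n_max=8)
        rev = hm.per_timepoint_diff(b, a, n_max=8)
        np.testing.assert_allclose(fwd["diff_pct"], -rev["diff_pct"])
        np.testing.assert_allclose(fwd["diff_da"], -rev["diff_da"])

    def test_mismatched_timepoints_rejected(self):
        a = _records({3.0: [1.0, 1.0]})
        b = _records({30.0: [1.0, 1.0]})
        with pytest.raises(ValueError):
            hm.per_timepoint_diff(a, b, n_max=5)


class TestDeltaHdx:
    def _frame(self, diffs):
        return pd.DataFrame({
            "timepoint_s": [3.0, 30.0, 300.0, 3000.0][: len(diffs)],
            "diff_pct": diffs,
            "diff_da": [0.0] * len(diffs),
            "p_value": [1.0] * len(diffs),
        })

    @pytest.mark.parametrize(
        "diffs,expected",
        [
            ([5, 12, 9, 7], (12.0, 30.0)),
            ([-5, -15, -8, -2], (-15.0, 30.0)),
            ([10, -10, 0, 0], (10.0, 3.0)),  # magnitude tie breaks to earliest
        ],
    )
    def test_signed_max_with_tie_rule(self, diffs, expected):
        assert hm.delta_hdx(self._frame(diffs)) == expected


class TestUnpairedTTest:
    def test_frozen_reference_value(self):
        # pooled sd 0.1, t = 1.0/(0.1*sqrt(2/3)) = 12.25, df = 4
        p = hm.unpaired_t_test([1.0, 1.1, 0.9], [2.0, 2.1, 1.9])
        assert p == pytest.approx(2.55e-4, rel=0.02)

    def test_equal_groups_p_one(self):
        assert hm.unpaired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_zero_variance_degenerate_cases(self):
        assert hm.unpaired_t_test([1.0, 1.0], [1.0, 1.0]) == 1.0
        assert hm.unpaired_t_test([1.0, 1.0], [2.0, 2.0]) == 0.0

    def test_symmetric_under_label_swap(self):
        a, b = [1.0, 1.3, 0.8], [1.9, 2.4, 2.2]
        assert hm.unpaired_t_test(a, b) == hm.unpaired_t_test(b, a)

    def test_scale_invariance(self):
        # identical p whether computed on #D, %HDX or raw Da values
        a, b = [1.0, 1.3, 0.8], [1.9, 2.4, 2.2]
        scaled = hm.unpaired_t_test([x * 17.2 for x in a], [x * 17.2 for x in b])
        assert scaled == pytest.approx(hm.unpaired_t_test(a, b), rel=1e-12)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            hm.unpaired_t_test([1.0], [1.0, 2.0])


class TestCallPeptide:
    @pytest.mark.parametrize(
        "delta,p,da,expect_sig,expect_reasons",
        [
            (12.0, 0.01, 0.6, True, ()),
            (12.0, 0.01, 0.4, False, ("min_da",)),
            (9.0, 0.001, 1.0, False, ("min_delta_pct",)),
            (-12.0, 0.01, -0.6, True, ()),          # thresholds act on magnitudes
            (12.0, 0.01, 0.5, True, ()),            # Da bound is inclusive
            (10.0, 0.01, 0.6, False, ("min_delta_pct",)),  # % bound is strict
            (12.0, 0.05, 0.6, False, ("alpha",)),    # alpha bound is strict
            (9.0, 0.5, 0.1, False, ("min_delta_pct", "alpha", "min_da")),
        ],
    )
    def test_three_criterion_rule(self, delta, p, da, expect_sig, expect_reasons):
        sig, reasons = hm.call_peptide(delta, p, da)
        assert sig is expect_sig
        assert reasons == expect_reasons

    def test_monotone_in_thresholds(self):
        # raising any threshold never turns a non-significant call significant
        cases = [(12.0, 0.01, 0.6), (11.0, 0.04, 0.5), (25.0, 0.001, 2.0)]
        base = hm.CallingThresholds()
        for delta, p, da in cases:
            sig0, _ = hm.call_peptide(delta, p, da, base)
            for stricter in [
                hm.CallingThresholds(min_delta_pct=base.min_delta_pct * 2),
                hm.CallingThresholds(alpha=base.alpha / 10),
                hm.CallingThresholds(min_da=base.min_da * 3),
            ]:
                sig1, _ = hm.call_peptide(delta, p, da, stricter)
                assert not (sig1 and not sig0)


class TestAnalyzeDifferential:
    def _planted_tables(self, factor=100.0, noise=0.01, seed=0):
        pair = hm.make_two_state_protein(60, [(20, 40, factor)], seed=seed)
        cond = hm.LabelingConditions(noise_sd=noise)
        peps = hm.build_peptides(pair, hm.make_peptide_map(60, seed=seed))
        free = hm.simulate_uptake(pair, "free", peps, cond, seed=seed + 1)
        bound = hm.simulate_uptake(pair, "bound", peps, cond, seed=seed + 2)
        return pair, peps, free, bound

    def test_null_case_no_significant(self):
        pair = hm.make_two_state_protein(60, [], seed=3)
        cond = hm.LabelingConditions(noise_sd=0.0)
        peps = hm.build_peptides(pair, hm.make_peptide_map(60, seed=3))
        free = hm.simulate_uptake(pair, "free", peps, cond, seed=1)
        bound = hm.simulate_uptake(pair, "bound", peps, cond, seed=2)
        results = hm.analyze_differential(free, bound)
        assert all(not r.significant for r in results)
        assert all(r.direction == "none" for r in results)

    def test_planted_protection_called_decrease(self):
        pair, peps, free, bound = self._planted_tables()
        results = hm.analyze_differential(free, bound)
        inside = [r for r in results if r.peptide.start >= 20 and r.peptide.end <= 40]
        assert inside
        assert all(r.significant and r.direction == "decrease" for r in inside)

    def test_planted_deprotection_called_increase(self):
        pair, peps, free, bound = self._planted_tables(factor=0.01)
        results = hm.analyze_differential(free, bound)
        inside = [r for r in results if r.peptide.start >= 20 and r.peptide.end <= 40]
        assert inside
        assert all(r.significant and r.direction == "increase" for r in inside)

    def test_antisymmetry_of_full_analysis(self):
        _, _, free, bound = self._planted_tables()
        fwd = hm.analyze_differential(free, bound)
        rev = hm.analyze_differential(bound, free)
        flip = {"decrease": "increase", "increase": "decrease", "none": "none"}
        for a, b in zip(fwd, rev):
            assert a.peptide == b.peptide
            assert a.delta_hdx_pct == pytest.approx(-b.delta_hdx_pct)
            assert a.significant == b.significant
            assert flip[a.direction] == b.direction

    def test_results_sorted_and_one_per_peptide(self):
        _, peps, free, bound = self._planted_tables()
        results = hm.analyze_differential(free, bound)
        keys = [(r.peptide.protein_id, r.peptide.start, r.peptide.end) for r in results]
        assert keys == sorted(keys)
        assert len(results) == len({(p.start, p.end) for p in peps})

    def test_disjoint_maps_rejected(self):
        _, _, free, bound = self._planted_tables()
        shifted = bound.copy()
        shifted["start"] += 1000
        shifted["end"] += 1000
        with pytest.raises(ValueError):
            hm.analyze_differential(free, shifted)

    def test_peptide_missing_in_one_state_excluded_with_warning(self, caplog):
        _, peps, free, bound = self._planted_tables()
        key = (peps[0].start, peps[0].end)
        trimmed = bound[~((bound["start"] == key[0]) & (bound["end"] == key[1]))]
        with caplog.at_level(logging.WARNING):
            results = hm.analyze_differential(free, trimmed)
        assert len(results) == len({(p.start, p.end) for p in peps}) - 1
        assert any("only one state" in rec.message for rec in caplog.records)

    def test_single_replicate_excluded(self, caplog):
        _, peps, free, bound = self._planted_tables()
        key = (peps[0].start, peps[0].end)
        mask = (bound["start"] == key[0]) & (bound["end"] == key[1]) & (bound["replicate"] > 1)
        with caplog.at_level(logging.WARNING):
            results = hm.analyze_differential(free, bound[~mask])
        assert all((r.peptide.start, r.peptide.end) != key for r in results)

    @settings(derandomize=True, deadline=None, max_examples=15)
    @given(st.integers(min_value=0, max_value=99))
    def test_raising_thresholds_shrinks_significant_set(self, seed):
        _, _, free, bound = self._planted_tables(factor=5.0, noise=0.1, seed=seed)
        strict_thr = hm.CallingThresholds(min_delta_pct=20.0, alpha=0.01, min_da=1.0)
        loose = hm.analyze_differential(free, bound)
        strict = hm.analyze_differential(free, bound, strict_thr)
        loose_keys = {(r.peptide.start, r.peptide.end) for r in loose if r.significant}
        strict_keys = {(r.peptide.start, r.peptide.end) for r in strict if r.significant}
        assert strict_keys <= loose_keys
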