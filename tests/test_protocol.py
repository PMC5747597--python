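import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bpval.model import SessionSeries, Variable
from bpval.protocol import (
    BASE_N_SUBJECTS,
    BandThresholds,
    ProtocolError,
    band_counts,
    evaluate_phase1,
    evaluate_phase2,
    per_subject_band1_counts,
    scale_requirements,
    select_differences,
    validate_device,
)
from bpval.simulate import SimulationConfig, generate_study

from ._oracles import brute_phase_verdicts, brute_selected_differences
from .conftest import build_dataset

BP_BANDS = BandThresholds.for_variable("SBP")


def series(values, pid="P1", session=1, var="SBP"):
    return SessionSeries(pid, session, Variable(var), list(map(float, values)))


class TestSelectDifferences:
    def test_hand_enumerated_example(self):
        t = select_differences(series([120, 121, 122, 119, 118, 121, 120]))
        assert t.flanking == ((1, 1), (3, 1), (3, 1))
        assert t.selected == (1, 1, 1)

    def test_all_equal(self):
        t = select_differences(series([115] * 7))
        assert t.selected == (0, 0, 0)

    def test_equal_flanks(self):
        t = select_differences(series([100, 110, 100, 110, 100, 110, 100]))
        assert t.selected == (10, 10, 10)

    def test_signed_follows_selected_flank(self):
        # p=2: flanks (|121-120|, |121-124|) -> preceding flank, signed +1
        t = select_differences(series([120, 121, 124, 119, 118, 121, 120]))
        assert t.signed[0] == 1.0
        assert t.selected[0] == 1.0

    def test_incomplete_series_rejected(self):
        s = SessionSeries("P1", 1, Variable.SBP, [120.0] * 6 + [None])
        with pytest.raises(Exception, match="incomplete"):
            select_differences(s)

    @given(st.lists(st.integers(40, 220).map(float), min_size=7, max_size=7))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_enumeration(self, values):
        t = select_differences(series(values))
        assert list(t.selected) == brute_selected_differences(values)

    @given(st.lists(st.integers(40, 220).map(float), min_size=7, max_size=7))
    @settings(max_examples=100, deadline=None)
    def test_selected_at_most_both_flanks(self, values):
        t = select_differences(series(values))
        for d, (before, after) in zip(t.selected, t.flanking):
            assert d <= before and d <= after and d >= 0


class TestBandCounts:
    def _triples(self, selected_list, var="SBP"):
        out = []
        for i, sel in enumerate(selected_list):
            vals = [100.0, 100 + sel[0], 100.0, 100 + sel[1], 100.0, 100 + sel[2], 100.0]
            out.append(select_differences(series(vals, pid=f"P{i}", var=var)))
        return out

    def test_all_zero(self):
        triples = self._triples([(0, 0, 0)] * 100)
        counts, beyond = band_counts(triples, BP_BANDS)
        assert counts == (300, 300, 300) and beyond == 0

    def test_hand_banding(self):
        counts, beyond = band_counts(self._triples([(4, 6, 20)]), BP_BANDS)
        assert counts == (1, 2, 2) and beyond == 1

    def test_boundary_is_inclusive(self):
        counts, _ = band_counts(self._triples([(5, 10, 15)]), BP_BANDS)
        assert counts == (1, 2, 3)

    def test_mixed_variables_rejected(self):
        triples = self._triples([(0, 0, 0)]) + self._triples([(0, 0, 0)], var="HR")
        with pytest.raises(ValueError, match="mixed"):
            band_counts(triples, BP_BANDS)

    def test_wrong_thresholds_rejected(self):
        with pytest.raises(ValueError, match="thresholds"):
            band_counts(self._triples([(0, 0, 0)], var="HR"), BP_BANDS)

    @given(st.lists(st.tuples(*[st.integers(0, 30)] * 3), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_cumulative_counts_monotone(self, sels):
        counts, beyond = band_counts(self._triples(sels), BP_BANDS)
        assert counts[0] <= counts[1] <= counts[2] <= 3 * len(sels)
        assert beyond == 3 * len(sels) - counts[2]


class TestScaleRequirements:
    def test_n100_printed_thresholds(self):
        req = scale_requirements(100)
        assert req.pair_two_of == (219, 261, 288)
        assert req.pair_all_of == (195, 243, 279)
        assert req.subj_min_good == 72
        assert req.subj_max_bad == 9
        assert req.scale_factor == 3

    def test_base_cohort(self):
        req = scale_requirements(33)
        assert req.pair_two_of == (73, 87, 96)
        assert req.pair_all_of == (65, 81, 93)
        assert req.subj_min_good == 24
        assert req.subj_max_bad == 3

    def test_doubled_cohort(self):
        req = scale_requirements(66)
        assert req.pair_two_of == (146, 174, 192)
        assert req.pair_all_of == (130, 162, 186)
        assert req.subj_min_good == 48
        assert req.subj_max_bad == 6

    def test_below_base_rejected(self):
        with pytest.raises(ProtocolError):
            scale_requirements(32)

    @given(st.integers(33, 400))
    @settings(max_examples=60, deadline=None)
    def test_thresholds_feasible_or_rejected(self, n):
        try:
            req = scale_requirements(n)
        except ProtocolError:
            # cohort too far below a multiple of 33: scaled counts cannot fit
            assert 96 * round(n / 33) > 3 * n
            return
        assert all(a <= t for a, t in zip(req.pair_all_of, req.pair_two_of))
        assert max(req.pair_two_of) <= req.n_pairs


REQ100 = scale_requirements(100)

# (band counts, phase-2 good, phase-2 bad) for every printed 100-subject row
PRINTED_ROWS = {
    "SBP1": ((242, 286, 298), 87, 0),
    "DBP1": ((277, 295, 299), 95, 0),
    "HR1": ((265, 287, 297), 90, 0),
    "SBP2": ((256, 289, 300), 94, 0),
    "DBP2": ((266, 295, 298), 95, 2),
    "HR2": ((272, 287, 295), 93, 0),
}


class TestEvaluatePhase1:
    @pytest.mark.parametrize("label", list(PRINTED_ROWS))
    def test_printed_count_sets_pass(self, label):
        counts, _, _ = PRINTED_ROWS[label]
        assert evaluate_phase1(counts, REQ100).passed

    def test_all_of_violation_fails(self):
        out = evaluate_phase1((194, 300, 300), REQ100)
        assert not out.passed
        assert out.criteria_met["two_of_satisfied"]
        assert not out.criteria_met["all_of_satisfied"]

    def test_two_of_needs_two(self):
        # clears only band 3 of the "two of" triple, all-of satisfied
        out = evaluate_phase1((218, 260, 300), REQ100)
        assert not out.passed

    def test_non_cumulative_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            evaluate_phase1((200, 190, 300), REQ100)

    def test_count_above_pairs_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            evaluate_phase1((200, 250, 301), REQ100)


class TestEvaluatePhase2:
    @staticmethod
    def _counts(good, bad, n=100):
        counts = {}
        for i in range(good):
            counts[f"G{i}"] = 3
        for i in range(bad):
            counts[f"B{i}"] = 0
        for i in range(n - good - bad):
            counts[f"M{i}"] = 1
        return counts

    @pytest.mark.parametrize("label", list(PRINTED_ROWS))
    def test_printed_subject_counts_pass(self, label):
        _, good, bad = PRINTED_ROWS[label]
        assert evaluate_phase2(self._counts(good, bad), REQ100).passed

    def test_just_below_good_threshold_fails(self):
        assert not evaluate_phase2(self._counts(71, 0), REQ100).passed

    def test_too_many_bad_fails(self):
        assert not evaluate_phase2(self._counts(90, 10), REQ100).passed

    def test_boundary_passes(self):
        assert evaluate_phase2(self._counts(72, 9), REQ100).passed

    def test_subject_count_mismatch_rejected(self):
        with pytest.raises(ProtocolError, match="subjects"):
            evaluate_phase2(self._counts(80, 0, n=99), REQ100)

    def test_counts_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            evaluate_phase2({"P1": 4, **self._counts(70, 0, n=99)}, REQ100)


class TestValidateDevice:
    def test_identical_devices_pass(self):
        rng = np.random.default_rng(0)
        ds = build_dataset({
            (f"P{i}", sess, "SBP"): [float(rng.integers(100, 160))] * 7
            for i in range(BASE_N_SUBJECTS)
            for sess in (1, 2)
        })
        verdict = validate_device(ds, variables=["SBP"])
        assert verdict.passed
        for r in verdict.results.values():
            assert r.mean_difference == 0.0 and r.sd_difference == 0.0

    def test_large_bias_fails_phase1(self):
        config = SimulationConfig(n_subjects=40, seed=3, dropout=0.0, test_bias=20.0)
        verdict = validate_device(generate_study(config), variables=["SBP", "DBP"])
        assert not verdict.passed
        for r in verdict.results.values():
            assert not r.phase1.passed
            # most selected differences land beyond the widest band
            assert r.phase1.counts["beyond_b3"] > r.phase1.requirements.n_pairs / 2
        assert verdict.failing()

    def test_paper_like_scenario_passes(self):
        from bpval.simulate import load_scenario
        ds = generate_study(load_scenario("paper_like"))
        verdict = validate_device(ds)
        assert verdict.n_subjects == 100
        assert verdict.passed

    def test_too_few_participants(self, tiny_dataset):
        with pytest.raises(ProtocolError, match="complete participants"):
            validate_device(tiny_dataset, variables=["SBP"])

    def test_absolute_difference_convention(self):
        config = SimulationConfig(n_subjects=35, seed=5, dropout=0.0)
        ds = generate_study(config)
        signed = validate_device(ds, variables=["SBP"])
        absolute = validate_device(ds, variables=["SBP"], use_absolute_differences=True)
        for key in signed.results:
            assert absolute.results[key].mean_difference >= abs(
                signed.results[key].mean_difference
            )

    def test_early_exit_stops_after_failing_session(self):
        config = SimulationConfig(n_subjects=35, seed=5, dropout=0.0, test_bias=20.0)
        ds = generate_study(config)
        verdict = validate_device(ds, variables=["SBP"], early_exit=True)
        assert list(verdict.results) == [(1, "SBP")]


class TestOracleEquivalence:
    def test_random_small_studies_match_brute_force(self, rng):
        bands = {"SBP": (5, 10, 15), "HR": (3, 5, 8)}
        for _ in range(60):
            var = "SBP" if rng.random() < 0.5 else "HR"
            spread = rng.integers(2, 12)
            raw = {
                f"P{i:02d}": list(map(float, rng.integers(
                    100, 160, size=7) + rng.integers(-spread, spread + 1, size=7)))
                for i in range(BASE_N_SUBJECTS)
            }
            ds = build_dataset({(pid, 1, var): v for pid, v in raw.items()})
            # package verdicts need both sessions; evaluate session 1 only
            triples = [
                select_differences(ds.get_series(pid, 1, var)) for pid in raw
            ]
            thresholds = BandThresholds.for_variable(var)
            counts, _ = band_counts(triples, thresholds)
            req = scale_requirements(BASE_N_SUBJECTS)
            p1 = evaluate_phase1(counts, req).passed
            p2 = evaluate_phase2(per_subject_band1_counts(triples, thresholds), req).passed
            assert (p1, p2) == brute_phase_verdicts(raw, bands[var], BASE_N_SUBJECTS)


class TestDecisionMonotonicity:
    def test_uniform_positive_offset_never_rescues_a_failure(self):
        """With all signed differences already non-negative, growing the test
        offset can only move differences further out of band."""
        base = SimulationConfig(n_subjects=35, seed=11, dropout=0.0)
        previous_passed = None
        for bias in (12.0, 16.0, 20.0, 30.0):
            ds = generate_study(base.replace(test_bias=bias))
            # bias dominates all noise terms: every signed difference positive
            verdict = validate_device(ds, variables=["SBP"])
            for r in verdict.results.values():
                assert r.mean_difference > 0
            if previous_passed is not None and not previous_passed:
                assert not verdict.passed
            previous_passed = verdict.passed
        assert previous_passed is False
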