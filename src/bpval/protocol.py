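"""Pass/fail decision machinery for alternating-device validation studies.

For each test-device reading (positions 2, 4, 6) the selected difference is
the smaller of its absolute differences against the flanking criterion
readings.  Selected differences are banded cumulatively (<=b1, <=b2, <=b3,
inclusive bounds) and counted against requirements scaled from a base cohort
of 33 subjects.  Two phases are evaluated per session x variable:

* pair level: band counts over all 3n selected differences must clear a
  "two of" triple (any two of three) and an "all of" triple (all three);
* subject level: enough subjects with >=2 of their 3 differences within b1,
  and few enough subjects with none within b1.

The device passes overall iff every evaluated session x variable passes
both phases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from statistics import mean, stdev
from typing import Iterable, Mapping, Optional, Sequence

from .model import SessionSeries, StudyDataset, Variable

__all__ = [
    "BandThresholds",
    "DifferenceTriple",
    "RequirementSet",
    "Phase",
    "Verdict",
    "PhaseOutcome",
    "SessionVariableResult",
    "ValidationVerdict",
    "ProtocolError",
    "BASE_N_SUBJECTS",
    "BASE_PAIR_TWO_OF",
    "BASE_PAIR_ALL_OF",
    "BASE_SUBJ_MIN_GOOD",
    "BASE_SUBJ_MAX_BAD",
    "DEFAULT_BANDS",
    "select_differences",
    "band_counts",
    "per_subject_band1_counts",
    "scale_requirements",
    "evaluate_phase1",
    "evaluate_phase2",
    "validate_device",
]

# Base requirements for the reference cohort size of 33 subjects (99 pairs).
BASE_N_SUBJECTS = 33
BASE_PAIR_TWO_OF = (73, 87, 96)
BASE_PAIR_ALL_OF = (65, 81, 93)
BASE_SUBJ_MIN_GOOD = 24
BASE_SUBJ_MAX_BAD = 3


class ProtocolError(ValueError):
    """Protocol preconditions not met (e.g. cohort too small)."""


class Phase(str, Enum):
    PAIR_LEVEL = "pair_level"
    SUBJECT_LEVEL = "subject_level"


class Verdict(str, Enum):
    PASS = "pass"
    FAIL = "fail"


@dataclass(frozen=True)
class BandThresholds:
    """Cumulative accuracy bands for one variable, inclusive upper bounds."""

    variable: Variable
    bands: tuple[float, float, float]

    def __post_init__(self) -> None:
        b1, b2, b3 = self.bands
        if not (0 < b1 < b2 < b3):
            raise ValueError(f"bands must be positive and increasing, got {self.bands}")

    @classmethod
    def for_variable(cls, variable: Variable | str) -> "BandThresholds":
        variable = Variable(variable)
        bands = (3.0, 5.0, 8.0) if variable is Variable.HR else (5.0, 10.0, 15.0)
        return cls(variable=variable, bands=bands)


DEFAULT_BANDS: Mapping[Variable, BandThresholds] = {
    v: BandThresholds.for_variable(v) for v in Variable
}


@dataclass(frozen=True)
class DifferenceTriple:
    """The three selected test-vs-criterion differences for one series.

    ``selected[i]`` is the smaller of the two flanking absolute differences
    for test position 2i+2; ``flanking[i]`` keeps both for audit; ``signed[i]``
    is test minus criterion for the selected flank (ties resolve to the
    preceding flank).
    """

    participant_id: str
    session: int
    variable: Variable
    selected: tuple[float, float, float]
    flanking: tuple[tuple[float, float], tuple[float, float], tuple[float, float]]
    signed: tuple[float, float, float]

    def __post_init__(self) -> None:
        for d, (before, after) in zip(self.selected, self.flanking):
            if d < 0 or not math.isclose(d, min(before, after)):
                raise ValueError(
                    f"selected difference {d} is not the minimum of flanking {before, after}"
                )


def select_differences(series: SessionSeries) -> DifferenceTriple:
    """Selected differences for one complete seven-reading series.

    For each test position p in {2, 4, 6}: d = min(|v_p - v_{p-1}|, |v_p - v_{p+1}|).
    """
    values = series.values
    series._require_complete()
    selected, flanking, signed = [], [], []
    for p in (2, 4, 6):
        v = values[p - 1]
        before = abs(v - values[p - 2])
        after = abs(v - values[p])
        flanking.append((before, after))
        if before <= after:
            selected.append(before)
            signed.append(v - values[p - 2])
        else:
            selected.append(after)
            signed.append(v - values[p])
    return DifferenceTriple(
        participant_id=series.participant_id,
        session=series.session,
        variable=series.variable,
        selected=tuple(selected),
        flanking=tuple(flanking),
        signed=tuple(signed),
    )


def band_counts(
    diffs: Iterable[DifferenceTriple], thresholds: BandThresholds
) -> tuple[tuple[int, int, int], int]:
    """Cumulative band counts over all selected differences.

    Returns ``((n <= b1, n <= b2, n <= b3), n > b3)``.  Band bounds are
    inclusive: a difference exactly at a threshold falls inside the band.
    """
    diffs = list(diffs)
    variables = {d.variable for d in diffs}
    if len(variables) > 1:
        raise ValueError(f"mixed variables in band count: {sorted(v.value for v in variables)}")
    if variables and next(iter(variables)) is not thresholds.variable:
        raise ValueError(
            f"thresholds are for {thresholds.variable.value}, "
            f"differences are {next(iter(variables)).value}"
        )
    b1, b2, b3 = thresholds.bands
    flat = [d for triple in diffs for d in triple.selected]
    counts = (
        sum(d <= b1 for d in flat),
        sum(d <= b2 for d in flat),
        sum(d <= b3 for d in flat),
    )
    return counts, len(flat) - counts[2]


def per_subject_band1_counts(
    diffs: Iterable[DifferenceTriple], thresholds: BandThresholds
) -> dict[str, int]:
    """Per participant, how many of the 3 selected differences fall within b1."""
    b1 = thresholds.bands[0]
    return {d.participant_id: sum(x <= b1 for x in d.selected) for d in diffs}


@dataclass(frozen=True)
class RequirementSet:
    """Pass thresholds scaled to the cohort size."""

    n_subjects: int
    scale_factor: int
    pair_two_of: tuple[int, int, int]
    pair_all_of: tuple[int, int, int]
    subj_min_good: int
    subj_max_bad: int

    @property
    def n_pairs(self) -> int:
        return 3 * self.n_subjects

    def __post_init__(self) -> None:
        if any(a > t for a, t in zip(self.pair_all_of, self.pair_two_of)):
            raise ValueError("'all of' thresholds must not exceed 'two of' thresholds")
        if max(self.pair_two_of) > self.n_pairs:
            raise ValueError("pair-level thresholds exceed the number of pairs")


def scale_requirements(n_subjects: int) -> RequirementSet:
    """Scale the base 33-subject requirements by k = round(n/33).

    A single integer factor is used; e.g. n = 100 gives k = 3 and thresholds
    (219, 261, 288) / (195, 243, 279), 72 good subjects minimum and 9 bad
    subjects maximum.
    """
    if n_subjects < BASE_N_SUBJECTS:
        raise ProtocolError(
            f"protocol undefined below {BASE_N_SUBJECTS} subjects (got {n_subjects})"
        )
    k = math.floor(n_subjects / BASE_N_SUBJECTS + 0.5)
    if BASE_PAIR_TWO_OF[2] * k > 3 * n_subjects:
        # cohorts well below k multiples of 33 cannot satisfy the scaled counts
        raise ProtocolError(
            f"requirements for scale factor {k} are infeasible with {n_subjects} "
            f"subjects; use a cohort size near a multiple of {BASE_N_SUBJECTS}"
        )
    return RequirementSet(
        n_subjects=n_subjects,
        scale_factor=k,
        pair_two_of=tuple(k * c for c in BASE_PAIR_TWO_OF),
        pair_all_of=tuple(k * c for c in BASE_PAIR_ALL_OF),
        subj_min_good=k * BASE_SUBJ_MIN_GOOD,
        subj_max_bad=k * BASE_SUBJ_MAX_BAD,
    )


@dataclass(frozen=True)
class PhaseOutcome:
    phase: Phase
    counts: dict
    requirements: RequirementSet
    criteria_met: dict
    verdict: Verdict

    @property
    def passed(self) -> bool:
        return self.verdict is Verdict.PASS


def evaluate_phase1(counts: Sequence[int], req: RequirementSet) -> PhaseOutcome:
    """Pair-level evaluation of cumulative band counts.

    Pass iff at least two of the three band counts clear the "two of"
    thresholds AND all three clear the "all of" thresholds.
    """
    counts = tuple(int(c) for c in counts)
    if len(counts) != 3:
        raise ValueError("expected a cumulative count triple")
    if any(c1 > c2 for c1, c2 in zip(counts, counts[1:])):
        raise ValueError(f"cumulative counts must be non-decreasing, got {counts}")
    if counts[2] > req.n_pairs:
        raise ValueError(f"count {counts[2]} exceeds {req.n_pairs} pairs")
    two_of_flags = tuple(c >= t for c, t in zip(counts, req.pair_two_of))
    all_of_flags = tuple(c >= t for c, t in zip(counts, req.pair_all_of))
    passed = sum(two_of_flags) >= 2 and all(all_of_flags)
    return PhaseOutcome(
        phase=Phase.PAIR_LEVEL,
        counts={"band_counts": counts, "beyond_b3": req.n_pairs - counts[2]},
        requirements=req,
        criteria_met={
            "two_of": two_of_flags,
            "two_of_satisfied": sum(two_of_flags) >= 2,
            "all_of": all_of_flags,
            "all_of_satisfied": all(all_of_flags),
        },
        verdict=Verdict.PASS if passed else Verdict.FAIL,
    )


def evaluate_phase2(
    per_subject_counts: Mapping[str, int] | Sequence[int], req: RequirementSet
) -> PhaseOutcome:
    """Subject-level evaluation.

    ``per_subject_counts`` maps each participant to the number (0..3) of
    selected differences within band 1.  Pass iff the number of subjects with
    count >= 2 meets ``subj_min_good`` and the number with count 0 does not
    exceed ``subj_max_bad``.
    """
    values = (
        list(per_subject_counts.values())
        if isinstance(per_subject_counts, Mapping)
        else list(per_subject_counts)
    )
    if any(v not in (0, 1, 2, 3) for v in values):
        raise ValueError("per-subject band-1 counts must be in 0..3")
    if len(values) != req.n_subjects:
        raise ProtocolError(
            f"{len(values)} subjects supplied but requirements scaled for {req.n_subjects}"
        )
    good = sum(v >= 2 for v in values)
    bad = sum(v == 0 for v in values)
    passed = good >= req.subj_min_good and bad <= req.subj_max_bad
    return PhaseOutcome(
        phase=Phase.SUBJECT_LEVEL,
        counts={"good": good, "bad": bad},
        requirements=req,
        criteria_met={
            "min_good": good >= req.subj_min_good,
            "max_bad": bad <= req.subj_max_bad,
        },
        verdict=Verdict.PASS if passed else Verdict.FAIL,
    )


@dataclass(frozen=True)
class SessionVariableResult:
    session: int
    variable: Variable
    phase1: PhaseOutcome
    phase2: PhaseOutcome
    mean_difference: float
    sd_difference: float
    n_subjects: int

    @property
    def passed(self) -> bool:
        return self.phase1.passed and self.phase2.passed


@dataclass
class ValidationVerdict:
    results: dict[tuple[int, str], SessionVariableResult] = field(default_factory=dict)
    requirements: Optional[RequirementSet] = None
    n_subjects: int = 0
    participants: list[str] = field(default_factory=list)

    @property
    def overall(self) -> Verdict:
        ok = all(r.passed for r in self.results.values())
        return Verdict.PASS if ok and self.results else Verdict.FAIL

    @property
    def passed(self) -> bool:
        return self.overall is Verdict.PASS

    def failing(self) -> list[str]:
        """Human-readable list of failing criteria."""
        out = []
        for (sess, var), r in sorted(self.results.items()):
            if not r.phase1.passed:
                out.append(f"session {sess} {var}: pair-level counts "
                           f"{r.phase1.counts['band_counts']} below requirements")
            if not r.phase2.passed:
                out.append(f"session {sess} {var}: subject-level counts "
                           f"{r.phase2.counts} outside requirements")
        return out


def validate_device(
    dataset: StudyDataset,
    variables: Sequence[Variable | str] = (Variable.SBP, Variable.DBP, Variable.HR),
    sessions: Sequence[int] = (1, 2),
    use_absolute_differences: bool = False,
    early_exit: bool = False,
) -> ValidationVerdict:
    """Run the full two-phase evaluation over the requested sessions x variables.

    Only participants with complete series for every requested session x
    variable are included, so the same cohort underlies every evaluation.
    ``use_absolute_differences`` switches the reported mean +/- SD from signed
    (test - criterion, selected flank) to absolute selected differences.
    ``early_exit`` stops at the first failing session (sequential reading of
    the protocol); off by default.
    """
    variables = [Variable(v) for v in variables]
    sessions = list(sessions)
    participants = dataset.complete_participants(sessions, variables)
    if len(participants) < BASE_N_SUBJECTS:
        raise ProtocolError(
            f"only {len(participants)} complete participants; "
            f"protocol requires at least {BASE_N_SUBJECTS}"
        )
    req = scale_requirements(len(participants))
    verdict = ValidationVerdict(
        requirements=req, n_subjects=len(participants), participants=participants
    )
    for sess in sessions:
        session_failed = False
        for var in variables:
            thresholds = DEFAULT_BANDS[var]
            triples = [
                select_differences(dataset.get_series(pid, sess, var))
                for pid in participants
            ]
            counts, _ = band_counts(triples, thresholds)
            phase1 = evaluate_phase1(counts, req)
            phase2 = evaluate_phase2(per_subject_band1_counts(triples, thresholds), req)
            diffs = [
                (abs(d) if use_absolute_differences else d)
                for t in triples
                for d in (t.selected if use_absolute_differences else t.signed)
            ]
            result = SessionVariableResult(
                session=sess,
                variable=var,
                phase1=phase1,
                phase2=phase2,
                mean_difference=mean(diffs),
                sd_difference=stdev(diffs) if len(diffs) > 1 else 0.0,
                n_subjects=len(participants),
            )
            verdict.results[(sess, var.value)] = result
            if not result.passed:
                session_failed = True
        if early_exit and session_failed:
            break
    return verdict
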