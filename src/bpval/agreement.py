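"""Between-device agreement on participant-level means: t-tests, Pearson
correlation and Bland-Altman limits of agreement."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .model import StudyDataset, Variable

__all__ = [
    "Scope",
    "TTestMode",
    "ParticipantDeviceMeans",
    "MeanComparisonResult",
    "CorrelationResult",
    "BlandAltmanSummary",
    "participant_means",
    "device_mean_comparison",
    "device_correlation",
    "bland_altman",
]

logger = logging.getLogger(__name__)


class Scope(str, Enum):
    SESSION1 = "session1"
    SESSION2 = "session2"
    INTERSESSION = "intersession"

    @property
    def sessions(self) -> tuple[int, ...]:
        return {"session1": (1,), "session2": (2,), "intersession": (1, 2)}[self.value]


class TTestMode(str, Enum):
    INDEPENDENT = "independent"
    PAIRED = "paired"


@dataclass(frozen=True)
class ParticipantDeviceMeans:
    participant_id: str
    variable: Variable
    scope: Scope
    criterion_mean: float
    test_mean: float


def participant_means(
    dataset: StudyDataset,
    scope: Scope | str = Scope.INTERSESSION,
    variables: Sequence[Variable | str] = (Variable.SBP, Variable.DBP, Variable.HR),
) -> list[ParticipantDeviceMeans]:
    """Per participant x variable, the mean criterion and test readings.

    Session scopes average the 4 criterion / 3 test readings of that session;
    the intersession scope averages over both sessions (8 and 6 readings).
    Participants lacking a complete series for the scope are excluded with a
    logged warning.
    """
    scope = Scope(scope)
    variables = [Variable(v) for v in variables]
    out: list[ParticipantDeviceMeans] = []
    excluded: dict[Variable, list[str]] = {v: [] for v in variables}
    for pid in dataset.participant_ids:
        for var in variables:
            series = [dataset.get_series(pid, s, var) for s in scope.sessions]
            if any(s is None or not s.complete for s in series):
                excluded[var].append(pid)
                continue
            crit = [v for s in series for v in s.criterion_values()]
            test = [v for s in series for v in s.test_values()]
            out.append(
                ParticipantDeviceMeans(
                    participant_id=pid,
                    variable=var,
                    scope=scope,
                    criterion_mean=float(np.mean(crit)),
                    test_mean=float(np.mean(test)),
                )
            )
    for var, pids in excluded.items():
        if pids:
            logger.warning(
                "%d participant(s) excluded from %s means for %s "
                "(incomplete series): %s",
                len(pids), scope.value, var.value, ", ".join(pids[:5])
                + (", ..." if len(pids) > 5 else ""),
            )
    return out


def _columns(means: Sequence[ParticipantDeviceMeans]) -> tuple[np.ndarray, np.ndarray]:
    if len({m.variable for m in means}) > 1:
        raise ValueError("means mix variables; compute per variable")
    crit = np.array([m.criterion_mean for m in means], dtype=float)
    test = np.array([m.test_mean for m in means], dtype=float)
    return crit, test


@dataclass(frozen=True)
class MeanComparisonResult:
    t: float
    p: float
    mode: TTestMode
    criterion_mean: float
    criterion_sd: float
    test_mean: float
    test_sd: float
    n: int
    degenerate: bool = False


def device_mean_comparison(
    means: Sequence[ParticipantDeviceMeans],
    mode: TTestMode | str = TTestMode.INDEPENDENT,
) -> MeanComparisonResult:
    """t-test for a device difference in participant means.

    Default treats the two devices' mean vectors as independent samples;
    ``paired`` mode pairs them within participant.
    """
    mode = TTestMode(mode)
    crit, test = _columns(means)
    if crit.size < 2:
        raise ValueError("need at least 2 participants per device")
    summary = dict(
        mode=mode,
        criterion_mean=float(crit.mean()),
        criterion_sd=float(crit.std(ddof=1)),
        test_mean=float(test.mean()),
        test_sd=float(test.std(ddof=1)),
        n=crit.size,
    )
    if mode is TTestMode.PAIRED:
        d = test - crit
        if d.std(ddof=1) == 0:
            t, p, dg = (0.0, 1.0, True) if d.mean() == 0 else (
                math.copysign(math.inf, d.mean()), 0.0, True)
            return MeanComparisonResult(t=t, p=p, degenerate=dg, **summary)
        t, p = stats.ttest_rel(test, crit)
    else:
        if crit.std(ddof=1) == 0 and test.std(ddof=1) == 0:
            delta = test.mean() - crit.mean()
            t, p, dg = (0.0, 1.0, True) if delta == 0 else (
                math.copysign(math.inf, delta), 0.0, True)
            return MeanComparisonResult(t=t, p=p, degenerate=dg, **summary)
        t, p = stats.ttest_ind(test, crit)
    return MeanComparisonResult(t=float(t), p=float(p), **summary)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    degenerate: bool = False


def device_correlation(means: Sequence[ParticipantDeviceMeans]) -> CorrelationResult:
    """Pearson correlation of (criterion_mean, test_mean) pairs."""
    crit, test = _columns(means)
    if crit.size < 3:
        raise ValueError("need at least 3 participants")
    if crit.std() == 0 or test.std() == 0:
        return CorrelationResult(r=float("nan"), p=float("nan"), n=crit.size,
                                 degenerate=True)
    res = stats.pearsonr(crit, test)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=crit.size)


@dataclass(frozen=True)
class BlandAltmanSummary:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    points: tuple[tuple[str, float, float], ...]  # (participant_id, average, difference)
    n: int
    variable: Optional[Variable] = None


def bland_altman(means: Sequence[ParticipantDeviceMeans]) -> BlandAltmanSummary:
    """Bias and 1.96-SD limits of agreement on test minus criterion means.

    One point per participant: x = average of the two device means,
    y = test mean minus criterion mean.
    """
    crit, test = _columns(means)
    if crit.size < 3:
        raise ValueError("need at least 3 participants")
    diff = test - crit
    avg = (test + crit) / 2.0
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltmanSummary(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        points=tuple(
            (m.participant_id, float(a), float(d))
            for m, a, d in zip(means, avg, diff)
        ),
        n=crit.size,
        variable=means[0].variable if means else None,
    )
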