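"""Torque-domain segmentation and performance indices.

The operant measure of self-learning is dwell time: how long the fly's
yaw torque stays in each sign domain.  The performance index of a
period is PI = (ta - tb) / (ta + tb), where tb is time punished (heat
on during training; time in the punished domain during pretests and
tests) and ta the complementary time.  PI = +1 means the whole period
was spent avoiding the punished situation, -1 the opposite, 0.5 means
90 of 120 s were spent unpunished.

Segmentation uses no hysteresis: a new dwell interval starts exactly at
each sign change of the torque.  A sample with torque exactly 0 inherits
the previous sample's domain (a leading zero-run inherits the first
nonzero sample's domain); an all-zero period has no defined PI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import Domain, ExperimentRecord, PeriodKind
from .errors import MissingTraceError, UndefinedPIError, UnsupportedProtocolError

__all__ = [
    "DwellInterval",
    "DwellSegmentation",
    "PerformanceIndex",
    "segment_domains",
    "period_times",
    "performance_index",
    "learning_score",
    "period_pi_table",
]


@dataclass(frozen=True)
class DwellInterval:
    start_s: float
    end_s: float
    domain: Domain


@dataclass
class DwellSegmentation:
    """Per torque period, the contiguous dwell intervals tiling it."""

    intervals: dict[int, list[DwellInterval]]  # period index -> intervals

    def domain_time(self, period_index: int, domain: Domain) -> float:
        return sum(
            iv.end_s - iv.start_s
            for iv in self.intervals[period_index]
            if iv.domain is domain
        )


@dataclass(frozen=True)
class PerformanceIndex:
    period_index: int
    ta: float  # seconds unpunished / heat off
    tb: float  # seconds punished / heat on
    pi: float


def _domain_signs(torque: np.ndarray) -> np.ndarray:
    """Per-sample domain sign (+1 right, -1 left) with zero inheritance.

    Zeros take the previous sample's sign; leading zeros take the first
    nonzero sign.  Returns an all-zero array iff torque is identically 0.
    """
    sign = np.sign(torque)
    nz = np.flatnonzero(sign)
    if len(nz) == 0:
        return sign.astype(int)
    # forward-fill zero runs from the previous nonzero sample
    idx = np.maximum.accumulate(np.where(sign != 0, np.arange(len(sign)), -1))
    # leading zeros: backfill from the first nonzero sample
    idx[idx < 0] = nz[0]
    return sign[idx].astype(int)


def segment_domains(record: ExperimentRecord) -> DwellSegmentation:
    """Segment every torque period of a record into dwell intervals.

    Interval boundaries sit at the sample times where the sign changes;
    each sample owns the half-open window [t_k, t_k + step), so summed
    interval durations equal per-sample counts times the step exactly.
    """
    if len(record.trace) == 0:
        raise MissingTraceError(f"{record.fly_id}: empty trace")
    step = record.sample_step_s
    out: dict[int, list[DwellInterval]] = {}
    for p in record.schedule.torque_periods():
        start, end = record.schedule.period_bounds(p.index)
        sl = record.period_slice(p.index)
        torque = sl["torque"].to_numpy(dtype=float)
        if len(torque) == 0:
            out[p.index] = []
            continue
        signs = _domain_signs(torque)
        if np.all(signs == 0):
            # all-zero period: leave undomained; PI will be undefined
            out[p.index] = []
            continue
        t = sl["t_s"].to_numpy(dtype=float)
        change = np.flatnonzero(np.diff(signs) != 0) + 1
        bounds = np.concatenate(([0], change, [len(signs)]))
        intervals = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            iv_start = start if a == 0 else float(t[a])
            iv_end = end if b == len(signs) else float(t[b])
            domain = Domain.RIGHT if signs[a] > 0 else Domain.LEFT
            intervals.append(DwellInterval(iv_start, iv_end, domain))
        out[p.index] = intervals
    return DwellSegmentation(intervals=out)


def period_times(
    segmentation: DwellSegmentation,
    record: ExperimentRecord,
    period_index: int,
) -> tuple[float, float]:
    """(ta, tb) for one torque period.

    Training periods count the recorded heat flag (honouring any device
    latency present in the data): tb = heat-on time.  Pretest and test
    periods count dwell time in the (to-be-)punished domain.
    """
    period = record.schedule.periods[period_index - 1]
    if not period.is_torque_period:
        raise UnsupportedProtocolError(
            f"period {period_index} is an optomotor period; no PI defined"
        )
    duration = period.duration_s
    if period.kind is PeriodKind.TRAINING:
        sl = record.period_slice(period_index)
        step = record.sample_step_s
        tb = float(np.count_nonzero(sl["heat"].to_numpy(dtype=bool))) * step
        tb = min(tb, duration)
        return duration - tb, tb
    if period_index not in segmentation.intervals or not segmentation.intervals[
        period_index
    ]:
        raise UndefinedPIError(
            f"{record.fly_id}: period {period_index} has no flight (all-zero torque)"
        )
    tb = segmentation.domain_time(period_index, record.punished_domain)
    ta = segmentation.domain_time(period_index, record.punished_domain.opposite)
    return ta, tb


def performance_index(ta: float, tb: float) -> float:
    """PI = (ta - tb) / (ta + tb); undefined when the fly never flew."""
    if ta < 0 or tb < 0:
        raise ValueError("ta and tb must be non-negative")
    total = ta + tb
    if total == 0:
        raise UndefinedPIError("ta + tb = 0: performance index undefined")
    return (ta - tb) / total


def learning_score(record: ExperimentRecord) -> float:
    """PI of the first test period after the last training period.

    Period 8 in the Tang protocol, period 12 in the new one; positive
    values mean the fly avoided the formerly punished domain.
    """
    idx = record.schedule.learning_test_index()
    seg = segment_domains(record)
    ta, tb = period_times(seg, record, idx)
    return performance_index(ta, tb)


def period_pi_table(record: ExperimentRecord) -> list[PerformanceIndex]:
    """ta, tb and PI for every torque period of the record.

    Periods with undefined PI (no flight) are reported with pi = nan.
    """
    seg = segment_domains(record)
    rows = []
    for p in record.schedule.torque_periods():
        try:
            ta, tb = period_times(seg, record, p.index)
            pi = performance_index(ta, tb)
        except UndefinedPIError:
            ta, tb, pi = 0.0, 0.0, float("nan")
        rows.append(PerformanceIndex(period_index=p.index, ta=ta, tb=tb, pi=pi))
    return rows
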