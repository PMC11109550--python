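"""Per-fly quality control: the four exclusion rules.

A fly's data are excluded from analysis when any of these fires:

1. laser_lethality — the fly survived the post-experiment laser
   exposure for 15 s or longer (boundary inclusive), indicating the
   punishing laser was mis-adjusted; missing survival metadata fails
   conservatively.
2. omr_presence — the before-training optomotor responses are absent
   (both magnitudes below a noise floor) or "shifted" (both stimulus
   directions elicit same-signed torque, or extreme pre-training
   asymmetry).  Tang-setup records, which store no optomotor periods,
   pass vacuously.
3. laser_experience — the fly was never heated during any training
   period (it never entered the punished domain, so nothing could be
   learned about the contingency).
4. flight_performance — constant stopping of flight: five or more
   flat spans, or more than 10 % of torque-period time spent with the
   1-s sliding torque standard deviation below 1 % of the trace's
   global standard deviation.

Exclusion never discards data: the full trace stays in the dataset and
the report records which rule fired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import ExperimentRecord, OmDirection, PeriodKind
from .errors import UnsupportedProtocolError
from .optomotor import OmFit, om_phase_fits
from .selflearn import period_pi_table

__all__ = [
    "QcCheck",
    "QcResult",
    "QcThresholds",
    "check_laser_lethality",
    "check_omr_presence",
    "check_laser_experience",
    "check_flight_performance",
    "run_qc",
    "qc_report",
]

RULES = (
    "laser_lethality",
    "omr_presence",
    "laser_experience",
    "flight_performance",
)


@dataclass(frozen=True)
class QcThresholds:
    """Configurable rule thresholds (defaults; override via descriptor)."""

    laser_survival_max_s: float = 15.0   # fail at >= this survival time
    omr_noise_floor_frac: float = 0.10   # fraction of global torque sd
    shifted_asym_max: float = 0.8        # |raw asymmetry| above this = shifted
    stop_sd_frac: float = 0.01           # flat iff 1-s sd < this * global sd
    stop_window_s: float = 1.0
    max_stops: int = 5                   # fail at >= this many stops
    max_stopped_frac: float = 0.10       # of torque-period time


@dataclass(frozen=True)
class QcCheck:
    rule: str
    passed: bool
    detail: str


@dataclass
class QcResult:
    fly_id: str
    checks: list[QcCheck]
    included: bool
    override_reason: str | None = None

    def failing_rules(self) -> list[str]:
        return [c.rule for c in self.checks if not c.passed]


def check_laser_lethality(
    record: ExperimentRecord, thresholds: QcThresholds = QcThresholds()
) -> QcCheck:
    raw = record.metadata.get("laser_survival_s")
    if raw is None:
        return QcCheck("laser_lethality", False, "laser survival not recorded")
    try:
        survival = float(raw)
    except ValueError:
        return QcCheck("laser_lethality", False, f"unparseable survival {raw!r}")
    passed = survival < thresholds.laser_survival_max_s
    return QcCheck(
        "laser_lethality",
        passed,
        f"survived laser for {survival:g} s "
        f"({'<' if passed else '>='} {thresholds.laser_survival_max_s:g} s)",
    )


def check_omr_presence(
    record: ExperimentRecord,
    om_fits: list[OmFit] | None = None,
    thresholds: QcThresholds = QcThresholds(),
) -> QcCheck:
    """Absent or shifted optomotor response before training.

    Uses before-phase fits; absent = both direction-congruent
    magnitudes below the noise floor (a fraction of the global torque
    sd); shifted = signed magnitudes of the two directions share a
    sign, or the pre-training raw asymmetry exceeds the configured
    bound.
    """
    if not record.schedule.om_periods():
        return QcCheck("omr_presence", True, "no stored OM periods (Tang setup)")
    if om_fits is None:
        om_fits = om_phase_fits(record, "before")
    cw = [f.magnitude for f in om_fits if f.direction is OmDirection.CLOCKWISE]
    ccw = [
        f.magnitude for f in om_fits if f.direction is OmDirection.COUNTERCLOCKWISE
    ]
    mean_cw = float(np.mean(cw))
    mean_ccw = float(np.mean(ccw))
    floor = thresholds.omr_noise_floor_frac * float(
        np.std(record.trace["torque"].to_numpy())
    )
    right = max(0.0, mean_cw)
    left = max(0.0, -mean_ccw)
    if right < floor and left < floor:
        return QcCheck(
            "omr_presence",
            False,
            f"no OMR: magnitudes ({right:.3g}, {left:.3g}) below floor {floor:.3g}",
        )
    if mean_cw * mean_ccw > 0:
        return QcCheck(
            "omr_presence",
            False,
            f"shifted OMR: both directions respond with the same sign "
            f"(cw {mean_cw:.3g}, ccw {mean_ccw:.3g})",
        )
    total = right + left
    raw = (right - left) / total if total > 0 else 0.0
    if abs(raw) > thresholds.shifted_asym_max:
        return QcCheck(
            "omr_presence",
            False,
            f"shifted OMR: pre-training asymmetry {raw:.2f} exceeds "
            f"{thresholds.shifted_asym_max:g}",
        )
    return QcCheck(
        "omr_presence", True, f"OMR present (cw {mean_cw:.3g}, ccw {mean_ccw:.3g})"
    )


def check_laser_experience(record: ExperimentRecord) -> QcCheck:
    t = record.trace["t_s"].to_numpy(dtype=float)
    heat = record.trace["heat"].to_numpy(dtype=bool)
    step = record.sample_step_s
    in_training = np.zeros(len(t), dtype=bool)
    for p in record.schedule.periods:
        if p.kind is PeriodKind.TRAINING:
            a, b = record.schedule.period_bounds(p.index)
            in_training |= (t >= a - 0.5 * step) & (t < b - 0.5 * step)
    heated = bool(np.any(heat & in_training))
    stray = bool(np.any(heat & ~in_training))
    detail = "heat experienced during training" if heated else (
        "heat never on during any training period"
    )
    if stray:
        detail += "; WARNING: heat flag set outside training (corrupt data?)"
    return QcCheck("laser_experience", heated, detail)


def _flight_stops(
    record: ExperimentRecord, thresholds: QcThresholds
) -> tuple[int, float, float]:
    """(number of stops, total stopped seconds, torque-period seconds).

    A stop is a maximal run of sliding windows (width stop_window_s)
    whose torque standard deviation falls below stop_sd_frac times the
    trace's global sd; any such run spans at least one window width.
    """
    step = record.sample_step_s
    w = max(2, int(round(thresholds.stop_window_s / step)))
    eps = thresholds.stop_sd_frac * float(np.std(record.trace["torque"].to_numpy()))
    n_stops = 0
    stopped_s = 0.0
    torque_time = 0.0
    for p in record.schedule.torque_periods():
        sl = record.period_slice(p.index)
        y = sl["torque"].to_numpy(dtype=float)
        torque_time += p.duration_s
        if len(y) < w:
            continue
        # rolling sd over windows [i, i+w)
        c1 = np.cumsum(np.insert(y, 0, 0.0))
        c2 = np.cumsum(np.insert(y * y, 0, 0.0))
        mean = (c1[w:] - c1[:-w]) / w
        var = np.maximum(0.0, (c2[w:] - c2[:-w]) / w - mean * mean)
        flat = np.sqrt(var) < eps
        if not flat.any():
            continue
        edges = np.diff(flat.astype(int))
        starts = list(np.flatnonzero(edges == 1) + 1)
        ends = list(np.flatnonzero(edges == -1) + 1)
        if flat[0]:
            starts.insert(0, 0)
        if flat[-1]:
            ends.append(len(flat))
        for a, b in zip(starts, ends):
            n_stops += 1
            stopped_s += ((b - a - 1) + w) * step
    return n_stops, stopped_s, torque_time


def check_flight_performance(
    record: ExperimentRecord, thresholds: QcThresholds = QcThresholds()
) -> QcCheck:
    n_stops, stopped_s, torque_time = _flight_stops(record, thresholds)
    frac = stopped_s / torque_time if torque_time > 0 else 0.0
    passed = n_stops < thresholds.max_stops and frac <= thresholds.max_stopped_frac
    return QcCheck(
        "flight_performance",
        passed,
        f"{n_stops} flight stop(s), {stopped_s:.1f} s stopped "
        f"({100 * frac:.1f}% of torque-period time)",
    )


def run_qc(
    record: ExperimentRecord,
    om_fits: list[OmFit] | None = None,
    thresholds: QcThresholds = QcThresholds(),
    override: tuple[bool, str] | None = None,
) -> QcResult:
    """Apply all four rules; a descriptor override supersedes them."""
    checks = [
        check_laser_lethality(record, thresholds),
        check_omr_presence(record, om_fits, thresholds),
        check_laser_experience(record),
        check_flight_performance(record, thresholds),
    ]
    included = all(c.passed for c in checks)
    reason = None
    if override is not None:
        included, reason = override
    return QcResult(
        fly_id=record.fly_id,
        checks=checks,
        included=included,
        override_reason=reason,
    )


def qc_report(
    record: ExperimentRecord,
    result: QcResult,
    om_fits_before: list[OmFit] | None = None,
    om_fits_after: list[OmFit] | None = None,
    plot_points: int = 600,
) -> dict:
    """Per-fly quality-control report as a JSON-serialisable dict.

    Contains a downsampled min/max envelope of the raw torque trace
    (plot data), the per-period PI table, optomotor fit summaries, the
    four rule outcomes and the final inclusion decision.  Regeneration
    from the same record is deterministic.
    """
    t = record.trace["t_s"].to_numpy(dtype=float)
    y = record.trace["torque"].to_numpy(dtype=float)
    n = len(t)
    stride = max(1, n // plot_points)
    m = n // stride
    yv = y[: m * stride].reshape(m, stride)
    envelope = {
        "t_s": t[: m * stride : stride].round(3).tolist(),
        "torque_min": yv.min(axis=1).round(4).tolist(),
        "torque_max": yv.max(axis=1).round(4).tolist(),
    }
    pi_rows = [
        {
            "period": r.period_index,
            "ta_s": round(r.ta, 3),
            "tb_s": round(r.tb, 3),
            "pi": None if np.isnan(r.pi) else round(r.pi, 4),
        }
        for r in period_pi_table(record)
    ]

    def _fit_row(f: OmFit) -> dict:
        return {
            "direction": f.direction.value,
            "model": f.model,
            "magnitude": round(f.magnitude, 4),
            "residual_sd": round(f.goodness, 4),
            "fallback": f.fallback,
        }

    return {
        "fly_id": record.fly_id,
        "setup": record.schedule.setup,
        "punished_domain": record.punished_domain.value,
        "metadata": dict(record.metadata),
        "checks": [
            {"rule": c.rule, "pass": c.passed, "detail": c.detail}
            for c in result.checks
        ],
        "included": result.included,
        "override_reason": result.override_reason,
        "performance_indices": pi_rows,
        "om_fits": {
            "before": [_fit_row(f) for f in (om_fits_before or [])],
            "after": [_fit_row(f) for f in (om_fits_after or [])],
        },
        "trace_envelope": envelope,
    }
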