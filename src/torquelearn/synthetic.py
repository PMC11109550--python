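"""Generative model of a tethered fly on the torque meter.

The torque trace is produced by a two-state semi-Markov domain process:
the fly dwells in the left or right torque domain and switches with a
constant hazard (``baseline_switch_rate``).  Within a domain, torque is
the domain sign times ``torque_scale`` plus AR(1) noise, clipped so it
never crosses zero except at switch events.  During training periods
heat is on exactly while the fly is in the punished domain, and the
hazard of leaving that domain is multiplied by ``heat_escape_factor``
(escape behaviour).  Learning is modelled as a dwell bias: from the
first training period onward the hazard of leaving the unpunished
domain is multiplied by (1 - learned_bias) and the hazard of leaving
the punished domain by (1 + learned_bias), with no forgetting.  The
stationary fraction of time spent unpunished is then
(1 + learned_bias) / 2, so the expected test-period performance index
equals ``learned_bias`` (a 3:1 dwell ratio corresponds to
learned_bias = 0.5 and an expected PI of 0.5).

During optomotor periods the torque follows a first-order saturating
rise toward the direction-appropriate gain (positive for clockwise
stimuli, negative for counterclockwise) plus the same AR(1) noise.
After training, the punished-side gain is multiplied by
(1 - om_coupling * learned_bias), emulating the observed post-training
reduction of the optomotor response toward the punished side.

Degenerate fixtures (one per quality-control exclusion rule) are built
by :func:`make_degenerate_fly`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .data_model import (
    Domain,
    ExperimentRecord,
    OmDirection,
    PeriodKind,
    PeriodSchedule,
    write_dataset_descriptor,
    write_experiment,
    DatasetDescriptor,
)
from .errors import UnsupportedProtocolError, ValidationError

__all__ = [
    "FlyConfig",
    "simulate_fly",
    "simulate_dataset",
    "make_degenerate_fly",
    "write_simulated_dataset",
    "learned_bias_for_dwell_ratio",
    "DEGENERATE_KINDS",
]

#: AR(1) correlation time of the within-domain torque noise, seconds.
NOISE_TAU_S = 0.2

#: Torque magnitude floor (fraction of torque_scale) keeping within-domain
#: torque strictly away from zero between switch events.
TORQUE_FLOOR_FRAC = 0.05

DEGENERATE_KINDS = (
    "laser_resistant",
    "no_omr",
    "shifted_omr",
    "no_laser_experience",
    "flight_stopper",
)


@dataclass(frozen=True)
class FlyConfig:
    """Parameters of the synthetic fly.

    Rates are in Hz, torque quantities in the same arbitrary units the
    torque meter reports.  ``om_gain_cw``/``om_gain_ccw`` are the
    asymptotic optomotor torque magnitudes per stimulus direction
    (positive = response in the direction-congruent sign; a negative
    gain models a direction-incongruent, "shifted" response).
    """

    seed: int = 0
    baseline_switch_rate: float = 0.5
    heat_escape_factor: float = 5.0
    learned_bias: float = 0.0
    torque_scale: float = 3.0
    torque_noise_sd: float = 0.5
    om_gain_cw: float = 3.0
    om_gain_ccw: float = 3.0
    om_tau_s: float = 3.0
    om_coupling: float = 0.0
    sample_rate_hz: float = 20.0

    def validate(self) -> None:
        if self.baseline_switch_rate < 0:
            raise ValidationError("baseline_switch_rate must be >= 0")
        if self.heat_escape_factor < 1:
            raise ValidationError("heat_escape_factor must be >= 1")
        if not (0 <= self.learned_bias < 1):
            raise ValidationError("learned_bias must be in [0, 1)")
        if self.torque_scale < 0 or self.torque_noise_sd < 0:
            raise ValidationError("torque scale and noise sd must be >= 0")
        if self.om_tau_s <= 0:
            raise ValidationError("om_tau_s must be > 0")
        if not (0 <= self.om_coupling <= 1):
            raise ValidationError("om_coupling must be in [0, 1]")
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz must be > 0")


def learned_bias_for_dwell_ratio(ratio: float) -> float:
    """learned_bias giving a stationary unpunished:punished dwell ratio.

    ratio = (1+b)/(1-b)  =>  b = (ratio-1)/(ratio+1).  A 3:1 ratio gives
    b = 0.5 and an expected test-period PI of 0.5.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    return (ratio - 1.0) / (ratio + 1.0)


def _stationary_ar1(rng: np.random.Generator, n: int, sd: float, dt: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal sd and correlation time NOISE_TAU_S."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    a = math.exp(-dt / NOISE_TAU_S)
    e = rng.normal(0.0, sd * math.sqrt(1.0 - a * a), size=n)
    x0 = rng.normal(0.0, sd)
    out = lfilter([1.0], [1.0, -a], e)
    out += x0 * a ** np.arange(1, n + 1)
    return out


def simulate_fly(
    config: FlyConfig,
    schedule: PeriodSchedule,
    punished_domain: Domain | str,
    *,
    fly_id: str = "fly_0000",
    metadata: dict[str, str] | None = None,
    _forced_training_domain: Domain | None = None,
) -> ExperimentRecord:
    """Simulate one fly through a full period schedule.

    Identical seeds produce bit-identical traces.  ``_forced_training_domain``
    pins the domain process during training periods (used to build the
    never-heated degenerate fixture).
    """
    config.validate()
    punished = Domain(punished_domain)
    rng = np.random.default_rng(config.seed)
    dt = 1.0 / config.sample_rate_hz
    n = int(round(schedule.total_duration_s / dt))
    t = np.arange(n) * dt
    noise = _stationary_ar1(rng, n, config.torque_noise_sd, dt)

    torque = np.zeros(n)
    heat = np.zeros(n, dtype=bool)
    stim = np.full(n, "none", dtype=object)
    sign = np.zeros(n, dtype=int)  # domain sign per torque-period sample

    state = int(rng.choice([-1, 1]))  # current domain sign
    training_indices = [
        p.index for p in schedule.periods if p.kind is PeriodKind.TRAINING
    ]
    first_training = min(training_indices) if training_indices else None
    b = config.learned_bias
    h0 = config.baseline_switch_rate
    floor = TORQUE_FLOOR_FRAC * config.torque_scale

    # pre-drawn pool of unit exponentials for dwell draws
    pool = rng.exponential(1.0, size=4096)
    pool_i = 0

    def next_exp() -> float:
        nonlocal pool, pool_i
        if pool_i >= len(pool):
            pool = rng.exponential(1.0, size=4096)
            pool_i = 0
        v = pool[pool_i]
        pool_i += 1
        return v

    start = 0.0
    for p in schedule.periods:
        end = start + p.duration_s
        k0 = int(round(start / dt))
        k1 = min(n, int(round(end / dt)))
        if p.kind is PeriodKind.OPTOMOTOR:
            phase = "after" if any(
                q.index < p.index for q in schedule.torque_periods()
            ) else "before"
            dir_sign = 1 if p.om_direction is OmDirection.CLOCKWISE else -1
            gain = (
                config.om_gain_cw
                if p.om_direction is OmDirection.CLOCKWISE
                else config.om_gain_ccw
            )
            # post-training reduction of the punished-side response
            if phase == "after" and dir_sign == punished.sign:
                gain = gain * (1.0 - config.om_coupling * config.learned_bias)
            t_rel = t[k0:k1] - start
            torque[k0:k1] = dir_sign * gain * (
                1.0 - np.exp(-t_rel / config.om_tau_s)
            ) + noise[k0:k1]
            stim[k0:k1] = p.om_direction.value
            start = end
            continue

        learning_on = first_training is not None and p.index >= first_training
        forced = (
            _forced_training_domain
            if (_forced_training_domain is not None and p.kind is PeriodKind.TRAINING)
            else None
        )
        if forced is not None:
            state = forced.sign
            sign[k0:k1] = state
        else:
            t_cur = start
            while t_cur < end - 1e-12:
                in_punished = state == punished.sign
                if learning_on:
                    hazard = h0 * ((1.0 + b) if in_punished else (1.0 - b))
                else:
                    hazard = h0
                if p.heat_on and in_punished:
                    hazard *= config.heat_escape_factor
                dwell = next_exp() / hazard if hazard > 0 else math.inf
                t_next = min(end, t_cur + dwell)
                i0 = max(k0, int(math.ceil(t_cur / dt - 1e-9)))
                i1 = min(k1, int(math.ceil(t_next / dt - 1e-9)))
                sign[i0:i1] = state
                if t_next < end:
                    state = -state
                t_cur = t_next
        seg = slice(k0, k1)
        torque[seg] = sign[seg] * np.maximum(
            floor, config.torque_scale + noise[seg]
        )
        if p.heat_on:
            heat[seg] = sign[seg] == punished.sign
        start = end

    trace = pd.DataFrame({"t_s": t, "torque": torque, "heat": heat, "stim": stim})
    meta = {"laser_survival_s": "5.0"}
    if metadata:
        meta.update({str(k): str(v) for k, v in metadata.items()})
    record = ExperimentRecord(
        fly_id=fly_id,
        punished_domain=punished,
        schedule=schedule,
        trace=trace,
        metadata=meta,
    )
    record.validate()
    return record


def simulate_dataset(
    n_flies: int,
    config: FlyConfig,
    schedule: PeriodSchedule,
) -> list[ExperimentRecord]:
    """Simulate a cohort; the punished domain alternates left/right.

    Per-fly seeds are derived deterministically from ``config.seed``, so
    two runs with the same master seed produce identical datasets.
    """
    if n_flies < 1:
        raise ValidationError("n_flies must be >= 1")
    seeds = np.random.SeedSequence(config.seed).generate_state(n_flies) & 0x7FFFFFFF
    records = []
    for i in range(n_flies):
        punished = Domain.LEFT if i % 2 == 0 else Domain.RIGHT
        fly_config = replace(config, seed=int(seeds[i]))
        records.append(
            simulate_fly(
                fly_config,
                schedule,
                punished,
                fly_id=f"fly_{i:04d}",
            )
        )
    return records


def make_degenerate_fly(
    kind: str,
    schedule: PeriodSchedule,
    *,
    seed: int = 0,
    config: FlyConfig | None = None,
) -> ExperimentRecord:
    """Build a fixture that violates exactly one quality-control rule.

    Kinds: ``laser_resistant`` (survived the post-experiment laser test
    for 20 s), ``no_omr`` (no optomotor response in either direction),
    ``shifted_omr`` (both stimulus directions elicit same-signed
    torque), ``no_laser_experience`` (never enters the punished domain
    during training, so heat never fires), ``flight_stopper`` (repeated
    multi-second flat spans of zero torque).
    """
    base = config if config is not None else FlyConfig(learned_bias=0.5)
    base = replace(base, seed=seed)
    if kind not in DEGENERATE_KINDS:
        raise ValueError(f"unknown degenerate kind {kind!r}")
    if kind in ("no_omr", "shifted_omr") and not schedule.om_periods():
        raise UnsupportedProtocolError(
            f"{kind} fixture requires a schedule with optomotor periods"
        )
    fly_id = f"degenerate_{kind}"
    if kind == "laser_resistant":
        return simulate_fly(
            base, schedule, Domain.LEFT, fly_id=fly_id,
            metadata={"laser_survival_s": "20.0"},
        )
    if kind == "no_omr":
        cfg = replace(base, om_gain_cw=0.0, om_gain_ccw=0.0)
        return simulate_fly(cfg, schedule, Domain.LEFT, fly_id=fly_id)
    if kind == "shifted_omr":
        # counterclockwise stimulus elicits right-turning torque too
        cfg = replace(base, om_gain_ccw=-base.om_gain_ccw)
        return simulate_fly(cfg, schedule, Domain.LEFT, fly_id=fly_id)
    if kind == "no_laser_experience":
        return simulate_fly(
            base, schedule, Domain.LEFT, fly_id=fly_id,
            _forced_training_domain=Domain.RIGHT,
        )
    # flight_stopper: overwrite six 2.5-s spans of unheated torque
    # periods with exactly zero torque (stalled flight)
    record = simulate_fly(base, schedule, Domain.LEFT, fly_id=fly_id)
    quiet = [
        p for p in schedule.torque_periods() if p.kind is not PeriodKind.TRAINING
    ]
    step = record.sample_step_s
    torque = record.trace["torque"].to_numpy().copy()
    n_stops = 0
    for p in quiet:
        start, _ = schedule.period_bounds(p.index)
        for offset in (30.0, 80.0):
            if n_stops >= 6:
                break
            i0 = int(round((start + offset) / step))
            i1 = i0 + int(round(2.5 / step))
            torque[i0:i1] = 0.0
            n_stops += 1
    record.trace["torque"] = torque
    return record


def write_simulated_dataset(
    records: list[ExperimentRecord],
    out_dir,
    *,
    group_name: str = "simulated",
    alpha: float = 0.005,
    bf_upper: float = 5.0,
    bf_lower: float = 1.0,
) -> "DatasetDescriptor":
    """Write raw experiment files plus a matching dataset descriptor.

    Returns the descriptor (with ``base_dir`` set to ``out_dir``); the
    descriptor file is written as ``dataset.yaml``.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    refs = []
    for rec in records:
        name = f"{rec.fly_id}.xml"
        write_experiment(rec, out_dir / name)
        refs.append(name)
    desc = DatasetDescriptor(
        groups={group_name: refs},
        alpha=alpha,
        bf_upper=bf_upper,
        bf_lower=bf_lower,
        base_dir=out_dir,
    )
    write_dataset_descriptor(desc, out_dir / "dataset.yaml")
    return desc
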