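"""Domain types and raw-file I/O for tethered-fly torque experiments.

The experiment: a fly, tethered to a torque meter, generates yaw torque.
The sign of the torque splits behaviour into two *domains* — negative =
left-turning, positive = right-turning.  During training periods an
infrared laser (heat) is switched on whenever the fly's torque is in the
punished domain; test periods measure whether the fly learned to avoid it.

Two devices are supported:

* ``tang``  — 9 torque periods of 120 s (pretest, training, test pattern);
  optomotor traces were not stored by this device.
* ``new``   — 17 periods: four 30-s optomotor periods, the same nine
  120-s torque periods, then four more optomotor periods.

Sign convention used throughout the package: positive torque is a
right-turning (clockwise-perceived) maneuver; "punished on left" means
heat is on while torque < 0.

File formats: raw experiments are stored in this package's own XML
dialect (see ``docs/file_formats.md``); dataset descriptors are YAML.
"""

from __future__ import annotations

import enum
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import (
    MalformedFileError,
    MissingTraceError,
    ScheduleMismatchError,
    UnknownProtocolError,
    ValidationError,
)

__all__ = [
    "PeriodKind",
    "OmDirection",
    "Domain",
    "PeriodDef",
    "PeriodSchedule",
    "ExperimentRecord",
    "DatasetDescriptor",
    "build_schedule",
    "read_experiment",
    "write_experiment",
    "read_dataset_descriptor",
    "write_dataset_descriptor",
    "OM_STRIPE_COUNT",
    "OM_ROTATION_PERIOD_S",
    "OM_PATTERN_WAVELENGTH_DEG",
    "OM_PATTERN_FREQUENCY_HZ",
    "DEFAULT_SAMPLE_RATE_HZ",
]

# Optomotor stimulus geometry: 15 vertical stripes, ~3.5 s per full
# arena rotation, giving a 24 deg pattern wavelength at ~4.3 Hz.
OM_STRIPE_COUNT = 15
OM_ROTATION_PERIOD_S = 3.5
OM_PATTERN_WAVELENGTH_DEG = 360.0 / OM_STRIPE_COUNT
OM_PATTERN_FREQUENCY_HZ = OM_STRIPE_COUNT / OM_ROTATION_PERIOD_S

#: Default sampling rate for synthetic traces; any uniform rate is
#: accepted on input.
DEFAULT_SAMPLE_RATE_HZ = 20.0

TORQUE_PERIOD_S = 120.0
OM_PERIOD_S = 30.0

FILE_FORMAT_VERSION = "1.0"


class PeriodKind(str, enum.Enum):
    PRETEST = "pretest"
    TRAINING = "training"
    TEST = "test"
    OPTOMOTOR = "optomotor"


class OmDirection(str, enum.Enum):
    NONE = "none"
    CLOCKWISE = "clockwise"
    COUNTERCLOCKWISE = "counterclockwise"


class Domain(str, enum.Enum):
    LEFT = "left"    # negative torque
    RIGHT = "right"  # positive torque

    @property
    def sign(self) -> int:
        return -1 if self is Domain.LEFT else 1

    @property
    def opposite(self) -> "Domain":
        return Domain.RIGHT if self is Domain.LEFT else Domain.LEFT


@dataclass(frozen=True)
class PeriodDef:
    """One period of the experimental sequence.

    ``heat_on`` means heat is contingent on the punished torque domain
    during this period (training periods only).
    """

    index: int  # 1-based ordinal within the schedule
    kind: PeriodKind
    duration_s: float
    heat_on: bool = False
    om_direction: OmDirection = OmDirection.NONE

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValidationError(f"period {self.index}: duration must be > 0")
        if self.heat_on and self.kind is not PeriodKind.TRAINING:
            raise ValidationError(
                f"period {self.index}: heat contingency only allowed in training"
            )
        is_om = self.kind is PeriodKind.OPTOMOTOR
        has_dir = self.om_direction is not OmDirection.NONE
        if is_om != has_dir:
            raise ValidationError(
                f"period {self.index}: om_direction set iff kind is optomotor"
            )

    @property
    def is_torque_period(self) -> bool:
        return self.kind is not PeriodKind.OPTOMOTOR


@dataclass(frozen=True)
class PeriodSchedule:
    """Ordered sequence of periods for one of the known protocols."""

    setup: str  # "tang" | "new"
    periods: tuple[PeriodDef, ...]

    def __post_init__(self) -> None:
        if self.setup not in ("tang", "new"):
            raise UnknownProtocolError(f"unknown setup {self.setup!r}")
        for want, got in zip(range(1, len(self.periods) + 1), self.periods):
            if got.index != want:
                raise ValidationError("period indices must be 1..n in order")

    @property
    def total_duration_s(self) -> float:
        return float(sum(p.duration_s for p in self.periods))

    def period_bounds(self, index: int) -> tuple[float, float]:
        """(start_s, end_s) of the 1-based period within the trace."""
        start = 0.0
        for p in self.periods:
            if p.index == index:
                return start, start + p.duration_s
            start += p.duration_s
        raise KeyError(f"no period {index}")

    def torque_periods(self) -> list[PeriodDef]:
        return [p for p in self.periods if p.is_torque_period]

    def om_periods(self, phase: str | None = None) -> list[PeriodDef]:
        """Optomotor periods, optionally only the 'before' or 'after' phase."""
        oms = [p for p in self.periods if p.kind is PeriodKind.OPTOMOTOR]
        if phase is None:
            return oms
        torque_idx = [p.index for p in self.torque_periods()]
        if not torque_idx:
            return []
        if phase == "before":
            return [p for p in oms if p.index < min(torque_idx)]
        if phase == "after":
            return [p for p in oms if p.index > max(torque_idx)]
        raise ValueError(f"unknown phase {phase!r}")

    def learning_test_index(self) -> int:
        """Index of the first test period after the last training period.

        This is the period whose performance index is the fly's learning
        score: period 8 in the Tang protocol, period 12 in the new one.
        """
        trainings = [p.index for p in self.periods if p.kind is PeriodKind.TRAINING]
        if not trainings:
            raise ValidationError("schedule has no training periods")
        last_training = max(trainings)
        for p in self.periods:
            if p.kind is PeriodKind.TEST and p.index > last_training:
                return p.index
        raise ValidationError("no test period after the last training period")


# Tang protocol: pretest, pretest, training, training, test, training,
# training, test, test — all 120 s, heat in periods 3, 4, 6, 7.
_TORQUE_KINDS = (
    PeriodKind.PRETEST,
    PeriodKind.PRETEST,
    PeriodKind.TRAINING,
    PeriodKind.TRAINING,
    PeriodKind.TEST,
    PeriodKind.TRAINING,
    PeriodKind.TRAINING,
    PeriodKind.TEST,
    PeriodKind.TEST,
)


def build_schedule(setup: str) -> PeriodSchedule:
    """Construct the period schedule for a known protocol.

    ``tang``: 9 torque periods of 120 s.  ``new``: 4 optomotor periods of
    30 s, the same 9 torque periods (numbered 5-13), then 4 more
    optomotor periods.  Optomotor direction alternates clockwise /
    counterclockwise starting clockwise in each optomotor block.
    """
    if setup == "tang":
        periods = [
            PeriodDef(
                index=i + 1,
                kind=kind,
                duration_s=TORQUE_PERIOD_S,
                heat_on=kind is PeriodKind.TRAINING,
            )
            for i, kind in enumerate(_TORQUE_KINDS)
        ]
        return PeriodSchedule(setup="tang", periods=tuple(periods))
    if setup == "new":
        periods: list[PeriodDef] = []
        om_cycle = (OmDirection.CLOCKWISE, OmDirection.COUNTERCLOCKWISE)
        for i in range(4):
            periods.append(
                PeriodDef(
                    index=i + 1,
                    kind=PeriodKind.OPTOMOTOR,
                    duration_s=OM_PERIOD_S,
                    om_direction=om_cycle[i % 2],
                )
            )
        for i, kind in enumerate(_TORQUE_KINDS):
            periods.append(
                PeriodDef(
                    index=i + 5,
                    kind=kind,
                    duration_s=TORQUE_PERIOD_S,
                    heat_on=kind is PeriodKind.TRAINING,
                )
            )
        for i in range(4):
            periods.append(
                PeriodDef(
                    index=i + 14,
                    kind=PeriodKind.OPTOMOTOR,
                    duration_s=OM_PERIOD_S,
                    om_direction=om_cycle[i % 2],
                )
            )
        return PeriodSchedule(setup="new", periods=tuple(periods))
    raise UnknownProtocolError(f"unknown setup {setup!r}")


@dataclass
class ExperimentRecord:
    """One fly's experiment: metadata, schedule, and the sampled trace.

    ``trace`` is a DataFrame with columns ``t_s`` (seconds from
    experiment start), ``torque`` (signed, arbitrary units), ``heat``
    (bool) and ``stim`` (one of "none"/"clockwise"/"counterclockwise").
    """

    fly_id: str
    punished_domain: Domain
    schedule: PeriodSchedule
    trace: pd.DataFrame
    metadata: dict[str, str] = field(default_factory=dict)

    @property
    def sample_step_s(self) -> float:
        t = self.trace["t_s"].to_numpy()
        if len(t) < 2:
            raise ValidationError("trace has fewer than 2 samples")
        return float(np.median(np.diff(t)))

    @property
    def sample_rate_hz(self) -> float:
        return 1.0 / self.sample_step_s

    def period_slice(self, index: int) -> pd.DataFrame:
        start, end = self.schedule.period_bounds(index)
        t = self.trace["t_s"].to_numpy()
        # half-step tolerance so boundary samples land in the period they open
        half = 0.5 * self.sample_step_s
        mask = (t >= start - half) & (t < end - half)
        return self.trace.iloc[np.flatnonzero(mask)]

    def validate(self) -> list[str]:
        """Check invariants; raise on hard violations, return warnings.

        Hard: strictly increasing uniform timestamps (1 % step
        tolerance), trace spanning the schedule within one sample.
        Soft (warning): heat flag set outside training periods.
        """
        t = self.trace["t_s"].to_numpy(dtype=float)
        if len(t) == 0:
            raise MissingTraceError(f"{self.fly_id}: empty trace")
        d = np.diff(t)
        if len(d) == 0:
            raise ValidationError(f"{self.fly_id}: trace has a single sample")
        if np.any(d <= 0):
            raise ValidationError(f"{self.fly_id}: timestamps not strictly increasing")
        step = float(np.median(d))
        if np.any(np.abs(d - step) > 0.01 * step):
            raise ValidationError(f"{self.fly_id}: sampling not uniform within 1%")
        total = self.schedule.total_duration_s
        span = t[-1] - t[0] + step
        if abs(span - total) > step + 1e-9:
            raise ScheduleMismatchError(
                f"{self.fly_id}: trace spans {span:.2f} s, schedule {total:.2f} s"
            )
        warnings: list[str] = []
        heat = self.trace["heat"].to_numpy(dtype=bool)
        if heat.any():
            in_training = np.zeros(len(t), dtype=bool)
            for p in self.schedule.periods:
                if p.kind is PeriodKind.TRAINING:
                    a, b = self.schedule.period_bounds(p.index)
                    in_training |= (t >= a - 0.5 * step) & (t < b - 0.5 * step)
            if np.any(heat & ~in_training):
                warnings.append("heat flag set outside training periods")
        return warnings


@dataclass
class DatasetDescriptor:
    """Experimental design of one dataset: groups, thresholds, overrides.

    ``groups`` maps group names to lists of raw-experiment file paths
    (relative to the descriptor's directory).  ``overrides`` maps fly ids
    to (include, reason) pairs that supersede automatic quality control.
    """

    groups: dict[str, list[str]]
    alpha: float = 0.005
    bf_upper: float = 5.0
    bf_lower: float = 1.0
    overrides: dict[str, tuple[bool, str]] = field(default_factory=dict)
    base_dir: Path = field(default_factory=Path)

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValidationError(f"alpha must be in (0,1), got {self.alpha}")
        if self.bf_lower > self.bf_upper:
            raise ValidationError(
                f"bf_lower ({self.bf_lower}) must be <= bf_upper ({self.bf_upper})"
            )
        if not self.groups:
            raise ValidationError("descriptor defines no groups")

    def resolve(self, ref: str) -> Path:
        return (Path(self.base_dir) / ref).resolve()

    def validate_references(self) -> None:
        for group, refs in self.groups.items():
            for ref in refs:
                p = self.resolve(ref)
                if not p.exists():
                    raise ValidationError(
                        f"group {group!r}: file reference {ref!r} not resolvable"
                    )


# ---------------------------------------------------------------------------
# Raw experiment XML I/O


_STIM_CODE = {"none": 0, "clockwise": 1, "counterclockwise": 2}
_STIM_NAME = {v: k for k, v in _STIM_CODE.items()}


def write_experiment(record: ExperimentRecord, path: str | Path) -> None:
    """Write a record to the package's XML dialect (version 1.0).

    Torque values are serialised with 17 significant digits so that
    float64 round-trips exactly; integer-coded columns round-trip
    bit-exactly.
    """
    root = ET.Element("flyrecord", version=FILE_FORMAT_VERSION)
    meta = ET.SubElement(root, "metadata", fly_id=record.fly_id)
    for k, v in record.metadata.items():
        e = ET.SubElement(meta, "entry", key=str(k))
        e.text = str(v)
    sched = ET.SubElement(root, "schedule", setup=record.schedule.setup)
    for p in record.schedule.periods:
        ET.SubElement(
            sched,
            "period",
            index=str(p.index),
            kind=p.kind.value,
            duration_s=format(p.duration_s, ".17g"),
            heat_on=str(p.heat_on).lower(),
            om_direction=p.om_direction.value,
        )
    pd_el = ET.SubElement(root, "punished_domain")
    pd_el.text = record.punished_domain.value
    tr = record.trace
    n = len(tr)
    t = tr["t_s"].to_numpy(dtype=float)
    step = float(np.median(np.diff(t))) if n > 1 else 0.0
    trace = ET.SubElement(
        root,
        "trace",
        n=str(n),
        t0_s=format(float(t[0]) if n else 0.0, ".17g"),
        step_s=format(step, ".17g"),
    )
    torque = ET.SubElement(trace, "torque")
    torque.text = " ".join(format(v, ".17g") for v in tr["torque"].to_numpy(dtype=float))
    heat = ET.SubElement(trace, "heat")
    heat.text = " ".join("1" if v else "0" for v in tr["heat"].to_numpy(dtype=bool))
    stim = ET.SubElement(trace, "stim")
    stim.text = " ".join(str(_STIM_CODE[v]) for v in tr["stim"])
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)


def read_experiment(path: str | Path) -> ExperimentRecord:
    """Read a raw experiment XML file and validate its invariants."""
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise MalformedFileError(f"{path}: {exc}") from exc
    if root.tag != "flyrecord":
        raise MalformedFileError(f"{path}: not a flyrecord file")
    meta_el = root.find("metadata")
    if meta_el is None:
        raise MalformedFileError(f"{path}: missing <metadata>")
    fly_id = meta_el.get("fly_id", "")
    metadata = {
        e.get("key", ""): (e.text or "") for e in meta_el.findall("entry")
    }
    sched_el = root.find("schedule")
    if sched_el is None:
        raise MalformedFileError(f"{path}: missing <schedule>")
    try:
        periods = tuple(
            PeriodDef(
                index=int(p.get("index")),
                kind=PeriodKind(p.get("kind")),
                duration_s=float(p.get("duration_s")),
                heat_on=p.get("heat_on") == "true",
                om_direction=OmDirection(p.get("om_direction", "none")),
            )
            for p in sched_el.findall("period")
        )
        schedule = PeriodSchedule(setup=sched_el.get("setup", ""), periods=periods)
    except (TypeError, ValueError) as exc:
        raise MalformedFileError(f"{path}: bad schedule: {exc}") from exc
    pd_el = root.find("punished_domain")
    if pd_el is None or pd_el.text not in ("left", "right"):
        raise MalformedFileError(f"{path}: missing/bad <punished_domain>")
    trace_el = root.find("trace")
    if trace_el is None:
        raise MissingTraceError(f"{path}: missing <trace>")

    def _column(tag: str) -> list[str]:
        el = trace_el.find(tag)
        if el is None or not (el.text or "").strip():
            raise MissingTraceError(f"{path}: trace column {tag!r} missing or empty")
        return el.text.split()

    try:
        n = int(trace_el.get("n", "0"))
        t0 = float(trace_el.get("t0_s", "0"))
        step = float(trace_el.get("step_s", "0"))
        torque = np.array(_column("torque"), dtype=float)
        heat = np.array(_column("heat"), dtype=int).astype(bool)
        stim_codes = np.array(_column("stim"), dtype=int)
    except ValueError as exc:
        raise MalformedFileError(f"{path}: bad trace data: {exc}") from exc
    if not (len(torque) == len(heat) == len(stim_codes) == n):
        raise MalformedFileError(
            f"{path}: trace column lengths disagree with n={n}"
        )
    t = t0 + step * np.arange(n)
    trace = pd.DataFrame(
        {
            "t_s": t,
            "torque": torque,
            "heat": heat,
            "stim": [_STIM_NAME[c] for c in stim_codes],
        }
    )
    record = ExperimentRecord(
        fly_id=fly_id,
        punished_domain=Domain(pd_el.text),
        schedule=schedule,
        trace=trace,
        metadata=metadata,
    )
    record.validate()
    return record


# ---------------------------------------------------------------------------
# Dataset descriptor YAML I/O


def read_dataset_descriptor(path: str | Path) -> DatasetDescriptor:
    """Read a YAML dataset descriptor, applying default thresholds.

    Absent ``alpha`` defaults to 0.005, ``bf_upper`` to 5, ``bf_lower``
    to 1.  File references are checked to be resolvable relative to the
    descriptor's directory.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise MalformedFileError(f"{path}: {exc}") from exc
    if not isinstance(raw, Mapping) or "groups" not in raw:
        raise MalformedFileError(f"{path}: descriptor must be a mapping with 'groups'")
    groups = {
        str(name): [str(r) for r in refs] for name, refs in raw["groups"].items()
    }
    overrides: dict[str, tuple[bool, str]] = {}
    for fly_id, ov in (raw.get("overrides") or {}).items():
        overrides[str(fly_id)] = (
            bool(ov.get("include", False)),
            str(ov.get("reason", "")),
        )
    desc = DatasetDescriptor(
        groups=groups,
        alpha=float(raw.get("alpha", 0.005)),
        bf_upper=float(raw.get("bf_upper", 5.0)),
        bf_lower=float(raw.get("bf_lower", 1.0)),
        overrides=overrides,
        base_dir=path.parent,
    )
    desc.validate_references()
    return desc


def write_dataset_descriptor(desc: DatasetDescriptor, path: str | Path) -> None:
    doc = {
        "alpha": desc.alpha,
        "bf_upper": desc.bf_upper,
        "bf_lower": desc.bf_lower,
        "groups": desc.groups,
    }
    if desc.overrides:
        doc["overrides"] = {
            fly: {"include": inc, "reason": reason}
            for fly, (inc, reason) in desc.overrides.items()
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
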