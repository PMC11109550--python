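"""Protocol schedules, domain-type invariants, and file round-trips."""

import numpy as np
import pytest
import yaml

import torquelearn as tl
from torquelearn.data_model import (
    OM_PATTERN_FREQUENCY_HZ,
    OM_PATTERN_WAVELENGTH_DEG,
    OmDirection,
    PeriodDef,
    PeriodKind,
)
from torquelearn.errors import (
    MalformedFileError,
    MissingTraceError,
    ScheduleMismatchError,
    UnknownProtocolError,
    ValidationError,
)


class TestSchedules:
    def test_tang_structure(self, tang_schedule):
        s = tang_schedule
        assert len(s.periods) == 9
        assert all(p.duration_s == 120.0 for p in s.periods)
        assert [p.index for p in s.periods if p.heat_on] == [3, 4, 6, 7]
        assert [p.index for p in s.periods if p.kind is PeriodKind.TEST] == [5, 8, 9]
        assert s.total_duration_s == 9 * 120.0
        assert s.learning_test_index() == 8

    def test_new_structure(self, new_schedule):
        s = new_schedule
        assert len(s.periods) == 17
        om = [p.index for p in s.periods if p.kind is PeriodKind.OPTOMOTOR]
        assert om == [1, 2, 3, 4, 14, 15, 16, 17]
        assert all(s.periods[i - 1].duration_s == 30.0 for i in om)
        torque = [p for p in s.periods if p.is_torque_period]
        assert [p.index for p in torque] == list(range(5, 14))
        assert all(p.duration_s == 120.0 for p in torque)
        assert [p.index for p in s.periods if p.heat_on] == [7, 8, 10, 11]
        assert s.learning_test_index() == 12

    def test_om_phases_and_direction_alternation(self, new_schedule):
        before = new_schedule.om_periods("before")
        after = new_schedule.om_periods("after")
        assert [p.index for p in before] == [1, 2, 3, 4]
        assert [p.index for p in after] == [14, 15, 16, 17]
        for block in (before, after):
            dirs = [p.om_direction for p in block]
            assert dirs == [
                OmDirection.CLOCKWISE,
                OmDirection.COUNTERCLOCKWISE,
                OmDirection.CLOCKWISE,
                OmDirection.COUNTERCLOCKWISE,
            ]

    def test_construction_deterministic(self):
        assert tl.build_schedule("new") == tl.build_schedule("new")
        assert tl.build_schedule("tang") == tl.build_schedule("tang")

    def test_unknown_setup_rejected(self):
        with pytest.raises(UnknownProtocolError):
            tl.build_schedule("goetz2")

    def test_stimulus_geometry_constants(self):
        assert OM_PATTERN_WAVELENGTH_DEG == pytest.approx(24.0)
        assert OM_PATTERN_FREQUENCY_HZ == pytest.approx(15 / 3.5)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(index=1, kind=PeriodKind.TEST, duration_s=0.0),
            dict(index=1, kind=PeriodKind.TEST, duration_s=120.0, heat_on=True),
            dict(index=1, kind=PeriodKind.OPTOMOTOR, duration_s=30.0),
            dict(
                index=1,
                kind=PeriodKind.TEST,
                duration_s=120.0,
                om_direction=OmDirection.CLOCKWISE,
            ),
        ],
    )
    def test_period_invariants_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            PeriodDef(**kwargs)


class TestExperimentRoundTrip:
    def test_write_read_identity(self, learner_fly, tmp_path):
        path = tmp_path / "fly.xml"
        tl.write_experiment(learner_fly, path)
        back = tl.read_experiment(path)
        assert back.fly_id == learner_fly.fly_id
        assert back.punished_domain == learner_fly.punished_domain
        assert back.schedule == learner_fly.schedule
        assert back.metadata == learner_fly.metadata
        # torque round-trips exactly; integer-coded columns bit-exactly
        assert np.array_equal(
            back.trace["torque"].to_numpy(), learner_fly.trace["torque"].to_numpy()
        )
        assert np.array_equal(
            back.trace["heat"].to_numpy(), learner_fly.trace["heat"].to_numpy()
        )
        assert list(back.trace["stim"]) == list(learner_fly.trace["stim"])

    def test_truncated_trace_is_schedule_mismatch(self, null_fly, tmp_path):
        short = tl.ExperimentRecord(
            fly_id=null_fly.fly_id,
            punished_domain=null_fly.punished_domain,
            schedule=null_fly.schedule,
            trace=null_fly.trace.iloc[: 900 * 20].reset_index(drop=True),
            metadata=null_fly.metadata,
        )
        with pytest.raises(ScheduleMismatchError):
            short.validate()

    def test_minimal_handwritten_file(self, tmp_path):
        # 2 periods of 10 s at 5 Hz -> 100 samples
        n = 100
        vals = " ".join(format(0.5 * ((-1) ** (i // 25)), ".17g") for i in range(n))
        xml = f"""<?xml version='1.0' encoding='utf-8'?>
<flyrecord version="1.0">
  <metadata fly_id="mini"><entry key="laser_survival_s">3</entry></metadata>
  <schedule setup="tang">
    <period index="1" kind="training" duration_s="10" heat_on="true" om_direction="none"/>
    <period index="2" kind="test" duration_s="10" heat_on="false" om_direction="none"/>
  </schedule>
  <punished_domain>left</punished_domain>
  <trace n="{n}" t0_s="0" step_s="0.2">
    <torque>{vals}</torque>
    <heat>{" ".join("0" * 1 for _ in range(n))}</heat>
    <stim>{" ".join("0" for _ in range(n))}</stim>
  </trace>
</flyrecord>"""
        path = tmp_path / "mini.xml"
        path.write_text(xml)
        rec = tl.read_experiment(path)
        assert len(rec.trace) == 100
        assert rec.sample_rate_hz == pytest.approx(5.0)
        assert rec.metadata["laser_survival_s"] == "3"

    def test_malformed_and_missing_trace_distinct(self, tmp_path):
        bad = tmp_path / "bad.xml"
        bad.write_text("<flyrecord><unclosed>")
        with pytest.raises(MalformedFileError):
            tl.read_experiment(bad)
        no_trace = tmp_path / "notrace.xml"
        no_trace.write_text(
            '<flyrecord version="1.0"><metadata fly_id="x"/>'
            '<schedule setup="tang"/>'
            "<punished_domain>left</punished_domain></flyrecord>"
        )
        with pytest.raises(MissingTraceError):
            tl.read_experiment(no_trace)


class TestDatasetDescriptor:
    def _write(self, tmp_path, doc):
        p = tmp_path / "dataset.yaml"
        p.write_text(yaml.safe_dump(doc))
        return p

    def test_defaults_applied(self, tmp_path):
        (tmp_path / "a.xml").touch()
        p = self._write(tmp_path, {"groups": {"g": ["a.xml"]}})
        desc = tl.read_dataset_descriptor(p)
        assert desc.alpha == 0.005
        assert desc.bf_upper == 5.0
        assert desc.bf_lower == 1.0

    def test_bf_threshold_order_enforced(self, tmp_path):
        (tmp_path / "a.xml").touch()
        p = self._write(
            tmp_path,
            {"groups": {"g": ["a.xml"]}, "bf_lower": 6, "bf_upper": 2},
        )
        with pytest.raises(ValidationError):
            tl.read_dataset_descriptor(p)

    def test_alpha_range_enforced(self, tmp_path):
        (tmp_path / "a.xml").touch()
        p = self._write(tmp_path, {"groups": {"g": ["a.xml"]}, "alpha": 1.5})
        with pytest.raises(ValidationError):
            tl.read_dataset_descriptor(p)

    def test_two_groups_enumerable(self, tmp_path):
        for name in ("a.xml", "b.xml", "c.xml"):
            (tmp_path / name).touch()
        p = self._write(
            tmp_path,
            {
                "groups": {"exp": ["a.xml", "b.xml"], "ctrl": ["c.xml"]},
                "overrides": {"flyX": {"include": False, "reason": "damaged"}},
            },
        )
        desc = tl.read_dataset_descriptor(p)
        assert sorted(desc.groups) == ["ctrl", "exp"]
        assert desc.groups["exp"] == ["a.xml", "b.xml"]
        assert desc.overrides["flyX"] == (False, "damaged")

    def test_unresolvable_reference_rejected(self, tmp_path):
        p = self._write(tmp_path, {"groups": {"g": ["missing.xml"]}})
        with pytest.raises(ValidationError):
            tl.read_dataset_descriptor(p)
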