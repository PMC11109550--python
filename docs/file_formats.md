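# File formats

## Raw experiment file (XML, dialect version 1.0)

One file per fly experiment. Written/read by
`torquelearn.write_experiment` / `torquelearn.read_experiment`.

```xml
<?xml version='1.0' encoding='utf-8'?>
<flyrecord version="1.0">
  <metadata fly_id="fly_0001">
    <entry key="laser_survival_s">5.0</entry>
    <entry key="comment">free-form experimenter note</entry>
  </metadata>
  <schedule setup="new">
    <period index="1" kind="optomotor" duration_s="30" heat_on="false"
            om_direction="clockwise"/>
    <!-- ... one element per period, in order ... -->
  </schedule>
  <punished_domain>left</punished_domain>
  <trace n="26400" t0_s="0" step_s="0.05">
    <torque>...</torque>  <!-- n space-separated floats, 17 significant digits -->
    <heat>...</heat>      <!-- n space-separated 0/1 flags -->
    <stim>...</stim>      <!-- n codes: 0 none, 1 clockwise, 2 counterclockwise -->
  </trace>
</flyrecord>
```

Field semantics:

| element / attribute | meaning |
|---|---|
| `metadata/@fly_id` | unique fly identifier |
| `entry[@key="laser_survival_s"]` | post-experiment laser-exposure survival, seconds; used by the lethality exclusion rule |
| `schedule/@setup` | `tang` (9 torque periods) or `new` (17 periods incl. optomotor) |
| `period/@kind` | `pretest`, `training`, `test`, `optomotor` |
| `period/@heat_on` | heat contingent on the punished domain in this period (training only) |
| `period/@om_direction` | `none`, `clockwise`, `counterclockwise` (optomotor only) |
| `punished_domain` | `left` (heat while torque < 0) or `right` (torque > 0) |
| `trace/@n`, `@t0_s`, `@step_s` | sample count, first timestamp, uniform step |

Invariants enforced on read: strictly increasing timestamps, uniform
step within 1 %, trace span equal to the summed schedule duration
within one sample. Torque values round-trip float64 exactly
(17 significant digits); heat and stimulus codes round-trip
bit-exactly. Sign convention: positive torque = right-turning
(clockwise-perceived) maneuver.

This dialect is this package's own; it mirrors the *role* of the
originally deposited raw files (metadata + full time series in one
XML document per fly) without reproducing their byte layout.

## Dataset descriptor (YAML)

One file per dataset, read by `read_dataset_descriptor`. Paths are
relative to the descriptor's directory.

```yaml
alpha: 0.005        # Wilcoxon significance level (default 0.005)
bf_upper: 5.0       # Bayes factor above this supports learning (default 5)
bf_lower: 1.0       # Bayes factor below this supports no learning (default 1)
groups:
  experimental: [fly_0000.xml, fly_0002.xml]
  control:      [fly_0001.xml, fly_0003.xml]
overrides:          # optional per-fly inclusion overrides
  fly_0002: {include: false, reason: "torque meter drifted"}
```

## Reports

* Per-fly quality control: `qc_<fly_id>.json` + `qc_<fly_id>.html`
  (rule outcomes, per-period PI table, optomotor fit summaries, raw
  torque min/max envelope).
* Dataset evaluation: `dataset_evaluation.json` + `.html` (per-group
  verdicts, inclusion table with reasons, pairwise comparisons,
  optomotor asymmetry section with the preference regression).
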