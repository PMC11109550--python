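# torquelearn

Analysis pipeline for **operant self-learning** experiments in
tethered *Drosophila* flight, plus a synthetic tethered-fly simulator
for validating it.

In these experiments a fly, tethered to a torque meter, generates yaw
torque whose sign splits behaviour into a left-turning and a
right-turning domain. During training periods, heat punishes one
domain (the laser is on exactly while the torque is in the punished
domain); test periods measure whether the fly learned to avoid it.
The package is for behavioural neuroscientists who need the full
evaluation chain — from raw per-fly time series to a per-group
learning verdict — as a tested, reusable library.

## What it computes

* **Performance index.** Each torque period is segmented at every
  torque sign change (no hysteresis) and scored as
  PI = (tₐ − t_b)/(tₐ + t_b), with t_b the punished time (heat-on
  during training, dwell time in the punished domain during tests).
  The learning score is the PI of the first test period after the
  last training period (period 8 of the 9-period Tang protocol,
  period 12 of the 17-period protocol).
* **Optomotor asymmetry.** In the 17-period protocol, 30-s optomotor
  periods bracket the experiment. Each period's torque trace is
  fitted per rotation direction with a line or a double-sigmoidal
  model (chosen by the detected slope); the response magnitude is
  the line's midpoint value or the double sigmoid's late-time
  asymptote. The asymmetry index (R − L)/(R + L) is sign-adjusted so
  positive values mean a shift toward the unpunished domain.
* **Quality control.** Four exclusion rules: laser survival ≥ 15 s,
  absent/shifted optomotor response, no heat experienced during
  training, constant stopping of flight. Per-fly JSON + HTML report
  sheets; excluded traces stay in the dataset.
* **Verdict.** Per group, a two-sided Wilcoxon signed-rank test of
  the learning PIs against zero and a one-sample JZS Bayes factor
  (Cauchy scale √2/2). *Intact* requires p < 0.005 **and**
  BF₁₀ > 5; *impaired* requires p > 0.05 **and** BF₁₀ < 1; anything
  conflicting or intermediate is *inconclusive*. Group differences
  use Mann–Whitney U + a two-sample Bayes factor, and the adjusted
  asymmetry is regressed on the learning PI.
* **Simulator.** A two-state semi-Markov domain process with escape
  behaviour under heat and a tunable dwell bias b ("learned_bias"),
  whose expected test-period PI equals b exactly; optomotor periods
  rise exponentially toward per-direction gains, optionally reduced
  on the punished side after training. Degenerate flies triggering
  each exclusion rule are built with `make_degenerate_fly`.

See `docs/methods.md` for the model and all numerical choices, and
`docs/file_formats.md` for the XML/YAML file dialects.

## Worked example

```python
import torquelearn as tl

schedule = tl.build_schedule("tang")
learners = tl.simulate_dataset(30, tl.FlyConfig(seed=101, learned_bias=0.5), schedule)
pis = [tl.learning_score(r) for r in learners]
print(tl.group_verdict("learners", pis))
```

Running `python examples/dataset_verdict.py` (two simulated groups of
30 flies, written to disk and evaluated through QC, scoring and
statistics) prints:

```
learners   n=30  median PI=+0.529 p=1.82e-06 BF10=1.11e+18 -> intact
null       n=30  median PI=+0.006 p=6.81e-01 BF10=0.194 -> impaired
learners vs null: p=3.02e-11 BF10=9.02e+18
```

The learner group (dwell bias 0.5 ⇒ expected PI 0.5) satisfies both
the frequentist and the Bayesian criterion, so its self-learning is
classified *intact*; the null group's PIs hover around zero and both
statistics agree on *impaired*. Other example scripts cover scoring
(`simulate_and_score.py`), optomotor fitting and asymmetry
(`optomotor_asymmetry.py`) and the exclusion rules
(`quality_control.py`).

A thin CLI wraps the same functions:

```
torquelearn simulate --setup new --n 30 --seed 7 --learned-bias 0.5 --out data/
torquelearn score    --in data/ --out scores.json
torquelearn omfit    --in data/ --phase both --out omfits.json
torquelearn qc       --in data/ --out qc/
torquelearn evaluate --dataset data/dataset.yaml --out report/
```

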