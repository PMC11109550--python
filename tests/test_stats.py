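"""Wilcoxon/Bayes-factor inference, verdicts, comparisons, regression."""

import math

import numpy as np
import pytest
from scipy import stats as ss

import torquelearn as tl
from torquelearn.errors import DegenerateSampleError, EmptyGroupError


class TestWilcoxon:
    def test_all_positive_exact_enumeration(self):
        # all 6 values positive: statistic at its extreme; two-sided
        # exact p = 2 / 2^6 = 0.03125
        assert tl.wilcoxon_vs_zero([1, 2, 3, 4, 5, 6]) == pytest.approx(0.03125)

    def test_perfectly_symmetric_sample(self):
        assert tl.wilcoxon_vs_zero([-3, -2, -1, 1, 2, 3]) == pytest.approx(1.0)

    def test_zeros_dropped(self):
        with_zeros = tl.wilcoxon_vs_zero([0.0, 0.0, 1, 2, 3, 4, 5, 6])
        assert with_zeros == pytest.approx(0.03125)

    def test_degenerate_samples_rejected(self):
        with pytest.raises(DegenerateSampleError):
            tl.wilcoxon_vs_zero([0.0] * 10)
        with pytest.raises(DegenerateSampleError):
            tl.wilcoxon_vs_zero([1.0, 2.0])

    def test_null_p_values_approximately_uniform(self):
        """Large-sample null calibration (KS over 1000 replicates)."""
        ps = np.array(
            [
                tl.wilcoxon_vs_zero(np.random.default_rng(i).normal(0, 1, 30))
                for i in range(1000)
            ]
        )
        assert ss.kstest(ps, "uniform").pvalue > 0.01
        assert 0.03 <= np.mean(ps < 0.05) <= 0.07


class TestBayesFactor:
    def test_matches_independent_jzs_implementation(self):
        """Cross-check the quadrature against pingouin's JZS formula."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        for _ in range(5):
            x = rng.normal(0.4, 1.0, 25)
            t = float(np.mean(x) / (np.std(x, ddof=1) / math.sqrt(len(x))))
            expected = float(
                pg.bayesfactor_ttest(t, len(x), paired=True, r=math.sqrt(2) / 2)
            )
            assert tl.bayes_factor_vs_zero(x) == pytest.approx(expected, rel=1e-6)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0.3, 1.0, 20)
        assert tl.bayes_factor_vs_zero(2 * x) == pytest.approx(
            tl.bayes_factor_vs_zero(x), rel=1e-9
        )

    def test_strong_effect_exceeds_threshold(self):
        """n=30 at d=1.5: BF10 > 5 in >= 95% of 200 seeded replicates."""
        wins = sum(
            tl.bayes_factor_vs_zero(np.random.default_rng(i).normal(1.5, 1.0, 30)) > 5
            for i in range(200)
        )
        assert wins >= 190

    def test_null_effect_median_below_one(self):
        bfs = [
            tl.bayes_factor_vs_zero(np.random.default_rng(i).normal(0.0, 1.0, 30))
            for i in range(200)
        ]
        assert np.median(bfs) < 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateSampleError):
            tl.bayes_factor_vs_zero([1.0] * 10)


class TestClassification:
    @pytest.mark.parametrize(
        "p,bf,expected",
        [
            (0.001, 12.0, "intact"),
            (0.30, 0.4, "impaired"),
            (0.02, 3.0, "inconclusive"),
            (0.001, 3.0, "inconclusive"),  # conflict: p strong, BF weak
            (0.30, 12.0, "inconclusive"),  # conflict: BF strong, p weak
        ],
    )
    def test_three_way_rule(self, p, bf, expected):
        assert tl.classify_learning(p, bf) == expected

    def test_verdict_monotone(self):
        """Decreasing p at fixed BF, or increasing BF at fixed p, never
        demotes a group from intact."""
        ps = np.logspace(-6, 0, 25)
        bfs = np.logspace(-2, 3, 25)
        for bf in bfs:
            intact = [tl.classify_learning(p, bf) == "intact" for p in ps]
            # once not intact as p grows, never intact again
            assert intact == sorted(intact, reverse=True)
        for p in ps:
            intact = [tl.classify_learning(p, bf) == "intact" for bf in bfs]
            assert intact == sorted(intact)


class TestCompareGroups:
    def test_identical_groups(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 20)
        p, bf = tl.compare_groups(x, x.copy())
        assert p > 0.9
        assert bf < 1.0

    def test_separated_groups_detected(self):
        """Groups shifted by 3 pooled sds: p < 0.005 and BF > 5 in
        >= 95% of seeded replicates."""
        wins = 0
        for i in range(100):
            rng = np.random.default_rng(i)
            a = rng.normal(0, 1, 20)
            b = rng.normal(3, 1, 20)
            p, bf = tl.compare_groups(a, b)
            wins += (p < 0.005) and (bf > 5)
        assert wins >= 95

    def test_label_swap_symmetric(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 15), rng.normal(1, 1, 17)
        p1, bf1 = tl.compare_groups(a, b)
        p2, bf2 = tl.compare_groups(b, a)
        assert p1 == pytest.approx(p2)
        assert bf1 == pytest.approx(bf2, rel=1e-9)


class TestRegression:
    def test_exact_line(self):
        x = np.linspace(-1, 1, 20)
        res = tl.regress_preference_vs_asymmetry(x, 0.5 * x)
        assert res.slope == pytest.approx(0.5)
        assert res.r_squared == pytest.approx(1.0)

    def test_permuted_pairing_null(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 40)
        y = 0.8 * x + rng.normal(0, 0.3, 40)
        ps = []
        for i in range(200):
            perm = np.random.default_rng(i).permutation(len(y))
            ps.append(tl.regress_preference_vs_asymmetry(x, y[perm]).p_value)
        assert ss.kstest(np.array(ps), "uniform").pvalue > 0.01

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(DegenerateSampleError):
            tl.regress_preference_vs_asymmetry([1.0] * 10, list(range(10)))


class TestEvaluateDataset:
    def _descriptor(self, groups, **kw):
        return tl.DatasetDescriptor(groups=groups, **kw)

    def test_learner_cohort_end_to_end(self, tang_schedule):
        recs = tl.simulate_dataset(
            12, tl.FlyConfig(seed=10, learned_bias=0.6), tang_schedule
        )
        desc = self._descriptor({"learners": [f"{r.fly_id}.xml" for r in recs]})
        report = tl.evaluate_dataset(desc, records={"learners": recs})
        g = report["groups"]["learners"]
        assert g["n_included"] == 12
        assert g["classification"] in ("intact", "inconclusive")
        assert g["median_pi"] > 0
        assert len(report["flies"]) == 12

    def test_two_group_comparison_present(self, tang_schedule):
        a = tl.simulate_dataset(8, tl.FlyConfig(seed=20, learned_bias=0.7), tang_schedule)
        b = tl.simulate_dataset(8, tl.FlyConfig(seed=21, learned_bias=0.0), tang_schedule)
        desc = self._descriptor(
            {"exp": [f"{r.fly_id}.xml" for r in a], "ctrl": [f"{r.fly_id}.xml" for r in b]}
        )
        report = tl.evaluate_dataset(desc, records={"exp": a, "ctrl": b})
        assert len(report["comparisons"]) == 1
        assert report["comparisons"][0]["groups"] == ["exp", "ctrl"]

    def test_all_excluded_cohort_raises(self, new_schedule):
        recs = [
            tl.make_degenerate_fly("laser_resistant", new_schedule, seed=s)
            for s in range(5)
        ]
        desc = self._descriptor({"broken": [f"{r.fly_id}.xml" for r in recs]})
        with pytest.raises(EmptyGroupError):
            tl.evaluate_dataset(desc, records={"broken": recs})

    def test_file_backed_round_trip(self, tang_schedule, tmp_path):
        recs = tl.simulate_dataset(
            6, tl.FlyConfig(seed=30, learned_bias=0.6), tang_schedule
        )
        tl.write_simulated_dataset(recs, tmp_path)
        desc = tl.read_dataset_descriptor(tmp_path / "dataset.yaml")
        report = tl.evaluate_dataset(desc)
        assert report["groups"]["simulated"]["n_included"] == 6
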