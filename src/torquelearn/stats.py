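"""Group-level inference and the three-way learning verdict.

Each group's learning scores (one PI per fly) are tested two ways:

* a two-sided Wilcoxon signed-rank test against zero (exact null
  distribution for n <= 25 without ties, normal approximation with
  continuity correction otherwise; exact zeros are dropped), and
* a one-sample JZS Bayes factor BF10 against zero — Cauchy prior with
  scale r = sqrt(2)/2 on the standardised effect, marginal likelihood
  evaluated by adaptive quadrature.

The verdict combines both at configurable thresholds: *intact*
(self-learning demonstrated) requires p < alpha (default 0.005) AND
BF10 > bf_upper (default 5); *impaired* requires p > 0.05 AND
BF10 < bf_lower (default 1); anything conflicting or intermediate is
*inconclusive*.

Group comparisons use a two-sided Mann-Whitney U test plus a
two-sample JZS Bayes factor; the preference-vs-asymmetry relation is
an ordinary least-squares regression of the adjusted optomotor
asymmetry on the learning PI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import integrate, stats

from .data_model import DatasetDescriptor, ExperimentRecord, read_experiment
from .errors import DegenerateSampleError, EmptyGroupError, UnsupportedProtocolError
from .optomotor import om_analysis, om_phase_fits
from .qc import QcThresholds, qc_report, run_qc
from .selflearn import learning_score

__all__ = [
    "Verdict",
    "RegressionResult",
    "wilcoxon_vs_zero",
    "bayes_factor_vs_zero",
    "classify_learning",
    "compare_groups",
    "regress_preference_vs_asymmetry",
    "group_verdict",
    "evaluate_dataset",
]

JZS_CAUCHY_SCALE = math.sqrt(2.0) / 2.0
_QUAD_TOL = 1e-8


@dataclass(frozen=True)
class Verdict:
    group: str
    n: int
    median_pi: float
    p_value: float
    bayes_factor: float
    classification: str  # "intact" | "impaired" | "inconclusive"


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def wilcoxon_vs_zero(values: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value against a zero median.

    Exact zeros are dropped (Wilcoxon's original treatment); the exact
    permutation distribution is used for n <= 25 without tied absolute
    values, otherwise the normal approximation with continuity
    correction and average ranks for ties.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 5:
        raise DegenerateSampleError(f"need n >= 5 values, got {len(x)}")
    nz = x[x != 0]
    if len(nz) == 0:
        raise DegenerateSampleError("all values are exactly zero")
    has_ties = len(np.unique(np.abs(nz))) < len(nz)
    method = "exact" if (len(nz) <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(
        nz, alternative="two-sided", method=method, correction=(method == "approx")
    )
    return float(res.pvalue)


def _jzs_bf10(t: float, n_eff: float, df: float, r: float = JZS_CAUCHY_SCALE) -> float:
    """JZS Bayes factor BF10 from a t statistic.

    Cauchy(0, r) prior on the standardised effect, equivalently a
    scaled inverse-chi^2 mixture over the unit-information g-prior:

        BF10 = [ integral over g of (1+Ng)^(-1/2)
                 (1 + t^2/((1+Ng) df))^(-(df+1)/2) pi(g) dg ]
               / (1 + t^2/df)^(-(df+1)/2),

    pi(g) = inverse-gamma(1/2, r^2/2).
    """
    t2 = t * t

    def integrand(g: float) -> float:
        ng1 = 1.0 + n_eff * g
        log_lik = -0.5 * math.log(ng1) - 0.5 * (df + 1) * math.log1p(t2 / (ng1 * df))
        log_prior = (
            0.5 * math.log(r * r / 2.0)
            - math.lgamma(0.5)
            - 1.5 * math.log(g)
            - r * r / (2.0 * g)
        )
        return math.exp(log_lik + log_prior)

    num, _ = integrate.quad(
        integrand, 0.0, np.inf, epsabs=_QUAD_TOL, epsrel=_QUAD_TOL, limit=200
    )
    log_null = -0.5 * (df + 1) * math.log1p(t2 / df)
    return num / math.exp(log_null)


def bayes_factor_vs_zero(values: Sequence[float]) -> float:
    """One-sample JZS Bayes factor BF10 for a nonzero mean."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise DegenerateSampleError(f"need n >= 3 values, got {len(x)}")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise DegenerateSampleError("zero variance sample")
    n = len(x)
    t = float(np.mean(x)) / (sd / math.sqrt(n))
    return _jzs_bf10(t, n_eff=float(n), df=float(n - 1))


def classify_learning(
    p: float,
    bf: float,
    descriptor: DatasetDescriptor | None = None,
    *,
    alpha: float | None = None,
    bf_upper: float | None = None,
    bf_lower: float | None = None,
) -> str:
    """Three-way verdict from the frequentist and Bayesian evidence.

    "intact" needs both p < alpha and BF10 > bf_upper; "impaired" needs
    both p > 0.05 and BF10 < bf_lower; conflicting or intermediate
    evidence is "inconclusive".
    """
    if descriptor is not None:
        alpha = descriptor.alpha if alpha is None else alpha
        bf_upper = descriptor.bf_upper if bf_upper is None else bf_upper
        bf_lower = descriptor.bf_lower if bf_lower is None else bf_lower
    alpha = 0.005 if alpha is None else alpha
    bf_upper = 5.0 if bf_upper is None else bf_upper
    bf_lower = 1.0 if bf_lower is None else bf_lower
    if p < alpha and bf > bf_upper:
        return "intact"
    if p > 0.05 and bf < bf_lower:
        return "impaired"
    return "inconclusive"


def group_verdict(
    group: str, values: Sequence[float], descriptor: DatasetDescriptor | None = None
) -> Verdict:
    x = np.asarray(values, dtype=float)
    p = wilcoxon_vs_zero(x)
    bf = bayes_factor_vs_zero(x)
    return Verdict(
        group=group,
        n=len(x),
        median_pi=float(np.median(x)),
        p_value=p,
        bayes_factor=bf,
        classification=classify_learning(p, bf, descriptor),
    )


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """(p, BF10) for a two-group comparison.

    Two-sided Mann-Whitney U p-value plus a two-sample JZS Bayes factor
    (effective sample size n_a n_b / (n_a + n_b)).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 5 or len(b) < 5:
        raise DegenerateSampleError("both groups need n >= 5")
    pooled_sd = math.sqrt(
        (
            (len(a) - 1) * np.var(a, ddof=1) + (len(b) - 1) * np.var(b, ddof=1)
        )
        / (len(a) + len(b) - 2)
    )
    if pooled_sd == 0:
        raise DegenerateSampleError("both groups are constant")
    p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    t = (float(np.mean(a)) - float(np.mean(b))) / (
        pooled_sd * math.sqrt(1.0 / len(a) + 1.0 / len(b))
    )
    n_eff = len(a) * len(b) / (len(a) + len(b))
    bf = _jzs_bf10(t, n_eff=float(n_eff), df=float(len(a) + len(b) - 2))
    return p, bf


def regress_preference_vs_asymmetry(
    pis: Sequence[float], adjusted_asyms: Sequence[float]
) -> RegressionResult:
    """OLS of adjusted optomotor asymmetry on the learning PI."""
    x = np.asarray(pis, dtype=float)
    y = np.asarray(adjusted_asyms, dtype=float)
    if len(x) != len(y):
        raise ValueError("pis and asymmetries must be paired (equal length)")
    if len(x) < 5:
        raise DegenerateSampleError("need n >= 5 pairs")
    if np.var(x) == 0:
        raise DegenerateSampleError("zero-variance predictor")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(x),
    )


def evaluate_dataset(
    descriptor: DatasetDescriptor,
    *,
    records: dict[str, list[ExperimentRecord]] | None = None,
    thresholds: QcThresholds = QcThresholds(),
) -> dict:
    """Full dataset evaluation: QC, scoring, optomotor analysis, verdicts.

    ``records`` may pre-supply loaded records per group (e.g. from the
    simulator); otherwise the descriptor's file references are read.
    Returns a JSON-serialisable report with per-fly QC summaries,
    per-group score tables and verdicts, pairwise group comparisons and
    (for new-setup records) the optomotor asymmetry analysis including
    the preference-vs-asymmetry regression.
    """
    if records is None:
        records = {
            group: [read_experiment(descriptor.resolve(ref)) for ref in refs]
            for group, refs in descriptor.groups.items()
        }
    report: dict = {
        "alpha": descriptor.alpha,
        "bf_upper": descriptor.bf_upper,
        "bf_lower": descriptor.bf_lower,
        "flies": [],
        "groups": {},
        "comparisons": [],
        "optomotor": None,
    }
    group_scores: dict[str, list[float]] = {}
    om_pairs: list[tuple[float, float, float]] = []  # (pi, adj_before, adj_after)
    for group, recs in records.items():
        scores: list[float] = []
        table = []
        for rec in recs:
            has_om = bool(rec.schedule.om_periods())
            fits_before = om_phase_fits(rec, "before") if has_om else None
            fits_after = om_phase_fits(rec, "after") if has_om else None
            qc = run_qc(
                rec,
                fits_before,
                thresholds,
                override=descriptor.overrides.get(rec.fly_id),
            )
            fly_report = qc_report(rec, qc, fits_before, fits_after)
            report["flies"].append(fly_report)
            row = {
                "fly_id": rec.fly_id,
                "punished_domain": rec.punished_domain.value,
                "included": qc.included,
                "excluded_by": qc.failing_rules() if not qc.included else [],
                "learning_pi": None,
            }
            if qc.included:
                pi = learning_score(rec)
                row["learning_pi"] = round(pi, 4)
                scores.append(pi)
                if has_om:
                    om = om_analysis(
                        rec, {"before": fits_before, "after": fits_after}
                    )
                    row["adjusted_asym_before"] = round(om["before"]["adjusted"], 4)
                    row["adjusted_asym_after"] = round(om["after"]["adjusted"], 4)
                    om_pairs.append(
                        (pi, om["before"]["adjusted"], om["after"]["adjusted"])
                    )
            table.append(row)
        if not scores:
            raise EmptyGroupError(f"group {group!r} has no included flies")
        group_scores[group] = scores
        verdict = group_verdict(group, scores, descriptor)
        report["groups"][group] = {
            "table": table,
            "n_included": len(scores),
            "median_pi": verdict.median_pi,
            "p_value": verdict.p_value,
            "bayes_factor": verdict.bayes_factor,
            "classification": verdict.classification,
        }
    names = list(group_scores)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            try:
                p, bf = compare_groups(group_scores[a], group_scores[b])
            except DegenerateSampleError:
                continue
            report["comparisons"].append(
                {"groups": [a, b], "p_value": p, "bayes_factor": bf}
            )
    if om_pairs:
        pis = [v[0] for v in om_pairs]
        before = [v[1] for v in om_pairs if not math.isnan(v[1])]
        after = [v[2] for v in om_pairs if not math.isnan(v[2])]
        om_section: dict = {
            "n": len(om_pairs),
            "mean_adjusted_before": float(np.mean(before)) if before else None,
            "mean_adjusted_after": float(np.mean(after)) if after else None,
        }
        if len(before) >= 5:
            om_section["wilcoxon_before_p"] = wilcoxon_vs_zero(before)
        if len(after) >= 5:
            om_section["wilcoxon_after_p"] = wilcoxon_vs_zero(after)
        if len(om_pairs) >= 5:
            try:
                reg = regress_preference_vs_asymmetry(
                    pis, [v[2] for v in om_pairs]
                )
                om_section["regression"] = {
                    "slope": reg.slope,
                    "intercept": reg.intercept,
                    "r_squared": reg.r_squared,
                    "p_value": reg.p_value,
                    "n": reg.n,
                }
            except DegenerateSampleError:
                pass
        report["optomotor"] = om_section
    return report
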