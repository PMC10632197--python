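"""Diagnostic-accuracy statistics for patient-level screening evaluation.

Implements the 2x2 confusion matrix against the reference standard, the five
accuracy metrics (sensitivity, specificity, PPV, NPV, overall accuracy) with
confidence intervals, subgroup analyses, and the Wald odds ratio for a 2x2
exposure table.

Two binomial interval methods are provided: the exact Clopper-Pearson
interval (Beta-distribution quantiles, conservative coverage) and the Wilson
score interval (approximate nominal coverage). Predictive values, which
depend on prevalence, get delta-method intervals on the logit scale
(Mercaldo-style), combining the binomial uncertainty of sensitivity and
specificity at the cohort prevalence. Every estimate records the method that
produced its bounds; degenerate cases (zero denominators, boundary variance)
are reported as undefined rather than as 0 or 1 with fabricated bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Iterable, Mapping, Optional

from scipy import stats as _sps

from .model import AccuracyReport, ConfusionMatrix, IntervalEstimate, ReferenceOutcome

CI_METHODS = ("clopper_pearson", "wilson")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal round-half-up, the convention used for reported percentages."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def as_percent(x: float, decimals: int = 1) -> float:
    # scale inside Decimal so 0.8865 -> 88.65 exactly, not 88.649999...
    q = Decimal(10) ** -decimals
    return float((Decimal(repr(x)) * 100).quantize(q, rounding=ROUND_HALF_UP))


def _check_counts(x: int, n: int) -> None:
    if n < 1 or not 0 <= x <= n:
        raise ValueError(f"invalid binomial counts x={x}, n={n}")


def clopper_pearson_ci(x: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial interval via Beta quantiles.

    lower = BetaInv(alpha/2; x, n-x+1), upper = BetaInv(1-alpha/2; x+1, n-x),
    with lower = 0 at x = 0 and upper = 1 at x = n.
    """
    _check_counts(x, n)
    alpha = 1.0 - confidence
    lower = 0.0 if x == 0 else float(_sps.beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(_sps.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lower, upper


def wilson_ci(x: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    _check_counts(x, n)
    z = float(_sps.norm.ppf(0.5 + confidence / 2))
    p = x / n
    denom = 1 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return max(0.0, center - half), min(1.0, center + half)


_BINOMIAL_CI: dict[str, Callable[[int, int, float], tuple[float, float]]] = {
    "clopper_pearson": clopper_pearson_ci,
    "wilson": wilson_ci,
}


def _proportion_estimate(x: int, n: int, ci_method: str, confidence: float) -> IntervalEstimate:
    if n == 0:
        return IntervalEstimate(point=None, method="none", confidence=confidence)
    lower, upper = _BINOMIAL_CI[ci_method](x, n, confidence)
    return IntervalEstimate(
        point=x / n, lower=lower, upper=upper, method=ci_method, confidence=confidence
    )


def predictive_value_ci_logit(
    which: str,
    se: float,
    sp: float,
    n1: int,
    n0: int,
    prevalence: float,
    confidence: float = 0.95,
) -> IntervalEstimate:
    """Predictive value at a given prevalence, with a logit-scale delta-method CI.

    Point estimates follow Bayes' theorem:

        PPV = se*p / (se*p + (1-sp)*(1-p))
        NPV = sp*(1-p) / ((1-se)*p + sp*(1-p))

    with delta-method variances on the logit scale

        Var(logit PPV) = (1-se)/(se*n1) + sp/((1-sp)*n0)
        Var(logit NPV) = se/((1-se)*n1) + (1-sp)/(sp*n0)

    where n1 and n0 are the condition-positive and condition-negative sample
    sizes behind se and sp. At boundary values of se or sp the variance is
    undefined and the point is returned without bounds (method ``none``).
    """
    if which not in ("PPV", "NPV"):
        raise ValueError("which must be 'PPV' or 'NPV'")
    if n1 < 1 or n0 < 1:
        raise ValueError("n1 and n0 must be at least 1")
    for name, v in (("se", se), ("sp", sp), ("prevalence", prevalence)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    p = prevalence
    if which == "PPV":
        denom = se * p + (1 - sp) * (1 - p)
        point = se * p / denom if denom > 0 else None
        defined = 0 < se and sp < 1
        var = (1 - se) / (se * n1) + sp / ((1 - sp) * n0) if defined else None
    else:
        denom = (1 - se) * p + sp * (1 - p)
        point = sp * (1 - p) / denom if denom > 0 else None
        defined = se < 1 and 0 < sp
        var = se / ((1 - se) * n1) + (1 - sp) / (sp * n0) if defined else None
    if point is None or var is None or not 0 < point < 1:
        return IntervalEstimate(point=point, method="none", confidence=confidence)
    z = float(_sps.norm.ppf(0.5 + confidence / 2))
    logit = math.log(point / (1 - point))
    lo = logit - z * math.sqrt(var)
    hi = logit + z * math.sqrt(var)
    expit = lambda u: 1.0 / (1.0 + math.exp(-u))
    return IntervalEstimate(
        point=point,
        lower=expit(lo),
        upper=expit(hi),
        method="mercaldo_logit",
        confidence=confidence,
    )


def build_confusion_matrix(
    screen_positive: Iterable[str],
    outcomes: Mapping[str, ReferenceOutcome],
    cohort: Iterable[str],
) -> ConfusionMatrix:
    """Patient-level confusion matrix of the screen against the reference standard."""
    cohort_set = set(cohort)
    positive_set = set(screen_positive)
    extra = positive_set - cohort_set
    if extra:
        raise ValueError(f"screen-positive patients not in cohort: {sorted(extra)[:5]}")
    missing = cohort_set - set(outcomes)
    if missing:
        raise ValueError(f"cohort patients without reference outcome: {sorted(missing)[:5]}")
    tp = fp = fn = tn = 0
    for pid in cohort_set:
        disease = outcomes[pid].brain_death_confirmed
        positive = pid in positive_set
        if positive and disease:
            tp += 1
        elif positive:
            fp += 1
        elif disease:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def diagnostic_metrics(
    matrix: ConfusionMatrix,
    ci_method: str = "clopper_pearson",
    confidence: float = 0.95,
) -> AccuracyReport:
    """The five accuracy metrics with confidence intervals.

    Sensitivity, specificity and overall accuracy get binomial intervals by
    ``ci_method``; PPV and NPV get logit-scale predictive-value intervals at
    the cohort prevalence. A metric whose denominator is zero, or whose
    interval variance is undefined, is reported with method ``none``.
    """
    if ci_method not in _BINOMIAL_CI:
        raise ValueError(f"unknown ci_method {ci_method!r}; expected one of {CI_METHODS}")
    n1 = matrix.tp + matrix.fn
    n0 = matrix.tn + matrix.fp
    n = matrix.n
    sens = _proportion_estimate(matrix.tp, n1, ci_method, confidence)
    spec = _proportion_estimate(matrix.tn, n0, ci_method, confidence)
    acc = _proportion_estimate(matrix.tp + matrix.tn, n, ci_method, confidence)
    if n1 >= 1 and n0 >= 1 and sens.point is not None and spec.point is not None:
        prev = n1 / n
        ppv = predictive_value_ci_logit("PPV", sens.point, spec.point, n1, n0, prev, confidence)
        npv = predictive_value_ci_logit("NPV", sens.point, spec.point, n1, n0, prev, confidence)
        # Bayes at prevalence n1/N coincides with tp/(tp+fp) and tn/(tn+fn);
        # an undefined Bayes denominator means the empirical one is 0 too.
        if matrix.tp + matrix.fp == 0:
            ppv = IntervalEstimate(point=None, method="none", confidence=confidence)
        if matrix.tn + matrix.fn == 0:
            npv = IntervalEstimate(point=None, method="none", confidence=confidence)
    else:
        ppv = _ratio_only(matrix.tp, matrix.tp + matrix.fp, confidence)
        npv = _ratio_only(matrix.tn, matrix.tn + matrix.fn, confidence)
    return AccuracyReport(
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv, accuracy=acc,
        matrix=matrix, n1=n1, n0=n0,
    )


def _ratio_only(x: int, n: int, confidence: float) -> IntervalEstimate:
    point = x / n if n > 0 else None
    return IntervalEstimate(point=point, method="none", confidence=confidence)


def subgroup_metrics(
    screen_positive: set[str],
    outcomes: Mapping[str, ReferenceOutcome],
    cohort: set[str],
    *,
    patient_filter: Optional[Callable[[str], bool]] = None,
    positivity_override: Optional[set[str]] = None,
    ci_method: str = "clopper_pearson",
    confidence: float = 0.95,
) -> AccuracyReport:
    """Accuracy metrics under one of two distinct subgroup semantics.

    ``patient_filter`` restricts the *cohort* to patients satisfying a
    predicate (e.g. mechanically ventilated patients) — both positives and
    the denominator shrink. ``positivity_override`` keeps the full cohort but
    redefines who counts as screen-positive (e.g. only patients detected
    repeatedly). Supplying both applies the filter to the overridden
    positivity.
    """
    positives = positivity_override if positivity_override is not None else screen_positive
    sub_cohort = cohort
    if patient_filter is not None:
        sub_cohort = {pid for pid in cohort if patient_filter(pid)}
        positives = positives & sub_cohort
    if not sub_cohort:
        raise ValueError("subgroup filter produced an empty cohort")
    matrix = build_confusion_matrix(positives, outcomes, sub_cohort)
    return diagnostic_metrics(matrix, ci_method=ci_method, confidence=confidence)


@dataclass(frozen=True)
class OddsRatioResult:
    """Odds ratio for a 2x2 exposure table with its Wald interval.

    ``odds_ratio`` is None when any cell is zero (no continuity correction is
    applied; the ``zero_cell`` flag marks the case).
    """

    odds_ratio: Optional[float]
    lower: Optional[float]
    upper: Optional[float]
    confidence: float
    zero_cell: bool


def odds_ratio_2x2(
    exposed_pos: int,
    unexposed_pos: int,
    exposed_neg: int,
    unexposed_neg: int,
    confidence: float = 0.95,
) -> OddsRatioResult:
    """Sample odds ratio (ad)/(bc) with the Wald log-scale interval.

    ``exposed_pos``/``unexposed_pos`` are outcome-positive counts by exposure,
    ``exposed_neg``/``unexposed_neg`` outcome-negative counts. Equivalent to a
    bivariate logistic regression with one binary predictor.
    """
    a, b, c, d = exposed_pos, unexposed_pos, exposed_neg, unexposed_neg
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("cell counts must be non-negative")
    if 0 in (a, b, c, d):
        return OddsRatioResult(None, None, None, confidence, zero_cell=True)
    orr = (a * d) / (b * c)
    z = float(_sps.norm.ppf(0.5 + confidence / 2))
    se_log = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OddsRatioResult(
        odds_ratio=orr,
        lower=math.exp(math.log(orr) - z * se_log),
        upper=math.exp(math.log(orr) + z * se_log),
        confidence=confidence,
        zero_cell=False,
    )
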