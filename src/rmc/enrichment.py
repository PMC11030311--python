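"""Case/control enrichment statistics.

Two families of statistics evaluate how well a constraint metric or score
concentrates disease-associated variation:

* per-stratum **rate ratios** — the per-individual variant rate in cases over
  that in controls, with 95% confidence intervals and p-value from a binomial
  test of the case/control split of variant counts given the cohort sizes;
* **top-percentile odds ratios** — case and control variants are pooled and
  ranked by a score, and a Fisher exact test compares case/control membership
  in the top percentile against the rest (ties at the percentile boundary are
  included in the top set).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from rmc.errors import InputError
from rmc.simulate import Cohort

#: Default MPC bin edges used in stratified de novo comparisons.
DEFAULT_MPC_BINS = (1.6, 2.6)


@dataclass(frozen=True)
class RateRatioResult:
    rr: float
    ci_lower: float
    ci_upper: float
    p_value: float
    case_count: int
    control_count: int


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]


def rate_ratio_counts(
    case_count: int, n_case: int, control_count: int, n_control: int
) -> RateRatioResult:
    """Rate ratio from variant counts and cohort sizes.

    The p-value and CI come from a binomial test of ``case_count`` successes
    in ``case_count + control_count`` trials against the null proportion
    ``n_case / (n_case + n_control)``; the proportion CI is transformed back
    to the rate-ratio scale. Zero control variants give an infinite estimate
    with a one-sided interval.
    """
    if n_case <= 0 or n_control <= 0:
        raise InputError("cohort sizes must be positive")
    if case_count < 0 or control_count < 0:
        raise InputError("counts must be non-negative")
    total = case_count + control_count
    if total == 0:
        return RateRatioResult(np.nan, np.nan, np.nan, np.nan, 0, 0)
    null_p = n_case / (n_case + n_control)
    bt = stats.binomtest(case_count, total, null_p)
    ci = bt.proportion_ci(confidence_level=0.95)

    def to_rr(p):
        if p >= 1.0:
            return np.inf
        return (p / (1.0 - p)) * (n_control / n_case)

    rr = (
        np.inf
        if control_count == 0
        else (case_count / n_case) / (control_count / n_control)
    )
    return RateRatioResult(
        rr=rr,
        ci_lower=to_rr(ci.low),
        ci_upper=to_rr(ci.high),
        p_value=float(bt.pvalue),
        case_count=int(case_count),
        control_count=int(control_count),
    )


def rate_ratio(case: Cohort, control: Cohort, stratum=None) -> RateRatioResult:
    """Rate ratio between two cohorts, optionally within a variant stratum.

    ``stratum`` is a callable mapping a variant table to a boolean mask
    (e.g. ``lambda v: v["oe_bin"] == 0``); None uses all variants.
    """
    cv, xv = case.variants, control.variants
    if stratum is not None:
        cv, xv = cv[stratum(cv)], xv[stratum(xv)]
    return rate_ratio_counts(len(cv), case.n_individuals, len(xv), control.n_individuals)


def _odds_ratio_ci(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Woolf logit 95% CI with Haldane 0.5 correction when any cell is zero."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = np.log((a * d) / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return float(np.exp(log_or - 1.96 * se)), float(np.exp(log_or + 1.96 * se))


def top_percentile_or(case_scores, control_scores, pct: float = 10.0) -> OddsRatioResult:
    """Odds ratio of case vs control membership in the pooled top percentile.

    Scores must be comparable on one scale (higher = more deleterious); only
    scored variants should be passed. All variants tied with the percentile
    boundary score enter the top set.
    """
    case_scores = np.asarray(case_scores, dtype=float)
    control_scores = np.asarray(control_scores, dtype=float)
    pooled = np.concatenate([case_scores, control_scores])
    if np.isnan(pooled).any():
        raise InputError("scores must not contain NaN; drop unscored variants first")
    n = len(pooled)
    n_top = int(np.ceil(pct / 100.0 * n))
    if n_top < 1:
        raise InputError(f"top {pct}% of {n} variants is empty")
    threshold = np.sort(pooled)[::-1][n_top - 1]
    a = int((case_scores >= threshold).sum())  # case, top
    b = int((control_scores >= threshold).sum())  # control, top
    c = len(case_scores) - a
    d = len(control_scores) - b
    table = np.array([[a, b], [c, d]])
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    lo, hi = _odds_ratio_ci(a, b, c, d)
    return OddsRatioResult(
        odds_ratio=float(odds),
        ci_lower=lo,
        ci_upper=hi,
        p_value=float(p),
        table=((a, b), (c, d)),
    )


def oe_bin_enrichment(
    case: Cohort,
    control: Cohort,
    bin_edges=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
) -> pd.DataFrame:
    """Per-bin rate ratios over local OE; final bin open-ended.

    Bins are left-closed right-open over the supplied edges, with the last
    edge opening an unbounded final bin. Bins with no variants in either
    cohort are marked undefined (NaN rate ratio).
    """
    edges = list(bin_edges) + [np.inf]
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        res = rate_ratio(
            case, control, stratum=lambda v, lo=lo, hi=hi: (v["local_oe"] >= lo) & (v["local_oe"] < hi)
        )
        rows.append(
            {
                "bin_lo": lo,
                "bin_hi": hi,
                "case_count": res.case_count,
                "control_count": res.control_count,
                "rr": res.rr,
                "ci_lower": res.ci_lower,
                "ci_upper": res.ci_upper,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows)


def score_bin_enrichment(
    case: Cohort,
    control: Cohort,
    score_column: str = "score",
    bin_edges=DEFAULT_MPC_BINS,
) -> pd.DataFrame:
    """Rate ratios per score bin (default MPC bins < 1.6, 1.6-2.6, >= 2.6)."""
    edges = [-np.inf] + list(bin_edges) + [np.inf]
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        res = rate_ratio(
            case,
            control,
            stratum=lambda v, lo=lo, hi=hi: (v[score_column] >= lo) & (v[score_column] < hi),
        )
        rows.append(
            {
                "bin_lo": lo,
                "bin_hi": hi,
                "case_count": res.case_count,
                "control_count": res.control_count,
                "rr": res.rr,
                "ci_lower": res.ci_lower,
                "ci_upper": res.ci_upper,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows)
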