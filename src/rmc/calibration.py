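"""ACMG/AMP evidence calibration from local posterior probabilities.

Given labeled variants (pathogenic/benign) and a continuous score (e.g. the
MCR missense OE, or MPC), the local posterior probability of pathogenicity is
estimated at each point of a score grid from the k nearest labeled variants,
with the local pathogenic fraction re-weighted from the labeled sample's
prevalence to a chosen prior. A one-sided 95% bootstrap bound on the
stringent side guards against sparse windows.

Evidence-strength thresholds follow the point-based probabilistic framework:
the odds of pathogenicity for very strong evidence is a constant c (default
350), and strong / moderate / supporting correspond to c^(1/2), c^(1/4),
c^(1/8); benign strengths use the reciprocal odds. Odds convert to posterior
cutoffs through the prior, and the score cutoff for a strength is the most
permissive score whose confidence bound — in an unbroken run from the
pathogenic (or benign) extreme of the grid — meets the posterior cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from rmc.errors import InputError

#: Canonical defaults of the published point-based framework.
DEFAULT_PRIOR = 0.0441
DEFAULT_POINT_SCALE = 350.0

STRENGTHS = ("supporting", "moderate", "strong", "very_strong")
_EXPONENTS = {"supporting": 0.125, "moderate": 0.25, "strong": 0.5, "very_strong": 1.0}


@dataclass
class PosteriorCurve:
    """Local posterior of pathogenicity along a score grid.

    ``ci_lower``/``ci_upper`` are the one-sided 95% bootstrap bounds; the
    pathogenic direction uses the lower (stringent) bound, the benign
    direction the upper. Undefined grid points (window too sparse) are NaN.
    """

    score_grid: np.ndarray
    posterior: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    window_k: int
    prior: float


@dataclass
class EvidenceThresholds:
    """Per-strength posterior cutoffs and the score cutoffs that meet them.

    ``score_cutoffs_pathogenic``/``score_cutoffs_benign`` map strength name to
    a score or None ("not reached").
    """

    prior: float
    point_scale: float
    posterior_cutoffs_pathogenic: dict[str, float]
    posterior_cutoffs_benign: dict[str, float]
    score_cutoffs_pathogenic: dict[str, float | None]
    score_cutoffs_benign: dict[str, float | None]


def _adjust_to_prior(p_local: np.ndarray, sample_prev: float, prior: float) -> np.ndarray:
    """Re-weight a local labeled fraction from the sample prevalence to a prior."""
    if not (0.0 < prior < 1.0):
        raise InputError("prior must be in (0, 1)")
    w = (prior / (1 - prior)) / (sample_prev / (1 - sample_prev))
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = w * p_local / (1 - p_local)
        post = odds / (1 + odds)
    return np.where(p_local >= 1.0, 1.0, np.where(p_local <= 0.0, 0.0, post))


def local_posterior(
    scores,
    labels,
    grid=None,
    window_k: int = 100,
    prior: float = DEFAULT_PRIOR,
    n_bootstrap: int = 1000,
    seed: int = 0,
    min_in_window: int = 10,
    n_grid: int = 50,
) -> PosteriorCurve:
    """Estimate the local posterior probability of pathogenicity.

    Parameters
    ----------
    scores, labels
        Labeled variants: continuous score and binary label (1 = pathogenic).
    grid
        Evaluation points; defaults to ``n_grid`` points spanning the scores.
    window_k
        Each grid point uses its ``window_k`` nearest labeled variants (by
        score distance); the score interval they span is fixed and re-used by
        the bootstrap.
    prior
        Target prevalence of pathogenicity; the local labeled fraction is
        re-weighted from the sample's prevalence to this prior.
    n_bootstrap, seed
        Bootstrap resamples of the variant set for the one-sided 95% bounds.
    min_in_window
        A grid point whose window holds fewer labeled variants than this (in
        a bootstrap replicate) is undefined there, never extrapolated.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise InputError("scores and labels must be parallel 1-d arrays")
    if not np.isin(labels, (0.0, 1.0)).all():
        raise InputError("labels must be binary")
    if len(scores) < max(window_k, min_in_window):
        raise InputError("not enough labeled variants for the requested window")
    order = np.argsort(scores, kind="mergesort")
    s_sorted, l_sorted = scores[order], labels[order]
    n = len(s_sorted)
    if grid is None:
        grid = np.linspace(s_sorted[0], s_sorted[-1], n_grid)
    grid = np.asarray(grid, dtype=float)
    sample_prev = float(labels.mean())
    if sample_prev in (0.0, 1.0):
        raise InputError("labels are all one class")

    # fixed k-nearest windows as score intervals [lo, hi] per grid point
    k = min(window_k, n)
    lo_idx = np.empty(len(grid), dtype=int)
    for gi, g in enumerate(grid):
        center = np.searchsorted(s_sorted, g)
        lo = int(np.clip(center - k // 2, 0, n - k))
        # slide the window to the true k-nearest set
        while lo > 0 and abs(s_sorted[lo - 1] - g) < abs(s_sorted[lo + k - 1] - g):
            lo -= 1
        while lo + k < n and abs(s_sorted[lo + k] - g) < abs(s_sorted[lo] - g):
            lo += 1
        lo_idx[gi] = lo
    win_lo = s_sorted[lo_idx]
    win_hi = s_sorted[lo_idx + k - 1]

    def curve_from(sorted_scores, sorted_labels):
        cl = np.concatenate([[0.0], np.cumsum(sorted_labels)])
        a = np.searchsorted(sorted_scores, win_lo, side="left")
        b = np.searchsorted(sorted_scores, win_hi, side="right")
        count = (b - a).astype(float)
        path = cl[b] - cl[a]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = path / count
        post = _adjust_to_prior(frac, sample_prev, prior)
        post[count < min_in_window] = np.nan
        return post

    posterior = curve_from(s_sorted, l_sorted)
    rng = np.random.default_rng(seed)
    boot = np.empty((n_bootstrap, len(grid)))
    for bi in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        bs = scores[idx]
        bl = labels[idx]
        o = np.argsort(bs, kind="mergesort")
        boot[bi] = curve_from(bs[o], bl[o])
    with np.errstate(invalid="ignore"):
        ci_lower = np.nanquantile(boot, 0.05, axis=0)
        ci_upper = np.nanquantile(boot, 0.95, axis=0)
    undefined = np.isnan(posterior)
    ci_lower[undefined] = np.nan
    ci_upper[undefined] = np.nan
    return PosteriorCurve(
        score_grid=grid,
        posterior=posterior,
        ci_lower=ci_lower,
        ci_upper=ci_upper,
        window_k=k,
        prior=prior,
    )


def posterior_cutoff(odds: float, prior: float) -> float:
    """Posterior implied by an odds-of-pathogenicity value at a given prior."""
    return odds * prior / ((odds - 1.0) * prior + 1.0)


def evidence_thresholds(
    curve: PosteriorCurve,
    prior: float | None = None,
    point_scale: float = DEFAULT_POINT_SCALE,
    low_score_is_pathogenic: bool = True,
    use_ci: bool = True,
) -> EvidenceThresholds:
    """Score cutoffs meeting each ACMG/AMP evidence strength.

    The pathogenic cutoff for a strength is the most permissive grid score
    such that every grid point at least as extreme (toward the pathogenic end)
    has a defined confidence bound meeting the posterior cutoff; analogously
    for benign with the reciprocal odds and the upper bound. ``use_ci=False``
    thresholds on the point estimate instead (less conservative).
    """
    prior = curve.prior if prior is None else prior
    if not (0.0 < prior < 1.0):
        raise InputError("prior must be in (0, 1)")
    post_path = {s: posterior_cutoff(point_scale ** _EXPONENTS[s], prior) for s in STRENGTHS}
    post_ben = {s: posterior_cutoff(point_scale ** -_EXPONENTS[s], prior) for s in STRENGTHS}

    grid = curve.score_grid
    path_bound = curve.ci_lower if use_ci else curve.posterior
    ben_bound = curve.ci_upper if use_ci else curve.posterior

    def run_from_extreme(bound, cutoff, pathogenic_direction: bool):
        # orient so index 0 is the relevant extreme of the grid
        extreme_first = low_score_is_pathogenic == pathogenic_direction
        vals = bound if extreme_first else bound[::-1]
        g = grid if extreme_first else grid[::-1]
        meets = (vals >= cutoff) if pathogenic_direction else (vals <= cutoff)
        meets = meets & ~np.isnan(vals)
        if not meets[0]:
            return None
        last = int(np.argmin(meets)) - 1 if not meets.all() else len(meets) - 1
        return float(g[last])

    score_path = {
        s: run_from_extreme(path_bound, post_path[s], True) for s in STRENGTHS
    }
    score_ben = {s: run_from_extreme(ben_bound, post_ben[s], False) for s in STRENGTHS}
    return EvidenceThresholds(
        prior=prior,
        point_scale=point_scale,
        posterior_cutoffs_pathogenic=post_path,
        posterior_cutoffs_benign=post_ben,
        score_cutoffs_pathogenic=score_path,
        score_cutoffs_benign=score_ben,
    )


def curve_frame(curve: PosteriorCurve) -> pd.DataFrame:
    """Posterior curve as a tidy table for TSV output."""
    return pd.DataFrame(
        {
            "score": curve.score_grid,
            "posterior": curve.posterior,
            "ci_lower": curve.ci_lower,
            "ci_upper": curve.ci_upper,
        }
    )
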