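"""Recursive Poisson likelihood-ratio search for missense constraint regions.

A transcript's observed rare-missense count in any coding interval is modeled
as Poisson around the interval's neutral expectation scaled by a depletion
ratio OE in [0, 1]. The null model shares one OE across the whole (sub)section;
the alternative gives each side of a candidate breakpoint its own OE. The
test statistic is

    chi2 = 2 (ln p1 - ln p0)

with p0/p1 products of Poisson likelihoods under the shared/section-specific
OEs. Factorial terms cancel in the ratio and are dropped; likelihoods are
computed in log space. Because each section's capped OE maximizes its own
Poisson likelihood over [0, 1], chi2 >= 0 always.

The search scans every eligible coding-position boundary (both resulting
sections need at least ``min_expected`` expected missense variants, default
16), takes the maximum-chi2 split if it clears the chi-square critical value
at ``alpha`` (default 0.001), and otherwise scans all ordered boundary pairs
(three sections, each with at least ``min_expected`` expected). The procedure
recurses into every new subsection as if it were an independent transcript
until no further significant break is found. A breakpoint at position k
assigns sites with cds_pos <= k to the left section (closed-left).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from rmc.constraint import EXP_FLOOR, OeRatio, TranscriptModel, capped_oe, oe
from rmc.errors import InputError


@dataclass(frozen=True)
class SearchConfig:
    """Tunable parameters of the breakpoint search."""

    min_expected: float = 16.0
    alpha: float = 0.001
    df_single: int = 1
    df_double: int = 2
    tie_break: str = "leftmost"

    def __post_init__(self):
        if self.min_expected <= 0:
            raise InputError("min_expected must be > 0")
        if not (0.0 < self.alpha < 1.0):
            raise InputError("alpha must be in (0, 1)")
        if self.tie_break != "leftmost":
            raise InputError(f"unknown tie_break rule: {self.tie_break}")

    @property
    def critical_single(self) -> float:
        return float(stats.chi2.isf(self.alpha, self.df_single))

    @property
    def critical_double(self) -> float:
        return float(stats.chi2.isf(self.alpha, self.df_double))


@dataclass(frozen=True)
class SplitStat:
    """A candidate split and its likelihood-ratio statistic."""

    positions: tuple[int, ...]
    chi_sq: float
    section_stats: tuple[OeRatio, ...]
    df: int
    pos_index: tuple[int, ...] = ()  # indices into TranscriptModel.positions


@dataclass(frozen=True)
class MissenseRegion:
    """A contiguous transcript subsection with its own depletion level."""

    transcript_id: str
    cds_start: int
    cds_end: int
    obs: int
    exp: float
    oe: float
    chi_sq: float
    created_by: str


def _loglik(obs, lam):
    """Poisson log-likelihood with factorial dropped: obs*ln(lam) - lam.

    Defined as -lam when obs == 0 (the 0*ln(0) limit), so a zero-rate,
    zero-count section contributes 0.
    """
    obs = np.asarray(obs, dtype=float)
    lam = np.asarray(lam, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(obs > 0, obs * np.log(np.maximum(lam, 1e-300)), 0.0)
    return term - lam


def _chi_sq_sections(obs_arr, exp_arr) -> float:
    """chi2 for an array of sections against their pooled single-OE null."""
    obs_arr = np.asarray(obs_arr, dtype=float)
    exp_arr = np.asarray(exp_arr, dtype=float)
    if (obs_arr < 0).any() or (exp_arr < 0).any():
        raise InputError("obs and exp must be non-negative")
    exp_f = np.maximum(exp_arr, EXP_FLOOR)
    oe_total = capped_oe(obs_arr.sum(), exp_arr.sum())
    oe_sec = capped_oe(obs_arr, exp_arr)
    ll0 = _loglik(obs_arr, exp_f * oe_total).sum()
    ll1 = _loglik(obs_arr, exp_f * oe_sec).sum()
    chi = 2.0 * (ll1 - ll0)
    return max(float(chi), 0.0)  # clip float negatives of order -1e-13


def chi_sq_two_section(obs_a, exp_a, obs_b, exp_b) -> SplitStat:
    """Likelihood-ratio statistic for one breakpoint splitting A | B."""
    stat = _chi_sq_sections([obs_a, obs_b], [exp_a, exp_b])
    return SplitStat(
        positions=(),
        chi_sq=stat,
        section_stats=(oe(obs_a, exp_a), oe(obs_b, exp_b)),
        df=1,
    )


def chi_sq_three_section(obs_a, exp_a, obs_b, exp_b, obs_c, exp_c) -> SplitStat:
    """Likelihood-ratio statistic for two simultaneous breakpoints A | B | C."""
    stat = _chi_sq_sections([obs_a, obs_b, obs_c], [exp_a, exp_b, exp_c])
    return SplitStat(
        positions=(),
        chi_sq=stat,
        section_stats=(oe(obs_a, exp_a), oe(obs_b, exp_b), oe(obs_c, exp_c)),
        df=2,
    )


def _range_cumulative(tm: TranscriptModel, i0: int, i1: int):
    """Cumulative obs/exp of positions[i0:i1] relative to the range start."""
    base_obs = tm.cum_obs[i0 - 1] if i0 else 0
    base_exp = tm.cum_exp[i0 - 1] if i0 else 0.0
    return tm.cum_obs[i0:i1] - base_obs, tm.cum_exp[i0:i1] - base_exp


def _chi_sq_vector(obs_list, exp_list) -> np.ndarray:
    """Vectorized chi2 over parallel section arrays (sections stacked first)."""
    obs_m = np.stack([np.asarray(o, dtype=float) for o in obs_list])
    exp_m = np.stack([np.asarray(e, dtype=float) for e in exp_list])
    exp_f = np.maximum(exp_m, EXP_FLOOR)
    tot_obs = obs_m.sum(axis=0)
    tot_exp = exp_m.sum(axis=0)
    oe_total = np.minimum(1.0, tot_obs / np.maximum(tot_exp, EXP_FLOOR))
    oe_sec = np.minimum(1.0, obs_m / exp_f)
    ll0 = _loglik(obs_m, exp_f * oe_total).sum(axis=0)
    ll1 = _loglik(obs_m, exp_f * oe_sec).sum(axis=0)
    return np.maximum(2.0 * (ll1 - ll0), 0.0)


def best_single_split(
    tm: TranscriptModel, cfg: SearchConfig, i0: int = 0, i1: int | None = None
) -> SplitStat | None:
    """Maximum-chi2 single breakpoint over eligible boundaries of a range.

    Evaluates every coding-position boundary whose two resulting sections both
    reach ``cfg.min_expected`` expected missense variants; returns the best
    split regardless of significance, or None when no boundary is eligible.
    Ties at the maximum go to the leftmost position.
    """
    if i1 is None:
        i1 = tm.n_positions()
    m = i1 - i0
    if m < 2:
        return None
    robs, rexp = _range_cumulative(tm, i0, i1)
    tot_obs, tot_exp = int(robs[-1]), float(rexp[-1])
    # boundary after local index k: left = [0..k], right = (k..m-1]
    exp_l = rexp[:-1]
    exp_r = tot_exp - exp_l
    eligible = (exp_l >= cfg.min_expected) & (exp_r >= cfg.min_expected)
    if not eligible.any():
        return None
    obs_l = robs[:-1][eligible]
    obs_r = tot_obs - obs_l
    chis = _chi_sq_vector([obs_l, obs_r], [exp_l[eligible], tot_exp - exp_l[eligible]])
    best = int(np.argmax(chis))
    k_local = int(np.flatnonzero(eligible)[best])
    k_abs = i0 + k_local
    o_l, e_l = int(robs[k_local]), float(rexp[k_local])
    return SplitStat(
        positions=(int(tm.positions[k_abs]),),
        chi_sq=float(chis[best]),
        section_stats=(oe(o_l, e_l), oe(tot_obs - o_l, tot_exp - e_l)),
        df=cfg.df_single,
        pos_index=(k_abs,),
    )


def best_double_split(
    tm: TranscriptModel, cfg: SearchConfig, i0: int = 0, i1: int | None = None
) -> SplitStat | None:
    """Maximum-chi2 ordered pair of breakpoints over a range.

    Exhaustively enumerates all boundary pairs whose three sections each reach
    ``cfg.min_expected`` expected variants (no pruning heuristics; section
    sums come from cumulative arrays). Ties go to the leftmost pair.
    """
    if i1 is None:
        i1 = tm.n_positions()
    m = i1 - i0
    if m < 3:
        return None
    robs, rexp = _range_cumulative(tm, i0, i1)
    tot_obs, tot_exp = int(robs[-1]), float(rexp[-1])
    if tot_exp < 3 * cfg.min_expected:
        return None
    best_chi = -np.inf
    best_pair: tuple[int, int] | None = None
    # first break after local index k1, second after k2 > k1
    for k1 in range(m - 2):
        exp_a = float(rexp[k1])
        if exp_a < cfg.min_expected:
            continue
        if tot_exp - exp_a < 2 * cfg.min_expected:
            break  # expectation is cumulative: later k1 only shrink the remainder
        obs_a = float(robs[k1])
        k2 = np.arange(k1 + 1, m - 1)
        exp_b = rexp[k2] - exp_a
        exp_c = tot_exp - rexp[k2]
        ok = (exp_b >= cfg.min_expected) & (exp_c >= cfg.min_expected)
        if not ok.any():
            continue
        k2 = k2[ok]
        exp_b = exp_b[ok]
        exp_c = exp_c[ok]
        obs_b = robs[k2] - obs_a
        obs_c = tot_obs - robs[k2]
        chis = _chi_sq_vector(
            [np.full(len(k2), obs_a), obs_b, obs_c],
            [np.full(len(k2), exp_a), exp_b, exp_c],
        )
        j = int(np.argmax(chis))
        if chis[j] > best_chi:
            best_chi = float(chis[j])
            best_pair = (k1, int(k2[j]))
    if best_pair is None:
        return None
    k1, k2 = best_pair
    o_a, e_a = int(robs[k1]), float(rexp[k1])
    o_ab, e_ab = int(robs[k2]), float(rexp[k2])
    return SplitStat(
        positions=(int(tm.positions[i0 + k1]), int(tm.positions[i0 + k2])),
        chi_sq=best_chi,
        section_stats=(
            oe(o_a, e_a),
            oe(o_ab - o_a, e_ab - e_a),
            oe(tot_obs - o_ab, tot_exp - e_ab),
        ),
        df=cfg.df_double,
        pos_index=(i0 + k1, i0 + k2),
    )


def scan_single_break(
    tm: TranscriptModel, cfg: SearchConfig | None = None, i0: int = 0, i1: int | None = None
) -> SplitStat | None:
    """Best single breakpoint if significant at ``cfg.alpha``, else None."""
    cfg = cfg or SearchConfig()
    stat = best_single_split(tm, cfg, i0, i1)
    if stat is not None and stat.chi_sq > cfg.critical_single:
        return stat
    return None


def scan_two_breaks(
    tm: TranscriptModel, cfg: SearchConfig | None = None, i0: int = 0, i1: int | None = None
) -> SplitStat | None:
    """Best simultaneous breakpoint pair if significant at ``cfg.alpha``, else None.

    Intended to run only on (sub)sections where :func:`scan_single_break`
    found nothing, mirroring the search flow.
    """
    cfg = cfg or SearchConfig()
    stat = best_double_split(tm, cfg, i0, i1)
    if stat is not None and stat.chi_sq > cfg.critical_double:
        return stat
    return None


def recursive_search(tm: TranscriptModel, cfg: SearchConfig | None = None) -> list[MissenseRegion]:
    """Segment a transcript into missense constraint regions.

    Each (sub)section is scanned for a single significant breakpoint; if none
    is found, for two simultaneous breakpoints; any resulting subsection is
    then treated as an independent transcript and re-scanned, until no
    significant break remains. Returns regions ordered by coding position;
    a single region covering the whole CDS means no significant structure.
    """
    cfg = cfg or SearchConfig()
    if tm.n_positions() == 0:
        return []
    regions: list[MissenseRegion] = []

    def emit(i0: int, i1: int, chi_sq: float, created_by: str) -> None:
        obs, exp = tm.section_obs_exp(i0, i1)
        regions.append(
            MissenseRegion(
                transcript_id=tm.transcript_id,
                cds_start=int(tm.positions[i0]),
                cds_end=int(tm.positions[i1 - 1]),
                obs=obs,
                exp=exp,
                oe=capped_oe(obs, exp),
                chi_sq=chi_sq,
                created_by=created_by,
            )
        )

    def search(i0: int, i1: int, chi_sq: float, created_by: str) -> None:
        stat = scan_single_break(tm, cfg, i0, i1)
        if stat is None:
            stat = scan_two_breaks(tm, cfg, i0, i1)
        if stat is None:
            emit(i0, i1, chi_sq, created_by)
            return
        kind = "single-break" if stat.df == cfg.df_single else "double-break"
        bounds = [i0] + [k + 1 for k in stat.pos_index] + [i1]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            search(lo, hi, stat.chi_sq, kind)

    search(0, tm.n_positions(), float("nan"), "whole-transcript")
    return regions
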