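"""Observed-variant filtering, transcript models and capped OE ratios.

The observed/expected (OE) ratio is the count of rare, high-quality missense
variants seen in the reference cohort divided by the neutral expectation from
the mutational model. Because the method looks for missense *depletion*, OE
is capped at 1, and a zero expectation is floored at 1e-9 so the ratio stays
finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from rmc.errors import InputError, SchemaError

#: Expectation floor preventing division by zero in OE ratios.
EXP_FLOOR = 1e-9

#: Rare-variant allele-frequency cutoff for the observed set.
DEFAULT_AF_CUTOFF = 0.001

OBSERVED_CRITERIA_COLUMNS = ("allele_count", "allele_freq", "qc_pass", "coverage")


@dataclass(frozen=True)
class OeRatio:
    """A capped observed/expected depletion ratio."""

    obs: int
    exp: float
    oe: float


def capped_oe(obs, exp):
    """Elementwise OE with the 1e-9 expectation floor and a cap at 1.

    Works on scalars and arrays; negative inputs are rejected.
    """
    obs_a = np.asarray(obs, dtype=float)
    exp_a = np.asarray(exp, dtype=float)
    if (obs_a < 0).any() or (exp_a < 0).any():
        raise InputError("obs and exp must be non-negative")
    ratio = np.minimum(1.0, obs_a / np.maximum(exp_a, EXP_FLOOR))
    return float(ratio) if ratio.ndim == 0 else ratio


def oe(obs: int, exp: float) -> OeRatio:
    """Capped OE ratio for one interval."""
    return OeRatio(obs=int(obs), exp=float(exp), oe=capped_oe(obs, exp))


def filter_observed(sites: pd.DataFrame, af_cutoff: float = DEFAULT_AF_CUTOFF) -> pd.DataFrame:
    """Finalize the ``observed`` flag of a possible-site table.

    A possible variant counts as observed iff all four criteria hold:
    allele count > 0, allele frequency < ``af_cutoff``, variant QC pass, and
    median coverage > 0. All rows are retained — the possible-site universe
    (the denominator of OE) is unchanged; only the flag is set.
    """
    missing = [c for c in OBSERVED_CRITERIA_COLUMNS if c not in sites.columns]
    if missing:
        raise SchemaError(f"site table missing required columns: {missing}")
    out = sites.copy()
    out["observed"] = (
        (out["allele_count"] > 0)
        & (out["allele_freq"] < af_cutoff)
        & out["qc_pass"].astype(bool)
        & (out["coverage"] > 0)
    )
    return out


class TranscriptModel:
    """Ordered eligible sites of one transcript with cumulative obs/exp arrays.

    Sites are ordered by coding position then alternate allele; a *position*
    for breakpoint purposes is a coding-position boundary, so observed counts
    and expectations of all alternate alleles at one cds_pos are pooled into a
    single entry of the position-level arrays.

    Attributes
    ----------
    positions : ndarray of int
        Distinct 1-based coding positions carrying a possible missense site.
    pos_obs, pos_exp : ndarray
        Observed count and expectation mass pooled per position.
    cum_obs, cum_exp : ndarray
        Inclusive cumulative sums of the two arrays above.
    """

    REQUIRED = ("transcript_id", "cds_pos", "alt", "observed", "mu_adj")

    def __init__(self, sites: pd.DataFrame, s_het: float | None = None):
        missing = [c for c in self.REQUIRED if c not in sites.columns]
        if missing:
            raise SchemaError(f"site table missing required columns: {missing}")
        tids = sites["transcript_id"].unique()
        if len(tids) != 1:
            raise InputError(f"expected a single transcript, got {len(tids)}")
        self.transcript_id: str = str(tids[0])
        self.sites = sites.sort_values(["cds_pos", "alt"], kind="mergesort").reset_index(
            drop=True
        )
        if (self.sites["cds_pos"] < 1).any():
            raise InputError("cds_pos must be >= 1")
        grouped = self.sites.groupby("cds_pos", sort=True).agg(
            obs=("observed", "sum"), exp=("mu_adj", "sum")
        )
        self.positions = grouped.index.to_numpy(dtype=np.int64)
        self.pos_obs = grouped["obs"].to_numpy(dtype=np.int64)
        self.pos_exp = grouped["exp"].to_numpy(dtype=float)
        self.cum_obs = np.cumsum(self.pos_obs)
        self.cum_exp = np.cumsum(self.pos_exp)
        self.total_obs = int(self.cum_obs[-1]) if len(self.cum_obs) else 0
        self.total_exp = float(self.cum_exp[-1]) if len(self.cum_exp) else 0.0
        self.n_possible = len(self.sites)
        self.s_het = s_het

    @property
    def oe(self) -> OeRatio:
        return oe(self.total_obs, self.total_exp)

    def n_positions(self) -> int:
        return len(self.positions)

    def section_obs_exp(self, i0: int, i1: int) -> tuple[int, float]:
        """Observed count and expectation of position-index slice [i0, i1)."""
        if not (0 <= i0 <= i1 <= len(self.positions)):
            raise InputError(f"invalid slice [{i0}, {i1})")
        if i0 == i1:
            return 0, 0.0
        obs = self.cum_obs[i1 - 1] - (self.cum_obs[i0 - 1] if i0 else 0)
        exp = self.cum_exp[i1 - 1] - (self.cum_exp[i0 - 1] if i0 else 0)
        return int(obs), float(exp)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"TranscriptModel({self.transcript_id!r}, n_possible={self.n_possible}, "
            f"obs={self.total_obs}, exp={self.total_exp:.2f})"
        )


def transcript_summary(transcripts: list[TranscriptModel]) -> pd.DataFrame:
    """Per-transcript summary table (`transcript_id total_obs total_exp oe n_possible`)."""
    rows = [
        {
            "transcript_id": tm.transcript_id,
            "total_obs": tm.total_obs,
            "total_exp": tm.total_exp,
            "oe": tm.oe.oe,
            "n_possible": tm.n_possible,
        }
        for tm in transcripts
    ]
    return pd.DataFrame(rows, columns=["transcript_id", "total_obs", "total_exp", "oe", "n_possible"])


def filter_outlier_transcripts(
    summary: pd.DataFrame,
    z_bound: float = 4.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude transcripts whose neutral-expectation counts are outliers.

    ``summary`` carries per-transcript observed and expected counts for the
    three variant classes as columns ``obs_<cls>`` / ``exp_<cls>`` for
    ``cls`` in {plof, mis, syn}. A transcript is excluded when any class has
    zero expectation, or when the Poisson z-score (obs − exp)/sqrt(exp) of
    any class exceeds ``z_bound`` in absolute value (too many observed in any
    class, or too few observed synonymous).

    Returns (retained summary, exclusion report with a ``reason`` per row).
    """
    classes = ("plof", "mis", "syn")
    for cls in classes:
        for col in (f"obs_{cls}", f"exp_{cls}"):
            if col not in summary.columns:
                raise SchemaError(f"summary missing required column: {col}")
    reasons = []
    for row in summary.itertuples():
        reason = None
        for cls in classes:
            if getattr(row, f"exp_{cls}") <= 0:
                reason = f"zero expected {cls}"
                break
        if reason is None:
            for cls in classes:
                obs_c = getattr(row, f"obs_{cls}")
                exp_c = getattr(row, f"exp_{cls}")
                z = (obs_c - exp_c) / np.sqrt(exp_c)
                if z > z_bound:
                    reason = f"too many observed {cls} (z={z:.2f})"
                    break
                if cls == "syn" and z < -z_bound:
                    reason = f"too few observed syn (z={z:.2f})"
                    break
        reasons.append(reason)
    excluded_mask = pd.Series([r is not None for r in reasons], index=summary.index)
    report = summary[excluded_mask].copy()
    report["reason"] = [r for r in reasons if r is not None]
    return summary[~excluded_mask].copy(), report
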