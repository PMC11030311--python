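"""Neutral mutational expectation model.

Per-site expected rare-missense contributions (``mu_adj``) are derived from a
trinucleotide-context mutation-rate table in three steps:

1. a *plateau* calibration — a linear fit of the proportion of possible
   synonymous variants actually observed in the reference cohort against the
   raw per-context mutation rate, which rescales per-generation rates to the
   cohort's effective size (fitted separately per chromosome class and CpG
   status);
2. a *coverage* correction for sites whose median sequencing depth falls
   below a threshold (default 40x), either a single scaling factor or an
   optional linear model on log10 depth;
3. summation of the adjusted per-site values over arbitrary site sets to give
   expected counts.

The module is data-agnostic: any rate table and any proportion-observed table
with the documented schemas can be used for calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from rmc.errors import ContextLookupError, DegenerateFitError, InputError

RATE_COLUMNS = ("context", "alt", "methyl_level", "mu")

#: Default median-depth threshold below which the coverage correction applies.
DEFAULT_COVERAGE_THRESHOLD = 40


class RateTable:
    """Lookup of per-generation mutation rates keyed by (context, alt, methyl_level).

    Parameters
    ----------
    table
        DataFrame with columns ``context`` (3-mer over ACGT), ``alt``
        (alternate base, different from the middle reference base),
        ``methyl_level`` (ordinal methylation bin, 0..2 by convention) and
        ``mu`` (per-generation mutation probability, > 0).
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in RATE_COLUMNS if c not in table.columns]
        if missing:
            raise InputError(f"rate table missing columns: {missing}")
        if (table["mu"] <= 0).any():
            raise InputError("rate table contains non-positive mu")
        bad_ctx = ~table["context"].str.fullmatch(r"[ACGT]{3}")
        if bad_ctx.any():
            raise InputError(
                f"invalid contexts: {sorted(table.loc[bad_ctx, 'context'].unique())}"
            )
        if (table["alt"] == table["context"].str[1]).any():
            raise InputError("alt allele equals the middle reference base")
        self._table = table.reset_index(drop=True)
        self._index = {
            (r.context, r.alt, int(r.methyl_level)): float(r.mu)
            for r in table.itertuples()
        }

    def mu(self, context: str, alt: str, methyl_level: int = 0) -> float:
        key = (context, alt, int(methyl_level))
        try:
            return self._index[key]
        except KeyError:
            raise ContextLookupError(
                f"no rate for context={context!r} alt={alt!r} methyl_level={methyl_level}"
            ) from None

    def lookup(self, sites: pd.DataFrame) -> np.ndarray:
        """Vectorized mu lookup for a site table with context/alt/methyl_level columns."""
        keys = list(
            zip(sites["context"], sites["alt"], sites["methyl_level"].astype(int))
        )
        out = np.empty(len(keys))
        for i, key in enumerate(keys):
            if key not in self._index:
                raise ContextLookupError(
                    f"no rate for context={key[0]!r} alt={key[1]!r} methyl_level={key[2]}"
                )
            out[i] = self._index[key]
        return out

    def to_frame(self) -> pd.DataFrame:
        return self._table.copy()

    def __len__(self) -> int:
        return len(self._table)


@dataclass(frozen=True)
class PlateauModel:
    """Linear calibration of proportion-observed against raw mutation rate.

    One (slope, intercept) pair per (model_class, cpg_status) stratum;
    ``model_class`` is one of ``autosomal`` (covering pseudoautosomal),
    ``chrX`` or ``chrY``. Predictions are proportions and are clamped to
    [0, 1] when ``clamp`` is set (the default).
    """

    model_class: str = "autosomal"
    cpg_status: str = "non-CpG"
    slope: float = 1.0
    intercept: float = 0.0
    clamp: bool = True

    def predict(self, mu):
        pred = self.slope * np.asarray(mu, dtype=float) + self.intercept
        if self.clamp:
            pred = np.clip(pred, 0.0, 1.0)
        return pred if pred.ndim else float(pred)


@dataclass(frozen=True)
class CoverageModel:
    """Correction for under-calling at low median depth.

    ``scaling_factor`` is the ratio of observed synonymous variants to the
    plateau-predicted expectation mass, applied to every site below
    ``low_coverage_threshold``. When ``coefficients`` = (intercept, slope) is
    set, the correction is instead ``intercept + slope * log10(depth)``,
    clamped to (0, 1]. Sites at or above the threshold are never corrected.
    """

    scaling_factor: float = 1.0
    low_coverage_threshold: int = DEFAULT_COVERAGE_THRESHOLD
    coefficients: tuple[float, float] | None = None

    def __post_init__(self):
        if not (0.0 < self.scaling_factor <= 1.0):
            raise InputError(
                f"scaling_factor must be in (0, 1], got {self.scaling_factor}"
            )
        if self.low_coverage_threshold <= 0:
            raise InputError("low_coverage_threshold must be positive")

    def correction(self, coverage):
        """Multiplicative correction factor per site (1.0 at/above threshold)."""
        cov = np.asarray(coverage, dtype=float)
        scalar = cov.ndim == 0
        cov = np.atleast_1d(cov)
        if (cov <= 0).any():
            raise InputError("coverage must be positive; zero-coverage sites are excluded upstream")
        out = np.ones_like(cov)
        low = cov < self.low_coverage_threshold
        if self.coefficients is None:
            out[low] = self.scaling_factor
        else:
            a, b = self.coefficients
            out[low] = np.clip(a + b * np.log10(cov[low]), 1e-12, 1.0)
        return float(out[0]) if scalar else out


def fit_plateau(
    proportion_observed: pd.DataFrame,
    rates: RateTable,
    model_class: str = "autosomal",
    cpg_status: str = "non-CpG",
    clamp: bool = True,
) -> PlateauModel:
    """Least-squares fit of proportion observed on the raw mutation rate.

    Parameters
    ----------
    proportion_observed
        Table with columns ``context``, ``alt``, ``methyl_level`` and
        ``proportion_observed`` — the fraction of possible synonymous variants
        of that context actually seen in the reference cohort.
    rates
        The rate table supplying the regressor ``mu`` for each row.

    Returns
    -------
    PlateauModel for the requested stratum.
    """
    required = {"context", "alt", "methyl_level", "proportion_observed"}
    missing = required - set(proportion_observed.columns)
    if missing:
        raise InputError(f"proportion-observed table missing columns: {sorted(missing)}")
    mu = rates.lookup(proportion_observed)
    prop = proportion_observed["proportion_observed"].to_numpy(dtype=float)
    if len(np.unique(np.round(np.c_[mu, prop], 15), axis=0)) < 2:
        raise DegenerateFitError("plateau fit needs >= 2 distinct (mu, proportion) pairs")
    if np.ptp(mu) == 0:
        # all contexts share one rate: slope is unidentifiable, fit the mean level
        slope, intercept = 0.0, float(np.mean(prop))
    else:
        slope, intercept = np.polyfit(mu, prop, deg=1)
    return PlateauModel(
        model_class=model_class,
        cpg_status=cpg_status,
        slope=float(slope),
        intercept=float(intercept),
        clamp=clamp,
    )


def fit_coverage_scaling(
    observed_synonymous: float,
    possible_synonymous_mu_sum: float,
    low_coverage_threshold: int = DEFAULT_COVERAGE_THRESHOLD,
) -> CoverageModel:
    """Single scaling factor: observed synonymous count over expectation mass."""
    if possible_synonymous_mu_sum <= 0:
        raise InputError("possible_synonymous_mu_sum must be > 0")
    if observed_synonymous < 0:
        raise InputError("observed_synonymous must be >= 0")
    factor = observed_synonymous / possible_synonymous_mu_sum
    return CoverageModel(
        scaling_factor=min(factor, 1.0) if factor > 0 else 1e-12,
        low_coverage_threshold=low_coverage_threshold,
    )


def fit_coverage_depth_model(
    depth_table: pd.DataFrame,
    low_coverage_threshold: int = DEFAULT_COVERAGE_THRESHOLD,
    scaling_factor: float | None = None,
) -> CoverageModel:
    """Linear correction on log10 depth fitted over low-coverage strata.

    ``depth_table`` has columns ``coverage`` (median depth of the stratum),
    ``observed`` (synonymous variants seen there) and ``mu_sum`` (plateau
    expectation mass there). The response is observed/mu_sum per stratum; only
    strata below the threshold enter the fit.
    """
    required = {"coverage", "observed", "mu_sum"}
    missing = required - set(depth_table.columns)
    if missing:
        raise InputError(f"depth table missing columns: {sorted(missing)}")
    low = depth_table[depth_table["coverage"] < low_coverage_threshold]
    if len(low) < 2:
        raise DegenerateFitError("coverage model fit needs >= 2 low-coverage strata")
    x = np.log10(low["coverage"].to_numpy(dtype=float))
    y = low["observed"].to_numpy(dtype=float) / low["mu_sum"].to_numpy(dtype=float)
    slope, intercept = np.polyfit(x, y, deg=1)
    return CoverageModel(
        scaling_factor=scaling_factor if scaling_factor is not None else 1.0,
        low_coverage_threshold=low_coverage_threshold,
        coefficients=(float(intercept), float(slope)),
    )


def compute_mu_adj(
    sites: pd.DataFrame,
    rates: RateTable,
    plateau: PlateauModel,
    coverage: CoverageModel,
) -> np.ndarray:
    """Adjusted per-site expectation contributions for a site table.

    ``mu_adj = plateau(mu)`` at full coverage, times the coverage correction
    below the threshold. Sites must have positive median coverage (zero
    coverage sites are excluded before this step).
    """
    mu = rates.lookup(sites)
    cal = np.asarray(plateau.predict(mu), dtype=float)
    corr = coverage.correction(sites["coverage"].to_numpy(dtype=float))
    return cal * corr


def mu_adj_single(
    mu: float, site_coverage: float, plateau: PlateauModel, coverage: CoverageModel
) -> float:
    """Scalar form of :func:`compute_mu_adj` for a known raw rate."""
    if site_coverage <= 0:
        raise InputError("coverage must be positive")
    return float(plateau.predict(mu)) * float(coverage.correction(site_coverage))


def expected_count(sites: pd.DataFrame | np.ndarray) -> float:
    """Sum of mu_adj over a site set (0.0 for an empty set); additive over partitions."""
    if isinstance(sites, pd.DataFrame):
        if len(sites) == 0:
            return 0.0
        if "mu_adj" not in sites.columns:
            raise InputError("sites must carry a mu_adj column")
        vals = sites["mu_adj"].to_numpy(dtype=float)
    else:
        vals = np.asarray(sites, dtype=float)
    if np.isnan(vals).any():
        raise InputError("mu_adj contains NaN")
    return float(math.fsum(vals))
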