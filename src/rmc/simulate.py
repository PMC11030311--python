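"""Synthetic inputs with planted ground truth.

Generates every table the toolkit consumes — possible-missense site tables
with region-specific depletion, labeled variant feature tables for training
the deleteriousness model, and case/control cohorts with per-bin rate
multipliers — so the full pipeline is testable without external data.

Observation is simulated per site: each possible missense site is observed
independently with probability ``true_OE x mu_adj`` (clamped to 1 with a
warning if exceeded), so section totals are Poisson-binomial, which at the
small per-site rates of real exomes is indistinguishable from the Poisson
model the search assumes, while keeping site-level granularity for the scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from rmc.constraint import TranscriptModel, filter_observed
from rmc.errors import InputError

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimProfile:
    """Layout of one simulated transcript.

    ``boundaries`` lists the last coding position of each region except the
    final one (closed-left convention, matching the search output); region
    ``i`` spans (boundaries[i-1], boundaries[i]]. ``n_sites`` counts coding
    positions; each position carries ``n_alts`` possible missense
    substitutions (real coding positions average ~2.2), one site row each.
    ``mu_adj`` is the per-substitution expectation, scalar or an array of
    length ``n_sites`` (shared by the alts at a position).
    """

    n_sites: int = 300
    n_alts: int = 2
    mu_adj: float | np.ndarray = 0.4
    boundaries: tuple[int, ...] = ()
    region_oe: tuple[float, ...] = (1.0,)
    coverage: float = 50.0
    transcript_id: str = "SIM_TX"
    contig: str = "chrS"
    genomic_offset: int = 1_000_000

    def __post_init__(self):
        if self.n_sites < 1:
            raise InputError("n_sites must be >= 1")
        if not (1 <= self.n_alts <= 3):
            raise InputError("n_alts must be 1..3 (a base has three alternates)")
        if len(self.region_oe) != len(self.boundaries) + 1:
            raise InputError("need exactly one more region OE than boundaries")
        if any(not (0.0 <= o <= 1.0) for o in self.region_oe):
            raise InputError("true region OEs must lie in [0, 1]")
        b = list(self.boundaries)
        if b != sorted(b) or (b and (b[0] < 1 or b[-1] >= self.n_sites)):
            raise InputError("boundaries must be increasing and within 1..n_sites-1")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def site_oe_profile(profile: SimProfile) -> np.ndarray:
    """Per-position true OE implied by the profile's regions."""
    oes = np.empty(profile.n_sites)
    edges = (0,) + profile.boundaries + (profile.n_sites,)
    for (lo, hi), o in zip(zip(edges[:-1], edges[1:]), profile.region_oe):
        oes[lo:hi] = o
    return oes


def simulate_transcript(profile: SimProfile, seed=0) -> tuple[pd.DataFrame, dict]:
    """Simulate a possible-missense site table under a planted OE profile.

    Returns (site table, truth record). The truth record carries the planted
    region boundaries and OEs. Each coding position emits ``n_alts``
    substitution rows; the genomic coordinate is a single-exon offset of
    cds_pos.
    """
    rng = _rng(seed)
    n = profile.n_sites
    mu_pos = np.broadcast_to(np.asarray(profile.mu_adj, dtype=float), (n,))
    if (mu_pos < 0).any():
        raise InputError("mu_adj must be non-negative")
    cds = np.repeat(np.arange(1, n + 1), profile.n_alts)
    mu = np.repeat(mu_pos, profile.n_alts)
    oes = np.repeat(site_oe_profile(profile), profile.n_alts)
    prob = oes * mu
    if (prob > 1).any():
        warnings.warn("per-site observation probability > 1; clamping", stacklevel=2)
        prob = np.minimum(prob, 1.0)
    m = len(cds)
    observed = rng.random(m) < prob
    refs = np.repeat(_BASES[rng.integers(0, 4, n)], profile.n_alts)
    alt_shift = np.tile(np.arange(1, profile.n_alts + 1), n)
    alts = _BASES[(np.searchsorted(_BASES, refs) + alt_shift) % 4]
    left = np.repeat(_BASES[rng.integers(0, 4, n)], profile.n_alts)
    right = np.repeat(_BASES[rng.integers(0, 4, n)], profile.n_alts)
    sites = pd.DataFrame(
        {
            "transcript_id": profile.transcript_id,
            "cds_pos": cds,
            "contig": profile.contig,
            "genomic_pos": profile.genomic_offset + cds,
            "ref": refs,
            "alt": alts,
            "context": pd.Series(left).str.cat([refs, right]),
            "methyl_level": 0,
            "coverage": profile.coverage,
            "allele_count": np.where(observed, 1, 0),
            "allele_freq": np.where(observed, 1e-5, 0.0),
            "qc_pass": True,
            "aa_sub": "Ala>Val",
            "mu_adj": mu,
        }
    )
    sites = filter_observed(sites)
    truth = {
        "transcript_id": profile.transcript_id,
        "boundaries": tuple(int(b) for b in profile.boundaries),
        "region_oe": tuple(float(o) for o in profile.region_oe),
        "n_sites": n,
    }
    return sites, truth


def simulate_transcript_model(profile: SimProfile, seed=0) -> tuple[TranscriptModel, dict]:
    """Convenience wrapper returning a ready :class:`TranscriptModel`."""
    sites, truth = simulate_transcript(profile, seed)
    return TranscriptModel(sites), truth


MPC_FEATURES = (
    "sub_overall_oe",
    "sub_oe_second_derivative",
    "blosum",
    "grantham",
    "local_oe",
    "polyphen2",
)

#: Class-conditional mean shifts (pathogenic minus benign, in SD units) used
#: by default: constraint-derived and impact features separate moderately.
DEFAULT_EFFECTS = {
    "sub_overall_oe": -0.8,
    "sub_oe_second_derivative": 0.4,
    "blosum": -0.6,
    "grantham": 0.8,
    "local_oe": -1.0,
    "polyphen2": 1.0,
}


def simulate_labeled_variants(
    n_path: int = 500,
    n_benign: int = 2000,
    effects: dict[str, float] | None = None,
    seed=0,
) -> pd.DataFrame:
    """Labeled feature table: class-conditional Gaussians with stated shifts.

    Benign features are standard normal; pathogenic features are shifted by
    ``effects`` (per-feature mean shift in SD units). ``label`` is 1 for
    pathogenic. Row count is n_path + n_benign.
    """
    rng = _rng(seed)
    effects = DEFAULT_EFFECTS if effects is None else effects
    if any(not np.isfinite(v) for v in effects.values()):
        raise InputError("effect sizes must be finite")
    frames = []
    for label, n in ((1, n_path), (0, n_benign)):
        df = pd.DataFrame(
            {f: rng.normal(effects.get(f, 0.0) * label, 1.0, n) for f in MPC_FEATURES}
        )
        df.insert(0, "label", label)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "variant_id", [f"v{i}" for i in range(len(out))])
    return out


@dataclass
class Cohort:
    """A cohort of individuals with their aggregated qualifying variants."""

    cohort_id: str
    n_individuals: int
    variants: pd.DataFrame  # one row per variant; carries score/bin annotations

    def __post_init__(self):
        if self.n_individuals <= 0:
            raise InputError("n_individuals must be > 0")


#: Default per-individual variant rates per local-OE bin for controls. The
#: bins are deciles of local OE; rates sum to ~0.7 de novo missense variants
#: per individual, weighted toward unconstrained sequence.
DEFAULT_BIN_RATES = (0.02, 0.03, 0.04, 0.05, 0.06, 0.08, 0.09, 0.10, 0.11, 0.12)


def simulate_cohorts(
    n_case: int = 5000,
    n_control: int = 5000,
    base_rates: tuple[float, ...] = DEFAULT_BIN_RATES,
    case_multipliers: tuple[float, ...] | None = None,
    bin_edges: tuple[float, ...] | None = None,
    seed=0,
) -> tuple[Cohort, Cohort]:
    """Case/control cohorts with per-bin Poisson variant counts.

    Control counts per local-OE bin are Poisson(n_control x base_rate); case
    counts multiply the base rate by ``case_multipliers`` (default all 1).
    Each simulated variant gets a local OE drawn uniformly within its bin and
    a continuous ``score`` decreasing in OE plus noise, so ranking-based
    statistics have a non-degenerate input.
    """
    rng = _rng(seed)
    k = len(base_rates)
    if case_multipliers is None:
        case_multipliers = (1.0,) * k
    if len(case_multipliers) != k:
        raise InputError("case_multipliers length must match base_rates")
    if any(m < 0 for m in case_multipliers):
        raise InputError("multipliers must be >= 0")
    if bin_edges is None:
        bin_edges = tuple(np.linspace(0.0, 1.0, k + 1))

    def draw(cohort_id, n_ind, mult):
        rows = []
        for b in range(k):
            lam = n_ind * base_rates[b] * mult[b]
            count = rng.poisson(lam)
            lo, hi = bin_edges[b], bin_edges[b + 1]
            oes = rng.uniform(lo, min(hi, 1.0), count)
            rows.append(
                pd.DataFrame(
                    {
                        "local_oe": oes,
                        "oe_bin": b,
                        "score": 3.0 * (1.0 - oes) + rng.normal(0, 0.5, count),
                    }
                )
            )
        variants = pd.concat(rows, ignore_index=True)
        return Cohort(cohort_id=cohort_id, n_individuals=n_ind, variants=variants)

    case = draw("case", n_case, case_multipliers)
    control = draw("control", n_control, (1.0,) * k)
    return case, control
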