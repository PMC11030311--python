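"""MPC: missense deleteriousness prediction by constraint.

A logistic regression separates pathogenic from benign (common-population)
missense variants using six features: the amino-acid substitution class's
overall OE and the second derivative of its OE across regional-constraint
bins, BLOSUM and Grantham substitution severity, the variant's local
(region or transcript) missense OE, and PolyPhen-2. The model's fitted
values are then rank-transformed against the benign training set:

    d_i = -log10(m_i / M),   m_i = max(0.83, f_i)

where f_i counts benign training variants with a fitted value strictly less
than variant i's, and M is the benign set size. Larger d_i means stronger
predicted deleteriousness; the 0.83 floor keeps the score finite when a
variant outranks every benign variant. For d_i to grow with deleteriousness,
the fitted value must be oriented benign-ward (a deleterious variant ranks
*below* the benign distribution), so the stored fitted values are the
negated linear predictor of the pathogenic class.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from rmc.constraint import capped_oe
from rmc.errors import InputError, SchemaError, TrainingError

FEATURES = (
    "sub_overall_oe",
    "sub_oe_second_derivative",
    "blosum",
    "grantham",
    "local_oe",
    "polyphen2",
)

#: Floor of m_i in the rank transform.
DEFAULT_FLOOR = 0.83

#: Left edges of the 10 local-OE bins; the last bin [0.9, inf) is open-ended
#: (OE values above 1 can occur only for uncapped inputs; capped OE lands the
#: top bin at [0.9, 1.0]).
OE_BIN_EDGES = np.arange(0.0, 1.0, 0.1)


def oe_bin_index(local_oe) -> np.ndarray:
    """Left-closed right-open decile bin of a local OE; final bin open-ended."""
    vals = np.asarray(local_oe, dtype=float)
    return np.minimum((vals * 10).astype(int), 9)


def second_difference(y: np.ndarray) -> np.ndarray:
    """Central second differences over unit-spaced bins, one-sided at the ends.

    Interior: y[i-1] - 2 y[i] + y[i+1]; the first and last entries reuse the
    nearest fully-interior stencil (one-sided), so a quadratic profile yields
    a constant vector at twice its leading coefficient.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 3:
        return np.zeros_like(y)
    d2 = np.empty_like(y)
    d2[1:-1] = y[:-2] - 2 * y[1:-1] + y[2:]
    d2[0] = y[0] - 2 * y[1] + y[2]
    d2[-1] = y[-3] - 2 * y[-2] + y[-1]
    return d2


def substitution_metrics(sites: pd.DataFrame) -> pd.DataFrame:
    """Per-substitution-class constraint metrics.

    ``sites`` is the possible-variant universe annotated with ``aa_sub``,
    ``observed``, ``mu_adj`` and ``local_oe`` (the OE of the region the site
    falls in, or of the transcript when it has a single region). Returns one
    row per class with the overall capped OE, the 10-bin OE profile over
    local-OE deciles, and its second-difference vector. Bins with no
    expectation mass are NaN; classes with no sites are absent (unscored).
    """
    required = {"aa_sub", "observed", "mu_adj", "local_oe"}
    missing = required - set(sites.columns)
    if missing:
        raise SchemaError(f"site table missing required columns: {sorted(missing)}")
    out_rows = []
    bins = oe_bin_index(sites["local_oe"])
    work = sites.assign(_bin=bins)
    for aa_sub, grp in work.groupby("aa_sub", sort=True):
        overall = capped_oe(grp["observed"].sum(), grp["mu_adj"].sum())
        oe_by_bin = np.full(10, np.nan)
        agg = grp.groupby("_bin").agg(obs=("observed", "sum"), exp=("mu_adj", "sum"))
        for b, row in agg.iterrows():
            if row["exp"] > 0:
                oe_by_bin[b] = capped_oe(row["obs"], row["exp"])
        if np.isnan(oe_by_bin).all():
            d2 = np.full(10, np.nan)
        else:
            d2 = second_difference(np.nan_to_num(oe_by_bin, nan=np.nanmean(oe_by_bin)))
            d2[np.isnan(oe_by_bin)] = np.nan
        out_rows.append(
            {
                "aa_sub": aa_sub,
                "overall_oe": overall,
                "oe_by_bin": oe_by_bin,
                "second_derivative_by_bin": d2,
            }
        )
    return pd.DataFrame(out_rows)


def annotate_substitution_features(
    variants: pd.DataFrame, metrics: pd.DataFrame
) -> pd.DataFrame:
    """Attach class-level features to variants from substitution metrics.

    Adds ``sub_overall_oe`` and ``sub_oe_second_derivative`` (the class's
    second-difference value at the decile bin containing the variant's
    ``local_oe``). Variants in classes with no metrics, or whose bin has no
    expectation mass, get NaN and are therefore unscored downstream.
    """
    for col in ("aa_sub", "local_oe"):
        if col not in variants.columns:
            raise SchemaError(f"variant table missing required column: {col}")
    by_class = metrics.set_index("aa_sub")
    out = variants.copy()
    overall = np.full(len(out), np.nan)
    d2_at_bin = np.full(len(out), np.nan)
    bins = oe_bin_index(out["local_oe"].fillna(0.0))
    for i, (sub, b, oe_na) in enumerate(
        zip(out["aa_sub"], bins, out["local_oe"].isna())
    ):
        if oe_na or sub not in by_class.index:
            continue
        row = by_class.loc[sub]
        overall[i] = row["overall_oe"]
        d2_at_bin[i] = row["second_derivative_by_bin"][b]
    out["sub_overall_oe"] = overall
    out["sub_oe_second_derivative"] = d2_at_bin
    return out


def assemble_training_sets(
    clinvar: pd.DataFrame,
    phaplo: pd.DataFrame,
    dd_genes,
    population: pd.DataFrame,
    phaplo_cutoff: float = 0.86,
    af_cutoff: float = 0.001,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble pathogenic and benign training variant sets.

    Pathogenic: clinically classified P/LP variants with non-conflicting
    interpretation and at least one review star, in genes that are either
    likely haploinsufficient (pHaplo >= ``phaplo_cutoff``) or in the supplied
    dominant non-LoF developmental-disorder gene list. Benign: common
    (AF > ``af_cutoff``) QC-passing population variants. Variants qualifying
    for both sets (by ``variant_id``) are removed from both.
    """
    for col in ("variant_id", "gene", "classification", "review_stars", "conflicting"):
        if col not in clinvar.columns:
            raise SchemaError(f"clinvar table missing required column: {col}")
    for col in ("variant_id", "allele_freq", "qc_pass"):
        if col not in population.columns:
            raise SchemaError(f"population table missing required column: {col}")
    if not {"gene", "phaplo"} <= set(phaplo.columns):
        raise SchemaError("pHaplo table needs columns: gene, phaplo")

    hi_genes = set(phaplo.loc[phaplo["phaplo"] >= phaplo_cutoff, "gene"])
    allowed = hi_genes | set(dd_genes)
    path = clinvar[
        clinvar["classification"].isin(["P", "LP"])
        & ~clinvar["conflicting"].astype(bool)
        & (clinvar["review_stars"] >= 1)
        & clinvar["gene"].isin(allowed)
    ]
    benign = population[
        (population["allele_freq"] > af_cutoff) & population["qc_pass"].astype(bool)
    ]
    overlap = set(path["variant_id"]) & set(benign["variant_id"])
    path = path[~path["variant_id"].isin(overlap)].reset_index(drop=True)
    benign = benign[~benign["variant_id"].isin(overlap)].reset_index(drop=True)
    if len(path) == 0 or len(benign) == 0:
        raise TrainingError(
            f"empty training set (pathogenic={len(path)}, benign={len(benign)})"
        )
    return path, benign


def stratified_split(
    transcripts: pd.DataFrame,
    train_frac: float = 0.8,
    n_bins: int = 5,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Train/test transcript split stratified on selection and power.

    Strata are the joint quantile bins of ``s_het`` (selection against
    heterozygotes) and ``n_possible`` (number of potential missense sites,
    a proxy for detection power); transcripts missing a stratifier form their
    own stratum. Assignment is order-canonicalized (sorted by transcript_id
    before shuffling), so permuting the input rows leaves the split unchanged.
    """
    if "transcript_id" not in transcripts.columns:
        raise SchemaError("transcripts table missing required column: transcript_id")
    work = transcripts.drop_duplicates("transcript_id").sort_values("transcript_id")
    rng = np.random.default_rng(seed)

    def bin_of(col):
        if col not in work.columns:
            return pd.Series("na", index=work.index)
        vals = work[col]
        labels = pd.Series("missing", index=work.index)
        ok = vals.notna()
        if ok.sum() >= 2:
            labels[ok] = pd.qcut(
                vals[ok].rank(method="first"), min(n_bins, ok.sum()), labels=False
            ).astype(str)
        elif ok.any():
            labels[ok] = "0"
        return labels

    strata = bin_of("s_het").str.cat(bin_of("n_possible"), sep="|")
    train, test = [], []
    for _, grp in work.groupby(strata.values):
        ids = grp["transcript_id"].tolist()
        perm = rng.permutation(len(ids))
        n_train = int(round(train_frac * len(ids)))
        for rank, idx in enumerate(perm):
            (train if rank < n_train else test).append(ids[idx])
    return sorted(train), sorted(test)


@dataclass
class MpcModel:
    """Fitted logistic coefficients plus the benign fitted-value distribution."""

    coefficients: dict[str, float]
    intercept: float
    benign_fitted_values: np.ndarray  # sorted ascending
    M: int
    floor: float = DEFAULT_FLOOR
    features: tuple[str, ...] = FEATURES

    def fitted(self, variants: pd.DataFrame) -> np.ndarray:
        """Benign-ward fitted value (negated pathogenic linear predictor).

        NaN for rows missing any feature. Lower values mean more deleterious,
        so f_i — the count of benign fitted values strictly below a
        variant's — shrinks, and d_i grows, with deleteriousness.
        """
        X = variants.reindex(columns=list(self.features)).to_numpy(dtype=float)
        vals = -(
            self.intercept
            + X @ np.array([self.coefficients[f] for f in self.features])
        )
        vals[np.isnan(X).any(axis=1)] = np.nan
        return vals

    def to_json(self, path: str | Path) -> None:
        payload = {
            "features": list(self.features),
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "benign_fitted_values": self.benign_fitted_values.tolist(),
            "M": self.M,
            "floor": self.floor,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "MpcModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            coefficients=payload["coefficients"],
            intercept=payload["intercept"],
            benign_fitted_values=np.asarray(payload["benign_fitted_values"], dtype=float),
            M=int(payload["M"]),
            floor=float(payload["floor"]),
            features=tuple(payload["features"]),
        )


def fit_mpc(
    pathogenic: pd.DataFrame,
    benign: pd.DataFrame,
    features: tuple[str, ...] = FEATURES,
) -> MpcModel:
    """Fit the logistic model (pathogenic = 1) and store the benign ranks.

    Training rows must carry all features; the fit is unpenalized by default
    and falls back to an L2-regularized fit (with a warning) when the
    unpenalized solve fails to converge, e.g. under perfect separation.
    """
    for name, df in (("pathogenic", pathogenic), ("benign", benign)):
        missing = set(features) - set(df.columns)
        if missing:
            raise SchemaError(f"{name} set missing feature columns: {sorted(missing)}")
        if df.reindex(columns=list(features)).isna().any().any():
            raise TrainingError(f"{name} set has missing feature values")
    if len(pathogenic) == 0 or len(benign) == 0:
        raise TrainingError("both training sets must be non-empty")
    X = pd.concat(
        [pathogenic.loc[:, list(features)], benign.loc[:, list(features)]],
        ignore_index=True,
    ).to_numpy(dtype=float)
    y = np.r_[np.ones(len(pathogenic)), np.zeros(len(benign))]
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf = LogisticRegression(C=np.inf, max_iter=2000).fit(X, y)
        except (ConvergenceWarning, ValueError):
            warnings.warn(
                "unpenalized logistic fit did not converge (possible perfect "
                "separation); refitting with L2 regularization",
                stacklevel=2,
            )
            clf = LogisticRegression(C=1.0, max_iter=2000).fit(X, y)
    coefs = dict(zip(features, clf.coef_[0].astype(float)))
    intercept = float(clf.intercept_[0])
    model = MpcModel(
        coefficients=coefs,
        intercept=intercept,
        benign_fitted_values=np.empty(0),
        M=len(benign),
        features=tuple(features),
    )
    model.benign_fitted_values = np.sort(model.fitted(benign))
    return model


def rank_to_score(fi, M: int, floor: float = DEFAULT_FLOOR):
    """d = -log10(max(floor, f)/M) — the rank transform on benign counts."""
    fi = np.asarray(fi, dtype=float)
    if (fi < 0).any() or M <= 0:
        raise InputError("fi must be >= 0 and M > 0")
    out = -np.log10(np.maximum(floor, fi) / M)
    return float(out) if out.ndim == 0 else out


def mpc_score(model: MpcModel, variants: pd.DataFrame) -> np.ndarray:
    """MPC deleteriousness scores; NaN marks variants missing any feature.

    f_i counts benign training variants whose fitted value is *strictly* less
    than the variant's (ties do not count), so scores are reproducible pure
    ranks; the transform is invariant to any strictly monotone transform of
    the fitted values.
    """
    fitted = model.fitted(variants)
    out = np.full(len(fitted), np.nan)
    ok = ~np.isnan(fitted)
    fi = np.searchsorted(model.benign_fitted_values, fitted[ok], side="left")
    out[ok] = rank_to_score(fi, model.M, model.floor)
    return out
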