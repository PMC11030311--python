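"""TSV/BED/JSON readers and writers with schema validation.

Conventions: coding and genomic coordinates in TSVs are 1-based inclusive;
BED output is 0-based half-open. Lines starting with ``#`` are header
comments and record the run seed and coordinate convention.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from rmc.breaks import MissenseRegion
from rmc.errors import SchemaError

SITE_COLUMNS = (
    "transcript_id",
    "cds_pos",
    "contig",
    "genomic_pos",
    "ref",
    "alt",
    "context",
    "methyl_level",
    "coverage",
    "allele_count",
    "allele_freq",
    "qc_pass",
    "aa_sub",
    "mu_adj",
)

REGION_COLUMNS = (
    "transcript_id",
    "cds_start",
    "cds_end",
    "obs",
    "exp",
    "oe",
    "chi_sq",
    "n_regions_in_transcript",
)


def _read_tsv(path, required=(), label="table") -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.ParserError as exc:
        raise SchemaError(f"malformed TSV {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{label} {path} missing required columns: {missing}")
    return df


def read_sites_tsv(path) -> pd.DataFrame:
    """Possible-missense site table (1-based coordinates)."""
    required = [c for c in SITE_COLUMNS if c not in ("aa_sub", "mu_adj")]
    df = _read_tsv(path, required, "site table")
    if "observed" in df.columns:
        df["observed"] = df["observed"].astype(bool)
    df["qc_pass"] = df["qc_pass"].astype(bool)
    return df


def write_sites_tsv(sites: pd.DataFrame, path, seed=None) -> None:
    _write_with_header(sites, path, seed)


def read_rates_tsv(path) -> pd.DataFrame:
    return _read_tsv(path, ("context", "alt", "methyl_level", "mu"), "rate table")


def _write_with_header(df: pd.DataFrame, path, seed=None, extra=()) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# coordinates: 1-based inclusive\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        for line in extra:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def regions_frame(regions: list[MissenseRegion]) -> pd.DataFrame:
    """Region list as the output table schema."""
    by_tx: dict[str, int] = {}
    for r in regions:
        by_tx[r.transcript_id] = by_tx.get(r.transcript_id, 0) + 1
    rows = [
        {
            "transcript_id": r.transcript_id,
            "cds_start": r.cds_start,
            "cds_end": r.cds_end,
            "obs": r.obs,
            "exp": r.exp,
            "oe": r.oe,
            "chi_sq": r.chi_sq,
            "n_regions_in_transcript": by_tx[r.transcript_id],
        }
        for r in regions
    ]
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def write_regions_tsv(regions: list[MissenseRegion], path, seed=None) -> None:
    _write_with_header(regions_frame(regions), path, seed)


def read_regions_tsv(path) -> pd.DataFrame:
    return _read_tsv(path, REGION_COLUMNS, "region table")


def region_genomic_intervals(
    region: MissenseRegion, sites: pd.DataFrame
) -> list[tuple[str, int, int]]:
    """Genomic pieces of a region as 1-based inclusive (contig, start, end).

    A region spanning an exon junction splits into one interval per run of
    consecutive genomic positions among its sites.
    """
    sub = sites[
        (sites["transcript_id"] == region.transcript_id)
        & (sites["cds_pos"] >= region.cds_start)
        & (sites["cds_pos"] <= region.cds_end)
    ].sort_values(["contig", "genomic_pos"])
    intervals: list[tuple[str, int, int]] = []
    for contig, grp in sub.groupby("contig", sort=True):
        pos = np.unique(grp["genomic_pos"].to_numpy())
        if len(pos) == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > 1)
        starts = np.r_[pos[0], pos[breaks + 1]]
        ends = np.r_[pos[breaks], pos[-1]]
        intervals.extend((str(contig), int(s), int(e)) for s, e in zip(starts, ends))
    return intervals


def write_regions_bed(regions: list[MissenseRegion], sites: pd.DataFrame, path) -> None:
    """BED (0-based half-open), one row per exon-piece of each region.

    name = transcript_id:region_index; score = round(1000 * (1 - oe)), so
    stronger depletion scores higher.
    """
    path = Path(path)
    idx_by_tx: dict[str, int] = {}
    with path.open("w") as fh:
        for r in regions:
            idx = idx_by_tx.get(r.transcript_id, 0)
            idx_by_tx[r.transcript_id] = idx + 1
            score = int(round(1000 * (1 - r.oe)))
            for contig, start, end in region_genomic_intervals(r, sites):
                fh.write(
                    f"{contig}\t{start - 1}\t{end}\t{r.transcript_id}:{idx}\t{score}\n"
                )


def read_config(path) -> dict:
    """YAML (or flat key=value) run configuration."""
    text = Path(path).read_text()
    try:
        cfg = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise SchemaError(f"malformed config {path}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise SchemaError(f"config {path} must be a mapping")
    return cfg


def write_manifest(path, config: dict, seed, input_paths=()) -> None:
    """Run manifest: config hash, seed, and a digest per input file."""
    digest = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()
    inputs = {}
    for p in input_paths:
        p = Path(p)
        inputs[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest() if p.exists() else None
    payload = {"config_sha256": digest, "seed": seed, "inputs": inputs}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
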