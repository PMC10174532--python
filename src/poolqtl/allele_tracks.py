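"""Allele-frequency tracks from pooled sequencing counts.

Turns per-marker read counts of the two sorted pools into the observable the
mapping works on: raw RM allele frequencies, an artifact filter, loess
smoothing along each chromosome, and the smoothed high-minus-low frequency
difference (dAF). The sign convention is fixed throughout the package:
positive dAF means the RM allele is associated with the higher-phenotype pool
(higher proteasome activity).

Coordinates are 1-based inclusive internally; BED exports are 0-based
half-open.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

#: artifact filter bounds on the raw per-pool allele frequency; strictly
#: outside (lo, hi) is removed, boundary values are retained.
AF_FILTER_LO = 0.1
AF_FILTER_HI = 0.9

#: default loess window, expressed as physical span along the chromosome.
#: QTL support intervals in this cross are tens of kb, so the window must not
#: erase ~50 kb features.
DEFAULT_SPAN_BP = 50_000

COUNT_COLUMNS = ["chrom", "pos", "ref_count", "alt_count"]


@dataclass
class PoolCounts:
    """Per-marker (ref=BY, alt=RM) read counts for one sequenced pool."""

    df: pd.DataFrame                 # columns: chrom, pos, ref_count, alt_count
    pool: str | None = None          # "high" or "low"
    replicate: int | None = None

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in COUNT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"count table missing columns: {missing}")
        if len(df) == 0:
            raise ValueError("no markers")
        if (df["ref_count"] < 0).any() or (df["alt_count"] < 0).any():
            raise ValueError("negative read counts")
        if df.duplicated(["chrom", "pos"]).any():
            raise ValueError("duplicate (chrom, pos) markers")
        self.df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def read_counts(path: str | Path, format: str = "tsv"):
    """Read pool counts; ``format`` is 'tsv' (one pool) or 'vcf' (one pool per
    sample, returned as a dict keyed by sample name)."""
    if format == "tsv":
        return read_counts_tsv(path)
    if format == "vcf":
        return read_counts_vcf(path)
    raise ValueError(f"unknown format {format!r}")


def read_counts_tsv(path: str | Path) -> PoolCounts:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: no markers")
    bad = df[COUNT_COLUMNS[1:]].isna().any(axis=1)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header and 1-based lines
        raise ValueError(f"{path}: malformed rows at lines {lines}")
    return PoolCounts(df[COUNT_COLUMNS].astype(
        {"pos": np.int64, "ref_count": np.int64, "alt_count": np.int64}))


def read_counts_vcf(path: str | Path) -> dict[str, PoolCounts]:
    """Parse biallelic records with per-sample allelic depths (FORMAT/AD)."""
    import pysam

    records: dict[str, list[tuple[str, int, int, int]]] = {}
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise ValueError(f"{path}: VCF has no samples")
        for name in samples:
            records[name] = []
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            if rec.alts is None or len(rec.alts) != 1:
                n_skipped += 1
                continue
            for name in samples:
                ad = rec.samples[name].get("AD")
                if ad is None or len(ad) < 2 or ad[0] is None:
                    raise ValueError(
                        f"{path}: missing AD for sample {name} at "
                        f"{rec.chrom}:{rec.pos}")
                records[name].append((rec.chrom, rec.pos, int(ad[0]), int(ad[1])))
    if n_skipped:
        warnings.warn(f"{path}: skipped {n_skipped} multi-allelic records",
                      stacklevel=2)
    out = {}
    for name, rows in records.items():
        if not rows:
            raise ValueError(f"{path}: no biallelic markers for sample {name}")
        out[name] = PoolCounts(pd.DataFrame(rows, columns=COUNT_COLUMNS))
    return out


# -- tracks -------------------------------------------------------------------

def allele_frequency(counts: PoolCounts) -> pd.DataFrame:
    """Raw RM allele-frequency track: chrom, pos, af_raw, depth.

    Zero-depth markers have an undefined frequency and are dropped (logged).
    """
    df = counts.df
    depth = (df["ref_count"] + df["alt_count"]).to_numpy()
    n_zero = int((depth == 0).sum())
    if n_zero:
        logger.info("dropping %d zero-depth markers", n_zero)
    keep = depth > 0
    track = pd.DataFrame({
        "chrom": df["chrom"][keep].to_numpy(),
        "pos": df["pos"][keep].to_numpy(),
        "af_raw": df["alt_count"][keep].to_numpy() / depth[keep],
        "depth": depth[keep],
    })
    return track


def filter_af(track: pd.DataFrame, lo: float = AF_FILTER_LO,
              hi: float = AF_FILTER_HI) -> pd.DataFrame:
    """Remove artifact-prone markers with raw frequency strictly above ``hi``
    or strictly below ``lo`` (boundary values are retained)."""
    if not lo < hi:
        raise ValueError("lo must be < hi")
    keep = (track["af_raw"] >= lo) & (track["af_raw"] <= hi)
    out = track.loc[keep].reset_index(drop=True)
    for chrom in pd.unique(track["chrom"]):
        if chrom not in set(out["chrom"]):
            warnings.warn(f"{chrom}: all markers removed by AF filter",
                          stacklevel=2)
    return out


def loess_smooth(track: pd.DataFrame, span_bp: float = DEFAULT_SPAN_BP,
                 min_markers: int = 5) -> pd.DataFrame:
    """Add ``af_smooth``: local-linear loess of af_raw on position.

    The loess fraction is chosen per chromosome so the window spans roughly
    ``span_bp`` of sequence; fits never cross chromosome boundaries, and the
    result is clamped to [0, 1]. Chromosomes with fewer than ``min_markers``
    markers pass through unsmoothed with a warning.
    """
    if span_bp <= 0:
        raise ValueError("span_bp must be positive")
    out = track.copy()
    smooth = np.empty(len(out))
    for chrom, idx in out.groupby("chrom", sort=False).groups.items():
        pos = out.loc[idx, "pos"].to_numpy(dtype=float)
        af = out.loc[idx, "af_raw"].to_numpy(dtype=float)
        where = out.index.get_indexer(idx)
        if len(idx) < min_markers:
            warnings.warn(f"{chrom}: fewer than {min_markers} markers; "
                          "raw values passed through", stacklevel=2)
            smooth[where] = af
            continue
        extent = pos[-1] - pos[0]
        frac = 1.0 if extent <= 0 else min(1.0, span_bp / extent)
        # ensure the local regressions are determined (>= 3 points)
        frac = max(frac, min(1.0, 3.0 / len(idx)))
        fitted = lowess(af, pos, frac=frac, it=0, return_sorted=False)
        smooth[where] = np.clip(fitted, 0.0, 1.0)
    out["af_smooth"] = smooth
    return out


def delta_af(high: pd.DataFrame, low: pd.DataFrame) -> pd.DataFrame:
    """Smoothed high-minus-low RM frequency difference per marker.

    Tracks are intersected on (chrom, pos) when their marker sets differ
    (logged); disjoint marker sets are an error.
    """
    for name, tr in (("high", high), ("low", low)):
        if "af_smooth" not in tr.columns:
            raise ValueError(f"{name} track is not smoothed; run loess_smooth")
    merged = high.merge(low, on=["chrom", "pos"], suffixes=("_high", "_low"))
    if len(merged) == 0:
        raise ValueError("high and low tracks share no markers")
    if len(merged) < max(len(high), len(low)):
        logger.info("dAF computed on %d shared markers (%d high, %d low)",
                    len(merged), len(high), len(low))
    return pd.DataFrame({
        "chrom": merged["chrom"],
        "pos": merged["pos"],
        "delta_af": merged["af_smooth_high"] - merged["af_smooth_low"],
    })


def pool_track(counts: PoolCounts, lo: float = AF_FILTER_LO,
               hi: float = AF_FILTER_HI,
               span_bp: float = DEFAULT_SPAN_BP) -> pd.DataFrame:
    """Convenience chain: frequencies -> AF filter -> loess smoothing."""
    return loess_smooth(filter_af(allele_frequency(counts), lo, hi), span_bp)


def write_track_tsv(track: pd.DataFrame, path: str | Path) -> None:
    track.to_csv(path, sep="\t", index=False, float_format="%.6f")
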