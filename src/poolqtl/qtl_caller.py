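"""Genome-wide LOD scoring and QTL calling from high/low pool counts.

The statistic is a two-model binomial likelihood ratio computed in bins along
each chromosome. Under the noncausal model the high and low pools share one
allele frequency; under the causal model each pool has its own. Both models
are maximised analytically (binomial MLEs), and the log10 ratio is the LOD.

Information is shared along the chromosome by pooling binned read counts with
a truncated Gaussian kernel, and the pooled counts are capped by a harmonic
effective-pool-size correction: a sequenced pool contains only ``n_eff``
independent genomes, so read counts can never contribute more than ``n_eff``
binomial trials no matter how deep the sequencing or how wide the kernel.

Called QTLs are maximal runs of bins above the LOD threshold; each carries a
peak, a 2-LOD support interval, and a direction of effect read off the
smoothed dAF track at the peak. Reported QTLs must be detected in both
biological replicates with concordant directions, and their summary values
are replicate means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import xlogy

from . import allele_tracks

logger = logging.getLogger(__name__)

LN10 = np.log(10.0)


@dataclass(frozen=True)
class LODParams:
    """Settings of the LOD scan.

    bin_bp: width of the counting bins (bp).
    bp_per_cM: genetic map scale of the cross.
    n_eff: effective pool size — independent genomes per sequenced pool.
    kernel_sd_bp: SD of the Gaussian count-pooling kernel (0 disables pooling).
    lod_threshold: genome-wide significance threshold for calling QTLs.
    """

    bin_bp: int = 100
    bp_per_cM: float = 2200.0
    n_eff: float = 1000.0
    kernel_sd_bp: float = 10_000.0
    lod_threshold: float = 4.5

    def __post_init__(self) -> None:
        if min(self.bin_bp, self.bp_per_cM, self.n_eff, self.lod_threshold) <= 0:
            raise ValueError("LOD parameters must be positive")
        if self.kernel_sd_bp != 0 and self.kernel_sd_bp < self.bin_bp:
            raise ValueError("kernel_sd_bp must be 0 or >= bin_bp")


@dataclass
class QTL:
    """One called locus; ``afd`` is the smoothed dAF at the peak and its sign
    is the direction of the RM allele's effect."""

    chromosome: str
    peak_pos: float
    lod: float
    afd: float
    left: float
    right: float
    reporter: str | None = None
    replicates: tuple["QTL", "QTL"] | None = None


# -- counts -> bins -----------------------------------------------------------

def filtered_counts(counts: allele_tracks.PoolCounts,
                    lo: float = allele_tracks.AF_FILTER_LO,
                    hi: float = allele_tracks.AF_FILTER_HI) -> pd.DataFrame:
    """Counts restricted to markers passing the depth and raw-AF filters."""
    df = counts.df
    depth = df["ref_count"] + df["alt_count"]
    af = df["alt_count"] / depth.where(depth > 0)
    keep = (depth > 0) & (af >= lo) & (af <= hi)
    return df.loc[keep].reset_index(drop=True)


def bin_counts(high: pd.DataFrame, low: pd.DataFrame, params: LODParams,
               chrom_lengths: dict[str, int]) -> dict[str, dict[str, np.ndarray]]:
    """Sum filtered (ref, alt) counts of both pools into bins tiling each
    chromosome. Bin edges are right-inclusive: a marker at bp ``b * bin_bp``
    falls in bin ``b``. Empty bins carry zero counts."""
    out = {}
    for chrom, length in chrom_lengths.items():
        nb = int(np.ceil(length / params.bin_bp))
        mid = (np.arange(nb) + 0.5) * params.bin_bp
        binned = {"mid": mid}
        for label, df in (("high", high), ("low", low)):
            sub = df[df["chrom"] == chrom]
            idx = (sub["pos"].to_numpy() - 1) // params.bin_bp
            alt = np.bincount(idx, weights=sub["alt_count"], minlength=nb)
            tot = alt + np.bincount(idx, weights=sub["ref_count"], minlength=nb)
            binned[f"k_{label}"] = alt
            binned[f"n_{label}"] = tot
        out[chrom] = binned
    return out


# -- likelihood machinery -----------------------------------------------------

def effective_counts(k, n, n_eff: float):
    """Downweight read counts for the finite number of pool genomes.

    The variance of a pooled frequency estimate is ~ p(1-p)(1/n + 1/N) for n
    reads from N genomes, which equals a binomial with n' = n N / (n + N)
    trials; counts are rescaled to that effective trial number."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(k > n):
        raise ValueError("alt count exceeds depth")
    n_prime = np.where(n > 0, n * n_eff / (n + n_eff), 0.0)
    k_prime = np.where(n > 0, k * n_prime / np.maximum(n, 1e-300), 0.0)
    return k_prime, n_prime


def lod_bin(k1, n1, k2, n2):
    """LOD = log10 of the causal/noncausal binomial likelihood ratio.

    Causal: each pool at its own MLE p_i = k_i / n_i. Noncausal: both pools
    at the pooled MLE (k1+k2)/(n1+n2). Zero-depth pairs score 0. Counts may
    be non-integer (kernel-weighted); the binomial coefficients cancel.
    """
    k1, n1, k2, n2 = (np.asarray(a, dtype=float) for a in (k1, n1, k2, n2))
    if np.any(k1 > n1) or np.any(k2 > n2):
        raise ValueError("alt count exceeds depth")

    def ll(k, n, p):
        return xlogy(k, p) + xlogy(n - k, 1.0 - p)

    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(n1 > 0, k1 / np.maximum(n1, 1e-300), 0.0)
        p2 = np.where(n2 > 0, k2 / np.maximum(n2, 1e-300), 0.0)
        denom = n1 + n2
        pp = np.where(denom > 0, (k1 + k2) / np.maximum(denom, 1e-300), 0.0)
        lod = (ll(k1, n1, p1) + ll(k2, n2, p2)
               - ll(k1, n1, pp) - ll(k2, n2, pp)) / LN10
    return np.maximum(lod, 0.0)


def _kernel(params: LODParams) -> np.ndarray:
    if params.kernel_sd_bp == 0:
        return np.ones(1)
    sd_bins = params.kernel_sd_bp / params.bin_bp
    radius = int(np.ceil(4 * sd_bins))
    offs = np.arange(-radius, radius + 1)
    return np.exp(-0.5 * (offs / sd_bins) ** 2)


def lod_track(binned: dict[str, dict[str, np.ndarray]],
              params: LODParams) -> pd.DataFrame:
    """Per-bin LOD along the genome: kernel-pool the binned counts (never
    crossing chromosome boundaries), cap them at the effective pool size,
    then apply the likelihood ratio."""
    w = _kernel(params)
    half = (w.size - 1) // 2
    frames = []
    for chrom, b in binned.items():
        nb = b["mid"].size
        pooled = {key: np.convolve(b[key], w, mode="full")[half:half + nb]
                  for key in ("k_high", "n_high", "k_low", "n_low")}
        k1, n1 = effective_counts(pooled["k_high"], pooled["n_high"], params.n_eff)
        k2, n2 = effective_counts(pooled["k_low"], pooled["n_low"], params.n_eff)
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": b["mid"],
            "lod": lod_bin(k1, n1, k2, n2),
            "n_eff_used": n1 + n2,
        }))
    return pd.concat(frames, ignore_index=True)


# -- calling ------------------------------------------------------------------

def _runs(mask: np.ndarray):
    """(start, stop) index pairs of maximal True runs, stop inclusive."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(int))
    starts = list(np.nonzero(d == 1)[0] + 1)
    stops = list(np.nonzero(d == -1)[0])
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask) - 1)
    return list(zip(starts, stops))


def call_qtls(lod: pd.DataFrame, daf: pd.DataFrame, params: LODParams,
              chrom_lengths: dict[str, int] | None = None,
              reporter: str | None = None) -> list[QTL]:
    """Call single-replicate QTLs from a LOD track and its dAF track.

    Maximal runs of bins with LOD >= threshold become candidate regions; the
    peak is the leftmost maximal bin, the support interval extends outward to
    the first bins where LOD drops 2 below the peak (clipped at chromosome
    ends), and the direction is the sign of the dAF interpolated at the peak.
    """
    qtls: list[QTL] = []
    for chrom, sub in lod.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        score = sub["lod"].to_numpy()
        dsub = daf[daf["chrom"] == chrom]
        for start, stop in _runs(score >= params.lod_threshold):
            peak_i = start + int(np.argmax(score[start:stop + 1]))
            peak_lod = score[peak_i]
            drop = peak_lod - 2.0
            below_left = np.nonzero(score[:peak_i] <= drop)[0]
            left = pos[below_left[-1]] if below_left.size else 0.0
            below_right = np.nonzero(score[peak_i + 1:] <= drop)[0]
            if below_right.size:
                right = pos[peak_i + 1 + below_right[0]]
            else:
                right = float(chrom_lengths[chrom]) if chrom_lengths else pos[-1]
            if len(dsub):
                afd = float(np.interp(pos[peak_i], dsub["pos"], dsub["delta_af"]))
            else:
                afd = float("nan")
            qtls.append(QTL(chromosome=chrom, peak_pos=float(pos[peak_i]),
                            lod=float(peak_lod), afd=afd,
                            left=float(left), right=float(right),
                            reporter=reporter))
    return qtls


def concordant_qtls(rep1: list[QTL], rep2: list[QTL],
                    max_dist: float = 100_000.0) -> list[QTL]:
    """Pair QTLs across the two biological replicates and average them.

    A pair requires the same chromosome, peaks within ``max_dist``, and the
    same dAF sign; many-to-many ambiguity is resolved by greedy nearest-peak
    matching. Unpaired QTLs are dropped (logged). The reported QTL carries
    the arithmetic mean of peak position, LOD, dAF, and interval bounds.
    """
    candidates = []
    for i, a in enumerate(rep1):
        for j, b in enumerate(rep2):
            if a.chromosome != b.chromosome:
                continue
            dist = abs(a.peak_pos - b.peak_pos)
            if dist <= max_dist and np.sign(a.afd) == np.sign(b.afd) != 0:
                candidates.append((dist, i, j))
    candidates.sort()
    used1: set[int] = set()
    used2: set[int] = set()
    merged = []
    for _, i, j in candidates:
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        a, b = rep1[i], rep2[j]
        merged.append(QTL(
            chromosome=a.chromosome,
            peak_pos=(a.peak_pos + b.peak_pos) / 2,
            lod=(a.lod + b.lod) / 2,
            afd=(a.afd + b.afd) / 2,
            left=(a.left + b.left) / 2,
            right=(a.right + b.right) / 2,
            reporter=a.reporter,
            replicates=(a, b)))
    n_drop = len(rep1) + len(rep2) - 2 * len(merged)
    if n_drop:
        logger.info("dropped %d replicate-discordant QTLs", n_drop)
    merged.sort(key=lambda q: (q.chromosome, q.peak_pos))
    return merged


# -- convenience pipeline -----------------------------------------------------

def qtl_scan(high: allele_tracks.PoolCounts, low: allele_tracks.PoolCounts,
             chrom_lengths: dict[str, int], params: LODParams = LODParams(),
             span_bp: float = allele_tracks.DEFAULT_SPAN_BP,
             reporter: str | None = None):
    """Single-replicate scan: filter, smooth, score, call.

    Returns ``(lod_track, delta_af_track, qtls)``.
    """
    high_f = filtered_counts(high)
    low_f = filtered_counts(low)
    binned = bin_counts(high_f, low_f, params, chrom_lengths)
    lod = lod_track(binned, params)
    daf = allele_tracks.delta_af(
        allele_tracks.loess_smooth(allele_tracks.allele_frequency(
            allele_tracks.PoolCounts(high_f)), span_bp),
        allele_tracks.loess_smooth(allele_tracks.allele_frequency(
            allele_tracks.PoolCounts(low_f)), span_bp))
    return lod, daf, call_qtls(lod, daf, params, chrom_lengths, reporter)


# -- output -------------------------------------------------------------------

def qtl_table(qtls: list[QTL]) -> pd.DataFrame:
    return pd.DataFrame([{
        "reporter": q.reporter, "chromosome": q.chromosome,
        "lod": round(q.lod, 2), "afd": round(q.afd, 2),
        "peak_pos": int(round(q.peak_pos)),
        "left": int(round(q.left)), "right": int(round(q.right)),
    } for q in qtls])


def write_qtl_tsv(qtls: list[QTL], path: str | Path) -> None:
    qtl_table(qtls).to_csv(path, sep="\t", index=False)


def write_qtl_bed(qtls: list[QTL], path: str | Path) -> None:
    """Support intervals as BED (0-based, half-open)."""
    with Path(path).open("w") as fh:
        for q in qtls:
            name = f"{q.reporter or 'qtl'}_{q.chromosome}_{int(q.peak_pos)}"
            fh.write(f"{q.chromosome}\t{max(0, int(round(q.left)) - 1)}\t"
                     f"{int(round(q.right))}\t{name}\t{q.lod:.2f}\n")
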