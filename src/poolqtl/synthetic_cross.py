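"""Forward simulation of a two-parent yeast cross with extreme-pool selection.

This module is a generative stand-in for the wet-lab half of a bulk-segregant
mapping experiment: it produces haploid recombinant segregants from a BY x RM
style cross, assigns them additive reporter phenotypes, draws FACS-like pools
from the phenotype tails, and sequences the pools to per-marker allele counts.
Every step is seeded, and the planted trait architecture is retained as ground
truth so that the downstream QTL caller can be benchmarked against it.

Genotypes are coded 0 = BY (reference) allele, 1 = RM (alternative) allele.
Phenotypes are on the tandem-fluorescent-timer scale (-log2 RFP/GFP), where
higher values mean faster proteasomal degradation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

# -- default experimental conditions -----------------------------------------
DEFAULT_BP_PER_CM = 2200.0     # genetic map scale of the cross, bp per centiMorgan
DEFAULT_TAIL_FRACTION = 0.02   # each sorted pool comes from a 2% phenotype tail
DEFAULT_POOL_CELLS = 20_000    # cells sorted per pool
DEFAULT_COVERAGE = 21.0        # median genome coverage of the pooled sequencing
FULL_MARKER_COUNT = 18_871     # biallelic marker panel size at full scale

# sacCer3-style chromosome lengths (bp), ~12.07 Mb total
_FULL_CHROM_BP = {
    "chrI": 230_218, "chrII": 813_184, "chrIII": 316_620, "chrIV": 1_531_933,
    "chrV": 576_874, "chrVI": 270_161, "chrVII": 1_090_940, "chrVIII": 562_643,
    "chrIX": 439_888, "chrX": 745_751, "chrXI": 666_816, "chrXII": 1_078_177,
    "chrXIII": 924_431, "chrXIV": 784_333, "chrXV": 1_091_291, "chrXVI": 948_066,
}


class ConfigurationError(ValueError):
    """Raised when simulation inputs are inconsistent with the marker map."""


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# -- domain types -------------------------------------------------------------

@dataclass
class MarkerMap:
    """Ordered biallelic marker positions per chromosome with a bp<->cM scale.

    Parameters
    ----------
    chromosomes
        ``(name, length_bp)`` pairs in genome order.
    markers
        Mapping from chromosome name to a sorted 1-based bp position array.
    bp_per_cM
        Physical distance corresponding to one centiMorgan.
    """

    chromosomes: list[tuple[str, int]]
    markers: dict[str, np.ndarray]
    bp_per_cM: float = DEFAULT_BP_PER_CM

    def __post_init__(self) -> None:
        if self.bp_per_cM <= 0:
            raise ConfigurationError("bp_per_cM must be positive")
        if not self.chromosomes:
            raise ConfigurationError("marker map has no chromosomes")
        lengths = dict(self.chromosomes)
        for chrom, pos in self.markers.items():
            pos = np.asarray(pos, dtype=np.int64)
            self.markers[chrom] = pos
            if pos.size == 0:
                raise ConfigurationError(f"{chrom}: no markers")
            if np.any(np.diff(pos) <= 0):
                raise ConfigurationError(f"{chrom}: positions must be strictly increasing")
            if pos[0] < 1 or pos[-1] > lengths[chrom]:
                raise ConfigurationError(f"{chrom}: positions outside [1, {lengths[chrom]}]")
        if not self.markers:
            raise ConfigurationError("marker map is empty")

    @property
    def chrom_names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def n_markers(self) -> int:
        return int(sum(p.size for p in self.markers.values()))

    def offsets(self) -> dict[str, int]:
        """Column offset of each chromosome's first marker in genome-wide arrays."""
        out, acc = {}, 0
        for chrom, _ in self.chromosomes:
            out[chrom] = acc
            acc += self.markers[chrom].size
        return out

    def slice(self, chrom: str) -> slice:
        off = self.offsets()[chrom]
        return slice(off, off + self.markers[chrom].size)

    def bp_to_cM(self, bp: float | np.ndarray) -> np.ndarray:
        return np.asarray(bp, dtype=float) / self.bp_per_cM

    def marker_index(self, chrom: str, pos: int) -> int:
        """Genome-wide column index of the marker nearest ``pos`` on ``chrom``."""
        if chrom not in self.markers:
            raise ConfigurationError(f"unknown chromosome {chrom!r}")
        p = self.markers[chrom]
        i = int(np.argmin(np.abs(p - pos)))
        return self.offsets()[chrom] + i

    def haldane_r(self, d_bp: float | np.ndarray) -> np.ndarray:
        """Recombination fraction between markers ``d_bp`` apart (Haldane)."""
        d_morgan = np.asarray(d_bp, dtype=float) / (self.bp_per_cM * 100.0)
        return 0.5 * (1.0 - np.exp(-2.0 * d_morgan))


@dataclass
class QTLLocus:
    """One planted causal locus; ``effect`` is signed, in phenotype SD units.

    Positive effect means the RM allele raises the phenotype (faster
    degradation, i.e. higher proteasome activity)."""

    chrom: str
    pos: int
    effect: float


@dataclass
class QTLArchitecture:
    loci: list[QTLLocus]
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")

    def to_json(self) -> str:
        return json.dumps(
            {"noise_sd": self.noise_sd,
             "loci": [{"chrom": l.chrom, "pos": l.pos, "effect": l.effect}
                      for l in self.loci]},
            indent=2)


@dataclass
class SegregantPopulation:
    marker_map: MarkerMap
    genotypes: np.ndarray                 # (n_segregants, n_markers) uint8, 0=BY 1=RM
    phenotypes: np.ndarray | None = None  # (n_segregants,) float

    @property
    def n_segregants(self) -> int:
        return self.genotypes.shape[0]


@dataclass
class SegregantPool:
    """A sorted tail pool: true per-marker RM frequencies plus sequenced counts."""

    tail: str                              # "high" or "low"
    fraction: float
    n_cells: int
    true_af: np.ndarray                    # (n_markers,) in [0, 1]
    read_counts: np.ndarray | None = None  # (n_markers, 2) = (ref, alt)


# -- genome profiles ----------------------------------------------------------

def desk_genome(n_chromosomes: int = 16, chrom_bp: int = 75_000,
                marker_spacing: int = 640,
                bp_per_cM: float = DEFAULT_BP_PER_CM) -> MarkerMap:
    """Small uniform genome (default 16 x 75 kb, ~1.9k markers) for fast runs."""
    chroms = [(f"chr{i + 1:02d}", chrom_bp) for i in range(n_chromosomes)]
    pos = np.arange(marker_spacing // 2, chrom_bp + 1, marker_spacing, dtype=np.int64)
    markers = {name: pos.copy() for name, _ in chroms}
    return MarkerMap(chroms, markers, bp_per_cM)


def full_genome(n_markers: int = FULL_MARKER_COUNT,
                bp_per_cM: float = DEFAULT_BP_PER_CM) -> MarkerMap:
    """Full-scale genome: 16 chromosomes totalling ~12.07 Mb with ``n_markers``
    markers spread evenly (~640 bp apart), emulating the cross's SNP panel."""
    total = sum(_FULL_CHROM_BP.values())
    chroms = list(_FULL_CHROM_BP.items())
    markers = {}
    assigned = 0
    for i, (name, length) in enumerate(chroms):
        if i == len(chroms) - 1:
            m = n_markers - assigned
        else:
            m = int(round(n_markers * length / total))
        assigned += m
        # even spacing, centred in the chromosome
        markers[name] = np.linspace(1, length, num=m + 2, dtype=np.int64)[1:-1]
    return MarkerMap(chroms, markers, bp_per_cM)


# -- operations ---------------------------------------------------------------

def simulate_segregants(marker_map: MarkerMap, n: int,
                        seed: int | np.random.Generator) -> SegregantPopulation:
    """Simulate ``n`` independent haploid meiotic products.

    Each chromosome starts as BY or RM with probability 1/2; crossovers follow
    a unit-rate Poisson process along the genetic map (Haldane model, no
    interference), so the switch probability between adjacent markers d bp
    apart is r = (1 - exp(-2 d / (100 bp_per_cM))) / 2.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = _rng(seed)
    geno = np.empty((n, marker_map.n_markers), dtype=np.uint8)
    for chrom, _ in marker_map.chromosomes:
        pos = marker_map.markers[chrom]
        m = pos.size
        sl = marker_map.slice(chrom)
        start = rng.integers(0, 2, size=n, dtype=np.uint8)
        if m == 1:
            geno[:, sl] = start[:, None]
            continue
        # genetic positions in Morgans, relative to the first marker
        g = (pos - pos[0]) / (marker_map.bp_per_cM * 100.0)
        L = g[-1]
        counts = rng.poisson(L, size=n)
        total = int(counts.sum())
        xover = rng.random(total) * L
        seg_ids = np.repeat(np.arange(n), counts)
        # first marker index strictly to the right of each crossover
        first_flipped = np.searchsorted(g, xover, side="right")
        switches = np.zeros((n, m), dtype=np.uint8)
        switches[:, 0] = start
        keep = first_flipped < m
        np.add.at(switches, (seg_ids[keep], first_flipped[keep]), 1)
        # in-place cumsum wraps mod 256, which preserves parity mod 2
        np.cumsum(switches, axis=1, out=switches)
        switches &= 1
        geno[:, sl] = switches
    return SegregantPopulation(marker_map, geno)


def assign_phenotypes(pop: SegregantPopulation, arch: QTLArchitecture,
                      seed: int | np.random.Generator) -> SegregantPopulation:
    """Additive phenotype: sum of signed locus effects for RM carriers plus
    Gaussian(0, noise_sd) residual. Loci snap to the nearest marker."""
    rng = _rng(seed)
    pheno = rng.normal(0.0, arch.noise_sd, size=pop.n_segregants)
    for locus in arch.loci:
        col = pop.marker_map.marker_index(locus.chrom, locus.pos)
        pheno += locus.effect * pop.genotypes[:, col].astype(float)
    pop.phenotypes = pheno
    return pop


def select_tails(pop: SegregantPopulation,
                 fraction: float = DEFAULT_TAIL_FRACTION,
                 n_cells: int = DEFAULT_POOL_CELLS,
                 seed: int | np.random.Generator = 0,
                 ) -> tuple[SegregantPool, SegregantPool]:
    """Draw the high- and low-tail pools by phenotype quantile.

    The top/bottom ``fraction`` of segregants form each tail; ``n_cells``
    cells are then sampled from the tail, without replacement when the tail
    is large enough, with replacement otherwise (a sorter can re-encounter
    clonal copies). ``true_af`` is the RM frequency among the sampled cells.
    """
    if pop.phenotypes is None:
        raise ConfigurationError("population has no phenotypes")
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    rng = _rng(seed)
    n = pop.n_segregants
    n_tail = max(1, int(round(fraction * n)))
    order = np.argsort(pop.phenotypes, kind="stable")
    tails = {"low": order[:n_tail], "high": order[-n_tail:]}
    pools = {}
    for name, idx in tails.items():
        replace = n_cells > idx.size
        cells = rng.choice(idx, size=n_cells, replace=replace)
        counts = np.bincount(cells, minlength=n)
        nz = np.nonzero(counts)[0]
        af = (counts[nz].astype(float) @ pop.genotypes[nz].astype(float)) / n_cells
        pools[name] = SegregantPool(tail=name, fraction=fraction,
                                    n_cells=n_cells, true_af=af)
    return pools["high"], pools["low"]


def sequence_pools(pool: SegregantPool, mean_coverage: float = DEFAULT_COVERAGE,
                   overdispersion: float = 0.0,
                   seed: int | np.random.Generator = 0) -> SegregantPool:
    """Sequence a pool: per-marker depth ~ Poisson(mean_coverage); alternative
    (RM) read count ~ Binomial(depth, true_af), or Beta-Binomial with the same
    mean when ``overdispersion`` (rho in [0, 1)) is positive."""
    if mean_coverage <= 0:
        raise ValueError("mean_coverage must be positive")
    if not 0 <= overdispersion < 1:
        raise ValueError("overdispersion must be in [0, 1)")
    rng = _rng(seed)
    af = pool.true_af
    depth = rng.poisson(mean_coverage, size=af.size)
    if overdispersion == 0:
        alt = rng.binomial(depth, af)
    else:
        conc = (1.0 - overdispersion) / overdispersion
        p = np.clip(af, 0.0, 1.0)
        interior = (p > 0) & (p < 1)
        draw = p.copy()
        draw[interior] = rng.beta(p[interior] * conc, (1 - p[interior]) * conc)
        alt = rng.binomial(depth, draw)
    pool.read_counts = np.column_stack([depth - alt, alt]).astype(np.int64)
    return pool


# -- output -------------------------------------------------------------------

def write_counts_tsv(pool: SegregantPool, marker_map: MarkerMap,
                     path: str | Path) -> None:
    """Write per-marker allele counts as TSV: chrom, pos, ref_count, alt_count."""
    if pool.read_counts is None:
        raise ValueError("pool has no read counts; call sequence_pools first")
    path = Path(path)
    with path.open("w") as fh:
        fh.write("chrom\tpos\tref_count\talt_count\n")
        row = 0
        for chrom, _ in marker_map.chromosomes:
            for pos in marker_map.markers[chrom]:
                ref, alt = pool.read_counts[row]
                fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\n")
                row += 1


def write_counts_vcf(pools: dict[str, SegregantPool], marker_map: MarkerMap,
                     path: str | Path) -> None:
    """Write a minimal biallelic VCF with one AD-carrying sample per pool."""
    names = list(pools)
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in marker_map.chromosomes:
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths (ref, alt)">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(names) + "\n")
        row = 0
        for chrom, _ in marker_map.chromosomes:
            for pos in marker_map.markers[chrom]:
                fields = [chrom, str(pos), ".", "A", "G", ".", "PASS", ".", "AD"]
                for name in names:
                    ref, alt = pools[name].read_counts[row]
                    fields.append(f"{ref},{alt}")
                fh.write("\t".join(fields) + "\n")
                row += 1


def write_truth_json(arch: QTLArchitecture, path: str | Path) -> None:
    Path(path).write_text(arch.to_json() + "\n")
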