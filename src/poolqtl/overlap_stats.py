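"""Substrate-specificity statistics on sets of QTLs.

Two QTLs "overlap" when their peaks lie within a distance cutoff (default
100 kb) on the same chromosome and their allele-frequency differences have
the same sign, i.e. the RM allele pushes the phenotype the same way for both
reporters. On top of that relation the module computes: pairwise one-to-one
matchings between two reporters' QTL sets, the overlap fraction (matched
pairs over matched pairs plus unmatched QTLs of either set), a pairwise
overlap matrix across many reporters, and the single-linkage merge of all
QTLs into distinct genomic loci.

A packaged table of previously reported proteasome-activity QTLs from the
BY x RM cross (11 for the ODC-degron reporter, 7 for the Rpn4-degron
reporter) is included for regression tests and worked examples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .qtl_caller import QTL

DEFAULT_MAX_DIST = 100_000.0
DEFAULT_MIN_QTLS = 7


@dataclass
class QTLSet:
    reporter: str
    qtls: list[QTL]

    def __len__(self) -> int:
        return len(self.qtls)


def load_reported_qtls() -> dict[str, QTLSet]:
    """The packaged ODC / Rpn4 proteasome-activity QTL table, as QTLSets."""
    with resources.files("poolqtl.data").joinpath("proteasome_qtls.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    out: dict[str, QTLSet] = {}
    for reporter, sub in df.groupby("reporter", sort=False):
        qtls = [QTL(chromosome=r.chromosome, peak_pos=float(r.peak_pos),
                    lod=float(r.lod), afd=float(r.afd),
                    left=float(r.left), right=float(r.right), reporter=reporter)
                for r in sub.itertuples()]
        out[reporter] = QTLSet(reporter, qtls)
    return out


def qtl_overlap(a: QTL, b: QTL, max_dist: float = DEFAULT_MAX_DIST) -> bool:
    """True iff same chromosome, peaks within ``max_dist``, same dAF sign."""
    if a.afd == 0 or b.afd == 0 or np.isnan(a.afd) or np.isnan(b.afd):
        raise ValueError("direction undefined for a QTL with dAF of 0")
    return (a.chromosome == b.chromosome
            and abs(a.peak_pos - b.peak_pos) <= max_dist
            and np.sign(a.afd) == np.sign(b.afd))


def match_pairs(set_a: QTLSet, set_b: QTLSet,
                max_dist: float = DEFAULT_MAX_DIST) -> list[tuple[int, int, float]]:
    """Greedy nearest-peak one-to-one matching under the overlap relation.

    Returns ``(index_a, index_b, distance)`` triples, nearest pairs first.
    """
    candidates = []
    for i, a in enumerate(set_a.qtls):
        for j, b in enumerate(set_b.qtls):
            if qtl_overlap(a, b, max_dist):
                candidates.append((abs(a.peak_pos - b.peak_pos), i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for dist, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j, dist))
    return pairs


def overlap_fraction(set_a: QTLSet, set_b: QTLSet,
                     max_dist: float = DEFAULT_MAX_DIST) -> float:
    """Matched pairs / (matched pairs + unmatched QTLs of both sets).

    Each matched pair counts once in the numerator; the denominator adds the
    reporter-specific (unmatched) QTLs of either set.
    """
    if len(set_a) == 0 or len(set_b) == 0:
        raise ValueError("overlap fraction of an empty QTL set is undefined")
    pairs = match_pairs(set_a, set_b, max_dist)
    n_pairs = len(pairs)
    n_specific = (len(set_a) - n_pairs) + (len(set_b) - n_pairs)
    return n_pairs / (n_pairs + n_specific)


def merge_distinct_loci(sets: list[QTLSet],
                        max_dist: float = DEFAULT_MAX_DIST) -> list[dict]:
    """Partition all QTLs into distinct loci by single-linkage merging.

    Connected components of the pairwise overlap relation across every set;
    each component is one locus, with a representative peak equal to the mean
    of its members' peaks.
    """
    if not sets:
        raise ValueError("need at least one QTL set")
    flat = [(s.reporter, q) for s in sets for q in s.qtls]
    n = len(flat)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if qtl_overlap(flat[i][1], flat[j][1], max_dist):
                parent[find(i)] = find(j)

    components: dict[int, list[int]] = {}
    for i in range(n):
        components.setdefault(find(i), []).append(i)
    loci = []
    for members in components.values():
        qtls = [flat[i][1] for i in members]
        loci.append({
            "chromosome": qtls[0].chromosome,
            "peak_pos": float(np.mean([q.peak_pos for q in qtls])),
            "reporters": sorted({flat[i][0] for i in members}),
            "qtls": qtls,
        })
    loci.sort(key=lambda l: (l["chromosome"], l["peak_pos"]))
    return loci


def pairwise_overlap_matrix(sets: list[QTLSet],
                            min_qtls: int = DEFAULT_MIN_QTLS,
                            max_dist: float = DEFAULT_MAX_DIST):
    """Overlap fractions among every pair of sets with >= ``min_qtls`` QTLs.

    Returns ``(matrix, median)`` where the matrix is a symmetric DataFrame
    with unit diagonal and the median is taken over distinct pairs.
    """
    kept = [s for s in sets if len(s) >= min_qtls]
    if len(kept) < 2:
        raise ValueError("need at least two QTL sets after the min_qtls filter")
    names = [s.reporter for s in kept]
    mat = pd.DataFrame(np.eye(len(kept)), index=names, columns=names)
    fractions = []
    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            f = overlap_fraction(kept[i], kept[j], max_dist)
            mat.iloc[i, j] = mat.iloc[j, i] = f
            fractions.append(f)
    return mat, float(np.median(fractions))


def overlap_report(sets: list[QTLSet],
                   max_dist: float = DEFAULT_MAX_DIST) -> dict:
    """Summary across a list of QTL sets: pairwise matches, per-pair overlap
    fractions, and the distinct-locus partition."""
    loci = merge_distinct_loci(sets, max_dist)
    report = {
        "n_qtls": sum(len(s) for s in sets),
        "n_distinct_loci": len(loci),
        "n_single_reporter_loci": sum(1 for l in loci if len(l["reporters"]) == 1),
        "loci": [{k: l[k] for k in ("chromosome", "peak_pos", "reporters")}
                 for l in loci],
        "pairs": {},
    }
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            a, b = sets[i], sets[j]
            pairs = match_pairs(a, b, max_dist)
            report["pairs"][f"{a.reporter}|{b.reporter}"] = {
                "n_overlapping": len(pairs),
                "overlap_fraction": overlap_fraction(a, b, max_dist),
            }
    return report


def read_qtl_sets(paths: list[str | Path]) -> list[QTLSet]:
    """Read QTL tables in the caller's TSV schema into QTLSets."""
    sets = []
    for path in paths:
        df = pd.read_csv(path, sep="\t")
        reporter = str(df["reporter"].iloc[0]) if "reporter" in df else Path(path).stem
        qtls = [QTL(chromosome=r.chromosome, peak_pos=float(r.peak_pos),
                    lod=float(r.lod), afd=float(r.afd),
                    left=float(getattr(r, "left", np.nan)),
                    right=float(getattr(r, "right", np.nan)),
                    reporter=reporter)
                for r in df.itertuples()]
        sets.append(QTLSet(reporter, qtls))
    return sets
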