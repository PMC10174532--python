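"""Configuration and end-to-end orchestration: simulate -> map -> overlap.

One pipeline run mirrors a complete bulk-segregant experiment for one
reporter: two independent biological replicates are simulated (independent
sporulations), each replicate's high/low pools are sequenced and mapped, and
only replicate-concordant QTLs are reported. Seeds are explicit and
per-replicate, per-stage, so reruns are byte-identical and stages can be
varied independently.

The module also hosts the benchmark loops used to characterise the caller:
``recovery_benchmark`` (planted-locus recovery at full genome scale) and
``fdr_benchmark`` (false-discovery rate over many simulated experiments with
null chromosomes).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import allele_tracks, overlap_stats, qtl_caller, synthetic_cross
from .allele_tracks import DEFAULT_SPAN_BP, PoolCounts
from .qtl_caller import LODParams, QTL
from .synthetic_cross import (MarkerMap, QTLArchitecture, QTLLocus,
                              desk_genome, full_genome)

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


# -- configuration ------------------------------------------------------------

@dataclass
class SimulationConfig:
    n_segregants: int = 50_000
    fraction: float = 0.02
    n_cells: int = 20_000
    coverage: float = 21.0
    overdispersion: float = 0.0
    architecture: QTLArchitecture = field(
        default_factory=lambda: QTLArchitecture(loci=[], noise_sd=1.0))


@dataclass
class MappingConfig:
    params: LODParams = field(default_factory=LODParams)
    span_bp: float = DEFAULT_SPAN_BP
    max_dist: float = overlap_stats.DEFAULT_MAX_DIST


@dataclass
class OverlapConfig:
    max_dist: float = overlap_stats.DEFAULT_MAX_DIST
    min_qtls: int = overlap_stats.DEFAULT_MIN_QTLS


@dataclass
class RunConfig:
    seed: int
    profile: str = "desk"
    reporter: str = "reporter"
    out_dir: str = "poolqtl_run"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    mapping: MappingConfig = field(default_factory=MappingConfig)
    overlap: OverlapConfig = field(default_factory=OverlapConfig)

    def marker_map(self) -> MarkerMap:
        if self.profile == "desk":
            return desk_genome()
        if self.profile == "full":
            return full_genome()
        raise ValueError(f"unknown genome profile {self.profile!r}")


class ConfigError(ValueError):
    pass


def _check_keys(block: dict, allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def validate_config(source: str | Path | dict) -> RunConfig:
    """Build a fully-defaulted, type-checked RunConfig from YAML/JSON/dict.

    Unknown keys and out-of-range values raise ``ConfigError`` naming the key.
    """
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text())
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    _check_keys(raw, {"seed", "profile", "reporter", "out_dir",
                      "simulation", "mapping", "overlap"}, "config")
    if "seed" not in raw or raw["seed"] is None:
        raise ConfigError("config key 'seed' is required (no wall-clock seeding)")
    seed = int(raw["seed"])

    sim_raw = raw.get("simulation", {}) or {}
    _check_keys(sim_raw, {"n_segregants", "fraction", "n_cells", "coverage",
                          "overdispersion", "architecture"}, "simulation")
    arch_raw = sim_raw.get("architecture", {}) or {}
    _check_keys(arch_raw, {"noise_sd", "loci"}, "simulation.architecture")
    loci = []
    for i, entry in enumerate(arch_raw.get("loci", []) or []):
        _check_keys(entry, {"chrom", "pos", "effect"},
                    f"simulation.architecture.loci[{i}]")
        loci.append(QTLLocus(chrom=str(entry["chrom"]), pos=int(entry["pos"]),
                             effect=float(entry["effect"])))
    arch = QTLArchitecture(loci=loci,
                           noise_sd=float(arch_raw.get("noise_sd", 1.0)))
    sim = SimulationConfig(
        n_segregants=int(sim_raw.get("n_segregants", 50_000)),
        fraction=float(sim_raw.get("fraction", 0.02)),
        n_cells=int(sim_raw.get("n_cells", 20_000)),
        coverage=float(sim_raw.get("coverage", 21.0)),
        overdispersion=float(sim_raw.get("overdispersion", 0.0)),
        architecture=arch)
    if not 0 < sim.fraction <= 0.5:
        raise ConfigError("simulation.fraction must be in (0, 0.5]")
    if sim.n_segregants < 1 or sim.n_cells < 1:
        raise ConfigError("simulation sizes must be positive")
    if sim.coverage <= 0:
        raise ConfigError("simulation.coverage must be positive")

    map_raw = raw.get("mapping", {}) or {}
    _check_keys(map_raw, {"bin_bp", "bp_per_cM", "n_eff", "kernel_sd_bp",
                          "lod_threshold", "span_bp", "max_dist"}, "mapping")
    try:
        params = LODParams(
            bin_bp=int(map_raw.get("bin_bp", 100)),
            bp_per_cM=float(map_raw.get("bp_per_cM", 2200.0)),
            n_eff=float(map_raw.get("n_eff", 1000.0)),
            kernel_sd_bp=float(map_raw.get("kernel_sd_bp", 10_000.0)),
            lod_threshold=float(map_raw.get("lod_threshold", 4.5)))
    except ValueError as exc:
        raise ConfigError(f"mapping: {exc}") from exc
    mapping = MappingConfig(params=params,
                            span_bp=float(map_raw.get("span_bp", DEFAULT_SPAN_BP)),
                            max_dist=float(map_raw.get("max_dist", 100_000.0)))
    if mapping.span_bp <= 0:
        raise ConfigError("mapping.span_bp must be positive")

    ovl_raw = raw.get("overlap", {}) or {}
    _check_keys(ovl_raw, {"max_dist", "min_qtls"}, "overlap")
    overlap = OverlapConfig(max_dist=float(ovl_raw.get("max_dist", 100_000.0)),
                            min_qtls=int(ovl_raw.get("min_qtls", 7)))

    return RunConfig(seed=seed, profile=str(raw.get("profile", "desk")),
                     reporter=str(raw.get("reporter", "reporter")),
                     out_dir=str(raw.get("out_dir", "poolqtl_run")),
                     simulation=sim, mapping=mapping, overlap=overlap)


# -- simulate -> map helpers --------------------------------------------------

def simulate_replicate(marker_map: MarkerMap, sim: SimulationConfig,
                       seed_seq: np.random.SeedSequence):
    """One biological replicate: sporulation, phenotyping, sorting, sequencing.

    Returns sequenced ``(high, low)`` pools. Stages draw from independent
    child streams of ``seed_seq`` so they can be varied independently.
    """
    s_geno, s_pheno, s_tails, s_seq = seed_seq.spawn(4)
    pop = synthetic_cross.simulate_segregants(
        marker_map, sim.n_segregants, np.random.default_rng(s_geno))
    synthetic_cross.assign_phenotypes(pop, sim.architecture,
                                      np.random.default_rng(s_pheno))
    high, low = synthetic_cross.select_tails(
        pop, sim.fraction, sim.n_cells, np.random.default_rng(s_tails))
    rng_seq = np.random.default_rng(s_seq)
    for pool in (high, low):
        synthetic_cross.sequence_pools(pool, sim.coverage,
                                       sim.overdispersion, rng_seq)
    return high, low


def _pool_counts(pool, marker_map: MarkerMap, label: str,
                 replicate: int) -> PoolCounts:
    chroms = np.concatenate([
        np.repeat(c, marker_map.markers[c].size) for c in marker_map.chrom_names])
    pos = np.concatenate([marker_map.markers[c] for c in marker_map.chrom_names])
    import pandas as pd
    df = pd.DataFrame({"chrom": chroms, "pos": pos,
                       "ref_count": pool.read_counts[:, 0],
                       "alt_count": pool.read_counts[:, 1]})
    return PoolCounts(df, pool=label, replicate=replicate)


def map_experiment(marker_map: MarkerMap, sim: SimulationConfig,
                   mapping: MappingConfig, seed: int | np.random.SeedSequence,
                   reporter: str | None = None, n_replicates: int = 2):
    """Simulate ``n_replicates`` biological replicates and map them.

    Returns ``(per_replicate, concordant)`` where ``per_replicate`` is a list
    of ``(lod_track, daf_track, qtls)`` and ``concordant`` the replicate-
    averaged QTL calls.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    rep_seeds = ss.spawn(n_replicates)
    per_rep = []
    for rep, rs in enumerate(rep_seeds, start=1):
        high, low = simulate_replicate(marker_map, sim, rs)
        scan = qtl_caller.qtl_scan(
            _pool_counts(high, marker_map, "high", rep),
            _pool_counts(low, marker_map, "low", rep),
            marker_map.chrom_lengths, mapping.params, mapping.span_bp,
            reporter=reporter)
        per_rep.append(scan)
    concordant = qtl_caller.concordant_qtls(per_rep[0][2], per_rep[1][2],
                                            mapping.max_dist)
    return per_rep, concordant


# -- full pipeline ------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> tracks -> LOD -> calls -> concordance and write
    all outputs plus a manifest under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker_map = config.marker_map()
    ss = np.random.SeedSequence(config.seed)
    rep_seeds = ss.spawn(2)

    outputs: dict[str, str] = {}
    per_rep_qtls = []
    for rep, rs in enumerate(rep_seeds, start=1):
        high, low = simulate_replicate(marker_map, config.simulation, rs)
        counts = {"high": _pool_counts(high, marker_map, "high", rep),
                  "low": _pool_counts(low, marker_map, "low", rep)}
        for label, pc in counts.items():
            path = out / f"counts_rep{rep}_{label}.tsv"
            pc.df.to_csv(path, sep="\t", index=False)
            outputs[path.name] = _sha256(path)
        lod, daf, qtls = qtl_caller.qtl_scan(
            counts["high"], counts["low"], marker_map.chrom_lengths,
            config.mapping.params, config.mapping.span_bp,
            reporter=config.reporter)
        for name, df in (("lod", lod), ("daf", daf)):
            path = out / f"{name}_rep{rep}.tsv"
            allele_tracks.write_track_tsv(df, path)
            outputs[path.name] = _sha256(path)
        path = out / f"qtls_rep{rep}.tsv"
        qtl_caller.write_qtl_tsv(qtls, path)
        outputs[path.name] = _sha256(path)
        per_rep_qtls.append(qtls)

    concordant = qtl_caller.concordant_qtls(per_rep_qtls[0], per_rep_qtls[1],
                                            config.mapping.max_dist)
    path = out / "qtls_concordant.tsv"
    qtl_caller.write_qtl_tsv(concordant, path)
    outputs[path.name] = _sha256(path)
    path = out / "qtls_concordant.bed"
    qtl_caller.write_qtl_bed(concordant, path)
    outputs[path.name] = _sha256(path)
    path = out / "architecture.json"
    synthetic_cross.write_truth_json(config.simulation.architecture, path)
    outputs[path.name] = _sha256(path)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "profile": config.profile,
        "reporter": config.reporter,
        "n_markers": marker_map.n_markers,
        "n_qtls_per_replicate": [len(q) for q in per_rep_qtls],
        "n_qtls_concordant": len(concordant),
        "outputs": outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    logger.info("pipeline wrote %d files to %s", len(outputs) + 1, out)
    return manifest


# -- benchmarks ---------------------------------------------------------------

def plant_architecture(marker_map: MarkerMap, rng: np.random.Generator,
                       effects: tuple[float, ...] = (0.75, 1.0, 1.25),
                       noise_sd: float = 1.0,
                       margin_bp: int = 10_000) -> QTLArchitecture:
    """Plant len(effects) QTLs on distinct random chromosomes with random
    signs and uniform positions away from chromosome ends."""
    chroms = rng.choice(marker_map.chrom_names, size=len(effects), replace=False)
    loci = []
    lengths = marker_map.chrom_lengths
    for chrom, eff in zip(chroms, effects):
        length = lengths[chrom]
        lo, hi = margin_bp, length - margin_bp
        pos = int(rng.integers(lo, hi + 1))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        loci.append(QTLLocus(chrom=str(chrom), pos=pos, effect=sign * eff))
    return QTLArchitecture(loci=loci, noise_sd=noise_sd)


def recovery_benchmark(n_runs: int = 20, seed: int = 0,
                       effects: tuple[float, ...] = (0.75, 1.0, 1.25),
                       tol_bp: float = 30_000.0,
                       marker_map: MarkerMap | None = None,
                       sim: SimulationConfig | None = None,
                       mapping: MappingConfig | None = None) -> dict:
    """Planted-QTL recovery over seeded full-scale experiments.

    A planted locus counts as recovered when a replicate-concordant call on
    its chromosome lies within ``tol_bp`` of it with the correct direction.
    """
    marker_map = marker_map or full_genome()
    sim = sim or SimulationConfig()
    mapping = mapping or MappingConfig()
    ss = np.random.SeedSequence(seed)
    n_planted = n_recovered = 0
    for run_seed in ss.spawn(n_runs):
        arch_seed, exp_seed = run_seed.spawn(2)
        arch = plant_architecture(marker_map, np.random.default_rng(arch_seed),
                                  effects=effects, noise_sd=sim.architecture.noise_sd,
                                  margin_bp=60_000)
        run_sim = SimulationConfig(**{**asdict(sim), "architecture": arch})
        run_sim.architecture = arch
        _, calls = map_experiment(marker_map, run_sim, mapping, exp_seed)
        for locus in arch.loci:
            n_planted += 1
            hit = any(c.chromosome == locus.chrom
                      and abs(c.peak_pos - locus.pos) <= tol_bp
                      and np.sign(c.afd) == np.sign(locus.effect)
                      for c in calls)
            n_recovered += hit
    return {"n_runs": n_runs, "n_planted": n_planted,
            "n_recovered": n_recovered,
            "recovery_rate": n_recovered / n_planted}


def fdr_benchmark(n_experiments: int = 100, seed: int = 0,
                  effects: tuple[float, ...] = (1.0, 1.0, 1.0),
                  match_dist: float = 100_000.0,
                  marker_map: MarkerMap | None = None,
                  sim: SimulationConfig | None = None,
                  mapping: MappingConfig | None = None) -> dict:
    """False-discovery rate of replicate-concordant calls.

    Each experiment plants len(effects) QTLs on distinct chromosomes of a
    (default desk-scale) genome, leaving the remaining chromosomes null. A
    call with no planted locus within ``match_dist`` on its chromosome is a
    false discovery. Returns counts and the FDR as a percentage.
    """
    marker_map = marker_map or desk_genome()
    sim = sim or SimulationConfig()
    mapping = mapping or MappingConfig()
    ss = np.random.SeedSequence(seed)
    n_calls = n_false = 0
    for exp_ss in ss.spawn(n_experiments):
        arch_seed, exp_seed = exp_ss.spawn(2)
        arch = plant_architecture(marker_map, np.random.default_rng(arch_seed),
                                  effects=effects, noise_sd=sim.architecture.noise_sd)
        run_sim = SimulationConfig(**{**asdict(sim), "architecture": arch})
        run_sim.architecture = arch
        _, calls = map_experiment(marker_map, run_sim, mapping, exp_seed)
        for call in calls:
            n_calls += 1
            matched = any(locus.chrom == call.chromosome
                          and abs(locus.pos - call.peak_pos) <= match_dist
                          for locus in arch.loci)
            n_false += not matched
    fdr = 100.0 * n_false / n_calls if n_calls else 0.0
    return {"n_experiments": n_experiments, "n_calls": n_calls,
            "n_false": n_false, "fdr_percent": fdr}
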