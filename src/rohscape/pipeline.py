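"""End-to-end orchestration of simulation and empirical ROH analyses.

The simulation experiment crosses demographic scenarios with
selection/recombination models, runs the simulator for a number of
iterations, calls ROH on each output (no MAF filter, matching how
simulated genotypes are handled), and reduces each iteration to the
per-individual ROH burden plus the hotspot threshold and maximum ROH
density. The empirical path runs MAF filtering, dual-coordinate ROH
calling, F_ROH, the SNP-density/end-trim corrections, hotspot
detection, the short-ROH variant and (when phased haplotypes are
supplied) the haplotype-diversity overlay.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from . import __version__
from .caller import RohParams, RohSummary, call_roh, summarize_roh
from .diversity import (PhasedHaplotypes, diversity_track,
                        low_diversity_fraction, overlay_hotspots)
from .markers_io import (GENETIC, PHYSICAL, GenotypeMatrix, MarkerMap,
                         apply_maf_filter, write_roh_table)
from .simulator import SimResult, build_scenario, run_simulation
from .statistics import (DEER_AUTOSOME_MB, compute_froh, detect_hotspots,
                         filter_short_roh, iteration_summary, roh_density,
                         snp_density_filter, trim_chromosome_ends)

logger = logging.getLogger(__name__)

ITERATION_COLUMNS = [
    "scenario", "model", "iteration", "seed", "n_markers", "n_individuals",
    "n_segments", "mean_roh_per_individual", "mean_kb_per_individual",
    "hotspot_threshold", "max_roh_density", "low_D_fraction", "runtime_s",
]


@dataclass
class HotspotParams:
    percentile: float = 99.0
    window_kb: float = 1500.0
    step_kb: float = 100.0
    min_window_snps: int = 23
    n_trim: int = 40
    merge_gap_markers: int = 1


@dataclass
class ExperimentConfig:
    """One simulation-experiment grid (scenarios x models x iterations)."""

    scenarios: tuple[str, ...] = ("no_bottleneck", "rum", "severe_bottleneck")
    models: tuple[int, ...] = (1,)
    n_iterations: int = 23
    rescale_Q: int = 25
    base_seed: int = 1
    chromosome_length: int = 100_000_000
    burn_in: str = "coalescent"
    burn_in_tail_generations: int = 0
    sample_size: int | None = None      # None: scenario default
    roh_params: RohParams = field(default_factory=RohParams)
    hotspot: HotspotParams = field(default_factory=HotspotParams)
    diversity_window_snps: int = 20
    diversity_step_snps: int = 10
    low_d_threshold: float = 0.05
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


def _iteration_seed(base_seed: int, scenario: str, model: int,
                    iteration: int) -> int:
    """Deterministic per-iteration seed, bound to the iteration index."""
    scen_idx = {"no_bottleneck": 0, "rum": 1, "severe_bottleneck": 2}[scenario]
    return (base_seed + 1_000_003 * scen_idx + 10_007 * model + iteration) % (2**31 - 1)


def analyze_simulated(result: SimResult, roh_params: RohParams | None = None,
                      hotspot: HotspotParams | None = None,
                      diversity_window_snps: int = 20,
                      diversity_step_snps: int = 10,
                      low_d_threshold: float = 0.05) -> dict:
    """Reduce one simulated output to the per-iteration summary scalars."""
    roh_params = roh_params or RohParams()
    hotspot = hotspot or HotspotParams()
    segments = call_roh(result.genotypes, result.marker_map, roh_params)
    summary = summarize_roh(segments, result.genotypes.n_individuals,
                            result.genotypes.individual_ids)
    density = roh_density(segments, result.marker_map,
                          result.genotypes.n_individuals)
    retained = (snp_density_filter(result.marker_map, hotspot.window_kb,
                                   hotspot.step_kb, hotspot.min_window_snps)
                & trim_chromosome_ends(result.marker_map, hotspot.n_trim))
    if retained.any():
        threshold, max_density = iteration_summary(density, retained,
                                                   hotspot.percentile)
    else:
        threshold, max_density = float("nan"), float("nan")
    track = diversity_track(result.haplotypes, result.marker_map,
                            diversity_window_snps, diversity_step_snps)
    return {
        "n_markers": result.marker_map.n_markers,
        "n_individuals": result.genotypes.n_individuals,
        "n_segments": summary.n_segments,
        "mean_roh_per_individual": summary.mean_per_individual,
        "mean_kb_per_individual": summary.mean_kb_per_individual,
        "hotspot_threshold": threshold,
        "max_roh_density": max_density,
        "low_D_fraction": low_diversity_fraction(track, low_d_threshold),
        "segments": segments,
    }


def shared_equilibrium_iteration(
        seed: int, chromosome_length: int = 50_000_000, rescale_Q: int = 25,
        scenarios: tuple[str, ...] = ("no_bottleneck", "rum",
                                      "severe_bottleneck"),
        model: int = 1, burn_in_tail_generations: int = 0,
        sample_size: int | None = None,
        roh_params: RohParams | None = None,
        hotspot: HotspotParams | None = None) -> dict[str, dict]:
    """One experiment iteration with a single equilibrium draw.

    Because all scenarios share the same pre-bottleneck history (a
    stationary population of Ne 7500, rescaled by Q), one coalescent
    equilibrium sample can seed every demographic endgame of the
    iteration, which costs one ARG instead of three. Returns
    {scenario: per-iteration metrics}.
    """
    from .simulator import SimPopulation, _Registry, equilibrium_population

    overrides = {"sample_size": sample_size} if sample_size else {}
    base = build_scenario(scenarios[0], model, rescale_Q=rescale_Q, seed=seed,
                          chromosome_length=chromosome_length, **overrides)
    equilibrium = equilibrium_population(
        base.burn_in_ne, chromosome_length, base.burn_in_mutation_rate,
        base.burn_in_recomb, seed=seed)
    out: dict[str, dict] = {}
    for k, name in enumerate(scenarios):
        scenario = build_scenario(
            name, model, rescale_Q=rescale_Q, seed=seed + 7 * k + 1,
            chromosome_length=chromosome_length,
            burn_in_tail_generations=burn_in_tail_generations, **overrides)
        start = SimPopulation(haplotypes=list(equilibrium.haplotypes),
                              selected=list(equilibrium.selected),
                              registry=_Registry())
        result = run_simulation(scenario, initial_population=start)
        metrics = analyze_simulated(result, roh_params, hotspot)
        metrics.pop("segments")
        out[name] = metrics
    return out


def run_simulation_experiment(config: ExperimentConfig,
                              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the whole grid; returns (per-iteration, aggregate) tables.

    With ``config.output_dir`` set, per-iteration rows are appended to
    ``iterations.csv`` as they finish and already-present rows are
    skipped on re-run, so an interrupted experiment resumes cleanly.
    """
    out_dir = Path(config.output_dir) if config.output_dir else None
    done: set[tuple[str, int, int]] = set()
    rows: list[dict] = []
    iter_path = out_dir / "iterations.csv" if out_dir else None
    if iter_path and iter_path.exists():
        existing = pd.read_csv(iter_path)
        rows = existing.to_dict("records")
        done = {(r["scenario"], int(r["model"]), int(r["iteration"]))
                for r in rows}
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = dataclasses.asdict(config)
        manifest["roh_params"] = dataclasses.asdict(config.roh_params)
        manifest["hotspot"] = dataclasses.asdict(config.hotspot)
        manifest["version"] = __version__
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                          default=str))
    n_failed = 0
    for scenario_name in config.scenarios:
        for model in config.models:
            for iteration in range(config.n_iterations):
                key = (scenario_name, model, iteration)
                if key in done:
                    continue
                seed = _iteration_seed(config.base_seed, scenario_name, model,
                                       iteration)
                overrides = {}
                if config.sample_size is not None:
                    overrides["sample_size"] = config.sample_size
                scenario = build_scenario(
                    scenario_name, model, rescale_Q=config.rescale_Q,
                    seed=seed, chromosome_length=config.chromosome_length,
                    burn_in_tail_generations=config.burn_in_tail_generations,
                    **overrides)
                t0 = time.perf_counter()
                try:
                    result = run_simulation(scenario, burn_in=config.burn_in)
                    metrics = analyze_simulated(
                        result, config.roh_params, config.hotspot,
                        config.diversity_window_snps,
                        config.diversity_step_snps, config.low_d_threshold)
                except Exception:
                    logger.exception("iteration failed: %s model %d it %d",
                                     scenario_name, model, iteration)
                    n_failed += 1
                    continue
                metrics.pop("segments")
                row = {"scenario": scenario_name, "model": model,
                       "iteration": iteration, "seed": seed,
                       **metrics, "runtime_s": time.perf_counter() - t0}
                rows.append(row)
                if iter_path:
                    pd.DataFrame(rows, columns=ITERATION_COLUMNS).to_csv(
                        iter_path, index=False)
    per_iteration = pd.DataFrame(rows, columns=ITERATION_COLUMNS)
    aggregate = aggregate_experiment(per_iteration)
    if out_dir:
        aggregate.to_csv(out_dir / "aggregate.csv", index=False)
    if n_failed:
        logger.warning("%d iterations failed", n_failed)
    return per_iteration, aggregate


def aggregate_experiment(per_iteration: pd.DataFrame) -> pd.DataFrame:
    """Scenario x model means/SDs over iterations (recomputable from rows)."""
    if len(per_iteration) == 0:
        return pd.DataFrame()
    grouped = per_iteration.groupby(["scenario", "model"], sort=False)
    agg = grouped.agg(
        n_iterations=("iteration", "size"),
        mean_roh_per_individual=("mean_roh_per_individual", "mean"),
        sd_roh_per_individual=("mean_roh_per_individual", "std"),
        mean_kb_per_individual=("mean_kb_per_individual", "mean"),
        mean_hotspot_threshold=("hotspot_threshold", "mean"),
        mean_max_roh_density=("max_roh_density", "mean"),
        mean_low_D_fraction=("low_D_fraction", "mean"),
    ).reset_index()
    return agg


# ---------------------------------------------------------------------------
# Empirical path


@dataclass
class MapAnalysis:
    coordinate_system: str
    segments: list
    summary: RohSummary
    froh: pd.DataFrame
    hotspots: object
    short_roh_hotspots: object | None
    diversity: pd.DataFrame | None
    diversity_regions: pd.DataFrame | None


def run_empirical(genotypes: GenotypeMatrix, marker_map: MarkerMap,
                  coordinate_systems: tuple[str, ...] = (PHYSICAL, GENETIC),
                  min_maf: float = 0.01,
                  roh_params: RohParams | None = None,
                  hotspot: HotspotParams | None = None,
                  genome_length_mb: float = DEER_AUTOSOME_MB,
                  phased: PhasedHaplotypes | None = None,
                  short_roh_bounds_mb: tuple[float, float] = (2.5, 5.0),
                  output_dir: str | None = None) -> dict[str, MapAnalysis]:
    """Empirical pipeline: MAF filter -> ROH per map -> F_ROH -> hotspots.

    Returns one :class:`MapAnalysis` per coordinate system. ``phased``
    haplotypes must be aligned to the unfiltered marker map; they are
    subset alongside the MAF filter.
    """
    if roh_params is None:
        roh_params = RohParams()
    if hotspot is None:
        hotspot = HotspotParams()
    freq_before = genotypes.n_markers
    genotypes, marker_map_f = apply_maf_filter(genotypes, marker_map, min_maf)
    if phased is not None:
        if phased.n_markers != freq_before:
            raise ValueError("phased haplotypes not aligned to input map")
        kept_ids = set(marker_map_f.marker_ids)
        keep = np.array([mid in kept_ids for mid in marker_map.marker_ids])
        phased = PhasedHaplotypes(phased.alleles[:, keep], phased.individual_ids)
    marker_map = marker_map_f

    results: dict[str, MapAnalysis] = {}
    out = Path(output_dir) if output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    for coords in coordinate_systems:
        params = dataclasses.replace(roh_params, coordinate_system=coords)
        segments = call_roh(genotypes, marker_map, params)
        summary = summarize_roh(segments, genotypes.n_individuals,
                                genotypes.individual_ids)
        froh = pd.DataFrame([dataclasses.asdict(r) for r in compute_froh(
            segments, genotypes.individual_ids, genome_length_mb)])
        retained = (snp_density_filter(marker_map, hotspot.window_kb,
                                       hotspot.step_kb, hotspot.min_window_snps,
                                       coordinate_system=coords)
                    & trim_chromosome_ends(marker_map, hotspot.n_trim))
        density = roh_density(segments, marker_map, genotypes.n_individuals)
        hotspots = detect_hotspots(density, retained, marker_map,
                                   hotspot.percentile, hotspot.merge_gap_markers)
        short = filter_short_roh(segments, *short_roh_bounds_mb)
        short_density = roh_density(short, marker_map, genotypes.n_individuals)
        short_hotspots = detect_hotspots(short_density, retained, marker_map,
                                         hotspot.percentile,
                                         hotspot.merge_gap_markers)
        track = regions = None
        if phased is not None:
            track = diversity_track(phased, marker_map)
            track, regions = overlay_hotspots(track, hotspots)
        results[coords] = MapAnalysis(
            coordinate_system=coords, segments=segments, summary=summary,
            froh=froh, hotspots=hotspots, short_roh_hotspots=short_hotspots,
            diversity=track, diversity_regions=regions)
        if out:
            write_roh_table(segments, out / f"roh_{coords}.tsv")
            froh.to_csv(out / f"froh_{coords}.csv", index=False)
    return results


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Plain one-way ANOVA (F, p) across groups of observations."""
    f, p = sp_stats.f_oneway(*groups)
    return float(f), float(p)
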