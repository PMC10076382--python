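"""Population-level ROH statistics.

Covers the genomic inbreeding coefficient F_ROH (total ROH length over
total autosome length, 2591.86 Mb for the red deer assembly), the
per-SNP ROH density (% of individuals whose ROH cover a marker), the
SNP-density bias filter (ROH callers under-call in sparsely genotyped
regions, so markers in low-density windows are discarded), trimming of
chromosome ends (ROH cannot span past a chromosome end), and
percentile-threshold hotspot detection with region merging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from string import ascii_lowercase

import numpy as np

from .markers_io import PHYSICAL, MarkerMap, RohSegment

logger = logging.getLogger(__name__)

#: Total autosome length of the mCerEla1.1 red deer assembly, Mb.
DEER_AUTOSOME_MB: float = 2591.86


@dataclass
class FrohRecord:
    """Per-individual genomic inbreeding coefficient."""

    individual_id: str
    sum_roh_mb: float
    genome_length_mb: float
    f_roh: float


def compute_froh(segments: list[RohSegment], individual_ids: list[str],
                 genome_length_mb: float = DEER_AUTOSOME_MB) -> list[FrohRecord]:
    """F_ROH = (sum of Mb in ROH across autosomes) / genome length.

    Individuals with no segments get 0. Genetic-map calls use the same
    denominator, relying on the 1 Mb ~ 1 cM equivalence.
    """
    if genome_length_mb <= 0:
        raise ValueError("genome_length_mb must be positive")
    total_mb: dict[str, float] = {ind: 0.0 for ind in individual_ids}
    for s in segments:
        if s.individual_id not in total_mb:
            raise ValueError(f"segment for unknown individual {s.individual_id}")
        total_mb[s.individual_id] += s.length_kb / 1000.0
    return [FrohRecord(ind, total_mb[ind], genome_length_mb,
                       total_mb[ind] / genome_length_mb)
            for ind in individual_ids]


def roh_density(segments: list[RohSegment], marker_map: MarkerMap,
                n_individuals: int) -> np.ndarray:
    """Percentage of individuals with a ROH covering each marker.

    Relies on segments of one individual being non-overlapping, so a
    plain sum of per-segment marker coverage counts individuals.
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    m = marker_map.n_markers
    diff = np.zeros(m + 1, dtype=np.int64)
    for s in segments:
        diff[s.start_index] += 1
        diff[s.end_index + 1] -= 1
    covered = np.cumsum(diff[:m])
    return 100.0 * covered / n_individuals


def snp_density_filter(marker_map: MarkerMap, window_kb: float = 1500.0,
                       step_kb: float = 100.0, min_snps: int = 23,
                       coordinate_system: str = PHYSICAL) -> np.ndarray:
    """Mask of markers surviving the SNP-density bias filter.

    Windows of ``window_kb`` (closed intervals) anchored at each
    chromosome's first marker and advancing by ``step_kb`` tile the
    chromosome; every marker that falls in ANY window holding fewer
    than ``min_snps`` markers is discarded. The last window is the
    first one whose end reaches the final marker, so every marker is
    covered and the final window is evaluated like any other (rather
    than sliding degenerate slivers past the end of the data).
    """
    pos_all = marker_map.positions_kb(coordinate_system)
    keep = np.ones(marker_map.n_markers, dtype=bool)
    for _, sl in marker_map.chromosome_slices():
        pos = pos_all[sl]
        if len(pos) == 0:
            continue
        last = pos[-1]
        start = pos[0]
        while True:
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, start + window_kb, side="right")
            if hi - lo < min_snps:
                keep[sl.start + lo:sl.start + hi] = False
            if start + window_kb >= last:
                break
            start += step_kb
    return keep


def trim_chromosome_ends(marker_map: MarkerMap, n_trim: int = 40) -> np.ndarray:
    """Mask removing the first and last ``n_trim`` markers per chromosome."""
    keep = np.ones(marker_map.n_markers, dtype=bool)
    if n_trim == 0:
        return keep
    for chrom, sl in marker_map.chromosome_slices():
        n = sl.stop - sl.start
        if n <= 2 * n_trim:
            logger.info("chromosome %s fully masked by end trimming (%d markers)",
                        chrom, n)
            keep[sl] = False
        else:
            keep[sl.start:sl.start + n_trim] = False
            keep[sl.stop - n_trim:sl.stop] = False
    return keep


@dataclass
class HotspotRegion:
    chromosome: int
    start_index: int
    end_index: int        # global map row indices, inclusive
    start_bp: int
    end_bp: int
    label: str            # "a", "b", ... by position within chromosome
    n_snps: int
    peak_density: float


@dataclass
class HotspotResult:
    """Per-marker ROH density with percentile-threshold hotspot calls."""

    density: np.ndarray
    retained_mask: np.ndarray
    threshold: float
    percentile: float
    hotspot_mask: np.ndarray          # True at hotspot markers (subset of retained)
    regions: list[HotspotRegion] = field(default_factory=list)
    max_density: float = 0.0
    mean_density: float = 0.0


def detect_hotspots(density: np.ndarray, retained_mask: np.ndarray,
                    marker_map: MarkerMap, percentile: float = 99.0,
                    merge_gap_markers: int = 1) -> HotspotResult:
    """Class markers at/above the given density percentile as hotspots.

    The threshold is the linear-interpolation percentile of densities
    over retained markers. Hotspot markers within ``merge_gap_markers``
    of each other in retained-marker order (same chromosome) merge into
    regions, labelled (a), (b), ... by position within a chromosome.
    """
    density = np.asarray(density, dtype=float)
    retained_mask = np.asarray(retained_mask, dtype=bool)
    if density.shape[0] != marker_map.n_markers or retained_mask.shape[0] != density.shape[0]:
        raise ValueError("density/mask/map lengths differ")
    if not retained_mask.any():
        raise ValueError("no retained markers")
    retained_density = density[retained_mask]
    threshold = float(np.percentile(retained_density, percentile))
    hotspot_mask = retained_mask & (density >= threshold)

    retained_idx = np.flatnonzero(retained_mask)
    rank_of = {int(j): r for r, j in enumerate(retained_idx)}
    chroms = marker_map.chromosomes
    bp = marker_map.bp_pos
    hot_idx = np.flatnonzero(hotspot_mask)

    groups: list[list[int]] = []
    for j in hot_idx:
        j = int(j)
        if (groups and chroms[j] == chroms[groups[-1][-1]]
                and rank_of[j] - rank_of[groups[-1][-1]] <= merge_gap_markers):
            groups[-1].append(j)
        else:
            groups.append([j])

    regions: list[HotspotRegion] = []
    per_chrom_count: dict[int, int] = {}
    for g in groups:
        chrom = int(chroms[g[0]])
        k = per_chrom_count.get(chrom, 0)
        per_chrom_count[chrom] = k + 1
        label = ascii_lowercase[k] if k < 26 else f"r{k+1}"
        regions.append(HotspotRegion(
            chromosome=chrom, start_index=g[0], end_index=g[-1],
            start_bp=int(bp[g[0]]), end_bp=int(bp[g[-1]]), label=label,
            n_snps=len(g), peak_density=float(density[g].max())))

    return HotspotResult(
        density=density, retained_mask=retained_mask, threshold=threshold,
        percentile=percentile, hotspot_mask=hotspot_mask, regions=regions,
        max_density=float(retained_density.max()),
        mean_density=float(retained_density.mean()))


def iteration_summary(density: np.ndarray, retained_mask: np.ndarray,
                      percentile: float = 99.0) -> tuple[float, float]:
    """(hotspot threshold, maximum ROH density) for one run."""
    retained_mask = np.asarray(retained_mask, dtype=bool)
    if not retained_mask.any():
        raise ValueError("no retained markers")
    retained = np.asarray(density, dtype=float)[retained_mask]
    return float(np.percentile(retained, percentile)), float(retained.max())


def filter_short_roh(segments: list[RohSegment], min_mb: float = 2.5,
                     max_mb: float = 5.0) -> list[RohSegment]:
    """Keep segments with min_mb <= length <= max_mb (bounds inclusive)."""
    if min_mb > max_mb:
        raise ValueError("min_mb must not exceed max_mb")
    return [s for s in segments
            if min_mb * 1000.0 <= s.length_kb <= max_mb * 1000.0]
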