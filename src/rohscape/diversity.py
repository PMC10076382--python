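"""Windowed haplotype diversity over phased haplotypes.

Diversity is a Simpson-type index: for a window with haplotype counts
n_1..n_k and N = sum(n_i),

    D = 1 - sum(n_i * (n_i - 1)) / (N * (N - 1)),

the probability that two haplotypes sampled without replacement from
the window differ. D runs from 0 (one haplotype only) to 1 (all
haplotypes unique). A selective sweep concentrates haplotype
frequencies and drags D down, so sharp local dips in a D track flag
candidate selection targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markers_io import MISSING, MarkerMap
from .statistics import HotspotResult

logger = logging.getLogger(__name__)


@dataclass
class PhasedHaplotypes:
    """2 x n_individuals haplotype rows of {0, 1, MISSING} allele calls."""

    alleles: np.ndarray                   # (2 * n_individuals, n_markers) int8
    individual_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2 or self.alleles.shape[0] % 2:
            raise ValueError("expected an even number of haplotype rows")
        if self.individual_ids is None:
            self.individual_ids = [f"id_{i+1}" for i in range(self.alleles.shape[0] // 2)]

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0] // 2

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]


def simpson_diversity(haplotype_counts) -> float:
    """Simpson-type diversity D from per-haplotype occurrence counts."""
    counts = np.asarray(list(haplotype_counts), dtype=np.int64)
    if counts.size == 0 or (counts <= 0).any():
        raise ValueError("counts must be positive integers")
    n_total = int(counts.sum())
    if n_total < 2:
        raise ValueError("D undefined for fewer than two haplotypes")
    return float(1.0 - (counts * (counts - 1)).sum() / (n_total * (n_total - 1)))


def _window_counts(block: np.ndarray) -> np.ndarray:
    """Occurrence counts of distinct allele strings among rows."""
    packed = np.ascontiguousarray(block).view(
        np.dtype((np.void, block.shape[1] * block.dtype.itemsize)))
    _, counts = np.unique(packed.ravel(), return_counts=True)
    return counts


def diversity_track(haplotypes: PhasedHaplotypes, marker_map: MarkerMap,
                    window_snps: int = 20, step_snps: int = 10,
                    drop_whole_window: bool = False) -> pd.DataFrame:
    """Simpson diversity in sliding marker windows along each chromosome.

    Haplotype rows with any missing call in a window are excluded from
    that window (set ``drop_whole_window`` to instead discard the whole
    window when any row has a missing call). Windows with fewer than
    two usable rows are omitted.
    """
    alleles = haplotypes.alleles
    records = []
    for chrom, sl in marker_map.chromosome_slices():
        block = alleles[:, sl]
        bp = marker_map.bp_pos[sl]
        m = block.shape[1]
        for start in range(0, m - window_snps + 1, step_snps):
            window = block[:, start:start + window_snps]
            has_missing = (window == MISSING).any(axis=1)
            if drop_whole_window and has_missing.any():
                continue
            usable = window[~has_missing]
            if usable.shape[0] < 2:
                logger.debug("window %s:%d skipped (<2 usable rows)", chrom, start)
                continue
            counts = _window_counts(usable)
            records.append((chrom, sl.start + start, sl.start + start + window_snps - 1,
                            int(bp[start]), int(bp[start + window_snps - 1]),
                            usable.shape[0], len(counts),
                            simpson_diversity(counts)))
    return pd.DataFrame(records, columns=[
        "chromosome", "start_index", "end_index", "start_bp", "end_bp",
        "n_haplotypes", "n_distinct", "D"])


def low_diversity_fraction(track: pd.DataFrame, threshold: float = 0.05) -> float:
    """Fraction of windows with D below ``threshold`` (sweep footprint)."""
    if len(track) == 0:
        return 0.0
    return float((track["D"] < threshold).mean())


def overlay_hotspots(track: pd.DataFrame, hotspots: HotspotResult,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag track windows overlapping hotspot regions; contrast D levels.

    Returns the annotated track plus a per-region table with the
    minimum D inside each region and the background median D (windows
    overlapping no region), making a "sharp decrease at a hotspot" a
    computable contrast.
    """
    track = track.copy()
    flag = np.zeros(len(track), dtype=bool)
    region_rows = []
    start = track["start_index"].to_numpy()
    end = track["end_index"].to_numpy()
    chrom = track["chromosome"].to_numpy()
    for region in hotspots.regions:
        overlap = ((chrom == region.chromosome)
                   & (start <= region.end_index) & (end >= region.start_index))
        flag |= overlap
        region_rows.append((region.chromosome, region.label,
                            region.start_bp, region.end_bp,
                            float(track.loc[overlap, "D"].min()) if overlap.any() else np.nan,
                            int(overlap.sum())))
    track["hotspot"] = flag
    background = track.loc[~flag, "D"]
    background_median = float(background.median()) if len(background) else np.nan
    regions = pd.DataFrame(region_rows, columns=[
        "chromosome", "label", "start_bp", "end_bp", "min_D", "n_windows"])
    regions["background_median_D"] = background_median
    return track, regions
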