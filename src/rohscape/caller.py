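"""Scanning-window detection of runs of homozygosity (ROH).

Reimplements the sliding-window ROH search popularised by PLINK 1.9's
``--homozyg`` command: windows of ``window_snps`` markers are accepted
when they contain at most ``window_max_het`` heterozygous and
``window_max_missing`` missing calls; a marker is ROH-eligible when the
fraction of accepted windows covering it reaches
``window_hit_threshold``; maximal eligible runs are then split at large
inter-marker gaps, trimmed to homozygous endpoints, curtailed at excess
heterozygotes and finally filtered on SNP count, length and SNP density.

Positions enter on a kb scale. Physical coordinates use bp/1000;
genetic coordinates use cM x 1000, so that every kb-denominated
threshold applies unchanged under the 1 Mb ~ 1 cM convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markers_io import (GENETIC, MISSING, PHYSICAL, GenotypeMatrix,
                         MarkerMap, RohSegment)

__all__ = ["RohParams", "window_hit_fraction", "call_roh", "summarize_roh",
           "RohSummary"]


@dataclass(frozen=True)
class RohParams:
    """Parameters of the scanning-window ROH search.

    Defaults follow the PLINK flag set used for 50K-array red deer data:
    ROH of at least 40 SNPs and 2500 kb, at most 1 SNP per 70 kb mean
    spacing, 35-SNP windows tolerating 4 missing calls, no heterozygote
    allowed inside a final segment. ``window_max_het``,
    ``window_hit_threshold`` and ``max_gap_kb`` sit at PLINK defaults.
    """

    min_snps: int = 40
    min_length_kb: float = 2500.0
    max_kb_per_snp: float = 70.0
    window_snps: int = 35
    window_max_missing: int = 4
    window_max_het: int = 1
    window_hit_threshold: float = 0.05
    max_gap_kb: float = 1000.0
    segment_max_het: int = 0
    coordinate_system: str = PHYSICAL

    def __post_init__(self) -> None:
        if not 0.0 < self.window_hit_threshold <= 1.0:
            raise ValueError("window_hit_threshold must be in (0, 1]")
        for name in ("min_snps", "window_snps", "window_max_missing",
                     "window_max_het", "segment_max_het"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.coordinate_system not in (PHYSICAL, GENETIC):
            raise ValueError(f"unknown coordinate system {self.coordinate_system!r}")


def _hit_fractions(calls: np.ndarray, params: RohParams) -> np.ndarray:
    """Fraction of accepted windows covering each marker, per individual.

    ``calls`` is (n_individuals, n_markers) for one chromosome, sorted
    by position. Returns a float matrix of the same shape.
    """
    n_ind, m = calls.shape
    w = params.window_snps
    if m < w:
        return np.zeros((n_ind, m))
    het = (calls == 1)
    mis = (calls == MISSING)
    cs_het = np.zeros((n_ind, m + 1), dtype=np.int32)
    cs_mis = np.zeros((n_ind, m + 1), dtype=np.int32)
    np.cumsum(het, axis=1, out=cs_het[:, 1:])
    np.cumsum(mis, axis=1, out=cs_mis[:, 1:])
    het_w = cs_het[:, w:] - cs_het[:, :-w]          # windows: m - w + 1
    mis_w = cs_mis[:, w:] - cs_mis[:, :-w]
    accepted = (het_w <= params.window_max_het) & (mis_w <= params.window_max_missing)
    n_win = m - w + 1
    cs_acc = np.zeros((n_ind, n_win + 1), dtype=np.int32)
    np.cumsum(accepted, axis=1, out=cs_acc[:, 1:])
    j = np.arange(m)
    lo = np.maximum(0, j - w + 1)
    hi = np.minimum(j, n_win - 1)
    hits = cs_acc[:, hi + 1] - cs_acc[:, lo]
    denom = (hi - lo + 1).astype(float)
    return hits / denom


def window_hit_fraction(calls: np.ndarray, params: RohParams) -> np.ndarray:
    """Per-marker accepted-window fraction for one individual's chromosome."""
    calls = np.atleast_2d(np.asarray(calls, dtype=np.int8))
    return _hit_fractions(calls, params)[0]


def _runs_of_true(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) inclusive index pairs."""
    if not mask.any():
        return []
    padded = np.r_[False, mask, False]
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    return [(int(edges[i]), int(edges[i + 1] - 1)) for i in range(0, len(edges), 2)]


def _finalize_candidate(start: int, end: int, hom: np.ndarray,
                        het_idx: np.ndarray, params: RohParams,
                        out: list[tuple[int, int]]) -> None:
    """Trim to homozygous endpoints, curtail at excess heterozygotes.

    Scanning left to right, a candidate ends just before the
    (segment_max_het + 1)-th heterozygote and restarts after it (with
    the count reset); every emitted piece is trimmed to homozygous
    endpoints. Appends surviving (start, end) index pairs to ``out``;
    final count/length/density filters are applied by the caller.
    """
    h = params.segment_max_het
    cur = start
    while cur <= end:
        while cur <= end and not hom[cur]:
            cur += 1
        if cur > end:
            return
        k = int(np.searchsorted(het_idx, cur))
        if k + h < len(het_idx) and het_idx[k + h] <= end:
            offending = int(het_idx[k + h])
            piece_end = offending - 1
        else:
            offending = None
            piece_end = end
        while piece_end >= cur and not hom[piece_end]:
            piece_end -= 1
        if piece_end >= cur:
            out.append((cur, piece_end))
        if offending is None:
            return
        cur = offending + 1


def _call_one(calls: np.ndarray, eligible: np.ndarray, pos_kb: np.ndarray,
              params: RohParams) -> list[tuple[int, int]]:
    """Segment index pairs for one individual on one chromosome."""
    candidates: list[tuple[int, int]] = []
    gap_break = np.diff(pos_kb) > params.max_gap_kb
    for start, end in _runs_of_true(eligible):
        if gap_break[start:end].any():
            piece_start = start
            for j in np.flatnonzero(gap_break[start:end]) + start:
                candidates.append((piece_start, int(j)))
                piece_start = int(j) + 1
            candidates.append((piece_start, end))
        else:
            candidates.append((start, end))
    hom = (calls == 0) | (calls == 2)
    het_idx = np.flatnonzero(calls == 1)
    final: list[tuple[int, int]] = []
    for start, end in candidates:
        _finalize_candidate(start, end, hom, het_idx, params, final)
    kept = []
    for start, end in final:
        n_snps = end - start + 1
        length = pos_kb[end] - pos_kb[start]
        if (n_snps >= params.min_snps and length >= params.min_length_kb
                and length / n_snps <= params.max_kb_per_snp):
            kept.append((start, end))
    return kept


def call_roh(genotypes: GenotypeMatrix, marker_map: MarkerMap,
             params: RohParams | None = None,
             individual_chunk: int = 64) -> list[RohSegment]:
    """Call ROH for every individual on every chromosome.

    Returns segments sorted by individual, chromosome, start. Marker
    indices in the segments are global row indices into ``marker_map``.
    Chromosomes with fewer markers than ``window_snps`` yield no calls.
    """
    if params is None:
        params = RohParams()
    if genotypes.n_markers != marker_map.n_markers:
        raise ValueError("genotype/map dimension mismatch")
    bp = marker_map.bp_pos
    chroms = marker_map.chromosomes
    order_ok = all(np.all(np.diff(bp[sl]) > 0) for _, sl in marker_map.chromosome_slices())
    if not order_ok:
        raise ValueError("marker map must be position-sorted within chromosomes")

    pos_kb_all = marker_map.positions_kb(params.coordinate_system)
    segments: list[RohSegment] = []
    for chrom, sl in marker_map.chromosome_slices():
        pos_kb = pos_kb_all[sl]
        offset = sl.start
        raw_pos = (marker_map.bp_pos[sl] if params.coordinate_system == PHYSICAL
                   else marker_map.cm_pos[sl] * 1e3)
        calls_chrom = genotypes.calls[:, sl]
        for block in range(0, genotypes.n_individuals, individual_chunk):
            rows = slice(block, min(block + individual_chunk, genotypes.n_individuals))
            block_calls = calls_chrom[rows]
            frac = _hit_fractions(block_calls, params)
            eligible = frac >= params.window_hit_threshold
            for i in range(eligible.shape[0]):
                ind = genotypes.individual_ids[block + i]
                for start, end in _call_one(block_calls[i], eligible[i],
                                            pos_kb, params):
                    segments.append(RohSegment(
                        individual_id=ind, chromosome=chrom,
                        start_index=offset + start, end_index=offset + end,
                        start_pos=float(raw_pos[start]), end_pos=float(raw_pos[end]),
                        n_snps=end - start + 1,
                        length_kb=float(pos_kb[end] - pos_kb[start]),
                        coordinate_system=params.coordinate_system))
    ind_rank = {ind: i for i, ind in enumerate(genotypes.individual_ids)}
    segments.sort(key=lambda s: (ind_rank[s.individual_id], s.chromosome, s.start_index))
    return segments


@dataclass
class RohSummary:
    """Population summary of a set of called segments."""

    n_segments: int
    mean_length_kb: float
    sd_length_kb: float
    mean_per_individual: float
    sd_per_individual: float
    min_per_individual: int
    max_per_individual: int
    mean_kb_per_individual: float


def summarize_roh(segments: list[RohSegment], n_individuals: int,
                  individual_ids: list[str] | None = None) -> RohSummary:
    """Mean/SD segment length and per-individual counts (zeros included)."""
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    lengths = np.array([s.length_kb for s in segments], dtype=float)
    counts: dict[str, int] = {}
    kb: dict[str, float] = {}
    for s in segments:
        counts[s.individual_id] = counts.get(s.individual_id, 0) + 1
        kb[s.individual_id] = kb.get(s.individual_id, 0.0) + s.length_kb
    if len(counts) > n_individuals:
        raise ValueError("more individuals with segments than n_individuals")
    per_ind = np.zeros(n_individuals)
    per_ind_kb = np.zeros(n_individuals)
    if individual_ids is not None:
        for i, ind in enumerate(individual_ids):
            per_ind[i] = counts.get(ind, 0)
            per_ind_kb[i] = kb.get(ind, 0.0)
    else:
        per_ind[:len(counts)] = list(counts.values())
        per_ind_kb[:len(kb)] = list(kb.values())
    return RohSummary(
        n_segments=len(segments),
        mean_length_kb=float(lengths.mean()) if len(lengths) else 0.0,
        sd_length_kb=float(lengths.std(ddof=1)) if len(lengths) > 1 else 0.0,
        mean_per_individual=float(per_ind.mean()),
        sd_per_individual=float(per_ind.std(ddof=1)) if n_individuals > 1 else 0.0,
        min_per_individual=int(per_ind.min()),
        max_per_individual=int(per_ind.max()),
        mean_kb_per_individual=float(per_ind_kb.mean()))
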