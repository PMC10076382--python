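"""Deterministic genotype/haplotype fixtures with known ground truth.

Every generator is a pure function of its spec and seed, so tests can
plant homozygous tracts (or haplotype pools with known frequencies) and
assert recovery without external data. ``oracle_call_roh`` is a
deliberately naive, exhaustive re-derivation of the scanning-window ROH
contract, used as an independent check of the vectorised caller on
small inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .caller import RohParams
from .markers_io import (MISSING, PHYSICAL, GenotypeMatrix, MarkerMap,
                         RohSegment)

__all__ = ["PlantedRohSpec", "generate_planted", "oracle_call_roh",
           "PhasedPoolSpec", "generate_phased"]


@dataclass
class PlantedRohSpec:
    """Recipe for a genotype matrix with homozygous tracts of known span.

    ``tracts`` are (individual_index, chromosome, start_bp, end_bp);
    inside a tract every call of that individual is homozygous. Outside,
    calls are heterozygous with probability ``background_het_rate``
    (0.3 by default, typical of SNP-array data, so tract boundaries are
    sharp) and homozygous otherwise. ``low_density_gaps`` removes
    markers from (chromosome, start_bp, end_bp) intervals to exercise
    SNP-density handling.
    """

    n_individuals: int
    chromosome_lengths: dict[int, int]      # chromosome -> length in bp
    spacing_bp: int = 50_000
    tracts: list[tuple[int, int, int, int]] = field(default_factory=list)
    background_het_rate: float = 0.3
    missing_rate: float = 0.0
    low_density_gaps: list[tuple[int, int, int]] = field(default_factory=list)
    seed: int = 0


def generate_planted(spec: PlantedRohSpec,
                     ) -> tuple[GenotypeMatrix, MarkerMap, list[tuple[int, int, int, int]]]:
    """Build (genotypes, map, truth-tract list) from a planted spec."""
    if spec.spacing_bp <= 0:
        raise ValueError("spacing_bp must be positive")
    by_ind_chrom: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for ind, chrom, start, end in spec.tracts:
        if chrom not in spec.chromosome_lengths:
            raise ValueError(f"tract on undeclared chromosome {chrom}")
        if not 0 <= start < end <= spec.chromosome_lengths[chrom]:
            raise ValueError(f"tract ({start}, {end}) outside chromosome {chrom}")
        spans = by_ind_chrom.setdefault((ind, chrom), [])
        for s0, e0 in spans:
            if start < e0 and s0 < end:
                raise ValueError(f"overlapping tracts for individual {ind}")
        spans.append((start, end))

    rng = np.random.default_rng(spec.seed)
    rows = []
    for chrom in sorted(spec.chromosome_lengths):
        length = spec.chromosome_lengths[chrom]
        positions = np.arange(spec.spacing_bp, length + 1, spec.spacing_bp)
        for gchrom, gstart, gend in spec.low_density_gaps:
            if gchrom == chrom:
                positions = positions[(positions < gstart) | (positions > gend)]
        for pos in positions:
            rows.append((chrom, f"snp_{chrom}_{pos}", int(pos), pos * 1e-6))
    marker_map = MarkerMap(pd.DataFrame(
        rows, columns=["chromosome", "marker_id", "bp_pos", "cm_pos"]))

    m = marker_map.n_markers
    bp = marker_map.bp_pos
    chroms = marker_map.chromosomes
    hom = rng.integers(0, 2, size=(spec.n_individuals, m)).astype(np.int8) * 2
    het = rng.random((spec.n_individuals, m)) < spec.background_het_rate
    calls = np.where(het, np.int8(1), hom)
    for (ind, chrom), spans in by_ind_chrom.items():
        for start, end in spans:
            inside = (chroms == chrom) & (bp >= start) & (bp <= end)
            calls[ind, inside] = hom[ind, inside]
    if spec.missing_rate > 0:
        miss = rng.random((spec.n_individuals, m)) < spec.missing_rate
        calls = np.where(miss, np.int8(MISSING), calls)
    genotypes = GenotypeMatrix(calls.astype(np.int8))
    return genotypes, marker_map, list(spec.tracts)


# ---------------------------------------------------------------------------
# Exhaustive oracle for the scanning-window ROH contract


def _oracle_window_accepted(calls: list[int], params: RohParams) -> list[bool]:
    w = params.window_snps
    accepted = []
    for start in range(len(calls) - w + 1):
        window = calls[start:start + w]
        n_het = sum(1 for c in window if c == 1)
        n_mis = sum(1 for c in window if c == MISSING)
        accepted.append(n_het <= params.window_max_het
                        and n_mis <= params.window_max_missing)
    return accepted


def _oracle_eligible(calls: list[int], params: RohParams) -> list[bool]:
    w = params.window_snps
    m = len(calls)
    if m < w:
        return [False] * m
    accepted = _oracle_window_accepted(calls, params)
    eligible = []
    for j in range(m):
        covering = [accepted[s] for s in range(len(accepted))
                    if s <= j <= s + w - 1]
        frac = sum(covering) / len(covering)
        eligible.append(frac >= params.window_hit_threshold)
    return eligible


def _oracle_pieces(calls: list[int], start: int, end: int,
                   params: RohParams) -> list[tuple[int, int]]:
    """Trim non-homozygous ends, then curtail at the first excess het."""
    while start <= end and calls[start] not in (0, 2):
        start += 1
    while end >= start and calls[end] not in (0, 2):
        end -= 1
    if start > end:
        return []
    hets = [j for j in range(start, end + 1) if calls[j] == 1]
    if len(hets) <= params.segment_max_het:
        return [(start, end)]
    cut = hets[params.segment_max_het]
    return (_oracle_pieces(calls, start, cut - 1, params)
            + _oracle_pieces(calls, cut + 1, end, params))


def oracle_call_roh(genotypes: GenotypeMatrix, marker_map: MarkerMap,
                    params: RohParams | None = None) -> list[RohSegment]:
    """Brute-force ROH caller: same contract, independent derivation.

    Enumerates every window and candidate interval with plain Python
    loops. Intended for test inputs of a few hundred markers.
    """
    if params is None:
        params = RohParams()
    segments: list[RohSegment] = []
    pos_kb_all = marker_map.positions_kb(params.coordinate_system)
    for i, ind in enumerate(genotypes.individual_ids):
        for chrom, sl in marker_map.chromosome_slices():
            calls = [int(c) for c in genotypes.calls[i, sl]]
            pos_kb = [float(p) for p in pos_kb_all[sl]]
            raw_pos = (marker_map.bp_pos[sl] if params.coordinate_system == PHYSICAL
                       else marker_map.cm_pos[sl] * 1e3)
            eligible = _oracle_eligible(calls, params)

            # maximal eligible runs
            runs = []
            j = 0
            while j < len(calls):
                if eligible[j]:
                    k = j
                    while k + 1 < len(calls) and eligible[k + 1]:
                        k += 1
                    runs.append((j, k))
                    j = k + 1
                else:
                    j += 1
            # split at gaps larger than max_gap_kb
            candidates = []
            for start, end in runs:
                piece = start
                for j in range(start + 1, end + 1):
                    if pos_kb[j] - pos_kb[j - 1] > params.max_gap_kb:
                        candidates.append((piece, j - 1))
                        piece = j
                candidates.append((piece, end))
            # trim + heterozygote curtailment + final filters
            for start, end in candidates:
                for s, e in _oracle_pieces(calls, start, end, params):
                    n_snps = e - s + 1
                    length = pos_kb[e] - pos_kb[s]
                    if (n_snps >= params.min_snps
                            and length >= params.min_length_kb
                            and length / n_snps <= params.max_kb_per_snp):
                        segments.append(RohSegment(
                            individual_id=ind, chromosome=chrom,
                            start_index=sl.start + s, end_index=sl.start + e,
                            start_pos=float(raw_pos[s]), end_pos=float(raw_pos[e]),
                            n_snps=n_snps, length_kb=float(length),
                            coordinate_system=params.coordinate_system))
    return segments


# ---------------------------------------------------------------------------
# Phased-haplotype pools with closed-form window diversity


@dataclass
class PhasedPoolSpec:
    """Haplotype rows drawn block-wise from a template pool.

    Each row picks, independently per ``block_snps``-marker block, one
    template according to ``frequencies``; diversity in windows aligned
    to blocks then has the closed-form expectation
    ``E[D] = 1 - sum(p_k^2)`` under the unbiased Simpson estimator.
    """

    n_rows: int
    n_blocks: int
    templates: np.ndarray           # (n_templates, block_snps) of {0,1}
    frequencies: np.ndarray
    seed: int = 0


def generate_phased(spec: PhasedPoolSpec) -> tuple[np.ndarray, MarkerMap, np.ndarray]:
    """Build (haplotypes, map, chosen-template matrix) from a pool spec."""
    freqs = np.asarray(spec.frequencies, dtype=float)
    templates = np.asarray(spec.templates, dtype=np.int8)
    if templates.ndim != 2 or len(freqs) != templates.shape[0]:
        raise ValueError("templates/frequencies shape mismatch")
    if not np.isclose(freqs.sum(), 1.0):
        raise ValueError("frequencies must sum to 1")
    rng = np.random.default_rng(spec.seed)
    block_snps = templates.shape[1]
    choice = rng.choice(len(freqs), size=(spec.n_rows, spec.n_blocks), p=freqs)
    haplotypes = templates[choice].reshape(spec.n_rows, spec.n_blocks * block_snps)
    m = spec.n_blocks * block_snps
    positions = (np.arange(m) + 1) * 1000
    marker_map = MarkerMap(pd.DataFrame({
        "chromosome": np.ones(m, dtype=int),
        "marker_id": [f"snp_{j+1}" for j in range(m)],
        "bp_pos": positions,
        "cm_pos": positions * 1e-6,
    }))
    return haplotypes, marker_map, choice
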