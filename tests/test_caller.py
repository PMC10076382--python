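"""Scanning-window ROH caller: window logic, planted tracts, invariances."""

import dataclasses

import numpy as np
import pytest

from rohscape.caller import RohParams, call_roh, summarize_roh, window_hit_fraction
from rohscape.fixtures import oracle_call_roh
from rohscape.markers_io import GENETIC, MISSING, GenotypeMatrix, RohSegment

from conftest import make_map


def brute_force_fractions(calls, params):
    """Directly enumerate every window for one individual."""
    m = len(calls)
    w = params.window_snps
    if m < w:
        return [0.0] * m
    accepted = []
    for s in range(m - w + 1):
        win = calls[s:s + w]
        accepted.append(sum(c == 1 for c in win) <= params.window_max_het
                        and sum(c == MISSING for c in win) <= params.window_max_missing)
    out = []
    for j in range(m):
        cover = [accepted[s] for s in range(m - w + 1) if s <= j < s + w]
        out.append(sum(cover) / len(cover))
    return out


class TestWindowHitFraction:
    def test_all_homozygous_gives_fraction_one(self):
        calls = np.zeros(100, dtype=np.int8)
        frac = window_hit_fraction(calls, RohParams())
        assert frac.max() == 1.0
        assert (frac == 1.0).all()

    def test_all_heterozygous_gives_zero(self):
        calls = np.ones(100, dtype=np.int8)
        frac = window_hit_fraction(calls, RohParams(window_max_het=1))
        assert (frac == 0.0).all()

    def test_single_het_matches_exhaustive_enumeration(self):
        calls = np.zeros(50, dtype=np.int8)
        calls[25] = 1
        params = RohParams(window_snps=35, window_max_het=1)
        frac = window_hit_fraction(calls, params)
        assert frac == pytest.approx(brute_force_fractions(list(calls), params))

    @pytest.mark.parametrize("seed", range(5))
    def test_random_sequences_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        calls = rng.choice([0, 1, 2, MISSING], size=80,
                           p=[0.4, 0.25, 0.3, 0.05]).astype(np.int8)
        params = RohParams(window_snps=int(rng.integers(5, 30)),
                           window_max_het=int(rng.integers(0, 3)),
                           window_max_missing=int(rng.integers(0, 4)))
        frac = window_hit_fraction(calls, params)
        assert frac == pytest.approx(brute_force_fractions(list(calls), params))

    def test_chromosome_shorter_than_window_is_all_zero(self):
        frac = window_hit_fraction(np.zeros(10, dtype=np.int8),
                                   RohParams(window_snps=35))
        assert (frac == 0.0).all()


def planted_matrix(n_markers, tract, spacing_bp=50_000, n_individuals=3,
                   seed=0, het_rate=0.35):
    """Hom/het matrix with a fully homozygous tract in individual 0."""
    rng = np.random.default_rng(seed)
    hom = rng.integers(0, 2, size=(n_individuals, n_markers)).astype(np.int8) * 2
    het = rng.random((n_individuals, n_markers)) < het_rate
    calls = np.where(het, np.int8(1), hom)
    lo, hi = tract
    calls[0, lo:hi + 1] = hom[0, lo:hi + 1]
    bp = (np.arange(n_markers) + 1) * spacing_bp
    return GenotypeMatrix(calls), make_map(bp)


class TestCallRoh:
    def test_planted_60_snp_tract_recovered_exactly_once(self):
        # 60 markers x 50 kb span 2950 kb between outermost; use 61 to pass 2500 kb
        genotypes, marker_map = planted_matrix(200, (70, 130))
        segments = call_roh(genotypes, marker_map,
                            RohParams(min_snps=40, min_length_kb=2500))
        mine = [s for s in segments if s.individual_id == "id_1"]
        assert len(mine) == 1
        seg = mine[0]
        assert seg.start_index <= 70 and seg.end_index >= 130
        assert seg.n_snps >= 60
        oracle = oracle_call_roh(genotypes, marker_map,
                                 RohParams(min_snps=40, min_length_kb=2500))
        assert [(s.start_index, s.end_index) for s in oracle] == \
            [(s.start_index, s.end_index) for s in segments]

    def test_tract_below_min_snps_not_called(self):
        genotypes, marker_map = planted_matrix(200, (70, 108))  # 39 SNPs
        params = RohParams(min_snps=40, min_length_kb=100, max_kb_per_snp=1000,
                           window_snps=20)
        segments = call_roh(genotypes, marker_map, params)
        # every called segment must respect the SNP minimum
        assert all(s.n_snps >= 40 for s in segments)
        assert oracle_call_roh(genotypes, marker_map, params) == segments

    def test_tract_below_min_length_not_called(self):
        # 60 SNPs x 25 kb spacing -> ~1500 kb < 2500 kb
        genotypes, marker_map = planted_matrix(200, (70, 130), spacing_bp=25_000)
        segments = call_roh(genotypes, marker_map,
                            RohParams(min_snps=40, min_length_kb=2500))
        assert segments == []

    def test_density_filter_rejects_sparse_segments(self):
        # 50 markers spaced 100 kb -> 100 kb per SNP > 70
        genotypes, marker_map = planted_matrix(60, (0, 59), spacing_bp=100_000,
                                               n_individuals=1, het_rate=0.0)
        params = RohParams(min_snps=40, min_length_kb=2500, max_kb_per_snp=70)
        assert call_roh(genotypes, marker_map, params) == []
        loose = dataclasses.replace(params, max_kb_per_snp=150)
        assert len(call_roh(genotypes, marker_map, loose)) == 1

    def test_gap_splitting(self):
        # homozygous chromosome with a 2 Mb hole in the middle
        calls = np.zeros((1, 120), dtype=np.int8)
        bp = np.concatenate([(np.arange(60) + 1) * 50_000,
                             5_000_000 + (np.arange(60) + 1) * 50_000])
        marker_map = make_map(bp)
        params = RohParams(min_snps=40, min_length_kb=2000, max_gap_kb=1000)
        segments = call_roh(GenotypeMatrix(calls), marker_map, params)
        assert len(segments) == 2
        assert all(s.length_kb < 3000 for s in segments)

    def test_hom_code_swap_invariance(self, planted_dataset):
        genotypes, marker_map, _ = planted_dataset
        swapped = genotypes.calls.copy()
        swapped[genotypes.calls == 0] = 2
        swapped[genotypes.calls == 2] = 0
        a = call_roh(genotypes, marker_map)
        b = call_roh(GenotypeMatrix(swapped, genotypes.individual_ids), marker_map)
        assert [(s.individual_id, s.start_index, s.end_index) for s in a] == \
            [(s.individual_id, s.start_index, s.end_index) for s in b]

    @pytest.mark.parametrize("field,looser,tighter", [
        ("min_snps", 30, 60), ("min_length_kb", 1500.0, 3500.0)])
    def test_raising_thresholds_never_adds_segments(self, planted_dataset,
                                                    field, looser, tighter):
        genotypes, marker_map, _ = planted_dataset
        base = RohParams()
        n_loose = len(call_roh(genotypes, marker_map,
                               dataclasses.replace(base, **{field: looser})))
        n_tight = len(call_roh(genotypes, marker_map,
                               dataclasses.replace(base, **{field: tighter})))
        assert n_tight <= n_loose

    def test_genetic_map_with_one_cm_per_mb_equals_physical(self, planted_dataset):
        genotypes, marker_map, _ = planted_dataset  # cm_pos == bp_pos * 1e-6
        phys = call_roh(genotypes, marker_map, RohParams())
        gen = call_roh(genotypes, marker_map,
                       RohParams(coordinate_system=GENETIC))
        assert [(s.start_index, s.end_index) for s in phys] == \
            [(s.start_index, s.end_index) for s in gen]
        for p, g in zip(phys, gen):
            assert g.length_kb == pytest.approx(p.length_kb)
            # genetic positions are cM x 1e3 = bp / 1000 under 1 cM = 1 Mb
            assert g.start_pos == pytest.approx(p.start_pos / 1000)

    def test_unsorted_map_rejected(self, small_genotypes, small_map):
        bad = small_map.table.copy()
        bad.loc[2, "bp_pos"] = bad.loc[1, "bp_pos"] - 1
        from rohscape.markers_io import MarkerMap
        with pytest.raises(ValueError, match="sorted"):
            call_roh(small_genotypes, MarkerMap(bad), RohParams())

    def test_segment_het_curtailment_matches_oracle(self):
        genotypes, marker_map = planted_matrix(200, (60, 140))
        calls = genotypes.calls.copy()
        calls[0, 100] = 1  # het inside the tract
        genotypes = GenotypeMatrix(calls, genotypes.individual_ids)
        params = RohParams(min_snps=30, min_length_kb=1000, segment_max_het=0)
        segments = call_roh(genotypes, marker_map, params)
        assert oracle_call_roh(genotypes, marker_map, params) == segments
        mine = [s for s in segments if s.individual_id == "id_1"]
        assert all(not (s.start_index <= 100 <= s.end_index) for s in mine)


class TestSummarize:
    def test_no_segments(self):
        s = summarize_roh([], 10)
        assert (s.mean_per_individual, s.min_per_individual,
                s.max_per_individual) == (0.0, 0, 0)

    def test_hand_counted_means(self):
        def seg(ind, start):
            return RohSegment(ind, 1, start, start + 49, start * 1e5,
                              start * 1e5 + 3e6, 50, 3000.0, "physical")
        segments = ([seg("a", 1)] + [seg("b", 1), seg("b", 60)]
                    + [seg("c", 1), seg("c", 60), seg("c", 120)])
        s = summarize_roh(segments, 3, ["a", "b", "c"])
        assert s.mean_per_individual == pytest.approx(2.0)
        assert (s.min_per_individual, s.max_per_individual) == (1, 3)
        assert s.mean_length_kb == pytest.approx(3000.0)
        assert s.mean_kb_per_individual == pytest.approx(6000.0)

    def test_zero_individuals_rejected(self):
        with pytest.raises(ValueError):
            summarize_roh([], 0)
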