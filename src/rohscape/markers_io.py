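"""Genotype, marker-map and ROH-table I/O in PLINK-compatible layouts.

Genotypes are held as a dense individuals x markers matrix of diploid
calls coded 0 (hom-ref), 1 (het), 2 (hom-alt) and :data:`MISSING`.
Allele polarity (which homozygote is "ref") is arbitrary for ROH
purposes; both homozygote codes are treated identically downstream.

Marker maps carry both a physical (bp) and a genetic (cM) coordinate per
marker. When a map file provides no usable cM column, genetic positions
default to ``bp * 1e-6`` (the 1 Mb ~ 1 cM convention for red deer).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing diploid call (both alleles unknown).
MISSING: int = -1

#: Autosome count of the red deer karyotype; maps may override.
DEFAULT_N_AUTOSOMES: int = 33

PHYSICAL = "physical"
GENETIC = "genetic"


class FormatError(ValueError):
    """Raised when genotype/map files are inconsistent or malformed."""


@dataclass
class MarkerMap:
    """Per-marker chromosome, identifier, physical and genetic position.

    The backing table is sorted by (chromosome, bp_pos); within a
    chromosome bp positions are strictly increasing and cM positions
    non-decreasing.
    """

    table: pd.DataFrame  # columns: chromosome, marker_id, bp_pos, cm_pos
    n_autosomes: int = DEFAULT_N_AUTOSOMES

    def __post_init__(self) -> None:
        required = ["chromosome", "marker_id", "bp_pos", "cm_pos"]
        missing_cols = [c for c in required if c not in self.table.columns]
        if missing_cols:
            raise FormatError(f"marker map lacks columns {missing_cols}")
        self.table = self.table.reset_index(drop=True)

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> np.ndarray:
        return self.table["chromosome"].to_numpy()

    @property
    def bp_pos(self) -> np.ndarray:
        return self.table["bp_pos"].to_numpy()

    @property
    def cm_pos(self) -> np.ndarray:
        return self.table["cm_pos"].to_numpy()

    @property
    def marker_ids(self) -> np.ndarray:
        return self.table["marker_id"].to_numpy()

    def positions_kb(self, coordinate_system: str = PHYSICAL) -> np.ndarray:
        """Marker positions on the kb scale used for ROH thresholds.

        Physical coordinates are bp / 1000; genetic coordinates are
        cM * 1000, i.e. the pseudo-physical map in which every
        kb-denominated threshold applies unchanged (1 cM = 1 "Mb").
        """
        if coordinate_system == PHYSICAL:
            return self.bp_pos.astype(float) / 1000.0
        if coordinate_system == GENETIC:
            return self.cm_pos.astype(float) * 1000.0
        raise ValueError(f"unknown coordinate system {coordinate_system!r}")

    def chromosome_slices(self) -> list[tuple[int, slice]]:
        """(chromosome, row-slice) pairs in table order."""
        chroms = self.chromosomes
        out = []
        if len(chroms) == 0:
            return out
        starts = np.flatnonzero(np.r_[True, chroms[1:] != chroms[:-1]])
        bounds = np.r_[starts, len(chroms)]
        for i, s in enumerate(starts):
            out.append((int(chroms[s]), slice(int(s), int(bounds[i + 1]))))
        return out

    def subset(self, mask: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.table.loc[np.asarray(mask, bool)].reset_index(drop=True),
                         n_autosomes=self.n_autosomes)


@dataclass
class GenotypeMatrix:
    """Dense diploid genotype calls, individuals x markers."""

    calls: np.ndarray  # int8, codes {0, 1, 2, MISSING}
    individual_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise FormatError("genotype matrix must be 2-D")
        if not self.individual_ids:
            self.individual_ids = [f"id_{i+1}" for i in range(self.calls.shape[0])]
        if len(self.individual_ids) != self.calls.shape[0]:
            raise FormatError("individual_ids length does not match matrix rows")
        valid = np.isin(self.calls, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.calls[~valid])
            raise FormatError(f"invalid genotype codes {bad.tolist()}")

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def subset_markers(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.calls[:, np.asarray(mask, bool)],
                              list(self.individual_ids))


@dataclass
class RohSegment:
    """One called run of homozygosity.

    ``start_pos``/``end_pos`` are in the coordinate system used for the
    call: bp for physical coordinates, cM x 1e3 ("kb-equivalents") for
    genetic coordinates. ``length_kb`` is end - start on the kb scale,
    with no +1, matching PLINK's KB column.
    """

    individual_id: str
    chromosome: int
    start_index: int
    end_index: int  # inclusive marker indices into the chromosome-wide map
    start_pos: float
    end_pos: float
    n_snps: int
    length_kb: float
    coordinate_system: str = PHYSICAL


ROH_TABLE_COLUMNS = [
    "individual_id", "chromosome", "start_index", "end_index",
    "start_pos", "end_pos", "n_snps", "length_kb", "coordinate_system",
]


# ---------------------------------------------------------------------------
# Map handling


def _finalize_map(table: pd.DataFrame, n_autosomes: int) -> MarkerMap:
    """Sort, restrict to autosomes and enforce position invariants."""
    table = table.copy()
    table["chromosome"] = pd.to_numeric(table["chromosome"], errors="coerce")
    non_auto = ~table["chromosome"].between(1, n_autosomes)
    if non_auto.any():
        warnings.warn(
            f"dropping {int(non_auto.sum())} markers on non-autosomal "
            f"chromosome labels", stacklevel=2)
        table = table[~non_auto]
    table["chromosome"] = table["chromosome"].astype(int)

    if (table["cm_pos"] == 0).all() and len(table) > 0:
        table["cm_pos"] = table["bp_pos"] * 1e-6  # 1 Mb ~ 1 cM default

    table = table.sort_values(["chromosome", "bp_pos"], kind="mergesort")
    dup = table.duplicated(subset=["chromosome", "bp_pos"])
    if dup.any():
        warnings.warn(f"dropping {int(dup.sum())} markers with duplicate bp "
                      f"positions", stacklevel=2)
        table = table[~dup]
    # reject markers whose cM position runs backwards within a chromosome
    keep = np.ones(len(table), dtype=bool)
    for _, idx in table.groupby("chromosome", sort=False).groups.items():
        cm = table.loc[idx, "cm_pos"].to_numpy(float)
        running = -np.inf
        for j, v in enumerate(cm):
            if v >= running:
                running = v
            else:
                keep[table.index.get_indexer(idx)[j]] = False
    keep = pd.Series(keep, index=table.index)
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} markers with "
                      f"non-monotone cM positions", stacklevel=2)
        table = table[keep]
    return MarkerMap(table.reset_index(drop=True), n_autosomes=n_autosomes)


def read_map(map_path: str | Path, n_autosomes: int = DEFAULT_N_AUTOSOMES) -> MarkerMap:
    """Read a PLINK .map/.bim file (chrom, id, cM, bp [, alleles])."""
    table = pd.read_csv(map_path, sep=r"\s+", header=None, comment="#")
    if table.shape[1] < 4:
        raise FormatError(f"{map_path}: expected >= 4 columns, got {table.shape[1]}")
    table = table.iloc[:, :4]
    table.columns = ["chromosome", "marker_id", "cm_pos", "bp_pos"]
    table["marker_id"] = table["marker_id"].astype(str)
    return _finalize_map(table[["chromosome", "marker_id", "bp_pos", "cm_pos"]],
                         n_autosomes)


def merge_linkage_map(marker_map: MarkerMap, linkage_path: str | Path) -> MarkerMap:
    """Merge a sidecar linkage-map table (chromosome, marker_id, cM) by id."""
    link = pd.read_csv(linkage_path, sep=r"\s+", header=None, comment="#",
                       names=["chromosome", "marker_id", "cm_pos"])
    link["marker_id"] = link["marker_id"].astype(str)
    table = marker_map.table.drop(columns="cm_pos").merge(
        link[["marker_id", "cm_pos"]], on="marker_id", how="left")
    n_missing = int(table["cm_pos"].isna().sum())
    if n_missing:
        warnings.warn(f"{n_missing} markers absent from linkage map; "
                      f"falling back to bp*1e-6", stacklevel=2)
        fallback = table["bp_pos"] * 1e-6
        table["cm_pos"] = table["cm_pos"].fillna(fallback)
    return _finalize_map(table, marker_map.n_autosomes)


# ---------------------------------------------------------------------------
# PLINK text (.ped/.map)


def _ped_alleles_to_calls(allele_a: np.ndarray, allele_b: np.ndarray) -> np.ndarray:
    """Code one marker's allele pairs as 0/1/2/MISSING.

    The lexicographically smaller observed allele is taken as "ref";
    polarity is arbitrary and irrelevant for homozygosity.
    """
    n = len(allele_a)
    calls = np.full(n, MISSING, dtype=np.int8)
    missing = (allele_a == "0") | (allele_b == "0")
    observed = sorted(set(allele_a[~missing]) | set(allele_b[~missing]))
    if len(observed) > 2:
        raise FormatError(f"marker has {len(observed)} alleles: {observed}")
    if not observed:
        return calls
    ref = observed[0]
    dose = (allele_a != ref).astype(np.int8) + (allele_b != ref).astype(np.int8)
    calls[~missing] = dose[~missing]
    return calls


def read_plink_text(ped_path: str | Path, map_path: str | Path,
                    n_autosomes: int = DEFAULT_N_AUTOSOMES,
                    ) -> tuple[GenotypeMatrix, MarkerMap]:
    raw_map = pd.read_csv(map_path, sep=r"\s+", header=None, comment="#")
    n_markers_file = len(raw_map)
    marker_map = read_map(map_path, n_autosomes=n_autosomes)

    ids: list[str] = []
    rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for line_no, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_markers_file:
                raise FormatError(
                    f"{ped_path}:{line_no}: expected {6 + 2 * n_markers_file} "
                    f"fields, got {len(fields)}")
            ids.append(fields[1])
            rows.append(np.array(fields[6:], dtype="U8"))
    if not rows:
        raise FormatError(f"{ped_path}: no individuals")
    alleles = np.stack(rows)  # individuals x (2*n_markers)
    calls = np.empty((len(ids), n_markers_file), dtype=np.int8)
    for j in range(n_markers_file):
        calls[:, j] = _ped_alleles_to_calls(alleles[:, 2 * j], alleles[:, 2 * j + 1])

    calls = _reorder_to_map(calls, raw_map, marker_map)
    return GenotypeMatrix(calls, ids), marker_map


def _reorder_to_map(calls: np.ndarray, raw_map: pd.DataFrame,
                    marker_map: MarkerMap) -> np.ndarray:
    """Reorder/subset genotype columns to match the finalized map."""
    raw_ids = raw_map.iloc[:, 1].astype(str).to_numpy()
    index = {mid: j for j, mid in enumerate(raw_ids)}
    cols = [index[mid] for mid in marker_map.marker_ids]
    return np.ascontiguousarray(calls[:, cols])


def write_plink_text(genotypes: GenotypeMatrix, marker_map: MarkerMap,
                     ped_path: str | Path, map_path: str | Path) -> None:
    if genotypes.n_markers != marker_map.n_markers:
        raise FormatError("genotype/map dimension mismatch")
    with open(map_path, "w") as fh:
        for rec in marker_map.table.itertuples(index=False):
            fh.write(f"{rec.chromosome}\t{rec.marker_id}\t{rec.cm_pos:.8g}\t"
                     f"{int(rec.bp_pos)}\n")
    pair = {0: "A A", 1: "A B", 2: "B B", MISSING: "0 0"}
    with open(ped_path, "w") as fh:
        for i, ind in enumerate(genotypes.individual_ids):
            geno = " ".join(pair[int(c)] for c in genotypes.calls[i])
            fh.write(f"FAM {ind} 0 0 0 -9 {geno}\n")


# ---------------------------------------------------------------------------
# PLINK binary (.bed/.bim/.fam), standard SNP-major 2-bit encoding

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit codes: 00 hom A1, 01 missing, 10 het, 11 hom A2.
# With A1 = "B" (alt) and A2 = "A" (ref): 00 -> 2, 01 -> MISSING, 10 -> 1, 11 -> 0
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0, MISSING: 1, 1: 2, 0: 3}


def read_plink_binary(bed_path: str | Path, bim_path: str | Path,
                      fam_path: str | Path,
                      n_autosomes: int = DEFAULT_N_AUTOSOMES,
                      ) -> tuple[GenotypeMatrix, MarkerMap]:
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None)
    ids = fam.iloc[:, 1].astype(str).tolist()
    n_ind = len(ids)
    raw_bim = pd.read_csv(bim_path, sep=r"\s+", header=None)
    marker_map = read_map(bim_path, n_autosomes=n_autosomes)
    n_markers_file = len(raw_bim)

    data = Path(bed_path).read_bytes()
    if data[:3] != _BED_MAGIC:
        raise FormatError(f"{bed_path}: not a SNP-major PLINK .bed file")
    bytes_per_marker = (n_ind + 3) // 4
    body = np.frombuffer(data, dtype=np.uint8, offset=3)
    if len(body) != bytes_per_marker * n_markers_file:
        raise FormatError(f"{bed_path}: size inconsistent with "
                          f"{n_ind} individuals x {n_markers_file} markers")
    body = body.reshape(n_markers_file, bytes_per_marker)
    # unpack 2-bit fields, little-endian within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    two_bit = (body[:, :, None] >> shifts) & 0b11  # markers x bytes x 4
    two_bit = two_bit.reshape(n_markers_file, -1)[:, :n_ind]
    calls = _BED_DECODE[two_bit].T  # individuals x markers
    calls = _reorder_to_map(np.ascontiguousarray(calls), raw_bim, marker_map)
    return GenotypeMatrix(calls, ids), marker_map


def write_plink_binary(genotypes: GenotypeMatrix, marker_map: MarkerMap,
                       bed_path: str | Path, bim_path: str | Path,
                       fam_path: str | Path) -> None:
    if genotypes.n_markers != marker_map.n_markers:
        raise FormatError("genotype/map dimension mismatch")
    with open(fam_path, "w") as fh:
        for ind in genotypes.individual_ids:
            fh.write(f"FAM {ind} 0 0 0 -9\n")
    with open(bim_path, "w") as fh:
        for rec in marker_map.table.itertuples(index=False):
            fh.write(f"{rec.chromosome}\t{rec.marker_id}\t{rec.cm_pos:.8g}\t"
                     f"{int(rec.bp_pos)}\tB\tA\n")
    n_ind = genotypes.n_individuals
    codes = np.empty_like(genotypes.calls, dtype=np.uint8)
    for call, code in _BED_ENCODE.items():
        codes[genotypes.calls == call] = code
    pad = (-n_ind) % 4
    if pad:
        codes = np.vstack([codes, np.full((pad, genotypes.n_markers),
                                          _BED_ENCODE[0], dtype=np.uint8)])
    codes = codes.T.reshape(genotypes.n_markers, -1, 4)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (codes << shifts).sum(axis=2).astype(np.uint8)
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_genotypes(genotype_path: str | Path, map_path: str | Path | None = None,
                   fam_path: str | Path | None = None,
                   linkage_map_path: str | Path | None = None,
                   n_autosomes: int = DEFAULT_N_AUTOSOMES,
                   ) -> tuple[GenotypeMatrix, MarkerMap]:
    """Read genotypes + map, dispatching on the PLINK dialect by suffix."""
    genotype_path = Path(genotype_path)
    if genotype_path.suffix == ".bed":
        bim = Path(map_path) if map_path else genotype_path.with_suffix(".bim")
        fam = Path(fam_path) if fam_path else genotype_path.with_suffix(".fam")
        genotypes, marker_map = read_plink_binary(genotype_path, bim, fam,
                                                  n_autosomes=n_autosomes)
    else:
        map_file = Path(map_path) if map_path else genotype_path.with_suffix(".map")
        genotypes, marker_map = read_plink_text(genotype_path, map_file,
                                                n_autosomes=n_autosomes)
    if linkage_map_path is not None:
        marker_map = merge_linkage_map(marker_map, linkage_map_path)
    return genotypes, marker_map


# ---------------------------------------------------------------------------
# ROH tables (PLINK .hom-style, tab separated)


def write_roh_table(segments: list[RohSegment], path: str | Path) -> None:
    frame = pd.DataFrame(
        [[s.individual_id, s.chromosome, s.start_index, s.end_index,
          s.start_pos, s.end_pos, s.n_snps, s.length_kb, s.coordinate_system]
         for s in segments],
        columns=ROH_TABLE_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)


def read_roh_table(path: str | Path) -> list[RohSegment]:
    frame = pd.read_csv(path, sep="\t", dtype={"individual_id": str},
                        float_precision="round_trip")
    segments = []
    for rec in frame.itertuples(index=False):
        segments.append(RohSegment(
            individual_id=str(rec.individual_id), chromosome=int(rec.chromosome),
            start_index=int(rec.start_index), end_index=int(rec.end_index),
            start_pos=float(rec.start_pos), end_pos=float(rec.end_pos),
            n_snps=int(rec.n_snps), length_kb=float(rec.length_kb),
            coordinate_system=str(rec.coordinate_system)))
    return segments


# ---------------------------------------------------------------------------
# Marker filters


def allele_frequencies(genotypes: GenotypeMatrix) -> np.ndarray:
    """Alt-allele frequency per marker over non-missing calls (NaN if none)."""
    calls = genotypes.calls
    known = calls != MISSING
    n_known = known.sum(axis=0)
    dose = np.where(known, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = dose / (2.0 * n_known)
    return np.where(n_known > 0, freq, np.nan)


def apply_maf_filter(genotypes: GenotypeMatrix, marker_map: MarkerMap,
                     min_maf: float) -> tuple[GenotypeMatrix, MarkerMap]:
    """Drop markers with minor-allele frequency below ``min_maf``.

    Markers with all calls missing are dropped regardless (and logged).
    ``min_maf = 0`` keeps every marker that has at least one call.
    """
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    freq = allele_frequencies(genotypes)
    all_missing = np.isnan(freq)
    if all_missing.any():
        logger.info("removing %d markers with no non-missing calls",
                    int(all_missing.sum()))
    maf = np.minimum(freq, 1.0 - freq)
    keep = ~all_missing & ((maf >= min_maf) | (min_maf == 0.0))
    return genotypes.subset_markers(keep), marker_map.subset(keep)


def apply_missingness_filter(genotypes: GenotypeMatrix, marker_map: MarkerMap,
                             max_missing_rate: float,
                             ) -> tuple[GenotypeMatrix, MarkerMap]:
    """Drop markers whose fraction of missing calls exceeds the threshold."""
    miss_rate = (genotypes.calls == MISSING).mean(axis=0)
    keep = miss_rate <= max_missing_rate
    return genotypes.subset_markers(keep), marker_map.subset(keep)
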