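"""Runs of homozygosity: sliding-window scanner, F_ROH, incidence, islands,
and LD decay.

The scanner reimplements the classic 50-SNP sliding-window ROH detection:
a window is "homozygous" when it contains at most ``window_het``
heterozygous and ``window_missing`` missing calls; each SNP's hit fraction
is the proportion of windows covering it that are homozygous, and SNPs at
or above ``window_threshold`` are ROH-eligible.  Maximal runs of eligible,
non-heterozygous SNPs become segments, split wherever the gap between
consecutive SNPs exceeds ``max_gap_kb``, then filtered on SNP count,
physical length and (optionally) SNP density.  Segment coordinates are the
positions of the first and last SNP of the run.

F_ROH is total ROH length divided by total autosome length
(930.82 Mb by default, the chicken autosome size).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, logger
from .snp_filtering import offset_r2

#: Total chicken autosome length in bp used for F_ROH.
DEFAULT_GENOME_SIZE_BP = 930_820_000


@dataclass
class ROHParams:
    window_snps: int = 50
    window_het: int = 1
    window_missing: int = 5
    window_threshold: float = 0.05
    max_gap_kb: float = 1000.0
    min_snps_per_segment: int = 50
    min_length_kb: float = 1000.0
    max_density_kb_per_snp: float | None = None  # disabled: sparse panels
    genome_size_bp: int = DEFAULT_GENOME_SIZE_BP

    def __post_init__(self):
        if self.window_snps < 1 or self.window_het < 0 or self.window_missing < 0:
            raise ValueError("window counts must be non-negative (window_snps >= 1)")
        if not 0 < self.window_threshold <= 1:
            raise ValueError("window_threshold must be in (0,1]")
        if self.genome_size_bp <= 0:
            raise ValueError("genome_size_bp must be positive")


@dataclass
class ROHSegment:
    sample_id: str
    chrom: str
    start_pos: int  # 1-based inclusive
    end_pos: int
    n_snps: int

    def __post_init__(self):
        if self.end_pos < self.start_pos:
            raise ValueError("segment end before start")

    @property
    def length_bp(self) -> int:
        return self.end_pos - self.start_pos + 1

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1000.0


@dataclass
class ROHIncidence:
    """Per-locus carrier counts over all individuals."""

    loci: pd.DataFrame = field(repr=False)
    carriers: np.ndarray = field(repr=False)
    n_individuals: int = 0

    @property
    def incidence_pct(self) -> np.ndarray:
        return 100.0 * self.carriers / self.n_individuals

    def to_frame(self) -> pd.DataFrame:
        out = self.loci[["chrom", "pos", "id"]].copy()
        out["carriers"] = self.carriers
        out["incidence_pct"] = self.incidence_pct
        return out


# ---------------------------------------------------------------------------
# Scanner
# ---------------------------------------------------------------------------


def _sliding_sum(x: np.ndarray, w: int) -> np.ndarray:
    """Sums of every length-w window of x (len(x)-w+1 values)."""
    c = np.concatenate(([0], np.cumsum(x)))
    return c[w:] - c[:-w]


def _scan_chromosome(
    codes: np.ndarray, pos: np.ndarray, params: ROHParams
) -> list[tuple[int, int, int]]:
    """Scan one individual x chromosome; codes: 0 hom, 1 het, 2 missing.

    Returns (start_idx, end_idx, n_snps) runs before segment-level filters.
    """
    L = codes.size
    w = min(params.window_snps, L)  # truncated single window on short chroms
    het = (codes == 1).astype(np.int64)
    mis = (codes == 2).astype(np.int64)
    het_c = _sliding_sum(het, w)
    mis_c = _sliding_sum(mis, w)
    ok = (het_c <= params.window_het) & (mis_c <= params.window_missing)

    n_win = L - w + 1
    # SNP i is covered by windows max(0, i-w+1) .. min(i, n_win-1)
    ok_cum = np.concatenate(([0], np.cumsum(ok)))
    i = np.arange(L)
    lo = np.maximum(0, i - w + 1)
    hi = np.minimum(i, n_win - 1)
    n_cov = hi - lo + 1
    n_ok = ok_cum[hi + 1] - ok_cum[lo]
    eligible = (n_ok / n_cov) >= params.window_threshold

    in_run = eligible & (codes != 1)
    max_gap_bp = params.max_gap_kb * 1000.0
    runs: list[tuple[int, int, int]] = []
    idxs = np.flatnonzero(in_run)
    if idxs.size == 0:
        return runs
    start = prev = int(idxs[0])
    for idx in idxs[1:]:
        idx = int(idx)
        # break on any intervening non-eligible/het SNP or oversized gap
        if idx - prev > 1 or (pos[idx] - pos[prev]) > max_gap_bp:
            runs.append((start, prev, prev - start + 1))
            start = idx
        prev = idx
    runs.append((start, prev, prev - start + 1))
    return runs


def scan_roh(gm: GenotypeMatrix, params: ROHParams | None = None) -> list[ROHSegment]:
    """Detect ROH segments for every individual in *gm*.

    Segments never overlap within an individual and never span chromosomes.
    Chromosomes shorter than the window are scanned with a single truncated
    window (logged once).
    """
    params = params or ROHParams()
    chroms = gm.loci["chrom"].to_numpy()
    pos_all = gm.loci["pos"].to_numpy()
    chrom_order = list(dict.fromkeys(chroms))
    short = [c for c in chrom_order if (chroms == c).sum() < params.window_snps]
    if short:
        logger.info("scan_roh: %d chromosomes shorter than the window: %s",
                    len(short), short)
    segments: list[ROHSegment] = []
    for chrom in chrom_order:
        cidx = np.flatnonzero(chroms == chrom)
        pos = pos_all[cidx]
        block = gm.calls[:, cidx]
        codes = np.where(block == MISSING, 2, np.where(block == 1, 1, 0))
        for s, sample_id in enumerate(gm.sample_ids):
            for start, end, n_snps in _scan_chromosome(codes[s], pos, params):
                seg = ROHSegment(
                    sample_id, str(chrom), int(pos[start]), int(pos[end]), n_snps
                )
                if seg.n_snps < params.min_snps_per_segment:
                    continue
                if seg.length_kb < params.min_length_kb:
                    continue
                if (
                    params.max_density_kb_per_snp is not None
                    and seg.length_kb / seg.n_snps > params.max_density_kb_per_snp
                ):
                    continue
                segments.append(seg)
    return segments


def segments_to_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "chrom": s.chrom,
                "start_pos": s.start_pos,
                "end_pos": s.end_pos,
                "n_snps": s.n_snps,
                "length_kb": s.length_kb,
            }
            for s in segments
        ],
        columns=["sample_id", "chrom", "start_pos", "end_pos", "n_snps", "length_kb"],
    )


def segments_to_bed(segments: list[ROHSegment], path) -> None:
    """BED4 export; converts 1-based inclusive to 0-based half-open."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start_pos - 1}\t{s.end_pos}\t{s.sample_id}\n")


# ---------------------------------------------------------------------------
# F_ROH and incidence
# ---------------------------------------------------------------------------


def f_roh(
    segments: list[ROHSegment], sample_id: str, params: ROHParams | None = None
) -> float:
    """Genomic inbreeding coefficient: total ROH length / genome size."""
    params = params or ROHParams()
    own = [s for s in segments if s.sample_id == sample_id]
    by_chrom: dict[str, list[ROHSegment]] = {}
    for s in own:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, segs in by_chrom.items():
        segs.sort(key=lambda s: s.start_pos)
        for a, b in zip(segs, segs[1:]):
            if b.start_pos <= a.end_pos:
                raise ValueError(
                    f"overlapping ROH segments for {sample_id} on {chrom}"
                )
    return sum(s.length_bp for s in own) / params.genome_size_bp


def f_roh_table(
    gm: GenotypeMatrix, segments: list[ROHSegment], params: ROHParams | None = None
) -> pd.DataFrame:
    """Per-sample F_ROH with population labels."""
    params = params or ROHParams()
    rows = []
    for _, s in gm.samples.iterrows():
        rows.append(
            {
                "sample_id": s["sample_id"],
                "population": s["population"],
                "f_roh": f_roh(segments, s["sample_id"], params),
            }
        )
    return pd.DataFrame(rows)


def roh_incidence(segments: list[ROHSegment], gm: GenotypeMatrix) -> ROHIncidence:
    """Count, per locus, the individuals whose ROH cover it.

    The denominator is every individual in the dataset, consistent with
    incidence percentages computed over the full sample.
    """
    chroms = gm.loci["chrom"].to_numpy()
    pos_all = gm.loci["pos"].to_numpy()
    carriers = np.zeros(gm.n_loci, dtype=np.int64)
    chrom_pos: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in dict.fromkeys(chroms):
        cidx = np.flatnonzero(chroms == chrom)
        chrom_pos[str(chrom)] = (pos_all[cidx], cidx)
    for seg in segments:
        if seg.chrom not in chrom_pos:
            continue
        pos, cidx = chrom_pos[seg.chrom]
        lo = np.searchsorted(pos, seg.start_pos, side="left")
        hi = np.searchsorted(pos, seg.end_pos, side="right")
        carriers[cidx[lo:hi]] += 1
    return ROHIncidence(gm.loci, carriers, gm.n_samples)


def roh_islands(incidence: ROHIncidence, top_fraction: float = 0.01) -> np.ndarray:
    """Locus indices in the top *top_fraction* of ROH incidence.

    The threshold is the ``1 - top_fraction`` quantile; ties at the
    threshold are all included, so with constant incidence every locus is
    returned.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0,1)")
    pct = incidence.incidence_pct
    thr = np.quantile(pct, 1 - top_fraction)
    return np.flatnonzero(pct >= thr)


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------


def ld_decay(
    gm: GenotypeMatrix,
    pop: str,
    max_dist_kb: float = 1000.0,
    bin_kb: float = 100.0,
) -> pd.DataFrame:
    """Mean pairwise r^2 per physical-distance bin within a population.

    Considers every intra-chromosomal locus pair closer than *max_dist_kb*;
    r^2 is the squared genotypic correlation over pairwise-complete samples.
    Returns columns ``bin_start_kb, bin_end_kb, n_pairs, mean_r2``.
    """
    sidx = gm.sample_indices(pop)
    calls = gm.calls[sidx, :]
    chroms = gm.loci["chrom"].to_numpy()
    pos_all = gm.loci["pos"].to_numpy().astype(float)
    max_bp = max_dist_kb * 1000.0
    n_bins = int(np.ceil(max_dist_kb / bin_kb))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for chrom in dict.fromkeys(chroms):
        cidx = np.flatnonzero(chroms == chrom)
        pos = pos_all[cidx]
        L = cidx.size
        for k in range(1, L):
            dist = pos[k:] - pos[:-k]
            within = dist <= max_bp
            if not within.any():
                break
            sel = np.flatnonzero(within)
            r2 = offset_r2(calls, cidx[sel], cidx[sel + k])
            bins = np.minimum((dist[sel] / 1000.0 / bin_kb).astype(int), n_bins - 1)
            np.add.at(sums, bins, r2)
            np.add.at(counts, bins, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_start_kb": np.arange(n_bins) * bin_kb,
            "bin_end_kb": (np.arange(n_bins) + 1) * bin_kb,
            "n_pairs": counts,
            "mean_r2": mean_r2,
        }
    )
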