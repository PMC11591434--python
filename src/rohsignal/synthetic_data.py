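"""Synthetic genotype datasets with known truth.

Emulates the statistical structure of a multi-population reduced-
representation SNP panel: ~11 populations of 7-16 diploid individuals,
~12,000 bi-allelic autosomal SNPs spread over ~930.82 Mb, population
divergence under the Balding-Nichols model (a direct Fst parameter),
missing genotypes, per-population inbreeding implanted as long runs of
homozygosity, and optional planted loci that are simultaneously high-Fst
and inside a population-shared ROH island.  Every artefact the generator
plants is echoed into a machine-readable truth object so estimators can be
tested for parameter recovery.

All randomness flows from one integer seed through numpy's PCG64
generator, so outputs are byte-for-byte reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    PopulationMap,
    write_popmap,
    write_vcf,
)

#: Default chromosome lengths (bp): ten chicken-like macrochromosomes scaled
#: to a 930.82 Mb autosomal total.
DEFAULT_CHROM_LENGTHS: dict[str, int] = {}
_weights = [196, 149, 110, 90, 60, 36, 36, 30, 24, 21]
_total = sum(_weights)
for _i, _w in enumerate(_weights, 1):
    DEFAULT_CHROM_LENGTHS[str(_i)] = int(round(930_820_000 * _w / _total))

#: Study-scale defaults: 11 populations, 119 individuals.
DEFAULT_POP_SIZES = [8, 12, 12, 10, 11, 10, 7, 12, 11, 16, 10]
#: Per-population Balding-Nichols divergence; spans weakly diverged breeds
#: to a highly drifted inbred line.
DEFAULT_TARGET_FST = [0.15, 0.20, 0.10, 0.25, 0.20, 0.20, 0.30, 0.15, 0.80, 0.50, 0.20]
#: Per-population genomic ROH fraction; near-zero to inbred-line levels.
DEFAULT_F_ROH = [0.10, 0.12, 0.02, 0.15, 0.12, 0.10, 0.18, 0.03, 0.45, 0.35, 0.03]


@dataclass
class IslandSpec:
    """A genomic interval forced homozygous in a fraction of individuals."""

    chrom: str
    start: int
    end: int
    carrier_fraction: float = 0.5
    n_carriers: int | None = None  # overrides the fraction when set

    def __post_init__(self):
        if self.end < self.start or self.start < 1:
            raise ValueError("island interval invalid")


@dataclass
class SimConfig:
    n_pops: int = 11
    n_ind_per_pop: list[int] = field(default_factory=lambda: list(DEFAULT_POP_SIZES))
    n_loci: int = 12000
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS)
    )
    target_fst: list[float] | float = field(
        default_factory=lambda: list(DEFAULT_TARGET_FST)
    )
    f_roh_target: list[float] | float = field(
        default_factory=lambda: list(DEFAULT_F_ROH)
    )
    missing_rate: float = 0.02
    n_outlier_loci: int = 0
    outlier_divergence_multiplier: float = 5.0
    outliers_in_island: bool = False
    planted_islands: list[IslandSpec] = field(default_factory=list)
    roh_length_range_mb: tuple[float, float] = (5.0, 20.0)
    ld_block_snps: int = 1  # >1 samples loci in haplotype-pool blocks
    ld_pool_size: int = 4
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.target_fst, (int, float)):
            self.target_fst = [float(self.target_fst)] * self.n_pops
        if isinstance(self.f_roh_target, (int, float)):
            self.f_roh_target = [float(self.f_roh_target)] * self.n_pops
        if len(self.n_ind_per_pop) != self.n_pops:
            raise ValueError("n_ind_per_pop length must equal n_pops")
        if len(self.target_fst) != self.n_pops or len(self.f_roh_target) != self.n_pops:
            raise ValueError("per-population parameter lists must have n_pops entries")
        for f in self.target_fst:
            if not 0 <= f < 1:
                raise ValueError("target_fst values must be in [0,1)")
        for f in self.f_roh_target:
            if not 0 <= f < 1:
                raise ValueError("f_roh_target values must be in [0,1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0,1)")

    @property
    def genome_size_bp(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    @property
    def pop_labels(self) -> list[str]:
        return [f"P{i+1:02d}" for i in range(self.n_pops)]


@dataclass
class SimTruth:
    """Ground truth of every planted artefact."""

    planted_roh: list[dict] = field(default_factory=list)  # sample/chrom/start/end
    island_intervals: list[dict] = field(default_factory=list)
    island_carriers: dict[int, list[str]] = field(default_factory=dict)
    outlier_locus_ids: list[str] = field(default_factory=list)
    pop_frequencies: dict[str, list[float]] | None = None
    config: dict | None = None

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=_json_default)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["island_carriers"] = {int(k): v for k, v in d["island_carriers"].items()}
        return cls(**d)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"cannot serialise {type(o)}")


# ---------------------------------------------------------------------------
# Locus placement and frequencies
# ---------------------------------------------------------------------------


def simulate_loci(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Place loci uniformly over the chromosomes, proportional to length."""
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    per_chrom = rng.multinomial(config.n_loci, lengths / lengths.sum())
    rows = []
    counter = 0
    bases = np.array(list("ACGT"))
    for chrom, n in zip(chroms, per_chrom):
        size = config.chrom_lengths[chrom]
        pos = np.sort(rng.choice(size, size=n, replace=False)) + 1
        for p in pos:
            counter += 1
            ref, alt = rng.choice(4, size=2, replace=False)
            rows.append(
                {
                    "chrom": chrom,
                    "pos": int(p),
                    "id": f"marker{counter:06d}",
                    "ref": bases[ref],
                    "alt": bases[alt],
                }
            )
    return pd.DataFrame(rows)


def _locus_indices_in(loci: pd.DataFrame, island: IslandSpec) -> np.ndarray:
    m = (
        (loci["chrom"] == island.chrom)
        & (loci["pos"] >= island.start)
        & (loci["pos"] <= island.end)
    )
    return np.flatnonzero(m.to_numpy())


def simulate_frequencies(
    config: SimConfig,
    loci: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Balding-Nichols allele frequencies.

    Ancestral frequencies are Uniform(0.05, 0.95); each population draws
    ``Beta(p (1-F)/F, (1-p)(1-F)/F)`` around the ancestral value with its
    own divergence F (F = 0 copies the ancestral frequency exactly).
    Outlier loci use ``F * outlier_divergence_multiplier`` (capped at 0.98)
    in every population.

    Returns ``(ancestral, pop_freqs, outlier_idx)`` with *pop_freqs* of
    shape ``(n_pops, n_loci)``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    L = config.n_loci
    anc = rng.uniform(0.05, 0.95, size=L)

    outlier_idx = np.empty(0, dtype=int)
    if config.n_outlier_loci > 0:
        if config.outliers_in_island and config.planted_islands:
            if loci is None:
                raise ValueError("outliers_in_island requires the loci table")
            pool = np.concatenate(
                [_locus_indices_in(loci, isl) for isl in config.planted_islands]
            )
            if pool.size < config.n_outlier_loci:
                raise ValueError(
                    f"islands contain {pool.size} loci; cannot plant "
                    f"{config.n_outlier_loci} outliers"
                )
        else:
            pool = np.arange(L)
        outlier_idx = np.sort(
            rng.choice(pool, size=config.n_outlier_loci, replace=False)
        )

    pop_freqs = np.empty((config.n_pops, L))
    for i, F in enumerate(config.target_fst):
        pop_freqs[i] = anc
        if F > 0:
            alpha = anc * (1 - F) / F
            beta = (1 - anc) * (1 - F) / F
            pop_freqs[i] = rng.beta(alpha, beta)

    # planted outliers: redraw under the amplified divergence until the locus
    # genuinely IS a high-Fst plant — polymorphic overall with realized
    # between-population variance on the order of the target.  A raw
    # Balding-Nichols draw at high F frequently fixes every population for
    # the same allele, which is no outlier at all.
    for j in outlier_idx:
        for _ in range(500):
            col = np.empty(config.n_pops)
            for i, F in enumerate(config.target_fst):
                Fe = min(max(F, 1e-6) * config.outlier_divergence_multiplier, 0.98)
                al = anc[j] * (1 - Fe) / Fe
                be = (1 - anc[j]) * (1 - Fe) / Fe
                col[i] = rng.beta(al, be)
            pbar = col.mean()
            Fe_min = min(
                min(max(F, 1e-6) * config.outlier_divergence_multiplier, 0.98)
                for F in config.target_fst
            )
            if 0.15 <= pbar <= 0.85 and col.var() >= 0.5 * Fe_min * pbar * (1 - pbar):
                break
        pop_freqs[:, j] = col
    return anc, pop_freqs, outlier_idx


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def simulate_genotypes(
    freqs: np.ndarray,
    config: SimConfig,
    loci: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Hardy-Weinberg diploid draws per individual, with missingness.

    With ``ld_block_snps > 1`` each consecutive block of loci is drawn from
    a small per-population pool of haplotypes instead of independently,
    inducing within-block linkage disequilibrium for LD-aware stages.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    L = config.n_loci
    rows = []
    calls_parts = []
    for i, pop in enumerate(config.pop_labels):
        n_ind = config.n_ind_per_pop[i]
        if config.ld_block_snps > 1:
            calls = _genotypes_ld_blocks(freqs[i], n_ind, config, rng)
        else:
            calls = rng.binomial(2, freqs[i], size=(n_ind, L)).astype(np.int8)
        calls_parts.append(calls)
        for j in range(n_ind):
            rows.append({"sample_id": f"{pop}_i{j+1:02d}", "population": pop})
    calls = np.concatenate(calls_parts, axis=0)
    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls[mask] = MISSING
    samples = pd.DataFrame(rows)
    return GenotypeMatrix(samples, loci, calls)


def _genotypes_ld_blocks(freq, n_ind, config, rng):
    L = freq.size
    calls = np.empty((n_ind, L), dtype=np.int8)
    K = config.ld_pool_size
    for start in range(0, L, config.ld_block_snps):
        sl = slice(start, min(start + config.ld_block_snps, L))
        pool = (rng.random((K, sl.stop - sl.start)) < freq[sl]).astype(np.int8)
        picks = rng.integers(0, K, size=(n_ind, 2))
        calls[:, sl] = pool[picks[:, 0]] + pool[picks[:, 1]]
    return calls


# ---------------------------------------------------------------------------
# ROH implantation
# ---------------------------------------------------------------------------


def _draw_intervals(
    config: SimConfig, target_fraction: float, rng: np.random.Generator
) -> list[tuple[str, int, int]]:
    """Disjoint genomic intervals totalling ~target_fraction of the genome."""
    if target_fraction <= 0:
        return []
    genome = config.genome_size_bp
    target_bp = target_fraction * genome
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    lo_mb, hi_mb = config.roh_length_range_mb
    chosen: list[tuple[str, int, int]] = []
    total = 0.0
    attempts = 0
    while total < target_bp and attempts < 10_000:
        attempts += 1
        ci = rng.choice(len(chroms), p=probs)
        clen = int(lengths[ci])
        span = int(rng.uniform(lo_mb, hi_mb) * 1e6)
        span = min(span, clen)
        start = int(rng.integers(1, max(clen - span, 1) + 1))
        end = start + span - 1
        overlap = any(
            c == chroms[ci] and not (end < s or start > e) for c, s, e in chosen
        )
        if overlap:
            continue
        chosen.append((chroms[ci], start, end))
        total += span
    return chosen


def _force_homozygous(
    calls: np.ndarray, row: int, locus_idx: np.ndarray, rng: np.random.Generator
) -> None:
    for j in locus_idx:
        d = calls[row, j]
        if d == 1:
            calls[row, j] = 0 if rng.random() < 0.5 else 2
        # 0/2 already homozygous; missing stays missing


def implant_roh(
    gm: GenotypeMatrix, config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, SimTruth]:
    """Force long homozygous tracts and planted islands into *gm*.

    Per individual, disjoint intervals totalling the population's
    ``f_roh_target`` of the genome are drawn and every genotype inside made
    homozygous (heterozygotes flip to 0 or 2 by a fair coin).  Planted
    islands are then forced homozygous in their carrier subset.  Returns
    the modified matrix and the :class:`SimTruth` record.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    calls = gm.calls.copy()
    loci = gm.loci
    truth = SimTruth()
    genome = config.genome_size_bp
    for c, s, e in [
        (isl.chrom, isl.start, isl.end) for isl in config.planted_islands
    ]:
        if c not in config.chrom_lengths or e > config.chrom_lengths[c]:
            raise ValueError(f"island {c}:{s}-{e} exceeds chromosome bounds")

    pop_of_row = gm.samples["population"].tolist()
    pop_index = {p: i for i, p in enumerate(config.pop_labels)}
    for row, sample_id in enumerate(gm.sample_ids):
        f_target = config.f_roh_target[pop_index[pop_of_row[row]]]
        for chrom, start, end in _draw_intervals(config, f_target, rng):
            idx = _locus_indices_in(loci, IslandSpec(chrom, start, end, 0))
            _force_homozygous(calls, row, idx, rng)
            truth.planted_roh.append(
                {
                    "sample_id": sample_id,
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "n_snps": int(idx.size),
                    "length_bp": end - start + 1,
                }
            )

    n_total = gm.n_samples
    for k, isl in enumerate(config.planted_islands):
        n_car = (
            isl.n_carriers
            if isl.n_carriers is not None
            else int(round(isl.carrier_fraction * n_total))
        )
        carrier_rows = rng.choice(n_total, size=n_car, replace=False)
        idx = _locus_indices_in(loci, isl)
        for row in carrier_rows:
            _force_homozygous(calls, int(row), idx, rng)
            truth.planted_roh.append(
                {
                    "sample_id": gm.sample_ids[int(row)],
                    "chrom": isl.chrom,
                    "start": isl.start,
                    "end": isl.end,
                    "n_snps": int(idx.size),
                    "length_bp": isl.end - isl.start + 1,
                }
            )
        truth.island_intervals.append(
            {
                "chrom": isl.chrom,
                "start": isl.start,
                "end": isl.end,
                "n_carriers": int(n_car),
                "n_snps": int(idx.size),
            }
        )
        truth.island_carriers[k] = [gm.sample_ids[int(r)] for r in carrier_rows]
    assert sum(x["length_bp"] for x in truth.planted_roh) <= genome * n_total
    return GenotypeMatrix(gm.samples, gm.loci, calls), truth


# ---------------------------------------------------------------------------
# End-to-end dataset generation
# ---------------------------------------------------------------------------


def simulate_dataset(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Run the full generator in memory: loci, frequencies, genotypes, ROH."""
    rng = np.random.default_rng(config.seed)
    loci = simulate_loci(config, rng)
    anc, pop_freqs, outlier_idx = simulate_frequencies(config, loci, rng)
    gm = simulate_genotypes(pop_freqs, config, loci, rng)
    gm, truth = implant_roh(gm, config, rng)
    truth.outlier_locus_ids = loci["id"].iloc[outlier_idx].tolist()
    truth.pop_frequencies = {
        pop: pop_freqs[i].tolist() for i, pop in enumerate(config.pop_labels)
    }
    truth.config = dataclasses.asdict(config)
    return gm, truth


def generate_dataset(config: SimConfig, out_prefix) -> dict[str, str]:
    """Write VCF + popmap + truth JSON; returns the file paths."""
    gm, truth = simulate_dataset(config)
    vcf_path = f"{out_prefix}.vcf"
    pop_path = f"{out_prefix}.popmap.tsv"
    truth_path = f"{out_prefix}.truth.json"
    write_vcf(gm, vcf_path)
    pm = PopulationMap(
        zip(gm.samples["sample_id"], gm.samples["population"])
    )
    write_popmap(pm, pop_path)
    truth.to_json(truth_path)
    return {"vcf": vcf_path, "popmap": pop_path, "truth": truth_path}
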