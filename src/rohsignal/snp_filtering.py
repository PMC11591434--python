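"""Post-variant-calling SNP filters.

Pipeline order mirrors the standard RAD-seq workflow: autosomal/bi-allelic
restriction, SNP call-rate then individual call-rate thresholds, monomorphic
removal, and finally windowed LD pruning on pairwise genotypic r^2
(50-SNP window, 5-SNP step, r^2 > 0.2 pruned, by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, logger


@dataclass
class LDPruneParams:
    window_snps: int = 50
    step_snps: int = 5
    r2_threshold: float = 0.2

    def __post_init__(self):
        if self.window_snps < 2:
            raise ValueError("window_snps must be >= 2")
        if not 0 < self.r2_threshold < 1:
            raise ValueError("r2_threshold must be in (0,1)")
        if self.step_snps < 1:
            raise ValueError("step_snps must be >= 1")


@dataclass
class FilterReport:
    """Per-stage accounting of dropped SNPs and individuals."""

    n_snps_in: int = 0
    n_snps_out: int = 0
    n_samples_in: int = 0
    n_samples_out: int = 0
    stage_drops: dict = field(default_factory=dict)

    def record(self, stage: str, n_dropped: int) -> None:
        if n_dropped < 0:
            raise ValueError("drop count cannot be negative")
        self.stage_drops[stage] = self.stage_drops.get(stage, 0) + int(n_dropped)

    def to_rows(self) -> list[dict]:
        rows = [
            {"stage": "input", "snps": self.n_snps_in, "samples": self.n_samples_in}
        ]
        rows += [
            {"stage": k, "snps": -v, "samples": 0} if not k.endswith("individuals")
            else {"stage": k, "snps": 0, "samples": -v}
            for k, v in self.stage_drops.items()
        ]
        rows.append(
            {"stage": "output", "snps": self.n_snps_out, "samples": self.n_samples_out}
        )
        return rows


def filter_autosomal_biallelic(gm: GenotypeMatrix, autosomes) -> GenotypeMatrix:
    """Keep only loci on whitelisted (autosomal) chromosomes.

    Bi-allelic restriction itself happens at VCF read time; this step removes
    whatever non-whitelisted chromosomes survived (sex chromosomes,
    scaffolds).  Chromosome labels are opaque strings.
    """
    allowed = {str(c) for c in autosomes}
    keep = gm.loci["chrom"].astype(str).isin(allowed).to_numpy()
    if not keep.any():
        logger.warning("autosome filter removed every locus")
    return gm.take_loci(np.flatnonzero(keep))


def filter_call_rates(
    gm: GenotypeMatrix, snp_rate: float = 0.95, ind_rate: float = 0.80
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop low-call-rate SNPs, then low-call-rate individuals.

    SNPs with non-missing fraction below *snp_rate* are removed first;
    individual call rates are then recomputed on the surviving SNPs and
    individuals below *ind_rate* removed.
    """
    for name, thr in (("snp_rate", snp_rate), ("ind_rate", ind_rate)):
        if not 0 < thr <= 1:
            raise ValueError(f"{name} must be in (0,1], got {thr}")
    report = FilterReport(
        n_snps_in=gm.n_loci, n_samples_in=gm.n_samples
    )
    called = gm.calls != MISSING
    snp_cr = called.mean(axis=0) if gm.n_samples else np.zeros(gm.n_loci)
    keep_snps = snp_cr >= snp_rate
    report.record("snp_call_rate", int((~keep_snps).sum()))
    gm = gm.take_loci(np.flatnonzero(keep_snps))

    called = gm.calls != MISSING
    ind_cr = called.mean(axis=1) if gm.n_loci else np.ones(gm.n_samples)
    keep_ind = ind_cr >= ind_rate
    report.record("ind_call_rate individuals", int((~keep_ind).sum()))
    gm = gm.take_samples(np.flatnonzero(keep_ind))

    report.n_snps_out = gm.n_loci
    report.n_samples_out = gm.n_samples
    return gm, report


def remove_monomorphic(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Remove loci where the non-missing calls carry only one allele."""
    calls = gm.calls
    valid = calls != MISSING
    has_ref = ((calls == 0) | (calls == 1)).any(axis=0)
    has_alt = ((calls == 2) | (calls == 1)).any(axis=0)
    polymorphic = has_ref & has_alt & valid.any(axis=0)
    return gm.take_loci(np.flatnonzero(polymorphic))


def genotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over pairwise-complete samples.  Undefined (zero-variance or
    fewer than two complete pairs) returns ``nan``; the pruner treats nan as
    r^2 = 0, since a locus monomorphic within the window cannot be in LD.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return float("nan")
    xs, ys = x[ok], y[ok]
    vx = xs.var()
    vy = ys.var()
    if vx == 0 or vy == 0:
        return float("nan")
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def offset_r2(calls: np.ndarray, cols_a: np.ndarray, cols_b: np.ndarray) -> np.ndarray:
    """Vectorised pairwise-complete r^2 between paired dosage columns.

    ``cols_a[i]`` is correlated with ``cols_b[i]``.  Pairs with fewer than
    two complete observations or zero variance yield 0 (treated as "not in
    LD", consistent with :func:`genotype_r2`'s nan convention).
    """
    x = calls[:, cols_a].astype(np.float64)
    y = calls[:, cols_b].astype(np.float64)
    ok = (x != MISSING) & (y != MISSING)
    x = np.where(ok, x, 0.0)
    y = np.where(ok, y, 0.0)
    n = ok.sum(axis=0).astype(np.float64)
    sx, sy = x.sum(axis=0), y.sum(axis=0)
    sxx, syy = (x * x).sum(axis=0), (y * y).sum(axis=0)
    sxy = (x * y).sum(axis=0)
    num = n * sxy - sx * sy
    den = (n * sxx - sx * sx) * (n * syy - sy * sy)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = (num * num) / den
    r2[(den <= 0) | (n < 2)] = 0.0
    return r2


def ld_prune(
    gm: GenotypeMatrix, params: LDPruneParams | None = None
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Greedy windowed LD pruning per chromosome.

    Whenever two retained loci that can co-occur in a *window_snps*-wide
    window (i.e. are fewer than *window_snps* apart in the retained list)
    have r^2 > *r2_threshold*, the later (larger-position) locus is removed,
    scanning left to right.  Passes repeat until a full sweep removes
    nothing — removals pull distant loci into a common window, so on output
    no retained pair co-occurring in ANY window placement exceeds the
    threshold.  Deterministic for a fixed input ordering.  *step_snps* is
    kept for interface compatibility with the classic sliding-window tools;
    the fixpoint sweep subsumes any step choice and is at least as strict.

    Returns the pruned matrix and the kept locus indices (into the input).
    """
    if params is None:
        params = LDPruneParams()
    chroms = gm.loci["chrom"].to_numpy()
    kept_global: list[int] = []
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        kept = _prune_chromosome(gm.calls[:, idx], params)
        kept_global.extend(idx[kept])
    kept_idx = np.array(sorted(kept_global), dtype=int)
    n_drop = gm.n_loci - kept_idx.size
    logger.info("ld_prune: removed %d of %d loci", n_drop, gm.n_loci)
    return gm.take_loci(kept_idx), kept_idx


def _prune_chromosome(calls: np.ndarray, params: LDPruneParams) -> list[int]:
    kept = list(range(calls.shape[1]))
    w, thr = params.window_snps, params.r2_threshold
    while True:
        m = len(kept)
        if m < 2:
            return kept
        kept_arr = np.asarray(kept)
        # offending pairs at each retained-list offset 1..w-1
        offenders: list[tuple[int, int]] = []
        for k in range(1, min(w, m)):
            r2 = offset_r2(calls, kept_arr[:-k], kept_arr[k:])
            for i in np.flatnonzero(r2 > thr):
                offenders.append((int(i), int(i + k)))
        if not offenders:
            return kept
        offenders.sort()
        alive = np.ones(m, dtype=bool)
        for i, j in offenders:
            if alive[i] and alive[j]:
                alive[j] = False
        kept = [kept[i] for i in np.flatnonzero(alive)]
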