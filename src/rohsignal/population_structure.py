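"""Population structure: Weir-Cockerham Fst, distance matrices, AMOVA,
neighbor-joining trees, and principal coordinate analysis.

Fst follows Weir & Cockerham (1984): per-locus variance components
``a`` (among populations), ``b`` (among individuals within populations) and
``c`` (within individuals), combined across loci as a ratio of sums.
Pairwise population Fst gets a percentile confidence interval from a
seeded locus bootstrap.  AMOVA partitions allele-level variance into the
three strata (among populations / among individuals within populations /
within individuals) with a permutation test on population labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, PopulationMap, logger


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix over labelled points."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class FstPairResult:
    pop_a: str
    pop_b: str
    fst: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_loci: int


@dataclass
class AMOVAResult:
    """Three-level molecular variance decomposition."""

    sigma_among_pops: float
    sigma_among_ind: float
    sigma_within_ind: float
    pct_among_pops: float
    pct_among_ind: float
    pct_within_ind: float
    phi_st: float
    phi_is: float
    phi_it: float
    p_among_pops: float
    n_permutations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": [
                    "among_populations",
                    "among_individuals_within_populations",
                    "within_individuals",
                ],
                "sigma2": [
                    self.sigma_among_pops,
                    self.sigma_among_ind,
                    self.sigma_within_ind,
                ],
                "percent": [
                    self.pct_among_pops,
                    self.pct_among_ind,
                    self.pct_within_ind,
                ],
                "phi": [self.phi_st, self.phi_is, self.phi_it],
                "p_value": [self.p_among_pops, np.nan, np.nan],
            }
        )


# ---------------------------------------------------------------------------
# Allele frequencies and Euclidean distances
# ---------------------------------------------------------------------------


def population_allele_frequencies(
    gm: GenotypeMatrix, popmap: PopulationMap | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-population per-locus alt-allele frequencies and copy counts.

    Returns ``(freqs, counts)``: DataFrames indexed by population with one
    column per locus id.  Cells with no callable copies are nan in *freqs*.
    """
    if popmap is not None:
        gm = gm.attach_popmap(popmap)
    pops = list(dict.fromkeys(gm.samples["population"]))
    freq_rows, count_rows = [], []
    for pop in pops:
        calls = gm.calls[gm.sample_indices(pop), :]
        valid = calls != MISSING
        tot = 2 * valid.sum(axis=0)
        alt = np.where(valid, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt / tot
        p = np.where(tot > 0, p, np.nan)
        freq_rows.append(p)
        count_rows.append(tot)
    ids = gm.loci["id"].tolist()
    freqs = pd.DataFrame(freq_rows, index=pops, columns=ids)
    counts = pd.DataFrame(count_rows, index=pops, columns=ids)
    return freqs, counts


def euclidean_distance_matrix(freqs: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distance between population allele-frequency vectors.

    For each pair, summed over the loci that are non-missing in both
    populations.  Errors if a pair shares no callable locus.
    """
    pops = list(freqs.index)
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    F = freqs.to_numpy(dtype=float)
    n = len(pops)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = np.isfinite(F[i]) & np.isfinite(F[j])
            if not ok.any():
                raise ValueError(f"no shared loci between {pops[i]} and {pops[j]}")
            diff = F[i, ok] - F[j, ok]
            d[i, j] = d[j, i] = float(np.sqrt(np.sum(diff * diff)))
    return DistanceMatrix(pops, d)


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) variance components
# ---------------------------------------------------------------------------


def weir_cockerham_components(
    gm: GenotypeMatrix, pops: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus WC84 variance components (a, b, c) over the given populations.

    Loci without at least two populations holding >= 2 allele copies are nan
    in all three components.  ``a`` is the among-population component; the
    per-locus estimate is ``a / (a + b + c)`` and the multi-locus estimate
    the ratio of sums.
    """
    if pops is None:
        pops = list(dict.fromkeys(gm.samples["population"]))
    if len(pops) < 2:
        raise ValueError("need >= 2 populations for Fst")
    L = gm.n_loci
    r_tot = len(pops)
    n_mat = np.zeros((r_tot, L))        # diploid sample sizes per pop/locus
    p_mat = np.zeros((r_tot, L))        # alt-allele frequencies
    h_mat = np.zeros((r_tot, L))        # observed heterozygote proportions
    for i, pop in enumerate(pops):
        calls = gm.calls[gm.sample_indices(pop), :]
        valid = calls != MISSING
        n_i = valid.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_mat[i] = np.where(valid, calls, 0).sum(axis=0) / (2 * n_i)
            h_mat[i] = (calls == 1).sum(axis=0) / n_i
        n_mat[i] = n_i

    usable = n_mat >= 1
    r = usable.sum(axis=0).astype(float)
    n_mat = np.where(usable, n_mat, 0.0)
    p_mat = np.where(usable, np.nan_to_num(p_mat), 0.0)
    h_mat = np.where(usable, np.nan_to_num(h_mat), 0.0)

    n_sum = n_mat.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n_sum / r
        nc = (n_sum - (n_mat**2).sum(axis=0) / n_sum) / (r - 1)
        pbar = (n_mat * p_mat).sum(axis=0) / n_sum
        s2 = (n_mat * (p_mat - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_mat * h_mat).sum(axis=0) / n_sum

        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1))
            * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - ((r - 1) / r) * s2
            - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0

    bad = (r < 2) | (nbar <= 1) | (nc <= 0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    if bad.any():
        logger.info("weir_cockerham: %d loci unusable (single population or n<=1)", int(bad.sum()))
    return a, b, c


def wc_fst_nocorr(
    gm: GenotypeMatrix, pops: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus WC Fst without the finite-sample correction, plus pooled He.

    This is the estimator whose neutral distribution is fit by the
    outlier scan: dropping the sample-size correction keeps the statistic
    non-negative so a scaled chi-square model applies.  Returns
    ``(fst_nocorr, het)`` where het is the expected heterozygosity at the
    sample-size-weighted pooled frequency.
    """
    if pops is None:
        pops = list(dict.fromkeys(gm.samples["population"]))
    L = gm.n_loci
    r_tot = len(pops)
    n_mat = np.zeros((r_tot, L))
    p_mat = np.zeros((r_tot, L))
    h_mat = np.zeros((r_tot, L))
    for i, pop in enumerate(pops):
        calls = gm.calls[gm.sample_indices(pop), :]
        valid = calls != MISSING
        n_i = valid.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_mat[i] = np.where(valid, calls, 0).sum(axis=0) / (2 * n_i)
            h_mat[i] = (calls == 1).sum(axis=0) / n_i
        n_mat[i] = n_i
    usable = n_mat >= 1
    r = usable.sum(axis=0).astype(float)
    n_mat = np.where(usable, n_mat, 0.0)
    p_mat = np.where(usable, np.nan_to_num(p_mat), 0.0)
    h_mat = np.where(usable, np.nan_to_num(h_mat), 0.0)
    n_sum = n_mat.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n_sum / r
        nc = (n_sum - (n_mat**2).sum(axis=0) / n_sum) / (r - 1)
        pbar = (n_mat * p_mat).sum(axis=0) / n_sum
        s2 = (n_mat * (p_mat - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_mat * h_mat).sum(axis=0) / n_sum
        a = (nbar / nc) * s2
        b = (
            pbar * (1 - pbar)
            - ((r - 1) / r) * s2
            - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0
        fst = a / (a + b + c)
    het = 2 * pbar * (1 - pbar)
    bad = (r < 2) | (nbar <= 1) | (nc <= 0) | ~np.isfinite(fst)
    fst = np.where(bad, np.nan, fst)
    het = np.where(r < 1, np.nan, het)
    return fst, het


def pairwise_fst(
    gm: GenotypeMatrix,
    popmap: PopulationMap | None,
    pop_a: str,
    pop_b: str,
    n_boot: int = 1000,
    seed: int | None = None,
) -> FstPairResult:
    """Multi-locus WC84 Fst between two populations with a locus bootstrap.

    The point estimate is the ratio of summed components
    ``sum(a) / sum(a+b+c)``; the CI is the 2.5/97.5 percentile of the same
    ratio over *n_boot* seeded resamplings of loci with replacement.
    """
    if popmap is not None:
        gm = gm.attach_popmap(popmap)
    for pop in (pop_a, pop_b):
        if len(gm.sample_indices(pop)) < 2:
            raise ValueError(f"population {pop!r} needs >= 2 individuals")
    a, b, c = weir_cockerham_components(gm, [pop_a, pop_b])
    ok = np.isfinite(a)
    if not ok.any():
        raise ValueError(f"no usable loci for pair ({pop_a}, {pop_b})")
    a, b, c = a[ok], b[ok], c[ok]
    denom = a + b + c
    fst = float(a.sum() / denom.sum()) if denom.sum() != 0 else float("nan")
    rng = np.random.default_rng(seed)
    L = a.size
    boots = np.empty(n_boot)
    for k in range(n_boot):
        idx = rng.integers(0, L, L)
        d = denom[idx].sum()
        boots[k] = a[idx].sum() / d if d != 0 else np.nan
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return FstPairResult(pop_a, pop_b, fst, float(lo), float(hi), n_boot, L)


def pairwise_fst_matrix(
    gm: GenotypeMatrix,
    popmap: PopulationMap | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[DistanceMatrix, pd.DataFrame]:
    """All pairwise Fst values as a distance matrix plus a tidy table."""
    if popmap is not None:
        gm = gm.attach_popmap(popmap)
    pops = list(dict.fromkeys(gm.samples["population"]))
    n = len(pops)
    d = np.zeros((n, n))
    ss = np.random.SeedSequence(seed)
    pair_seeds = ss.generate_state(n * n)
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            res = pairwise_fst(
                gm, None, pops[i], pops[j], n_boot=n_boot,
                seed=int(pair_seeds[i * n + j] % (2**31)),
            )
            # negative point estimates are sampling noise around 0; distances
            # are clamped for tree building while the table keeps raw values
            d[i, j] = d[j, i] = max(res.fst, 0.0)
            rows.append(res.__dict__)
    return DistanceMatrix(pops, d), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Trees and ordination
# ---------------------------------------------------------------------------


def neighbor_joining_tree(d: DistanceMatrix) -> str:
    """Saitou-Nei neighbor joining; returns a Newick string.

    Negative branch lengths are clamped to zero (scikit-bio's standard
    handling, which transfers the deficit to the sister branch).
    """
    import skbio
    from skbio.tree import nj

    if len(d.labels) < 3:
        raise ValueError("neighbor joining needs >= 3 labels")
    dm = skbio.DistanceMatrix(d.values, ids=d.labels)
    tree = nj(dm)
    return str(tree).strip()


def pcoa(d: DistanceMatrix, k: int | None = None) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical scaling (PCoA) of a distance matrix.

    Eigendecomposition of the double-centred ``-d^2/2`` matrix; axes are
    ordered by descending eigenvalue and axes with negative eigenvalues are
    excluded from the coordinates (the full eigenvalue spectrum is returned
    for inspection).  Returns ``(coordinates, eigenvalues)``.
    """
    n = len(d.labels)
    if k is not None and k >= n:
        raise ValueError("k must be < number of labels")
    D2 = d.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > 1e-12
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    if k is not None:
        coords = coords[:, :k]
    cols = [f"PCo{i+1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=d.labels, columns=cols), eigval


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


def _amova_sums(calls: np.ndarray, pop_idx: np.ndarray, n_pops: int):
    """Per-locus nested ANOVA sums of squares on allele indicators.

    Each called diploid genotype contributes two allele copies
    (dosage d -> copies summing to d).  Missing genotypes contribute
    nothing.  Returns total SS per stratum and the df / coefficient sums
    needed for variance-component estimation.
    """
    n_samples, L = calls.shape
    valid = calls != MISSING
    dose = np.where(valid, calls, 0).astype(float)

    # per-individual allele mean = dose/2; copy values are 0/1 with sum=dose
    # within-individual SS per locus: for dose 1 the two copies differ from
    # their mean 0.5 by 0.5 each -> SS 0.5; dose 0/2 -> 0
    ss_within = np.where(valid & (calls == 1), 0.5, 0.0).sum(axis=0)

    # population sums per locus
    P = np.zeros((n_pops, n_samples))
    P[pop_idx, np.arange(n_samples)] = 1.0
    pop_dose = P @ dose                     # alt copies per pop/locus
    pop_n = P @ valid                       # called individuals per pop/locus
    pop_copies = 2 * pop_n
    tot_dose = dose.sum(axis=0)
    tot_copies = 2 * valid.sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        pop_mean = pop_dose / pop_copies
        grand_mean = tot_dose / tot_copies

    # among individuals within populations: 2 * (ind_mean - pop_mean)^2
    ind_mean = dose / 2.0
    pm_per_ind = np.where(valid, np.nan_to_num(pop_mean)[pop_idx, :], 0.0)
    ss_ind = (2 * (ind_mean - pm_per_ind) ** 2 * valid).sum(axis=0)

    # among populations: 2 n_i (pop_mean - grand_mean)^2
    gm_b = np.nan_to_num(grand_mean)
    ss_pop = np.nansum(
        pop_copies * (np.nan_to_num(pop_mean) - gm_b) ** 2 * (pop_copies > 0), axis=0
    )

    # degrees of freedom per locus
    pops_present = (pop_n > 0).sum(axis=0)
    n_called = valid.sum(axis=0)
    df_pop = np.maximum(pops_present - 1, 0)
    df_ind = np.maximum(n_called - pops_present, 0)
    df_within = n_called  # one df per called individual (2 copies)

    # coefficient n0 relating MS_pop to sigma_a (copies-based)
    with np.errstate(invalid="ignore", divide="ignore"):
        n0 = (tot_copies - (pop_copies**2).sum(axis=0) / tot_copies) / np.maximum(
            df_pop, 1
        )
    n0 = np.where(df_pop > 0, n0, 0.0)

    return ss_pop, ss_ind, ss_within, df_pop, df_ind, df_within, n0


def _amova_components(calls, pop_idx, n_pops):
    ss_pop, ss_ind, ss_w, df_pop, df_ind, df_w, n0 = _amova_sums(
        calls, pop_idx, n_pops
    )
    SSp, SSi, SSw = ss_pop.sum(), ss_ind.sum(), ss_w.sum()
    DFp, DFi, DFw = df_pop.sum(), df_ind.sum(), df_w.sum()
    if DFp == 0 or DFi == 0 or DFw == 0:
        raise ValueError("AMOVA needs >= 2 populations each with >= 2 individuals")
    MSp, MSi, MSw = SSp / DFp, SSi / DFi, SSw / DFw
    sigma_w = MSw
    sigma_b = (MSi - MSw) / 2.0
    # weighted-average n0 across loci (weights: per-locus df_pop)
    n0_bar = float((n0 * df_pop).sum() / DFp)
    sigma_a = (MSp - MSi) / n0_bar if n0_bar > 0 else 0.0
    return sigma_a, sigma_b, sigma_w


def amova(
    gm: GenotypeMatrix,
    popmap: PopulationMap | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
) -> AMOVAResult:
    """Three-level AMOVA on allele-level squared differences.

    Components: among populations (sigma_a), among individuals within
    populations (sigma_b), within individuals (sigma_w); Phi statistics are
    the usual ratios.  Significance of the among-population stratum by
    permuting individuals across populations *n_perm* times (seeded);
    ``p = (exceedances + 1) / (n_perm + 1)``.
    """
    if popmap is not None:
        gm = gm.attach_popmap(popmap)
    pops = list(dict.fromkeys(gm.samples["population"]))
    if len(pops) < 2:
        raise ValueError("AMOVA needs >= 2 populations")
    pop_idx = np.array(
        [pops.index(p) for p in gm.samples["population"]], dtype=int
    )
    sigma_a, sigma_b, sigma_w = _amova_components(gm.calls, pop_idx, len(pops))
    total = sigma_a + sigma_b + sigma_w
    if total <= 0:
        pct = (0.0, 0.0, 100.0)
        phi_st = phi_is = phi_it = 0.0
    else:
        pct = (
            100 * sigma_a / total,
            100 * sigma_b / total,
            100 * sigma_w / total,
        )
        phi_st = sigma_a / total
        phi_is = sigma_b / (sigma_b + sigma_w) if (sigma_b + sigma_w) > 0 else 0.0
        phi_it = (sigma_a + sigma_b) / total

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(pop_idx)
        pa, _, _ = _amova_components(gm.calls, perm, len(pops))
        if pa >= sigma_a:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return AMOVAResult(
        sigma_a, sigma_b, sigma_w, pct[0], pct[1], pct[2],
        phi_st, phi_is, phi_it, p, n_perm,
    )
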