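"""Per-population genetic diversity measures.

Produces one summary row per population: segregating sites, minor-allele
frequency summary, private alleles (raw count and per-SNP rate),
heterozygosity He (per-individual heterozygous-call fraction, optionally
rescaled by dataset coverage), per-site nucleotide diversity pi, a
Watterson-type theta, the *raw* Tajima's D (pi - theta, not the classical
variance-normalised statistic), and a one-degree-of-freedom chi-square
contrast of pi against theta.

The raw pi - theta difference is the statistic reported here as "Tajima's D":
negative values indicate an excess of rare variants (sweeps, expansion),
positive values an excess of intermediate-frequency variants (balancing
selection, bottleneck recovery).  The classical normalised D is available
separately via :func:`tajima_d_classical`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, GenotypeMatrix, PopulationMap, logger


@dataclass
class HeParams:
    """``ntotal`` is the genome length covered by the dataset.

    It defaults to the SNP count (making the coverage correction factor 1);
    override with a bp length to express He per covered base.
    """

    ntotal: float | None = None

    def resolved(self, nsnps: int) -> float:
        nt = self.ntotal if self.ntotal is not None else nsnps
        if nt <= 0:
            raise ValueError("ntotal must be positive")
        return float(nt)


def _pop_calls(gm: GenotypeMatrix, pop: str) -> np.ndarray:
    return gm.calls[gm.sample_indices(pop), :]


def allele_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus (alt copies, total non-missing copies) for a call block."""
    valid = calls != MISSING
    alt = np.where(valid, calls, 0).sum(axis=0)
    tot = 2 * valid.sum(axis=0)
    return alt.astype(np.int64), tot.astype(np.int64)


def segregating_sites(gm: GenotypeMatrix, pop: str) -> int:
    """Loci at which both alleles are observed within the population."""
    alt, tot = allele_counts(_pop_calls(gm, pop))
    return int(((alt > 0) & (alt < tot)).sum())


def minor_allele_freq(gm: GenotypeMatrix, pop: str) -> tuple[np.ndarray, float]:
    """Per-locus minor-allele frequency and its mean over callable loci.

    Loci with no calls in the population are nan and excluded from the mean.
    """
    alt, tot = allele_counts(_pop_calls(gm, pop))
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / tot
    maf = np.minimum(p, 1 - p)
    maf[tot == 0] = np.nan
    mean = float(np.nanmean(maf)) if np.isfinite(maf).any() else float("nan")
    return maf, mean


def mean_alt_allele_freq(gm: GenotypeMatrix, pop: str) -> float:
    """Mean alternate-allele frequency (unfolded), for comparison with MAF."""
    alt, tot = allele_counts(_pop_calls(gm, pop))
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / tot
    p[tot == 0] = np.nan
    return float(np.nanmean(p))


def private_alleles(
    gm: GenotypeMatrix, popmap: PopulationMap | None = None
) -> pd.DataFrame:
    """Count (locus, allele) pairs observed in exactly one population.

    Returns a frame with columns ``population, private_alleles,
    private_rate`` where the rate is count / total loci.
    """
    if popmap is not None:
        gm = gm.attach_popmap(popmap)
    pops = list(dict.fromkeys(gm.samples["population"]))
    if len(pops) < 2:
        raise ValueError("private alleles need >= 2 populations")
    presence_ref = np.zeros((len(pops), gm.n_loci), dtype=bool)
    presence_alt = np.zeros_like(presence_ref)
    for i, pop in enumerate(pops):
        calls = _pop_calls(gm, pop)
        presence_ref[i] = ((calls == 0) | (calls == 1)).any(axis=0)
        presence_alt[i] = ((calls == 2) | (calls == 1)).any(axis=0)
    rows = []
    for i, pop in enumerate(pops):
        only_here = 0
        for presence in (presence_ref, presence_alt):
            others = presence[np.arange(len(pops)) != i].any(axis=0)
            only_here += int((presence[i] & ~others).sum())
        rows.append(
            {
                "population": pop,
                "private_alleles": only_here,
                "private_rate": only_here / gm.n_loci if gm.n_loci else 0.0,
            }
        )
    return pd.DataFrame(rows)


def heterozygosity_he(
    gm: GenotypeMatrix, pop: str, params: HeParams | None = None
) -> float:
    """Population He: mean over individuals of
    ``(het calls / non-missing calls) * (nsnps / ntotal)``.

    Individuals with zero non-missing calls are excluded with a warning.
    """
    params = params or HeParams()
    ntotal = params.resolved(gm.n_loci)
    calls = _pop_calls(gm, pop)
    n_called = (calls != MISSING).sum(axis=1)
    n_het = (calls == 1).sum(axis=1)
    usable = n_called > 0
    if not usable.all():
        logger.warning(
            "heterozygosity_he: excluding %d individuals with no calls in %s",
            int((~usable).sum()), pop,
        )
    if not usable.any():
        return float("nan")
    he_i = (n_het[usable] / n_called[usable]) * (gm.n_loci / ntotal)
    return float(he_i.mean())


def nucleotide_diversity_pi(gm: GenotypeMatrix, pop: str) -> float:
    """Per-site nucleotide diversity.

    Per locus the unbiased estimator ``2 p (1-p) n / (n-1)`` on the
    population's allele counts (n = non-missing copies); pi is the mean over
    loci with n >= 2.  Equals the brute-force mean proportion of differences
    over all distinct haplotype pairs.
    """
    alt, tot = allele_counts(_pop_calls(gm, pop))
    use = tot >= 2
    if not use.any():
        raise ValueError(f"population {pop!r} has no locus with >= 2 allele copies")
    p = alt[use] / tot[use]
    n = tot[use]
    per_locus = 2 * p * (1 - p) * n / (n - 1)
    return float(per_locus.mean())


def harmonic_number(m: int) -> float:
    """Sum_{k=1}^{m} 1/k."""
    return float(np.sum(1.0 / np.arange(1, m + 1))) if m >= 1 else 0.0


def watterson_theta(gm: GenotypeMatrix, pop: str, per_locus_n: bool = False) -> float:
    """Watterson's estimator per site: ``S / (a_{n-1} L)``.

    With missing data the allele-copy count n varies by locus; by default n
    is the median per-locus count (and ``a`` a single harmonic number).
    With ``per_locus_n`` each segregating locus contributes ``1/a_{n_l-1}``
    instead.
    """
    alt, tot = allele_counts(_pop_calls(gm, pop))
    callable_ = tot >= 2
    L = int(callable_.sum())
    if L == 0:
        raise ValueError(f"population {pop!r}: no callable loci")
    seg = (alt > 0) & (alt < tot) & callable_
    if per_locus_n:
        a = np.array([harmonic_number(int(n) - 1) for n in tot[seg]])
        return float(np.sum(1.0 / a) / L) if a.size else 0.0
    n_med = int(np.median(tot[callable_]))
    if n_med < 2:
        raise ValueError("median allele-copy count < 2")
    return float(seg.sum() / (harmonic_number(n_med - 1) * L))


def tajima_d_raw(pi: float, theta: float) -> float:
    """The raw difference pi - theta (unnormalised Tajima's D)."""
    return pi - theta


def tajima_d_classical(gm: GenotypeMatrix, pop: str) -> float:
    """Classical variance-normalised Tajima's D (for comparison only).

    Uses the median per-locus allele-copy count as the sample size n and the
    standard constants; nan when there are no segregating sites.
    """
    alt, tot = allele_counts(_pop_calls(gm, pop))
    callable_ = tot >= 2
    S = int(((alt > 0) & (alt < tot) & callable_).sum())
    if S == 0:
        return float("nan")
    n = int(np.median(tot[callable_]))
    a1 = harmonic_number(n - 1)
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    # pi and theta here are totals over loci, not per-site
    L = int(callable_.sum())
    pi_tot = nucleotide_diversity_pi(gm, pop) * L
    th_tot = S / a1
    var = e1 * S + e2 * S * (S - 1)
    return float((pi_tot - th_tot) / np.sqrt(var)) if var > 0 else float("nan")


def pi_theta_chi2(pi: float, theta: float, L: int) -> tuple[float, float]:
    """One-df goodness-of-fit contrast of observed pi against expected theta.

    ``chi2 = (pi L - theta L)^2 / (theta L)``; p from the chi-square(1)
    survival function.  Returns ``(nan, nan)`` when theta == 0.
    """
    if L <= 0:
        raise ValueError("L must be positive")
    if theta <= 0:
        return float("nan"), float("nan")
    stat = (pi * L - theta * L) ** 2 / (theta * L)
    p = float(stats.chi2.sf(stat, df=1))
    return float(stat), p


def diversity_summary(
    gm: GenotypeMatrix,
    popmap: PopulationMap | None = None,
    he_params: HeParams | None = None,
) -> pd.DataFrame:
    """One row per population with every diversity column."""
    if popmap is not None:
        gm = gm.attach_popmap(popmap)
    pops = list(dict.fromkeys(gm.samples["population"]))
    priv = private_alleles(gm).set_index("population") if len(pops) >= 2 else None
    rows = []
    for pop in pops:
        pi = nucleotide_diversity_pi(gm, pop)
        theta = watterson_theta(gm, pop)
        alt, tot = allele_counts(_pop_calls(gm, pop))
        L = int((tot >= 2).sum())
        chi2_stat, chi2_p = pi_theta_chi2(pi, theta, L)
        _, maf_mean = minor_allele_freq(gm, pop)
        rows.append(
            {
                "population": pop,
                "n_individuals": len(gm.sample_indices(pop)),
                "seg_sites": segregating_sites(gm, pop),
                "maf_mean": maf_mean,
                "alt_freq_mean": mean_alt_allele_freq(gm, pop),
                "private_alleles": int(priv.loc[pop, "private_alleles"]) if priv is not None else 0,
                "private_rate": float(priv.loc[pop, "private_rate"]) if priv is not None else 0.0,
                "he": heterozygosity_he(gm, pop, he_params),
                "pi": pi,
                "theta": theta,
                "tajima_d_raw": tajima_d_raw(pi, theta),
                "pi_theta_chi2": chi2_stat,
                "pi_theta_chi2_p": chi2_p,
            }
        )
    return pd.DataFrame(rows)
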