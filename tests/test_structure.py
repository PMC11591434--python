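"""Distances, Fst, AMOVA, NJ and PCoA against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from rohsignal.genotype_io import MISSING
from rohsignal.population_structure import (
    AMOVAResult,
    DistanceMatrix,
    _amova_sums,
    amova,
    euclidean_distance_matrix,
    neighbor_joining_tree,
    pairwise_fst,
    pcoa,
    population_allele_frequencies,
    weir_cockerham_components,
)
from rohsignal.synthetic_data import SimConfig, simulate_dataset

from conftest import make_gm, random_gm


# ---------------------------------------------------------------------------
# allele frequencies / Euclidean distances
# ---------------------------------------------------------------------------


def test_population_allele_frequencies_census(rng):
    calls = np.array([[0], [1], [2]], dtype=np.int8)
    gm = make_gm(calls, populations=["A"] * 3)
    freqs, counts = population_allele_frequencies(gm)
    assert freqs.loc["A"].iloc[0] == pytest.approx(0.5)
    assert counts.loc["A"].iloc[0] == 6

    gm2 = random_gm(rng, n_samples=9, n_loci=30,
                    populations=["A"] * 4 + ["B"] * 5, missing_rate=0.2)
    freqs2, _ = population_allele_frequencies(gm2)
    for pop in ("A", "B"):
        rows = [i for i, p in enumerate(gm2.samples["population"]) if p == pop]
        for j in range(gm2.n_loci):
            col = [gm2.calls[i, j] for i in rows if gm2.calls[i, j] != MISSING]
            expected = sum(col) / (2 * len(col)) if col else np.nan
            got = freqs2.loc[pop].iloc[j]
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)


def test_euclidean_distance_arithmetic_and_loop_oracle(rng):
    freqs = pd.DataFrame(
        [[0.5, 0.5], [0.2, 0.9]], index=["A", "B"], columns=["m1", "m2"]
    )
    d = euclidean_distance_matrix(freqs)
    assert d.values[0, 1] == pytest.approx(0.5)  # sqrt(0.3^2 + 0.4^2)

    F = rng.random((4, 20))
    freqs4 = pd.DataFrame(F, index=list("ABCD"))
    d4 = euclidean_distance_matrix(freqs4)
    for i in range(4):
        assert d4.values[i, i] == 0.0
        for j in range(4):
            brute = np.sqrt(sum((F[i, k] - F[j, k]) ** 2 for k in range(20)))
            assert d4.values[i, j] == pytest.approx(brute, abs=1e-12)


def test_euclidean_identical_frequency_vectors():
    freqs = pd.DataFrame([[0.3, 0.7], [0.3, 0.7]], index=["A", "B"])
    assert euclidean_distance_matrix(freqs).values[0, 1] == 0.0


# ---------------------------------------------------------------------------
# Weir-Cockerham Fst
# ---------------------------------------------------------------------------


def test_fst_complete_differentiation():
    """Two populations fixed for alternate alleles give Fst exactly 1."""
    calls = np.vstack([np.zeros((6, 50)), np.full((6, 50), 2)]).astype(np.int8)
    gm = make_gm(calls, populations=["A"] * 6 + ["B"] * 6)
    res = pairwise_fst(gm, None, "A", "B", n_boot=50, seed=1)
    assert res.fst == pytest.approx(1.0)
    assert res.ci_low == pytest.approx(1.0) and res.ci_high == pytest.approx(1.0)


def test_fst_panmictic_null():
    """Two samples from one pool: |Fst| < 0.02."""
    cfg = SimConfig(n_pops=2, n_ind_per_pop=[50, 50], n_loci=1000,
                    target_fst=0.0, f_roh_target=0.0, missing_rate=0.0, seed=5)
    gm, _ = simulate_dataset(cfg)
    res = pairwise_fst(gm, None, "P01", "P02", n_boot=50, seed=2)
    assert abs(res.fst) < 0.02


def test_fst_bootstrap_seed_reproducible(rng):
    gm = random_gm(rng, n_samples=20, n_loci=100,
                   populations=["A"] * 10 + ["B"] * 10, missing_rate=0.05)
    r1 = pairwise_fst(gm, None, "A", "B", n_boot=200, seed=99)
    r2 = pairwise_fst(gm, None, "A", "B", n_boot=200, seed=99)
    assert (r1.fst, r1.ci_low, r1.ci_high) == (r2.fst, r2.ci_low, r2.ci_high)


def test_fst_monotone_in_divergence():
    ests = []
    for F in (0.05, 0.15, 0.30):
        cfg = SimConfig(n_pops=2, n_ind_per_pop=[30, 30], n_loci=2000,
                        target_fst=F, f_roh_target=0.0, missing_rate=0.0, seed=17)
        gm, _ = simulate_dataset(cfg)
        ests.append(pairwise_fst(gm, None, "P01", "P02", n_boot=10, seed=3).fst)
    assert ests[0] < ests[1] < ests[2]


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


def brute_amova_ss(calls, pop_of_row, pops):
    """Sums of squares from explicit pairwise squared allele differences.

    Complete data only.  Per locus: SS of a set of allele copies equals the
    sum of pairwise squared differences divided by the number of copies.
    """
    calls = np.asarray(calls)
    n, L = calls.shape
    ss_total = ss_within_pop = ss_within_ind = 0.0
    for j in range(L):
        copies = []
        for i in range(n):
            d = calls[i, j]
            pair = (1, 1) if d == 2 else ((0, 1) if d == 1 else (0, 0))
            copies.append(pair)
        flat = [y for pair in copies for y in pair]
        ss_total += _ss_from_pairs(flat)
        for pop in pops:
            rows = [i for i in range(n) if pop_of_row[i] == pop]
            flat_p = [y for i in rows for y in copies[i]]
            ss_within_pop += _ss_from_pairs(flat_p)
        for i in range(n):
            ss_within_ind += _ss_from_pairs(list(copies[i]))
    ss_among_pop = ss_total - ss_within_pop
    ss_among_ind = ss_within_pop - ss_within_ind
    return ss_among_pop, ss_among_ind, ss_within_ind


def _ss_from_pairs(values):
    m = len(values)
    if m < 2:
        return 0.0
    return sum(
        (values[a] - values[b]) ** 2 for a in range(m) for b in range(a + 1, m)
    ) / m


def test_amova_ss_match_pairwise_brute_force(rng):
    """ANOVA-style sums equal the pairwise-distance partition on toys."""
    for _ in range(5):
        pops = ["A"] * 4 + ["B"] * 3 + ["C"] * 4
        calls = rng.integers(0, 3, size=(11, 10)).astype(np.int8)
        gm = make_gm(calls, populations=pops)
        pop_idx = np.array([("A", "B", "C").index(p) for p in pops])
        ss_pop, ss_ind, ss_w, *_ = _amova_sums(gm.calls, pop_idx, 3)
        bp, bi, bw = brute_amova_ss(calls, pops, ("A", "B", "C"))
        assert ss_pop.sum() == pytest.approx(bp, abs=1e-9)
        assert ss_ind.sum() == pytest.approx(bi, abs=1e-9)
        assert ss_w.sum() == pytest.approx(bw, abs=1e-9)


def test_amova_identical_individuals_all_zero():
    gm = make_gm(np.full((8, 10), 2, dtype=np.int8),
                 populations=["A"] * 4 + ["B"] * 4)
    res = amova(gm, n_perm=19, seed=0)
    assert res.sigma_among_pops == res.sigma_among_ind == res.sigma_within_ind == 0.0
    assert res.pct_among_pops + res.pct_among_ind + res.pct_within_ind == pytest.approx(100)


def test_amova_fixed_populations():
    """Opposite fixation: all non-zero variance lies among populations."""
    calls = np.vstack([np.zeros((5, 20)), np.full((5, 20), 2)]).astype(np.int8)
    gm = make_gm(calls, populations=["A"] * 5 + ["B"] * 5)
    res = amova(gm, n_perm=99, seed=1)
    assert res.pct_among_pops == pytest.approx(100.0)
    assert res.sigma_among_ind == pytest.approx(0.0, abs=1e-12)
    assert res.sigma_within_ind == pytest.approx(0.0, abs=1e-12)
    # p bounded by the tie-adjusted minimum: only the exact repartition of
    # individuals reproduces the observed among-population variance
    assert res.p_among_pops <= 0.15


def test_amova_percentages_sum_and_structured_significance():
    cfg = SimConfig(n_pops=3, n_ind_per_pop=[10, 10, 10], n_loci=300,
                    target_fst=0.3, f_roh_target=0.0, missing_rate=0.02, seed=8)
    gm, _ = simulate_dataset(cfg)
    res = amova(gm, n_perm=99, seed=4)
    assert res.pct_among_pops + res.pct_among_ind + res.pct_within_ind == pytest.approx(
        100.0, abs=1e-6
    )
    assert res.p_among_pops <= 0.05
    assert res.pct_among_pops > 15
    assert 0 < res.p_among_pops <= 1


def test_amova_single_population_errors(rng):
    gm = random_gm(rng, n_samples=6, n_loci=10, populations=["A"] * 6)
    with pytest.raises(ValueError):
        amova(gm, n_perm=9, seed=0)


def test_amova_null_permutation_calibration():
    """Panmictic data: permutation p is roughly uniform, not skewed small."""
    ps = []
    for seed in range(12):
        cfg = SimConfig(n_pops=3, n_ind_per_pop=[8, 8, 8], n_loci=100,
                        target_fst=0.0, f_roh_target=0.0, missing_rate=0.0,
                        seed=100 + seed)
        gm, _ = simulate_dataset(cfg)
        ps.append(amova(gm, n_perm=49, seed=seed).p_among_pops)
    assert 0.2 < np.mean(ps) < 0.8


# ---------------------------------------------------------------------------
# Neighbor joining and PCoA
# ---------------------------------------------------------------------------


def _patristic(newick, labels):
    import io
    from skbio import TreeNode

    tree = TreeNode.read(io.StringIO(newick))
    dm = tree.tip_tip_distances(endpoints=list(labels))
    return np.array([[dm[a, b] for b in labels] for a in labels])


def test_nj_three_taxa_closed_form():
    d = DistanceMatrix(["a", "b", "c"],
                       np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float))
    newick = neighbor_joining_tree(d)
    np.testing.assert_allclose(_patristic(newick, "abc"), d.values, atol=1e-9)


def test_nj_additive_four_taxon_recovery():
    """Additive metric: patristic distances reproduce the input exactly."""
    vals = np.array(
        [[0, 5, 9, 9], [5, 0, 10, 10], [9, 10, 0, 8], [9, 10, 8, 0]], dtype=float
    )
    d = DistanceMatrix(list("abcd"), vals)
    newick = neighbor_joining_tree(d)
    np.testing.assert_allclose(_patristic(newick, "abcd"), vals, atol=1e-9)
    # the generating cherry (a,b) must appear: a-b path avoids c/d edges
    assert "a" in newick and "b" in newick


def test_nj_label_order_invariance():
    vals = np.array(
        [[0, 5, 9, 9], [5, 0, 10, 10], [9, 10, 0, 8], [9, 10, 8, 0]], dtype=float
    )
    d1 = DistanceMatrix(list("abcd"), vals)
    perm = [2, 0, 3, 1]
    d2 = DistanceMatrix([list("abcd")[i] for i in perm], vals[np.ix_(perm, perm)])
    p1 = _patristic(neighbor_joining_tree(d1), "abcd")
    p2 = _patristic(neighbor_joining_tree(d2), "abcd")
    np.testing.assert_allclose(p1, p2, atol=1e-9)


def test_nj_too_few_labels():
    with pytest.raises(ValueError):
        neighbor_joining_tree(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0.]])))


def test_pcoa_reconstructs_euclidean_distances(rng):
    pts = rng.random((6, 3))
    d = DistanceMatrix([f"p{i}" for i in range(6)], squareform(pdist(pts)))
    coords, eigvals = pcoa(d)
    rec = squareform(pdist(coords.to_numpy()))
    np.testing.assert_allclose(rec, d.values, atol=1e-9)
    assert (np.diff(eigvals) <= 1e-9).all()  # non-increasing


def test_pcoa_identical_points():
    d = DistanceMatrix(list("abc"), np.zeros((3, 3)))
    coords, eigvals = pcoa(d)
    np.testing.assert_allclose(eigvals, 0.0, atol=1e-12)
    assert coords.shape[1] == 0


def test_distance_matrix_validation():
    with pytest.raises(ValueError):
        DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0.]]))
    with pytest.raises(ValueError):
        DistanceMatrix(["a", "b"], np.array([[1, 1], [1, 0.]]))
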