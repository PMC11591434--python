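"""ROH scanner, F_ROH, incidence, islands and LD decay."""

import numpy as np
import pytest

from rohsignal.genotype_io import MISSING
from rohsignal.roh_analysis import (
    ROHIncidence,
    ROHParams,
    ROHSegment,
    f_roh,
    ld_decay,
    roh_incidence,
    roh_islands,
    scan_roh,
    segments_to_frame,
)

from conftest import make_gm


def het_background(rng, n_loci, het_rate=0.5):
    """Genotypes with enough heterozygosity that no window passes."""
    return rng.choice([0, 1, 2], size=n_loci, p=[(1 - het_rate) / 2, het_rate,
                                                 (1 - het_rate) / 2]).astype(np.int8)


def test_fully_heterozygous_individual_has_no_segments():
    calls = np.ones((1, 500), dtype=np.int8)
    gm = make_gm(calls, positions=np.arange(1, 501) * 10_000)
    assert scan_roh(gm, ROHParams()) == []


def test_fully_homozygous_chromosome_single_segment():
    """500 homozygous SNPs over 5 Mb with no gaps -> exactly one segment
    spanning the first to last SNP."""
    pos = np.arange(1, 501) * 10_000
    calls = np.zeros((1, 500), dtype=np.int8)
    gm = make_gm(calls, positions=pos)
    segs = scan_roh(gm, ROHParams())
    assert len(segs) == 1
    s = segs[0]
    assert (s.start_pos, s.end_pos, s.n_snps) == (10_000, 5_000_000, 500)


def test_implanted_tract_recovered_within_window_span(rng):
    """A 200-SNP homozygous tract in a het background is found with
    boundaries within one window span of the implant."""
    n_loci = 1000
    pos = np.sort(rng.choice(50_000_000, n_loci, replace=False)) + 1
    calls = het_background(rng, n_loci)[None, :].copy()
    lo, hi = 400, 599  # implant indices
    calls[0, lo : hi + 1] = rng.choice([0, 2], size=200)
    gm = make_gm(calls, positions=pos)
    params = ROHParams(min_length_kb=100)  # sparse toy map
    segs = scan_roh(gm, params)
    assert len(segs) >= 1
    cover = [s for s in segs if s.start_pos <= pos[500] <= s.end_pos]
    assert len(cover) == 1
    s = cover[0]
    start_idx = int(np.searchsorted(pos, s.start_pos))
    end_idx = int(np.searchsorted(pos, s.end_pos))
    assert abs(start_idx - lo) <= params.window_snps
    assert abs(end_idx - hi) <= params.window_snps


def test_segments_never_overlap_or_span_chromosomes(rng):
    n_loci = 800
    chroms = ["1"] * 400 + ["2"] * 400
    pos = np.concatenate([np.sort(rng.choice(30_000_000, 400, replace=False)) + 1
                          for _ in range(2)])
    calls = np.vstack([
        np.zeros(n_loci, dtype=np.int8),
        het_background(rng, n_loci),
    ])
    gm = make_gm(calls, chroms=chroms, positions=pos)
    segs = scan_roh(gm, ROHParams(min_length_kb=100))
    frame = segments_to_frame(segs)
    for (sample, chrom), grp in frame.groupby(["sample_id", "chrom"]):
        grp = grp.sort_values("start_pos")
        assert (grp["start_pos"].to_numpy()[1:] > grp["end_pos"].to_numpy()[:-1]).all()
    # chromosome bounds respected
    for _, row in frame.iterrows():
        sub = [p for c, p in zip(chroms, pos) if c == row["chrom"]]
        assert min(sub) <= row["start_pos"] <= row["end_pos"] <= max(sub)


def test_max_gap_splits_runs(rng):
    """A >1000 kb gap inside a homozygous run splits the segment."""
    pos = np.concatenate([
        np.arange(1, 201) * 10_000,                 # 10 kb spacing
        np.arange(1, 201) * 10_000 + 3_500_000,     # 1.5 Mb gap
    ])
    calls = np.zeros((1, 400), dtype=np.int8)
    gm = make_gm(calls, positions=pos)
    segs = scan_roh(gm, ROHParams(min_length_kb=500))
    assert len(segs) == 2


def test_f_roh_arithmetic_and_bounds():
    params = ROHParams(genome_size_bp=930_820_000)
    segs = [ROHSegment("s1", "1", 1, 93_082_000, 1200)]
    assert f_roh(segs, "s1", params) == pytest.approx(0.1)
    assert f_roh([], "s1", params) == 0.0
    whole = [ROHSegment("s1", "1", 1, 930_820_000, 12_000)]
    assert f_roh(whole, "s1", params) == pytest.approx(1.0)


def test_f_roh_rejects_overlapping_segments():
    segs = [
        ROHSegment("s1", "1", 100, 5000, 60),
        ROHSegment("s1", "1", 4000, 9000, 60),
    ]
    with pytest.raises(ValueError, match="overlapping"):
        f_roh(segs, "s1")


def test_roh_incidence_interval_stabbing(rng):
    """Carrier counts equal a brute-force per-locus interval-stabbing scan."""
    n_loci = 300
    pos = np.sort(rng.choice(10_000_000, n_loci, replace=False)) + 1
    gm = make_gm(np.zeros((10, n_loci), dtype=np.int8), positions=pos,
                 sample_ids=[f"i{k}" for k in range(10)])
    segs = []
    for k in range(10):
        for _ in range(rng.integers(0, 4)):
            a, b = sorted(rng.integers(1, 10_000_000, size=2))
            segs.append(ROHSegment(f"i{k}", "1", int(a), int(b), 999))
    # de-overlap per individual to satisfy the scanner contract
    cleaned = []
    for k in range(10):
        own = sorted((s for s in segs if s.sample_id == f"i{k}"),
                     key=lambda s: s.start_pos)
        last_end = 0
        for s in own:
            if s.start_pos > last_end:
                cleaned.append(s)
                last_end = s.end_pos
    inc = roh_incidence(cleaned, gm)
    for j in range(n_loci):
        brute = sum(
            1
            for k in range(10)
            if any(
                s.sample_id == f"i{k}" and s.start_pos <= pos[j] <= s.end_pos
                for s in cleaned
            )
        )
        assert inc.carriers[j] == brute
    assert ((0 <= inc.incidence_pct) & (inc.incidence_pct <= 100)).all()


def test_roh_incidence_examples():
    gm = make_gm(np.zeros((119, 3), dtype=np.int8), positions=[100, 5000, 9000],
                 sample_ids=[f"i{k}" for k in range(119)])
    segs = [ROHSegment(f"i{k}", "1", 4000, 6000, 60) for k in range(64)]
    inc = roh_incidence(segs, gm)
    assert inc.incidence_pct[0] == 0.0
    assert round(float(inc.incidence_pct[1]), 2) == 53.78
    all_cov = [ROHSegment(f"i{k}", "1", 1, 10_000, 60) for k in range(119)]
    assert roh_incidence(all_cov, gm).incidence_pct[2] == 100.0


def test_roh_islands_quantile_and_ties():
    loci_stub = make_gm(np.zeros((1, 1000), dtype=np.int8)).loci
    distinct = ROHIncidence(loci_stub, np.arange(1000), 1000)
    top = roh_islands(distinct, 0.01)
    assert len(top) == 10 and set(top) == set(range(990, 1000))
    tied = ROHIncidence(loci_stub, np.full(1000, 7), 1000)
    assert len(roh_islands(tied, 0.01)) == 1000


def test_roh_islands_planted_cluster(rng):
    carriers = rng.integers(0, 5, size=500)
    carriers[100:110] = 90  # planted high-incidence cluster
    inc = ROHIncidence(make_gm(np.zeros((1, 500), dtype=np.int8)).loci,
                       carriers, 100)
    islands = set(roh_islands(inc, 0.02))
    assert set(range(100, 110)) <= islands


def test_ld_decay_duplicated_adjacent_loci(rng):
    base = rng.binomial(2, 0.5, size=(40, 1)).astype(np.int8)
    indep = rng.binomial(2, 0.5, size=(40, 1)).astype(np.int8)
    calls = np.column_stack([base, base, indep])
    gm = make_gm(calls, positions=[1000, 2000, 900_000])
    tab = ld_decay(gm, "pop1", max_dist_kb=1000, bin_kb=100)
    assert tab["mean_r2"].iloc[0] == pytest.approx(1.0)
    assert tab["n_pairs"].sum() == 3


def test_ld_decay_unlinked_null_expectation(rng):
    """Independent loci: mean r^2 is near the finite-sample floor 1/n."""
    n = 50
    calls = rng.binomial(2, 0.5, size=(n, 200)).astype(np.int8)
    gm = make_gm(calls, positions=np.arange(1, 201) * 5_000)
    tab = ld_decay(gm, "pop1", max_dist_kb=1000, bin_kb=250)
    got = np.nansum(tab["mean_r2"] * tab["n_pairs"]) / tab["n_pairs"].sum()
    assert got == pytest.approx(1 / n, rel=0.5)


def test_ld_decay_monotone_on_block_structure():
    from rohsignal.synthetic_data import SimConfig, simulate_dataset

    cfg = SimConfig(n_pops=1, n_ind_per_pop=[40], n_loci=3000, target_fst=0.3,
                    f_roh_target=0.0, missing_rate=0.0, ld_block_snps=20,
                    ld_pool_size=4, seed=21)
    gm, _ = simulate_dataset(cfg)
    tab = ld_decay(gm, "P01", max_dist_kb=4000, bin_kb=1000)
    ok = tab.dropna(subset=["mean_r2"])
    assert ok["mean_r2"].iloc[0] > ok["mean_r2"].iloc[-1]
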