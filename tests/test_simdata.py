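"""Generator correctness: marker maps, crossovers, gametes, SVs, digestion."""

import numpy as np
import pytest
from scipy import stats as sps

from conftest import brute_force_digest_cuts
from gametemap.constants import HET, HOM0, HOM1
from gametemap.simdata import (
    AneuploidySpec,
    SimConfig,
    digest_sequence,
    fragment_length_summary,
    simulate_crossovers,
    simulate_dataset,
    simulate_gamete,
    simulate_nonhaploid_cell,
    simulate_snp_map,
    simulate_sv_dataset,
)

# ---------------------------------------------------------------------------
# marker map


def test_snp_map_positions_sorted_and_in_range():
    cfg = SimConfig(chromosomes={"chr1": 100_000_000}, snps_per_chrom=1000, seed=5)
    m = simulate_snp_map(cfg)
    pos = m.positions["chr1"]
    assert pos.size == 1000
    assert (np.diff(pos) > 0).all()
    assert pos.min() >= 1 and pos.max() <= 100_000_000
    assert (m.allele0["chr1"] != m.allele1["chr1"]).all()


def test_snp_map_deterministic_under_seed():
    cfg = SimConfig(chromosomes={"chrA": 5_000_000}, snps_per_chrom=500, seed=7)
    m1 = simulate_snp_map(cfg)
    m2 = simulate_snp_map(cfg)
    np.testing.assert_array_equal(m1.positions["chrA"], m2.positions["chrA"])
    np.testing.assert_array_equal(m1.allele0["chrA"], m2.allele0["chrA"])


def test_snp_count_exceeding_length_rejected():
    cfg = SimConfig(chromosomes={"chr1": 100}, snps_per_chrom=200, seed=0)
    with pytest.raises(ValueError, match="exceed"):
        simulate_snp_map(cfg)


def test_mean_spacing_matches_order_statistics():
    """Mean inter-site spacing of uniform draws is ~L/(n+1) (within 3
    standard errors of the 50-seed empirical mean)."""
    length, n = 10_000_000, 1000
    means = []
    for seed in range(50):
        cfg = SimConfig(chromosomes={"c": length}, snps_per_chrom=n, seed=seed)
        means.append(np.diff(simulate_snp_map(cfg).positions["c"]).mean())
    means = np.array(means)
    expected = length / (n + 1)
    se = means.std(ddof=1) / np.sqrt(len(means))
    assert abs(means.mean() - expected) < 3 * se


# ---------------------------------------------------------------------------
# crossovers


def test_zero_rate_gives_no_crossovers():
    assert simulate_crossovers(1_000_000, 0.0, 1.0, 3).size == 0


def test_no_interference_gives_exponential_gaps():
    """Shape 1 renewal is a Poisson process: inter-crossover distances
    pass a KS test against the exponential at alpha=0.01."""
    rng = np.random.default_rng(42)
    gaps = []
    while len(gaps) < 10_000:
        xo = simulate_crossovers(1e8, 50.0, 1.0, rng)
        gaps.extend(np.diff(xo))
    gaps = np.array(gaps[:10_000])
    stat = sps.kstest(gaps, "expon", args=(0, 1e8 / 50.0))
    assert stat.pvalue > 0.01


def test_interference_inflates_gap_median():
    rng = np.random.default_rng(43)
    gaps1, gaps5 = [], []
    for _ in range(300):
        gaps1.extend(np.diff(simulate_crossovers(1e8, 40.0, 1.0, rng)))
        gaps5.extend(np.diff(simulate_crossovers(1e8, 40.0, 5.0, rng)))
    assert np.median(gaps5) > np.median(gaps1)


def test_crossovers_inside_chromosome_and_sorted():
    rng = np.random.default_rng(44)
    for _ in range(50):
        xo = simulate_crossovers(5e7, 3.0, 5.0, rng, obligate=True)
        assert (np.diff(xo) > 0).all()
        assert ((xo > 0) & (xo < 5e7)).all()


def test_obligate_bivalent_thinning_rate():
    """With the obligate flag the chromatid inherits each bivalent
    crossover with probability 1/2; the bivalent itself always has one."""
    rng = np.random.default_rng(45)
    counts = [simulate_crossovers(1e8, 2.0, 1.0, rng, obligate=True).size for _ in range(2000)]
    # conditional bivalent mean = mu / (1 - exp(-mu)); chromatid = half
    mu = 2.0
    expect = 0.5 * mu / (1 - np.exp(-mu))
    assert abs(np.mean(counts) - expect) < 0.1


def test_expected_count_scales_with_length():
    """Proportional-to-length rate model: expected chromatid counts are
    linear in chromosome length (Pearson r > 0.99)."""
    lengths = np.array([30, 60, 90, 120, 150, 180]) * 1e6
    cfg = SimConfig(seed=0)
    expected = [cfg.expected_chromatid_crossovers(int(l)) for l in lengths]
    r = sps.pearsonr(lengths, expected)[0]
    assert r > 0.99


# ---------------------------------------------------------------------------
# gametes


def _one_cell_bundle(seed=0, **overrides):
    kwargs = dict(
        chromosomes={"chr1": 10_000_000},
        snps_per_chrom=2000,
        n_haploid=1,
        n_diploid=0,
        seed=seed,
    )
    kwargs.update(overrides)
    return simulate_dataset(SimConfig(**kwargs))


def test_noise_free_gamete_equals_truth():
    b = _one_cell_bundle(error_rate=0.0, dropout_rate=0.0)
    cell = b.cells[0]
    truth = b.truth[cell.cell_id]
    states = truth.states("chr1", cell.data["pos"].to_numpy())
    np.testing.assert_array_equal(cell.data["gt"].to_numpy(), states)
    assert len(cell.data) == 2000


def test_gamete_error_rate_calibrated():
    """Observed mismatch fraction against truth is 0.035 within 3 binomial
    standard errors over 10^4 sites (sequencing accuracy 96.5%)."""
    b = _one_cell_bundle(snps_per_chrom=10_000, error_rate=0.035, dropout_rate=0.0, seed=9)
    cell = b.cells[0]
    truth = b.truth[cell.cell_id]
    states = truth.states("chr1", cell.data["pos"].to_numpy())
    mismatch = (cell.data["gt"].to_numpy() != states).mean()
    se = np.sqrt(0.035 * 0.965 / 10_000)
    assert abs(mismatch - 0.035) < 3 * se


def test_full_dropout_leaves_nothing():
    b = _one_cell_bundle(dropout_rate=1.0)
    assert len(b.cells[0].data) == 0


def test_support_counts_consistent_with_call():
    b = _one_cell_bundle(seed=3)
    df = b.cells[0].data
    hom0 = df[df["gt"] == HOM0]
    hom1 = df[df["gt"] == HOM1]
    assert (hom0["ad0"] >= 1).all() and (hom0["ad1"] == 0).all()
    assert (hom1["ad1"] >= 1).all() and (hom1["ad0"] == 0).all()


# ---------------------------------------------------------------------------
# non-haploid cells


def test_diploid_without_dropout_is_fully_heterozygous():
    b = _one_cell_bundle(n_haploid=0, n_diploid=1, error_rate=0.0, dropout_rate=0.0)
    cell = b.cells[0]
    assert len(cell.data) == 2000
    assert (cell.data["gt"] == HET).all()


def _aneuploid_bundle(specs, **overrides):
    kwargs = dict(
        chromosomes={f"chr{i}": 10_000_000 for i in (1, 6, 11, 19)},
        snps_per_chrom=400,
        n_haploid=0,
        n_diploid=0,
        aneuploid_specs=(tuple(specs),),
        error_rate=0.0,
        dropout_rate=0.0,
        seed=17,
    )
    kwargs.update(overrides)
    return simulate_dataset(SimConfig(**kwargs))


def test_chromosome_loss_silences_only_that_chromosome():
    b = _aneuploid_bundle([AneuploidySpec("chr11", "loss")])
    df = b.cells[0].data
    assert (df["chrom"] != "chr11").all()
    for chrom in ("chr1", "chr6", "chr19"):
        assert (df["chrom"] == chrom).sum() == 400


def test_chromatid_gain_heterozygous_only_on_gained_chromosomes():
    b = _aneuploid_bundle(
        [AneuploidySpec(c, "gain") for c in ("chr1", "chr6", "chr19")]
    )
    df = b.cells[0].data
    het_by_chrom = df.groupby("chrom").apply(
        lambda g: (g["gt"] == HET).any(), include_groups=False
    )
    assert not het_by_chrom["chr11"]
    for chrom in ("chr1", "chr6", "chr19"):
        assert het_by_chrom[chrom]


def test_unknown_chromosome_in_spec_rejected():
    with pytest.raises(ValueError, match="unknown chromosome"):
        _aneuploid_bundle([AneuploidySpec("chr99", "loss")])


def test_partial_loss_restricted_to_interval():
    b = _aneuploid_bundle([AneuploidySpec("chr1", "loss", interval=(1, 2_500_000))])
    df = b.cells[0].data
    chr1 = df[df["chrom"] == "chr1"]
    assert (chr1["pos"] > 2_500_000).all()
    assert len(chr1) > 0


# ---------------------------------------------------------------------------
# SVs


def test_sv_matrix_reflects_ancestry_without_noise():
    cfg = SimConfig(
        chromosomes={"chr1": 50_000_000},
        n_haploid=12,
        n_svs=60,
        sv_missing_rate=0.0,
        sv_flip_rate=0.0,
        seed=21,
    )
    sv = simulate_sv_dataset(cfg)
    np.testing.assert_array_equal(
        sv.matrix, (sv.ancestry == sv.carrier[:, None]).astype(np.int8)
    )


def test_crossover_free_cells_have_identical_or_complementary_columns():
    """Without crossovers a cell's column is fully determined by its
    single inherited haplotype: columns agree within a haplotype group
    and are complementary between groups."""
    cfg = SimConfig(
        chromosomes={"chr1": 50_000_000},
        n_haploid=10,
        n_svs=40,
        xo_rate_per_mb=0.0,
        proportional_to_length=True,
        obligate=False,
        sv_missing_rate=0.0,
        sv_flip_rate=0.0,
        seed=22,
    )
    sv = simulate_sv_dataset(cfg)
    assert (sv.ancestry == sv.ancestry[0]).all(axis=0).all()  # constant per cell
    hap = sv.ancestry[0]
    for i in range(sv.matrix.shape[1]):
        if hap[i] == hap[0]:
            np.testing.assert_array_equal(sv.matrix[:, i], sv.matrix[:, 0])
        else:
            np.testing.assert_array_equal(sv.matrix[:, i], 1 - sv.matrix[:, 0])


def test_sv_missing_rate_calibrated():
    cfg = SimConfig(
        chromosomes={"chr1": 50_000_000}, n_haploid=50, n_svs=200,
        sv_missing_rate=0.05, seed=23,
    )
    sv = simulate_sv_dataset(cfg)
    frac = (sv.matrix == -1).mean()
    se = np.sqrt(0.05 * 0.95 / sv.matrix.size)
    assert abs(frac - 0.05) < 3 * se


def test_single_crossover_switches_parental_pattern_exactly_once():
    cfg = SimConfig(
        chromosomes={"chr1": 50_000_000}, n_haploid=30, n_svs=50,
        sv_missing_rate=0.0, sv_flip_rate=0.0, seed=24,
    )
    sv = simulate_sv_dataset(cfg)
    # parental label per locus = presence XOR (1 XOR carrier) = ancestry
    switches = (np.diff(sv.ancestry, axis=0) != 0).sum(axis=0)
    one_xo = np.flatnonzero(switches == 1)
    assert one_xo.size > 0
    for i in one_xo[:3]:
        relabeled = 1 ^ sv.matrix[:, i] ^ sv.carrier
        np.testing.assert_array_equal(relabeled, sv.ancestry[:, i])
        assert (np.diff(relabeled) != 0).sum() == 1


# ---------------------------------------------------------------------------
# digestion


def test_digest_hand_example():
    r = digest_sequence("AAAGAATTCAAA", "GAATTC", 1)
    np.testing.assert_array_equal(r.cuts, [4])
    np.testing.assert_array_equal(r.fragment_lengths, [4, 8])


def test_digest_no_occurrence_single_fragment():
    r = digest_sequence("ACGTACGT", "GAATTC", 1)
    assert r.cuts.size == 0
    np.testing.assert_array_equal(r.fragment_lengths, [8])


def test_digest_counts_overlapping_occurrences():
    r = digest_sequence("AAAA", "AA", 1)
    np.testing.assert_array_equal(r.cuts, [1, 2, 3])
    np.testing.assert_array_equal(r.fragment_lengths, [1, 1, 1, 1])


def test_digest_rejects_ambiguous_site_and_bad_offset():
    with pytest.raises(ValueError):
        digest_sequence("ACGT", "GANTC", 1)
    with pytest.raises(ValueError):
        digest_sequence("ACGT", "GAATTC", 7)


def test_digest_agrees_with_brute_force_scan(rng):
    for _ in range(100):
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        site = "".join(rng.choice(list("ACGT"), size=int(rng.integers(2, 5))))
        offset = int(rng.integers(0, len(site) + 1))
        r = digest_sequence(seq, site, offset)
        assert list(r.cuts) == brute_force_digest_cuts(seq, site, offset)
        assert r.fragment_lengths.sum() == len(seq)
        assert r.fragment_lengths.size == r.cuts.size + 1


def test_fragment_summary_hand_examples():
    s = fragment_length_summary([500, 1500, 2500, 5000])
    assert s.frac_fragments_in_window == 0.5
    assert fragment_length_summary([1000, 2000, 3000]).frac_fragments_in_window == 1.0
    assert fragment_length_summary([500, 1500]).frac_bp_in_window == 1500 / 2000
    with pytest.raises(ValueError):
        fragment_length_summary([])


# ---------------------------------------------------------------------------
# determinism


def test_dataset_byte_identical_under_seed():
    cfg = SimConfig(
        chromosomes={"chr1": 5_000_000, "chr2": 4_000_000},
        snps_per_chrom=300,
        n_haploid=5,
        n_diploid=2,
        seed=99,
    )
    b1, b2 = simulate_dataset(cfg), simulate_dataset(cfg)
    for c1, c2 in zip(b1.cells, b2.cells):
        assert c1.data.equals(c2.data)
    for cid in b1.truth:
        for chrom in b1.truth[cid].crossovers:
            np.testing.assert_array_equal(
                b1.truth[cid].crossovers[chrom], b2.truth[cid].crossovers[chrom]
            )
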