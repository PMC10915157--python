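"""SV matching/merging rules and the matrix-phasing pipeline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gametemap.simdata import SimConfig, simulate_sv_dataset
from gametemap.svphase import (
    SvCall,
    SvGenotypeMatrix,
    assemble_haplotypes,
    build_sv_matrix,
    impute_missing,
    loo_proofread,
    match_sv,
    merge_sv_calls,
    select_framework,
    sv_phasing_metrics,
    sv_precision_recall,
)

# ---------------------------------------------------------------------------
# matching


def test_match_insertions_by_breakpoint_and_length():
    assert match_sv(SvCall("chr1", 1000, "INS", 120), SvCall("chr1", 1400, "INS", 150))
    assert not match_sv(SvCall("chr1", 1000, "INS", 120), SvCall("chr1", 1600, "INS", 120))


def test_match_deletions_by_overlap_and_length():
    assert match_sv(SvCall("chr1", 100, "DEL", 200), SvCall("chr1", 150, "DEL", 200))
    assert not match_sv(SvCall("chr1", 100, "DEL", 100), SvCall("chr1", 300, "DEL", 100))


def test_length_tolerance_is_hard():
    a = SvCall("chr1", 1000, "INS", 100)
    assert not match_sv(a, SvCall("chr1", 1000, "INS", 250))
    d = SvCall("chr1", 1000, "DEL", 100)
    assert not match_sv(d, SvCall("chr1", 1000, "DEL", 250))


def test_type_and_chromosome_mismatch_is_no_match():
    assert not match_sv(SvCall("chr1", 100, "DEL", 100), SvCall("chr1", 100, "INS", 100))
    assert not match_sv(SvCall("chr1", 100, "DEL", 100), SvCall("chr2", 100, "DEL", 100))


def test_ins_match_is_symmetric():
    a = SvCall("chr1", 1000, "INS", 120)
    b = SvCall("chr1", 1400, "INS", 180)
    assert match_sv(a, b) == match_sv(b, a)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    p1=st.integers(1, 10_000), l1=st.integers(50, 500),
    p2=st.integers(1, 10_000), l2=st.integers(50, 500),
)
def test_del_overlap_agrees_with_interval_oracle(p1, l1, p2, l2):
    a, b = SvCall("chr1", p1, "DEL", l1), SvCall("chr1", p2, "DEL", l2)
    overlap = max(0, min(p1 + l1, p2 + l2) - max(p1, p2))
    want = overlap >= 1 and abs(l1 - l2) <= 100
    assert match_sv(a, b) == want


# ---------------------------------------------------------------------------
# merging / precision


def test_merge_jittered_calls_from_two_cells():
    calls = {
        "a": pd.DataFrame([{"chrom": "chr1", "pos": 1000, "svtype": "INS", "length": 120}]),
        "b": pd.DataFrame([{"chrom": "chr1", "pos": 1300, "svtype": "INS", "length": 130}]),
    }
    merged = merge_sv_calls(calls)
    assert len(merged) == 1
    assert merged[0].support == 2
    assert merged[0].pos == 1150 and merged[0].length == 125


def test_merge_discards_small_and_splits_distant():
    calls = {
        "a": pd.DataFrame(
            [
                {"chrom": "chr1", "pos": 1000, "svtype": "DEL", "length": 40},
                {"chrom": "chr1", "pos": 5000, "svtype": "INS", "length": 80},
                {"chrom": "chr1", "pos": 5600, "svtype": "INS", "length": 80},
            ]
        )
    }
    merged = merge_sv_calls(calls)
    assert all(c.length >= 50 for c in merged)
    assert sum(c.svtype == "INS" for c in merged) == 2  # 600 bp apart: two clusters
    assert not any(c.svtype == "DEL" for c in merged)


def test_precision_recall_counts():
    bench = [SvCall("chr1", i * 10_000, "INS", 100) for i in range(1, 11)]
    merged = [SvCall("chr1", i * 10_000 + 50, "INS", 110, support=2) for i in range(1, 9)]
    merged += [SvCall("chr1", 900_000 + i, "INS", 100, support=1) for i in (0, 5_000)]
    table = sv_precision_recall(merged, bench, support_levels=(1, 2))
    row1 = table.set_index("min_support").loc[1]
    assert row1["tp"] == 8 and row1["precision"] == pytest.approx(0.8)
    assert row1["recall"] == pytest.approx(0.8)
    row2 = table.set_index("min_support").loc[2]
    assert row2["precision"] == 1.0


def test_benchmark_records_credited_once():
    bench = [SvCall("chr1", 1000, "INS", 100)]
    merged = [SvCall("chr1", 1000, "INS", 100), SvCall("chr1", 1100, "INS", 100)]
    table = sv_precision_recall(merged, bench, support_levels=(1,))
    assert table.loc[0, "tp"] == 1
    assert table.loc[0, "precision"] == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# matrix construction


def test_build_matrix_rules():
    bench = pd.DataFrame(
        [
            {"chrom": "chr1", "pos": 1000, "svtype": "INS", "length": 100},
            {"chrom": "chr1", "pos": 5000, "svtype": "DEL", "length": 200},
        ]
    )
    calls = {
        "a": pd.DataFrame([{"chrom": "chr1", "pos": 1050, "svtype": "INS", "length": 130}]),
        "b": pd.DataFrame([{"chrom": "chr1", "pos": 1300, "svtype": "INS", "length": 100}]),
    }
    covered = np.array([[True, True], [True, False]])
    m = build_sv_matrix(calls, bench, covered)
    assert m.data[0, 0] == 1  # matching call within 100 bp
    assert m.data[0, 1] == 0  # 300 bp away: too far at matrix tolerance, covered
    assert m.data[1, 0] == 0  # covered, uncalled -> the other genotype
    assert m.data[1, 1] == -1  # uncovered


def test_framework_selection_rules():
    rng = np.random.default_rng(50)
    n_loci, n_cells = 30, 120
    data = rng.integers(0, 2, size=(n_loci, n_cells)).astype(np.int8)
    data[0, :] = -1
    data[0, :4] = 1  # genotyped in only 4 cells -> dropped
    data[1, :] = 0
    data[1, :2] = 1  # supported by 2 cells -> dropped
    loci = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(1, n_loci + 1) * 1000,
            "svtype": "INS",
            "length": 100,
        }
    )
    m = SvGenotypeMatrix(loci, [f"c{i:03d}" for i in range(n_cells)], data)
    fw = select_framework(m)
    assert fw.n_cells == 100
    assert 1000 not in fw.loci["pos"].values
    assert 2000 not in fw.loci["pos"].values


def test_framework_tiebreak_is_deterministic():
    data = np.ones((6, 5), dtype=np.int8)  # all cells identical totals
    loci = pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(1, 7) * 1000, "svtype": "DEL", "length": 100}
    )
    m = SvGenotypeMatrix(loci, ["e", "c", "a", "d", "b"], data)
    fw = select_framework(m, top_cells=3)
    assert sorted(fw.cell_ids) == ["a", "b", "c"]


def test_empty_framework_raises():
    data = np.full((3, 4), -1, dtype=np.int8)
    loci = pd.DataFrame(
        {"chrom": "chr1", "pos": [1, 2, 3], "svtype": "DEL", "length": 100}
    )
    with pytest.raises(ValueError, match="empty"):
        select_framework(SvGenotypeMatrix(loci, list("abcd"), data))


# ---------------------------------------------------------------------------
# proofreading / imputation / assembly on constructed matrices


def _clean_matrix(n_loci=40, n_cells=12, seed=60, spacing=300_000):
    """Noise-free presence matrix with known carriers and ancestries."""
    rng = np.random.default_rng(seed)
    carrier = rng.integers(0, 2, size=n_loci).astype(np.int8)
    ancestry = np.zeros((n_loci, n_cells), dtype=np.int8)
    for i in range(n_cells):
        state = rng.integers(0, 2)
        breaks = np.sort(rng.choice(n_loci - 1, size=rng.integers(0, 2), replace=False))
        col = np.full(n_loci, state, dtype=np.int8)
        for b in breaks:
            col[b + 1 :] = 1 - col[b + 1 :]
        ancestry[:, i] = col
    data = (ancestry == carrier[:, None]).astype(np.int8)
    loci = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(1, n_loci + 1) * spacing,
            "svtype": "INS",
            "length": 100,
        }
    )
    m = SvGenotypeMatrix(loci, [f"c{i:02d}" for i in range(n_cells)], data)
    return m, carrier, ancestry


def test_proofread_fixes_single_flip_without_exclusions():
    m, carrier, _ = _clean_matrix()
    original = m.data.copy()
    m.data[10, 3] = 1 - m.data[10, 3]
    corrected, report = loo_proofread(m)
    assert report.excluded_rows.size == 0
    np.testing.assert_array_equal(corrected.data, original)


def test_proofread_excludes_randomized_row():
    m, _, _ = _clean_matrix(n_cells=20, seed=61)
    rng = np.random.default_rng(0)
    m.data[15] = rng.integers(0, 2, size=m.n_cells).astype(np.int8)
    corrected, report = loo_proofread(m)
    assert 15 in report.excluded_rows
    assert corrected.n_loci == m.n_loci - report.excluded_rows.size


def test_impute_uses_consistent_flanks_only():
    m, carrier, ancestry = _clean_matrix(seed=62)
    truth = m.data.copy()
    m.data[20, 5] = -1
    imputed = impute_missing(m)
    assert imputed.data[20, 5] == truth[20, 5]


def test_impute_leaves_conflicts_missing():
    loci = pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(1, 8) * 100_000, "svtype": "INS", "length": 100}
    )
    # two supporting cells imply opposite values at the missing locus
    col_a = np.array([0, 0, 0, -1, 0, 0, 0], dtype=np.int8)
    col_b = np.array([0, 0, 0, 0, 0, 0, 0], dtype=np.int8)
    col_c = np.array([0, 0, 0, 1, 0, 0, 0], dtype=np.int8)
    m = SvGenotypeMatrix(loci, ["a", "b", "c"], np.stack([col_a, col_b, col_c], axis=1))
    imputed = impute_missing(m)
    assert imputed.data[3, 0] == -1


def test_impute_requires_enough_consecutive_support():
    loci = pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(1, 4) * 100_000, "svtype": "INS", "length": 100}
    )
    col_a = np.array([0, -1, 0], dtype=np.int8)
    col_b = np.array([0, 1, 0], dtype=np.int8)
    m = SvGenotypeMatrix(loci, ["a", "b"], np.stack([col_a, col_b], axis=1))
    imputed = impute_missing(m)  # only 1-locus flanks: below nSPT
    assert imputed.data[1, 0] == -1


def test_assembly_consensus_on_clean_matrix():
    m, carrier, _ = _clean_matrix(n_cells=15, seed=63)
    phased = assemble_haplotypes(m)
    bench = m.loci.assign(carrier=carrier)
    precision, recall = sv_phasing_metrics(phased, bench)
    assert precision == 1.0
    assert recall == 1.0


def test_assembly_drops_missing_and_enforces_min_cells():
    m, carrier, _ = _clean_matrix(n_cells=5, seed=64)
    m.data[0, :2] = -1  # two missing in one row -> row dropped
    m.data[5, 4] = -1  # one missing -> column c04 dropped
    phased = assemble_haplotypes(m)
    assert len(phased.loci) == m.n_loci - 1
    assert "c04" not in phased.cell_ids
    m2, _, _ = _clean_matrix(n_cells=3, seed=65)
    m2.data[3, 0] = -1
    with pytest.raises(ValueError, match="cells"):
        assemble_haplotypes(m2)


def test_blip_run_flipped_before_voting():
    """A 1-locus blip in one cell's mosaic is treated as an error under
    cvlink=2 and does not corrupt the consensus."""
    m, carrier, _ = _clean_matrix(n_cells=8, seed=66)
    m.data[12, 2] = 1 - m.data[12, 2]
    phased = assemble_haplotypes(m)
    bench = m.loci.assign(carrier=carrier)
    precision, _ = sv_phasing_metrics(phased, bench)
    assert precision == 1.0


def test_metrics_swap_invariance():
    m, carrier, _ = _clean_matrix(n_cells=10, seed=67)
    phased = assemble_haplotypes(m)
    bench = m.loci.assign(carrier=carrier)
    p1, _ = sv_phasing_metrics(phased, bench)
    bench_flipped = m.loci.assign(carrier=1 - carrier)
    p2, _ = sv_phasing_metrics(phased, bench_flipped)
    assert p1 == p2 == 1.0


# ---------------------------------------------------------------------------
# end-to-end on the generator


def test_pipeline_recovers_simulated_carriers():
    cfg = SimConfig(
        chromosomes={"chr1": 150_000_000}, n_haploid=60, n_svs=200,
        sv_missing_rate=0.05, sv_flip_rate=0.02, seed=68,
    )
    sv = simulate_sv_dataset(cfg)
    loci = pd.DataFrame(
        {
            "chrom": [s.chrom for s in sv.loci],
            "pos": [s.pos for s in sv.loci],
            "svtype": [s.svtype for s in sv.loci],
            "length": [s.length for s in sv.loci],
        }
    )
    m = SvGenotypeMatrix(loci, sv.cell_ids, sv.matrix)
    fw = select_framework(m)
    proofed, _ = loo_proofread(fw)
    imputed = impute_missing(proofed)
    phased = assemble_haplotypes(imputed)
    bench = loci.assign(carrier=sv.carrier)
    precision, recall = sv_phasing_metrics(phased, bench)
    assert precision >= 0.95
    assert recall >= 0.4
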