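"""Structural-variant benchmarking and gamete-matrix phasing.

Heterozygous deletions/insertions of an F1 hybrid segregate through
gametes exactly like SNP alleles: each gamete carries an SV wherever its
local parental ancestry equals the SV's carrier haplotype.  Stacking the
per-cell presence/absence genotypes over a benchmark hetSV set gives a
loci x cells matrix whose columns differ from each other only through
crossovers (plus genotyping noise), and the carrier haplotype of every SV
can be recovered — up to a global per-chromosome label swap — from the
co-segregation pattern.

The phasing pipeline follows a framework-selection / leave-one-out
HMM proofreading / imputation / consensus-assembly sequence:

1. ``select_framework`` keeps well-genotyped loci and the most informative
   cells;
2. ``loo_proofread`` holds out each cell in turn and decodes every other
   cell's *agreement vector* with the held-out cell using a two-state HMM
   whose switch probability scales with physical distance,
   ``P(d) = 1 - exp(-d * 1e-8)``.  The XOR of two cells' genotype vectors
   cancels the carrier labels and leaves the XOR of their ancestry
   mosaics — a piecewise-constant signal the HMM can smooth.  Loci where
   more than 5 cells (or at least half of the informative cells) disagree
   with the held-out cell are tallied as wrong; rows wrong in more than 5
   cells are excluded, rows wrong in fewer than 3 have the flagged
   entries flipped, the [3, 5] gap is left unchanged and reported;
3. ``impute_missing`` fills a missing entry only when supporting cells
   with a consistent local haplotype relation imply a single value over
   more than ``nspt`` consecutive flanking loci, with no conflict;
4. ``assemble_haplotypes`` drops loci with 2+ residual missing entries and
   cells with any, relabels every cell to a common parental frame via its
   own crossover segmentation (blip runs shorter than ``cvlink`` loci are
   treated as errors and flipped) and majority-votes the consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hmm import bidirectional_states, distance_switch_prob

__all__ = [
    "SvCall",
    "match_sv",
    "merge_sv_calls",
    "sv_precision_recall",
    "SvGenotypeMatrix",
    "build_sv_matrix",
    "select_framework",
    "loo_proofread",
    "impute_missing",
    "assemble_haplotypes",
    "PhasedSvHaplotype",
    "sv_phasing_metrics",
]

MISSING = -1
MIN_SV_SIZE = 50


@dataclass(frozen=True)
class SvCall:
    """One deletion or insertion call."""

    chrom: str
    pos: int  # 1-based breakpoint
    svtype: str  # "DEL" | "INS"
    length: int
    support: int = 1

    def __post_init__(self) -> None:
        if self.svtype not in ("DEL", "INS"):
            raise ValueError(f"svtype must be DEL or INS, got {self.svtype!r}")
        if self.length <= 0:
            raise ValueError("SV length must be positive")

    @property
    def end(self) -> int:
        return self.pos + self.length if self.svtype == "DEL" else self.pos


def match_sv(
    candidate: SvCall,
    reference: SvCall,
    max_bp_dist: int = 500,
    max_len_diff: int = 100,
) -> bool:
    """Benchmark matching rule: same chromosome and type; insertions need
    breakpoints within ``max_bp_dist`` bp, deletions need >= 1 bp interval
    overlap; both need lengths within ``max_len_diff`` bp."""
    if candidate.chrom != reference.chrom or candidate.svtype != reference.svtype:
        return False
    if abs(candidate.length - reference.length) > max_len_diff:
        return False
    if candidate.svtype == "INS":
        return abs(candidate.pos - reference.pos) <= max_bp_dist
    return candidate.pos < reference.end and reference.pos < candidate.end


def merge_sv_calls(
    per_cell_calls: dict[str, pd.DataFrame],
    max_distance: int = 500,
    min_size: int = MIN_SV_SIZE,
) -> list[SvCall]:
    """Merge per-cell SV calls by single-linkage clustering of breakpoints
    within type and chromosome (link when breakpoints are <= max_distance
    apart); the representative is the member-wise median position/length;
    merged calls shorter than ``min_size`` are discarded.  Support is the
    number of distinct cells in the cluster."""
    rows = []
    for cell, df in per_cell_calls.items():
        for rec in df.itertuples(index=False):
            rows.append((rec.chrom, rec.svtype, int(rec.pos), int(rec.length), cell))
    if not rows:
        return []
    table = pd.DataFrame(rows, columns=["chrom", "svtype", "pos", "length", "cell"])
    merged: list[SvCall] = []
    for (chrom, svtype), grp in table.groupby(["chrom", "svtype"], sort=False):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        # in 1-D, single linkage chains adjacent sorted breakpoints
        new_cluster = np.concatenate([[True], np.diff(pos) > max_distance])
        cluster_id = np.cumsum(new_cluster)
        for _, members in grp.assign(cluster=cluster_id).groupby("cluster"):
            length = int(np.median(members["length"]))
            if length < min_size:
                continue
            merged.append(
                SvCall(
                    chrom,
                    int(np.median(members["pos"])),
                    svtype,
                    length,
                    support=int(members["cell"].nunique()),
                )
            )
    merged.sort(key=lambda c: (c.chrom, c.pos))
    return merged


def sv_precision_recall(
    merged: list[SvCall],
    benchmark: list[SvCall],
    support_levels=(1, 2, 3),
    max_bp_dist: int = 500,
    max_len_diff: int = 100,
) -> pd.DataFrame:
    """Precision/recall of merged calls against the benchmark at rising
    cell-support thresholds.  A call is a true positive when it matches at
    least one benchmark record; each benchmark record is creditable once
    (split calls do not inflate precision)."""
    if not benchmark:
        raise ValueError("benchmark must be non-empty")
    rows = []
    for k in support_levels:
        calls = [c for c in merged if c.support >= k]
        used = [False] * len(benchmark)
        tp = 0
        for call in calls:
            for j, ref in enumerate(benchmark):
                if not used[j] and match_sv(call, ref, max_bp_dist, max_len_diff):
                    used[j] = True
                    tp += 1
                    break
        fp = len(calls) - tp
        precision = tp / (tp + fp) if calls else float("nan")
        rows.append(
            {
                "min_support": k,
                "n_calls": len(calls),
                "tp": tp,
                "precision": precision,
                "recall": sum(used) / len(benchmark),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# genotype matrix


@dataclass
class SvGenotypeMatrix:
    """Benchmark SV loci x cells presence genotypes.

    Entries: 1 — the cell carries the SV, 0 — the locus is covered with no
    SV ("the other genotype"), -1 — not covered.  Loci are ordered by
    chromosome then position.
    """

    loci: pd.DataFrame  # columns: chrom, pos, svtype, length
    cell_ids: list[str]
    data: np.ndarray  # (n_loci, n_cells) int8

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.shape != (len(self.loci), len(self.cell_ids)):
            raise ValueError("matrix shape does not match loci x cells")
        if self.data.size and not np.isin(self.data, (-1, 0, 1)).all():
            raise ValueError("entries must be in {-1, 0, 1}")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def row_support(self) -> np.ndarray:
        return (self.data == 1).sum(axis=1)

    def row_genotyped(self) -> np.ndarray:
        return (self.data != MISSING).sum(axis=1)

    def chrom_blocks(self):
        """Yield (chrom, row index array) in locus order."""
        for chrom in self.loci["chrom"].unique():
            yield chrom, np.flatnonzero((self.loci["chrom"] == chrom).to_numpy())


def build_sv_matrix(
    cell_calls: dict[str, pd.DataFrame],
    benchmark: pd.DataFrame,
    covered: np.ndarray,
    tol_bp: int = 100,
    tol_len: int = 100,
) -> SvGenotypeMatrix:
    """Genotype each cell at each benchmark hetSV locus.

    Entry 1 when a cell call matches the locus (same chromosome/type,
    breakpoints within ``tol_bp`` and length within ``tol_len``); 0 when
    the locus is covered by reads but no SV was called; -1 uncovered.
    ``covered`` is a (n_loci x n_cells) boolean matrix.
    """
    bench = benchmark.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    cells = list(cell_calls)
    cov = np.asarray(covered, dtype=bool)
    if cov.shape != (len(bench), len(cells)):
        raise ValueError("covered must be (n_loci x n_cells)")
    data = np.where(cov, 0, MISSING).astype(np.int8)
    for ci, cell in enumerate(cells):
        df = cell_calls[cell]
        for rec in df.itertuples(index=False):
            hit = (
                (bench["chrom"] == rec.chrom)
                & (bench["svtype"] == rec.svtype)
                & ((bench["pos"] - int(rec.pos)).abs() <= tol_bp)
                & ((bench["length"] - int(rec.length)).abs() <= tol_len)
            )
            rows = np.flatnonzero(hit.to_numpy())
            for j in rows:
                if cov[j, ci]:
                    data[j, ci] = 1
    return SvGenotypeMatrix(bench[["chrom", "pos", "svtype", "length"]], cells, data)


def select_framework(
    matrix: SvGenotypeMatrix,
    min_cells_genotyped: int = 5,
    top_cells: int = 100,
    min_support: int = 3,
) -> SvGenotypeMatrix:
    """Framework selection: keep loci genotyped in >= 5 cells, then the
    top 100 cells by total SV count (ties broken by cell id), then drop
    loci carried by fewer than 3 of the retained cells."""
    keep_rows = matrix.row_genotyped() >= min_cells_genotyped
    data = matrix.data[keep_rows]
    loci = matrix.loci.loc[keep_rows].reset_index(drop=True)
    totals = (data == 1).sum(axis=0)
    order = sorted(
        range(len(matrix.cell_ids)), key=lambda i: (-totals[i], matrix.cell_ids[i])
    )
    kept_cols = sorted(order[:top_cells])
    data = data[:, kept_cols]
    cells = [matrix.cell_ids[i] for i in kept_cols]
    support = (data == 1).sum(axis=1)
    keep2 = support >= min_support
    out = SvGenotypeMatrix(loci.loc[keep2].reset_index(drop=True), cells, data[keep2])
    if out.n_loci == 0 or out.n_cells == 0:
        raise ValueError(
            f"framework selection left an empty matrix "
            f"({int(keep_rows.sum())} rows genotyped, {len(cells)} cells kept)"
        )
    return out


# ---------------------------------------------------------------------------
# leave-one-out proofreading


def _agreement(test_col: np.ndarray, others: np.ndarray) -> np.ndarray:
    """(n_other x m) agreement observations: 0 same genotype, 1 different,
    -1 where either entry is missing."""
    m = test_col.size
    obs = np.where(others.T != test_col[None, :], 1, 0).astype(np.int8)
    obs[(others.T == MISSING) | (test_col[None, :] == MISSING)] = -1
    return obs


@dataclass
class ProofreadReport:
    excluded_rows: np.ndarray  # indices into the input matrix rows
    flipped: int
    wrong_tally: np.ndarray  # per input row


def loo_proofread(
    matrix: SvGenotypeMatrix,
    emission: float = 0.99,
    max_wrong_cells: int = 5,
    flip_below: int = 3,
) -> tuple[SvGenotypeMatrix, ProofreadReport]:
    """Leave-one-out HMM proofreading of the framework matrix (see module
    docstring for the algorithm and thresholds)."""
    data = matrix.data.copy()
    n_loci, n_cells = data.shape
    flagged = np.zeros((n_loci, n_cells), dtype=bool)
    for chrom, rows in matrix.chrom_blocks():
        pos = matrix.loci["pos"].to_numpy()[rows]
        q = distance_switch_prob(np.diff(pos.astype(float)))
        block = data[rows]
        for t in range(n_cells):
            others_idx = [i for i in range(n_cells) if i != t]
            obs = _agreement(block[:, t], block[:, others_idx])
            states, amb = bidirectional_states(obs, switch=q, tie_tol=1e-12)
            informative = (obs >= 0) & ~np.atleast_2d(amb)
            disagree = informative & (states != obs)
            votes = disagree.sum(axis=0)
            n_inf = informative.sum(axis=0)
            # the half-of-informative-cells clause needs a quorum: at a real
            # crossover boundary the filtering consensus leaves most pairs
            # ambiguous, and a lone informative pair must not decide alone
            hit = (votes > max_wrong_cells) | ((n_inf >= 4) & (2 * votes >= n_inf))
            hit &= block[:, t] != MISSING
            flagged[rows[hit], t] = True
    tally = flagged.sum(axis=1)
    excluded = np.flatnonzero(tally > max_wrong_cells)
    flip_rows = np.flatnonzero((tally > 0) & (tally < flip_below))
    flipped = 0
    for j in flip_rows:
        cols = np.flatnonzero(flagged[j] & (data[j] != MISSING))
        data[j, cols] = 1 - data[j, cols]
        flipped += cols.size
    keep = np.ones(n_loci, dtype=bool)
    keep[excluded] = False
    out = SvGenotypeMatrix(
        matrix.loci.loc[keep].reset_index(drop=True), list(matrix.cell_ids), data[keep]
    )
    return out, ProofreadReport(excluded, flipped, tally)


# ---------------------------------------------------------------------------
# imputation


def impute_missing(matrix: SvGenotypeMatrix, nspt: int = 2) -> SvGenotypeMatrix:
    """Impute missing entries from cells sharing the local haplotype.

    A supporting cell implies a value for a missing entry when, on at
    least one side of the locus, its agreement relation with the target
    cell is constant over more than ``nspt`` consecutive informative
    flanking loci.  The entry is imputed only when every implication
    (across supporting cells and sides) names the same value; conflicts —
    including a crossover falling right at the locus, which makes the two
    sides imply opposite values — leave it missing.
    """
    data = matrix.data.copy()
    need = nspt + 1
    for chrom, rows in matrix.chrom_blocks():
        block = data[rows]
        m, n = block.shape
        for j in range(m):
            for t in range(n):
                if block[j, t] != MISSING:
                    continue
                implied: set[int] = set()
                for i in range(n):
                    if i == t or block[j, i] == MISSING:
                        continue
                    implied |= _side_implications(block, j, t, i, need)
                    if len(implied) > 1:
                        break
                if len(implied) == 1:
                    data[rows[j], t] = implied.pop()
    return SvGenotypeMatrix(matrix.loci.copy(), list(matrix.cell_ids), data)


def _side_implications(block: np.ndarray, j: int, t: int, i: int, need: int) -> set[int]:
    """Values supporting cell ``i`` implies for the missing entry (j, t):
    one per side whose nearest ``need`` informative loci share a constant
    agreement relation (0 same, 1 opposite) between the two cells."""
    implied: set[int] = set()
    for step in (-1, 1):
        rels = []
        k = j + step
        while 0 <= k < block.shape[0] and len(rels) < need:
            a, b = block[k, t], block[k, i]
            if a != MISSING and b != MISSING:
                rels.append(int(a != b))
            k += step
        if len(rels) >= need and len(set(rels)) == 1:
            implied.add(int(block[j, i]) ^ rels[0])
    return implied


# ---------------------------------------------------------------------------
# assembly


def _despike(states: np.ndarray, min_run: int) -> np.ndarray:
    """Flip runs shorter than ``min_run`` to the neighbouring state,
    iterating to a fixed point (the cvlink proofreading rule)."""
    s = states.copy()
    changed = True
    while changed and s.size:
        changed = False
        boundaries = np.flatnonzero(np.diff(s) != 0)
        starts = np.concatenate([[0], boundaries + 1])
        ends = np.concatenate([boundaries, [s.size - 1]])
        if starts.size <= 1:
            break
        lengths = ends - starts + 1
        order = np.argsort(lengths, kind="stable")
        for ri in order:
            if lengths[ri] < min_run:
                s[starts[ri] : ends[ri] + 1] = 1 - s[starts[ri]]
                changed = True
                break
    return s


@dataclass
class PhasedSvHaplotype:
    """Consensus carrier haplotype over the benchmark loci."""

    loci: pd.DataFrame
    labels: np.ndarray  # carrier haplotype per retained locus (0/1)
    margin: np.ndarray  # majority-vote margin per locus
    cell_ids: list[str]
    row_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


def assemble_haplotypes(
    matrix: SvGenotypeMatrix,
    max_missing_per_row: int = 1,
    cvlink: int = 2,
    min_cells: int = 3,
) -> PhasedSvHaplotype:
    """Consensus assembly of the carrier haplotype (per chromosome, up to
    a global label swap).

    Loci with more than ``max_missing_per_row`` missing genotypes and then
    cells with any missing genotype are dropped.  Each remaining cell is
    relabelled to a common parental frame through its decoded agreement
    mosaic with a reference cell (blip runs shorter than ``cvlink`` loci
    flipped as errors); the per-locus majority of the relabelled vectors,
    corrected for the reference cell's own crossover mosaic (breakpoints
    present in more than half of the decoded pairwise mosaics belong to
    the reference), is the consensus carrier haplotype.
    """
    keep_rows = (matrix.data == MISSING).sum(axis=1) <= max_missing_per_row
    data = matrix.data[keep_rows]
    loci = matrix.loci.loc[keep_rows].reset_index(drop=True)
    keep_cols = ~(data == MISSING).any(axis=0)
    data = data[:, keep_cols]
    cells = [c for c, k in zip(matrix.cell_ids, keep_cols) if k]
    if len(cells) < min_cells:
        raise ValueError(f"only {len(cells)} cells survive missing-data filters")
    labels = np.empty(len(loci), dtype=np.int8)
    margin = np.empty(len(loci), dtype=float)
    tmp = SvGenotypeMatrix(loci, cells, data)
    for chrom, rows in tmp.chrom_blocks():
        block = data[rows]
        pos = loci["pos"].to_numpy()[rows].astype(float)
        m, n = block.shape
        q = distance_switch_prob(np.diff(pos))
        mosaics = np.zeros((n, m), dtype=np.int8)  # a_ref XOR a_i, smoothed
        for i in range(1, n):
            obs = np.where(block[:, i] != block[:, 0], 1, 0).astype(np.int8)
            states, amb = bidirectional_states(obs, switch=q)
            states = np.atleast_1d(states).astype(np.int8)
            mosaics[i] = _despike(states, cvlink) if m else states
        relabelled = block ^ mosaics.T
        votes1 = (relabelled == 1).sum(axis=1)
        consensus_ref_frame = (2 * votes1 > n).astype(np.int8)
        if n > 1 and m > 1:
            switch_frac = (np.diff(mosaics[1:], axis=1) != 0).mean(axis=0)
            ref_breaks = switch_frac > 0.5
        else:
            ref_breaks = np.zeros(max(m - 1, 0), dtype=bool)
        a_ref = np.concatenate([[0], np.cumsum(ref_breaks) % 2]).astype(np.int8)
        labels[rows] = consensus_ref_frame ^ a_ref
        votes = np.maximum(votes1, n - votes1)
        margin[rows] = (2 * votes - n) / n
    return PhasedSvHaplotype(loci, labels, margin, cells, np.flatnonzero(keep_rows))


def sv_phasing_metrics(
    phased: PhasedSvHaplotype, benchmark_truth: pd.DataFrame
) -> tuple[float, float]:
    """(precision, recall) of a phased haplotype against truth.

    ``benchmark_truth`` has columns (chrom, pos, carrier) for the full
    benchmark hetSV set.  Precision is the fraction of phased loci with
    the correct carrier label, maximized over the global label swap per
    chromosome; recall is phased loci over benchmark loci.
    """
    merged = (
        phased.loci.assign(label=phased.labels)
        .merge(benchmark_truth[["chrom", "pos", "carrier"]], on=["chrom", "pos"], how="inner")
    )
    if len(merged) == 0:
        raise ValueError("no phased locus overlaps the benchmark truth")
    total_match = 0
    for _, grp in merged.groupby("chrom", sort=False):
        match = int((grp["label"] == grp["carrier"]).sum())
        total_match += max(match, len(grp) - match)
    precision = total_match / len(merged)
    recall = len(phased.loci) / len(benchmark_truth)
    return precision, recall
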