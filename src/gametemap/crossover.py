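"""Crossover calling, recombination-map summaries and gamete-based SNP
phasing.

A gamete's genotype vector along a chromosome is decoded with the
two-state error-correcting HMM (see :mod:`gametemap.hmm`); the consensus
states are segmented into parental-haplotype runs, and pseudo-crossovers
are removed by an iterative support filter: any run supported by fewer
SNPs than ``min_snps`` or spanning less than ``min_span`` bp is deleted
and its neighbours merged, until stable.  Each surviving boundary is one
crossover, reported as the interval between the last marker of the left
run and the first marker of the right run.

The summary layer computes resolution statistics, 1 Mb density profiles
on a normalized chromosome coordinate, per-chromosome crossover frequency
versus chromosome size, crossover interference (observed adjacent
distances versus a uniform re-placement null, rank-sum tested) and
crossover class distributions.  The phasing layer assembles
chromosome-scale parental haplotypes by relabelling each gamete's allele
observations into a common parental frame via its own segmentation and
taking a per-site majority vote.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .constants import HET, HOM0, HOM1, MISSING
from .hmm import HmmParams, bidirectional_states, viterbi_states
from .simdata import GameteCell, HetSnpMap

__all__ = [
    "CrossoverCall",
    "Run",
    "prefilter_homozygous",
    "recode_het_as_maternal",
    "segment_and_call",
    "call_cell",
    "call_dataset",
    "resolution_summary",
    "density_profile",
    "frequency_by_chromosome",
    "interference_analysis",
    "InterferenceResult",
    "crossover_class_distribution",
    "phase_snps_from_gametes",
    "phasing_precision",
]

#: printed defaults of the support filter
MIN_SNPS = 100
MIN_SPAN = 500_000


@dataclass(frozen=True)
class CrossoverCall:
    """One crossover: the flanking-marker interval on a chromosome."""

    cell_id: str
    chrom: str
    left: int  # last marker position of the left haplotype run (bp)
    right: int  # first marker position of the right run (bp)

    @property
    def resolution(self) -> int:
        return self.right - self.left

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.left + self.right)


@dataclass
class Run:
    """A maximal same-state stretch of consensus sites."""

    start: int  # index into the retained-site arrays
    end: int  # inclusive
    state: int
    n_snps: int
    span: int  # bp, first to last supporting marker


def recode_het_as_maternal(gt):
    """Zygote preprocessing: recode heterozygous calls to the maternal
    (haplotype 0) state.

    In a zygote formed with a paternal-strain sperm, the female
    pronucleus's paternal-haplotype alleles appear homozygous while its
    maternal-haplotype alleles appear heterozygous (the sperm contributes
    the paternal-strain allele); recoding het calls to the maternal state
    lets the crossover caller read the female pronucleus as a haploid.
    The paternal genome itself is not modelled.
    """
    g = np.asarray(gt).copy()
    g[g == HET] = HOM0
    return g


def prefilter_homozygous(gt, pos):
    """Keep homozygous parental calls only, in positional order.

    Heterozygous and missing calls carry no parental signal in a haploid
    and are removed before decoding; the remaining calls become the HMM
    observation vector (0/1).
    """
    g = np.asarray(gt)
    p = np.asarray(pos)
    order = np.argsort(p, kind="stable")
    g, p = g[order], p[order]
    keep = (g == HOM0) | (g == HOM1)
    return p[keep], g[keep].astype(np.int8)


def _build_runs(states: np.ndarray, positions: np.ndarray) -> list[Run]:
    runs: list[Run] = []
    if states.size == 0:
        return runs
    boundaries = np.flatnonzero(np.diff(states) != 0)
    starts = np.concatenate([[0], boundaries + 1])
    ends = np.concatenate([boundaries, [states.size - 1]])
    for s, e in zip(starts, ends):
        runs.append(
            Run(int(s), int(e), int(states[s]), int(e - s + 1), int(positions[e] - positions[s]))
        )
    return runs


def segment_and_call(
    states,
    positions,
    min_snps: int = MIN_SNPS,
    min_span: int = MIN_SPAN,
    cell_id: str = "",
    chrom: str = "",
) -> tuple[list[Run], list[CrossoverCall]]:
    """Build haplotype runs and emit crossovers after the support filter.

    Runs failing the (>= min_snps SNPs AND >= min_span bp) rule are
    deleted iteratively — weakest first (fewest SNPs, then shortest span,
    then leftmost) — and their same-state neighbours merged, re-checking
    until stable.  Sites of a deleted run do not count as support of the
    merged run.  The filter is idempotent.
    """
    states = np.asarray(states, dtype=np.int8)
    positions = np.asarray(positions)
    runs = _build_runs(states, positions)

    def failing(r: Run) -> bool:
        return r.n_snps < min_snps or r.span < min_span

    while len(runs) > 1:
        bad = [r for r in runs if failing(r)]
        if not bad:
            break
        weakest = min(bad, key=lambda r: (r.n_snps, r.span, r.start))
        i = runs.index(weakest)
        if 0 < i < len(runs) - 1:
            left, right = runs[i - 1], runs[i + 1]
            merged = Run(
                left.start,
                right.end,
                left.state,
                left.n_snps + right.n_snps,
                int(positions[right.end] - positions[left.start]),
            )
            runs[i - 1 : i + 2] = [merged]
        else:
            runs.pop(i)
    if len(runs) == 1 and failing(runs[0]):
        runs = []
    calls = [
        CrossoverCall(cell_id, chrom, int(positions[a.end]), int(positions[b.start]))
        for a, b in zip(runs, runs[1:])
    ]
    return runs, calls


def call_cell(
    cell: GameteCell,
    params: HmmParams | None = None,
    min_snps: int = MIN_SNPS,
    min_span: int = MIN_SPAN,
    decoder: str = "filter-consensus",
):
    """Decode one cell chromosome-by-chromosome and call crossovers.

    Returns ``(calls, segmentation)`` where ``segmentation`` maps each
    chromosome to its list of surviving runs.  ``decoder`` selects the
    bidirectional filtering consensus (default) or plain Viterbi.
    """
    params = params or HmmParams()
    calls: list[CrossoverCall] = []
    segmentation: dict[str, list[Run]] = {}
    for chrom, grp in cell.data.groupby("chrom", sort=False):
        pos, obs = prefilter_homozygous(grp["gt"].to_numpy(), grp["pos"].to_numpy())
        if pos.size == 0:
            segmentation[chrom] = []
            continue
        if decoder == "viterbi":
            states = viterbi_states(obs, params=params)
            keep = np.ones(states.size, dtype=bool)
        else:
            states, ambiguous = bidirectional_states(obs, params=params)
            keep = ~ambiguous
        runs, chrom_calls = segment_and_call(
            states[keep], pos[keep], min_snps, min_span, cell.cell_id, chrom
        )
        segmentation[chrom] = runs
        calls.extend(chrom_calls)
    return calls, segmentation


def call_dataset(cells, params=None, min_snps=MIN_SNPS, min_span=MIN_SPAN) -> pd.DataFrame:
    """Crossover calls for many cells as one tidy table.

    Decoding is batched across cells chromosome-by-chromosome (constant
    per-step transitions make padded batching exact), which is much
    faster than :func:`call_cell` in a loop but yields identical calls.
    """
    params = params or HmmParams()
    work = []  # (cell_id, chrom, positions, observations)
    for cell in cells:
        for chrom, grp in cell.data.groupby("chrom", sort=False):
            pos, obs = prefilter_homozygous(grp["gt"].to_numpy(), grp["pos"].to_numpy())
            if pos.size:
                work.append((cell.cell_id, chrom, pos, obs))
    from .hmm import bidirectional_states_ragged

    decoded = bidirectional_states_ragged([w[3] for w in work], params)
    calls: list[CrossoverCall] = []
    for (cell_id, chrom, pos, _), (states, ambiguous) in zip(work, decoded):
        keep = ~ambiguous
        _, chrom_calls = segment_and_call(
            states[keep], pos[keep], min_snps, min_span, cell_id, chrom
        )
        calls.extend(chrom_calls)
    rows = [
        {
            "cell_id": c.cell_id,
            "chrom": c.chrom,
            "left": c.left,
            "right": c.right,
            "midpoint": c.midpoint,
            "resolution": c.resolution,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows, columns=["cell_id", "chrom", "left", "right", "midpoint", "resolution"]
    )


def recovery_stats(calls: pd.DataFrame, truth: dict, tol_bp: float = 1_000_000):
    """Compare calls against known truth (simulation benchmarking).

    ``truth`` maps cell_id -> {chrom: true crossover positions}.  Each
    true crossover is recovered when an unused call midpoint on the same
    cell-chromosome lies within ``tol_bp``; unmatched calls are false
    positives.  Returns ``(n_truth, n_recovered, n_false)``.
    """
    n_truth = sum(int(np.size(p)) for per in truth.values() for p in per.values())
    n_rec = 0
    n_false = int(len(calls))
    grouped = {k: g for k, g in calls.groupby(["cell_id", "chrom"])} if len(calls) else {}
    for cell_id, per_chrom in truth.items():
        for chrom, pos in per_chrom.items():
            grp = grouped.get((cell_id, chrom))
            mids = grp["midpoint"].to_numpy(float) if grp is not None else np.empty(0)
            used = np.zeros(mids.size, dtype=bool)
            for x in np.atleast_1d(pos):
                d = np.abs(mids - x)
                d[used] = np.inf
                if d.size and d.min() <= tol_bp:
                    used[int(np.argmin(d))] = True
                    n_rec += 1
                    n_false -= 1
    return n_truth, n_rec, n_false


# ---------------------------------------------------------------------------
# summaries


def resolution_summary(calls: pd.DataFrame, thresholds=(100_000, 200_000, 300_000)):
    """Median crossover resolution and cumulative fraction below thresholds."""
    if len(calls) == 0:
        raise ValueError("no crossover calls")
    res = calls["resolution"].to_numpy(dtype=float)
    return {
        "median": float(np.median(res)),
        "cumulative": {int(t): float((res <= t).mean()) for t in thresholds},
    }


def density_profile(
    calls: pd.DataFrame, chrom_lengths: dict[str, int], window: int = 1_000_000
):
    """Crossover counts in fixed windows plus normalized positions.

    A crossover's point position is its interval midpoint; windows are
    half-open [k*w, (k+1)*w).  The normalized coordinate midpoint/length
    runs from 0 (top of the chromosome) to 1 (bottom).
    """
    rows = []
    norm = []
    for chrom, length in chrom_lengths.items():
        n_win = int(np.ceil(length / window))
        counts = np.zeros(n_win, dtype=int)
        sub = calls.loc[calls["chrom"] == chrom]
        if len(sub):
            mids = sub["midpoint"].to_numpy(dtype=float)
            idx = np.clip((mids // window).astype(int), 0, n_win - 1)
            np.add.at(counts, idx, 1)
            norm.append(pd.DataFrame({"chrom": chrom, "norm_pos": mids / length}))
        starts = np.arange(n_win) * window
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": np.minimum(starts + window, length),
                    "count": counts,
                }
            )
        )
    windows = pd.concat(rows, ignore_index=True)
    normalized = (
        pd.concat(norm, ignore_index=True)
        if norm
        else pd.DataFrame(columns=["chrom", "norm_pos"])
    )
    return windows, normalized


def frequency_by_chromosome(
    calls: pd.DataFrame, n_cells: int, chrom_lengths: dict[str, int]
):
    """Mean crossovers per cell per chromosome and Pearson r versus size.

    Returns ``(table, r)``; ``r`` is NaN when undefined (no calls, fewer
    than two chromosomes, or zero variance).
    """
    if n_cells < 2:
        raise ValueError("need >= 2 cells")
    counts = calls.groupby("chrom").size() if len(calls) else pd.Series(dtype=int)
    table = pd.DataFrame(
        {
            "chrom": list(chrom_lengths),
            "length": [chrom_lengths[c] for c in chrom_lengths],
            "mean_crossovers": [counts.get(c, 0) / n_cells for c in chrom_lengths],
        }
    )
    r = float("nan")
    if len(table) >= 2:
        x = table["length"].to_numpy(float)
        y = table["mean_crossovers"].to_numpy(float)
        if np.std(x) > 0 and np.std(y) > 0:
            r = float(sps.pearsonr(x, y)[0])
    return table, r


@dataclass
class InterferenceResult:
    observed: np.ndarray
    null: np.ndarray
    median_observed: float
    median_null: float
    pvalue: float


def interference_analysis(
    calls: pd.DataFrame,
    chrom_lengths: dict[str, int],
    n_replicates: int = 1,
    seed: int | None = None,
) -> InterferenceResult:
    """Inter-crossover distances versus a uniform re-placement null.

    Observed distances are between adjacent crossover midpoints within
    each cell-chromosome carrying >= 2 crossovers.  The null re-places,
    for each such cell-chromosome, the same number of crossovers uniformly
    at random (``n_replicates`` times) and collects adjacent distances.
    Interference shows as observed distances stochastically larger than
    the null; a two-sided rank-sum test compares the distributions.
    """
    rng = np.random.default_rng(seed)
    observed = []
    null = []
    for (cell, chrom), grp in calls.groupby(["cell_id", "chrom"]):
        mids = np.sort(grp["midpoint"].to_numpy(dtype=float))
        if mids.size < 2:
            continue
        observed.extend(np.diff(mids))
        length = chrom_lengths[chrom]
        for _ in range(n_replicates):
            sim = np.sort(rng.uniform(0, length, size=mids.size))
            null.extend(np.diff(sim))
    if not observed:
        raise ValueError("no cell-chromosome with >= 2 crossovers")
    obs = np.asarray(observed)
    nul = np.asarray(null)
    p = float(sps.ranksums(obs, nul).pvalue)
    return InterferenceResult(obs, nul, float(np.median(obs)), float(np.median(nul)), p)


def crossover_class_distribution(
    calls: pd.DataFrame, cell_ids, chromosomes
) -> pd.DataFrame:
    """Fraction of cells with 0, 1, 2 and 3+ crossovers per chromosome."""
    cell_ids = list(cell_ids)
    n = len(cell_ids)
    if n == 0:
        raise ValueError("cell set is empty")
    counts = calls.groupby(["chrom", "cell_id"]).size()
    rows = []
    for chrom in chromosomes:
        per_cell = np.array(
            [counts.get((chrom, cid), 0) for cid in cell_ids], dtype=int
        )
        rows.append(
            {
                "chrom": chrom,
                "0": float((per_cell == 0).mean()),
                "1": float((per_cell == 1).mean()),
                "2": float((per_cell == 2).mean()),
                "3+": float((per_cell >= 3).mean()),
            }
        )
    return pd.DataFrame(rows).set_index("chrom")


# ---------------------------------------------------------------------------
# gamete-based SNP phasing


def phase_snps_from_gametes(allele_obs: np.ndarray, ancestry: np.ndarray):
    """Chromosome-scale haplotype from >= 3 gametes by majority vote.

    Parameters
    ----------
    allele_obs
        (cells x sites) allele codes in 0/1 (reference/alternate) coding,
        -1 missing: which of the two alleles the gamete shows at each site.
    ancestry
        (cells x sites) each gamete's decoded parental state at each site
        (its crossover segmentation expanded to sites), -1 unknown.

    Each gamete's observations are relabelled to the haplotype-0 parental
    frame (an observation made while the gamete carries haplotype 1 is
    complemented); per-chromosome label swaps between gametes are resolved
    by maximizing agreement with the first informative gamete.  The
    per-site majority across gametes is the haplotype-0 allele; confidence
    is the vote margin.  Returns ``(haplotype, confidence)`` with -1 at
    sites that received no votes or tied.
    """
    obs = np.asarray(allele_obs, dtype=np.int8)
    anc = np.asarray(ancestry, dtype=np.int8)
    if obs.shape != anc.shape:
        raise ValueError("observation and ancestry matrices must align")
    n_cells, m = obs.shape
    if n_cells < 3:
        raise ValueError("need at least 3 gametes to phase")
    valid = (obs >= 0) & (anc >= 0)
    relab = np.where(valid, obs ^ anc, -1).astype(np.int8)
    ref = relab[0]
    for i in range(1, n_cells):
        both = (relab[i] >= 0) & (ref >= 0)
        if not both.any():
            continue
        agree = int((relab[i][both] == ref[both]).sum())
        if agree * 2 < int(both.sum()):
            relab[i] = np.where(relab[i] >= 0, 1 - relab[i], -1).astype(np.int8)
    v1 = (relab == 1).sum(axis=0)
    v0 = (relab == 0).sum(axis=0)
    total = v0 + v1
    hap = np.full(m, -1, dtype=np.int8)
    hap[v1 > v0] = 1
    hap[v0 > v1] = 0
    conf = np.zeros(m, dtype=float)
    nz = total > 0
    conf[nz] = np.abs(v1[nz] - v0[nz]) / total[nz]
    return hap, conf


def phasing_precision(inferred, truth) -> float:
    """Fraction of phased sites matching truth, maximized over the global
    label swap (a phased haplotype is defined only up to which parent is
    called haplotype 0)."""
    inf = np.asarray(inferred, dtype=np.int8)
    tru = np.asarray(truth, dtype=np.int8)
    both = (inf >= 0) & (tru >= 0)
    n = int(both.sum())
    if n == 0:
        raise ValueError("no overlapping phased sites")
    match = int((inf[both] == tru[both]).sum())
    return max(match, n - match) / n
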