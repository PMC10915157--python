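"""Per-cell QC, diploid screening, sex assignment, aneuploidy calling and
binned copy-ratio profiling for single-gamete genotype data.

A haploid gamete shows long runs of one parental genotype along each
chromosome, interrupted only at crossovers and at occasional genotyping
errors.  A contaminating diploid cell carries both parental genomes, and
allele dropout turns it into a pseudo-random alternation of the two
homozygous calls — its switch rate ("non-continuity score") is far above
haploid level.  Aneuploid gametes betray an extra chromatid through three
signals confined to the affected chromosome: an elevated non-continuity
score, an elevated heterozygosity rate (both alleles captured), and — for
losses — a collapse in the recall of map hetSNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import HET, HOM0, HOM1, MISSING
from .simdata import GameteCell, HetSnpMap

__all__ = [
    "qc_filter",
    "genotype_sites",
    "heterozygosity_rate",
    "hetsnp_recall",
    "non_continuity_score",
    "cell_noncontinuity",
    "detect_inflection",
    "assign_sex",
    "chromosome_stats",
    "call_aneuploidy",
    "AneuploidyResult",
    "screen_diploids",
    "PloidyReport",
    "copy_ratio",
    "doublet_by_species",
    "autosomes_of",
]

_SEX_NAMES = {"chrX", "chrY", "X", "Y"}


def autosomes_of(chromosomes) -> list[str]:
    return [c for c in chromosomes if c not in _SEX_NAMES]


def qc_filter(cells: list[GameteCell], min_coverage: float = 0.01) -> dict[str, bool]:
    """Pass cells with genome coverage strictly above ``min_coverage``
    (covered bp / genome bp; the default keeps cells above 1%)."""
    return {c.cell_id: bool(c.coverage > min_coverage) for c in cells}


def genotype_sites(ad0, ad1, min_reads: int = 1) -> np.ndarray:
    """Allele-count genotyping rule: heterozygous iff both alleles have
    >= 1 supporting read and the total reaches ``min_reads``; otherwise
    homozygous for the majority allele; missing below ``min_reads``."""
    a0 = np.asarray(ad0, dtype=np.int64)
    a1 = np.asarray(ad1, dtype=np.int64)
    if np.any(a0 < 0) or np.any(a1 < 0):
        raise ValueError("allele support counts must be >= 0")
    total = a0 + a1
    gt = np.full(a0.shape, MISSING, dtype=np.int8)
    callable_ = total >= max(min_reads, 1)
    het = callable_ & (a0 >= 1) & (a1 >= 1)
    gt[callable_ & (a0 > a1)] = HOM0
    gt[callable_ & (a1 > a0)] = HOM1
    gt[het] = HET
    return gt


def heterozygosity_rate(cell: GameteCell) -> dict[str, float]:
    """Het calls / covered calls per chromosome; NaN when a chromosome has
    no covered site (undefined, not zero)."""
    out: dict[str, float] = {}
    for chrom, grp in cell.data.groupby("chrom", sort=False):
        gt = grp["gt"].to_numpy()
        covered = gt != MISSING
        out[chrom] = float((gt == HET).sum() / covered.sum()) if covered.any() else float("nan")
    return out


def hetsnp_recall(cell: GameteCell, snp_map: HetSnpMap) -> dict[str, float]:
    """Covered map sites / total map sites, per chromosome."""
    covered = cell.data.loc[cell.data["gt"] != MISSING].groupby("chrom")["pos"].nunique()
    out = {}
    for chrom in snp_map.chromosomes:
        n = snp_map.n_sites(chrom)
        out[chrom] = float(covered.get(chrom, 0) / n) if n else float("nan")
    return out


def non_continuity_score(gt, normalized: bool = True) -> float | None:
    """Frequency of switching between the two parental genotypes along a
    chromosome.  Heterozygous and missing calls are dropped first (a het
    call is uninformative for parental state in a haploid); the number of
    adjacent opposite-genotype transitions is divided by the number of
    adjacent pairs (``normalized=False`` returns the raw switch count).
    Returns None when fewer than two informative calls remain."""
    g = np.asarray(gt)
    g = g[(g == HOM0) | (g == HOM1)]
    if g.size < 2:
        return None
    switches = int((np.diff(g) != 0).sum())
    return switches / (g.size - 1) if normalized else float(switches)


def cell_noncontinuity(scores: dict[str, float | None], autosomes=None) -> float:
    """Summed per-autosome non-continuity, excluding the single autosome
    with the highest score (so a chromosome gain is not mistaken for a
    diploid cell).  Sex chromosomes never contribute."""
    chroms = autosomes_of(scores) if autosomes is None else list(autosomes)
    vals = [scores[c] for c in chroms if scores.get(c) is not None]
    if len(vals) < 2:
        raise ValueError("need >= 2 autosomes with defined scores")
    return float(sum(vals) - max(vals))


def detect_inflection(scores, min_cells: int = 5, tol_frac: float = 1e-3) -> float | None:
    """Knee of the sorted score curve via the extremum-distance estimator.

    Scores are sorted ascending and compared against the chord joining the
    endpoints; for a convex knee the curve dips below the chord and the
    elbow is the point of extremum (most negative) distance — the last
    cell of the low-score group.  Returns the threshold score midway
    between the elbow and the next cell, separating haploid-like (below)
    from diploid-candidate (above) cells, or None when the curve is
    featureless (e.g. a linear ramp, which never leaves the chord): then
    all cells are treated as haploid.
    """
    y = np.sort(np.asarray(scores, dtype=float))
    n = y.size
    if n < min_cells:
        raise ValueError(f"need at least {min_cells} cells")
    span = y[-1] - y[0]
    if span <= 0:
        return None
    chord = y[0] + (y[-1] - y[0]) * np.arange(n) / (n - 1)
    d = y - chord
    tol = tol_frac * span
    if -d.min() < tol:
        return None
    i_lo = int(np.argmin(d))
    if i_lo >= n - 1:
        return None
    # the elbow brackets the knee from below; the split itself is the
    # steepest rise of the sorted curve at or beyond the elbow
    k = i_lo + int(np.argmax(np.diff(y[i_lo:])))
    return float((y[k] + y[k + 1]) / 2.0)


def screen_diploids(summed_scores: dict[str, float]) -> tuple[dict[str, str], float | None]:
    """Label cells haploid / diploid-candidate from their summed
    non-continuity scores using the inflection threshold."""
    ids = list(summed_scores)
    thr = detect_inflection([summed_scores[i] for i in ids])
    labels = {
        i: ("diploid" if thr is not None and summed_scores[i] > thr else "haploid")
        for i in ids
    }
    return labels, thr


def assign_sex(
    x_reads: int,
    y_reads: int,
    upper: float = 0.8,
    lower: float = 0.2,
    both_min: int | None = None,
    both_max: int | None = None,
) -> str:
    """Assign X / Y / ambiguous from read counts on the sex chromosomes.

    X when the X fraction x/(x+y) >= ``upper``, Y when <= ``lower``,
    otherwise ambiguous.  Optionally, cells with both counts above
    ``both_min`` (sex-chromosome gain) or both below ``both_max``
    (sex-chromosome loss) are forced to ambiguous.
    """
    if x_reads < 0 or y_reads < 0:
        raise ValueError("read counts must be >= 0")
    total = x_reads + y_reads
    if total == 0:
        return "ambiguous"
    if both_min is not None and x_reads > both_min and y_reads > both_min:
        return "ambiguous"
    if both_max is not None and x_reads < both_max and y_reads < both_max:
        return "ambiguous"
    frac = x_reads / total
    if frac >= upper:
        return "X"
    if frac <= lower:
        return "Y"
    return "ambiguous"


# ---------------------------------------------------------------------------
# aneuploidy


def _region_stats(grp: pd.DataFrame, n_map_sites: int) -> tuple[float, float, float, int, int]:
    """(recall, het_rate, nc, n_covered, n_pairs) for one chromosome region."""
    if grp is None or len(grp) == 0:
        return 0.0, float("nan"), float("nan"), 0, 0
    gt = grp["gt"].to_numpy()
    covered = gt != MISSING
    n_cov = int(covered.sum())
    recall = n_cov / n_map_sites if n_map_sites else float("nan")
    het = float((gt == HET).sum() / n_cov) if n_cov else float("nan")
    nc = non_continuity_score(gt)
    hom = ((gt == HOM0) | (gt == HOM1)).sum()
    return recall, het, nc if nc is not None else float("nan"), n_cov, max(int(hom) - 1, 0)


def chromosome_stats(cell: GameteCell, snp_map: HetSnpMap) -> pd.DataFrame:
    """Per-chromosome hetSNP recall, heterozygosity rate and
    non-continuity score for one cell."""
    by_chrom = dict(tuple(cell.data.groupby("chrom", sort=False)))
    rows = []
    for chrom in snp_map.chromosomes:
        recall, het, nc, n_cov, n_pairs = _region_stats(
            by_chrom.get(chrom), snp_map.n_sites(chrom)
        )
        rows.append(
            {
                "chrom": chrom,
                "recall": recall,
                "het_rate": het,
                "nc_score": nc,
                "n_map_sites": snp_map.n_sites(chrom),
                "n_covered": n_cov,
                "n_pairs": n_pairs,
            }
        )
    return pd.DataFrame(rows).set_index("chrom")


def _binomial_floor(p_hat: float, n: int) -> float:
    """Lower bound on the dispersion scale: the binomial standard error of
    a rate estimated from n sites, which a small-sample MAD can undercut."""
    if n <= 0 or not np.isfinite(p_hat):
        return np.inf
    p = min(max(p_hat, 1.0 / n), 1.0 - 1.0 / n)
    return float(np.sqrt(p * (1.0 - p) / n))


def _robust_z(value: float, others: np.ndarray, n_value: int) -> float:
    others = others[np.isfinite(others)]
    if others.size < 3 or not np.isfinite(value):
        return float("nan")
    med = float(np.median(others))
    mad = 1.4826 * float(np.median(np.abs(others - med)))
    scale = max(mad, _binomial_floor(med, n_value))
    if scale == 0 or not np.isfinite(scale):
        return float("nan")
    return (value - med) / scale


@dataclass
class AneuploidyResult:
    events: list  # (chrom, kind) or (chrom, kind, (lo, hi)) in interval mode
    artifact: bool
    zscores: pd.DataFrame


def call_aneuploidy(
    cell: GameteCell,
    snp_map: HetSnpMap,
    z_thresh: float = 5.0,
    intervals: int = 1,
) -> AneuploidyResult:
    """Three-signal aneuploidy screen on a haploid-labelled cell.

    For each autosome (or equal sub-interval when ``intervals > 1``) a
    robust z-score — median/MAD across the cell's *other* autosomes, with
    a binomial-standard-error floor on the scale — is computed for the
    non-continuity score, the heterozygosity rate and the hetSNP recall.
    A chromatid gain needs both the non-continuity and heterozygosity z
    above ``z_thresh``; a loss needs the recall z below ``-z_thresh``.
    Cells in which more than half of the autosomes deviate are flagged as
    amplification artifacts rather than aneuploid.
    """
    autosomes = autosomes_of(snp_map.chromosomes)
    stats = chromosome_stats(cell, snp_map).loc[autosomes]
    defined = stats["recall"].notna() & stats["nc_score"].notna()
    if int(defined.sum()) < 5:
        raise ValueError("need >= 5 autosomes with defined statistics")
    by_chrom = dict(tuple(cell.data.groupby("chrom", sort=False)))
    events = []
    z_rows = []
    deviant = 0
    for chrom in autosomes:
        others = stats.drop(index=chrom)
        base = {
            "recall": others["recall"].to_numpy(float),
            "het_rate": others["het_rate"].to_numpy(float),
            "nc_score": others["nc_score"].to_numpy(float),
        }
        regions = _chrom_regions(snp_map, chrom, intervals)
        chrom_hit = False
        for lo, hi in regions:
            grp = by_chrom.get(chrom)
            if grp is not None and intervals > 1:
                grp = grp.loc[(grp["pos"] >= lo) & (grp["pos"] <= hi)]
            pos = snp_map.positions[chrom]
            n_map = int(((pos >= lo) & (pos <= hi)).sum())
            recall, het, nc, n_cov, n_pairs = _region_stats(grp, n_map)
            z_recall = _robust_z(recall, base["recall"], n_map)
            z_het = _robust_z(het, base["het_rate"], n_cov)
            z_nc = _robust_z(nc, base["nc_score"], n_pairs)
            # a fully lost region yields no nc/het values at all: still a loss
            if n_cov == 0 and n_map > 0:
                z_recall = _robust_z(0.0, base["recall"], n_map)
            tag = None if intervals == 1 else (lo, hi)
            if np.isfinite(z_nc) and np.isfinite(z_het) and z_nc > z_thresh and z_het > z_thresh:
                events.append((chrom, "gain") if tag is None else (chrom, "gain", tag))
                chrom_hit = True
            if np.isfinite(z_recall) and z_recall < -z_thresh:
                events.append((chrom, "loss") if tag is None else (chrom, "loss", tag))
                chrom_hit = True
            z_rows.append(
                {
                    "chrom": chrom,
                    "lo": lo,
                    "hi": hi,
                    "z_recall": z_recall,
                    "z_het": z_het,
                    "z_nc": z_nc,
                }
            )
        if chrom_hit or any(
            np.isfinite(v) and abs(v) > z_thresh
            for v in (z_rows[-1]["z_recall"], z_rows[-1]["z_het"], z_rows[-1]["z_nc"])
        ):
            deviant += 1
    artifact = deviant > len(autosomes) / 2
    return AneuploidyResult(events, artifact, pd.DataFrame(z_rows))


def _chrom_regions(snp_map: HetSnpMap, chrom: str, intervals: int):
    length = snp_map.lengths[chrom]
    if intervals <= 1:
        return [(1, length)]
    edges = np.linspace(0, length, intervals + 1).astype(int)
    return [(int(edges[i]) + 1, int(edges[i + 1])) for i in range(intervals)]


# ---------------------------------------------------------------------------
# reports, CNV, doublets


@dataclass
class PloidyReport:
    """Per-cell screening summary over a dataset."""

    cells: pd.DataFrame  # cell_id, coverage, qc_pass, summed_nc, label, sex
    per_chromosome: pd.DataFrame  # cell_id, chrom, recall, het_rate, nc_score
    events: pd.DataFrame  # cell_id, chrom, kind
    inflection: float | None = None
    meta: dict = field(default_factory=dict)


def copy_ratio(bins, baseline_ploidy: float = 1.0, ddof: int = 0):
    """Per-bin copy number ``ploidy * count / mean(count)`` over retained
    bins, plus the CV of copy number against the cell's mean copy.
    1 Mb windows with ploidy 1 reproduce haploid germ-cell profiling."""
    kept = bins.retained().copy()
    x = kept["count"].to_numpy(dtype=float)
    if x.size == 0 or x.mean() <= 0:
        raise ValueError("copy ratio undefined: zero mean count")
    copy = baseline_ploidy * x / x.mean()
    kept["copy"] = copy
    cv = float(np.std(copy, ddof=ddof) / copy.mean())
    return kept, cv


def doublet_by_species(reads_per_genome: dict[str, int], max_minor: float = 0.10):
    """Species-mixing doublet rule: a cell whose minor genome carries more
    than ``max_minor`` of the reads is a cross-contaminant/doublet."""
    total = sum(reads_per_genome.values())
    if total <= 0:
        raise ValueError("total read count must be > 0")
    major = max(reads_per_genome, key=reads_per_genome.get)
    minor_frac = 1.0 - reads_per_genome[major] / total
    return minor_frac > max_minor, major
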