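"""Amplification-uniformity statistics on binned read counts.

Whole-genome amplification from picogram inputs is noisy; three summary
statistics quantify how evenly the reads cover the genome:

* spikiness ``s = sum_t |x_{t+1} - x_t| / sum_t x_t`` — bin-to-bin
  variation of the read count (0 for perfectly constant counts),
* Shannon entropy of the bin proportions ``e = -sum_t (x_t/X) log(x_t/X)``
  — maximal (``log T``) for a uniform distribution, 0 for a point mass,
* coefficient of variation of read depth, at several bin scales.

Blacklisted bins are removed before anything else, so the metrics are
invariant to whatever counts those bins contain.  Adjacent-bin pairs never
span a chromosome boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BinCounts", "spikiness", "shannon_entropy", "depth_cv", "pseudobulk"]


@dataclass
class BinCounts:
    """Binned read counts: (chrom, start, end, count, blacklisted) records
    on a fixed-size grid; start/end are 0-based half-open (BED)."""

    data: pd.DataFrame  # columns: chrom, start, end, count, blacklisted
    bin_size: int

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "count"}
        if not required <= set(self.data.columns):
            raise ValueError(f"BinCounts needs columns {sorted(required)}")
        if "blacklisted" not in self.data.columns:
            self.data = self.data.assign(blacklisted=False)
        if (self.data["count"] < 0).any():
            raise ValueError("counts must be non-negative")
        for chrom, grp in self.data.groupby("chrom", sort=False):
            if not grp["start"].is_monotonic_increasing:
                raise ValueError(f"{chrom}: bins must be sorted")
            if (grp["end"].values[:-1] > grp["start"].values[1:]).any():
                raise ValueError(f"{chrom}: bins must not overlap")

    def retained(self) -> pd.DataFrame:
        return self.data.loc[~self.data["blacklisted"]]

    @classmethod
    def from_counts(cls, counts, bin_size: int = 1_000_000, chrom: str = "chr1"):
        counts = np.asarray(counts)
        starts = np.arange(counts.size) * bin_size
        return cls(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + bin_size,
                    "count": counts,
                }
            ),
            bin_size,
        )


def spikiness(bins: BinCounts) -> float:
    """Sum of absolute adjacent-bin count differences over total count."""
    kept = bins.retained()
    total = kept["count"].sum()
    if kept.empty or total <= 0:
        raise ValueError("spikiness needs at least one retained bin with reads")
    num = 0.0
    for _, grp in kept.groupby("chrom", sort=False):
        x = grp["count"].to_numpy(dtype=float)
        if x.size >= 2:
            num += np.abs(np.diff(x)).sum()
    return float(num / total)


def shannon_entropy(bins: BinCounts, base: float | None = None) -> float:
    """Shannon entropy of the bin count proportions; nats by default."""
    kept = bins.retained()
    x = kept["count"].to_numpy(dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("entropy undefined for all-zero counts")
    p = x[x > 0] / total
    e = float(-(p * np.log(p)).sum())
    if base is not None:
        e /= np.log(base)
    return e


def depth_cv(bins: BinCounts, target_bin_size: int | None = None, ddof: int = 0) -> float:
    """Coefficient of variation (sd / mean) of counts aggregated to
    ``target_bin_size`` (summation; partial terminal bins retained).

    Population sd by default; ``ddof=1`` switches to the sample
    convention.  Aggregated bins containing any blacklisted input bin are
    excluded, so the metric ignores blacklisted regions entirely.
    """
    if target_bin_size is None:
        target_bin_size = bins.bin_size
    if target_bin_size % bins.bin_size != 0:
        raise ValueError("target bin size must be a multiple of the input bin size")
    parts = []
    for chrom, grp in bins.data.groupby("chrom", sort=False):
        agg_index = grp["start"].to_numpy() // target_bin_size
        agg = grp.groupby(agg_index).agg(
            count=("count", "sum"), blacklisted=("blacklisted", "any")
        )
        parts.append(agg)
    agg_all = pd.concat(parts)
    x = agg_all.loc[~agg_all["blacklisted"], "count"].to_numpy(dtype=float)
    if x.size == 0 or x.mean() == 0:
        raise ValueError("CV undefined: zero mean after aggregation")
    return float(np.std(x, ddof=ddof) / x.mean())


def pseudobulk(cells: list[BinCounts]) -> BinCounts:
    """Element-wise sum of identically gridded per-cell bin counts."""
    if not cells:
        raise ValueError("pseudobulk needs at least one cell")
    ref = cells[0]
    key_cols = ["chrom", "start", "end"]
    for other in cells[1:]:
        if other.bin_size != ref.bin_size or not other.data[key_cols].reset_index(
            drop=True
        ).equals(ref.data[key_cols].reset_index(drop=True)):
            raise ValueError("bin grids differ between cells")
    total = sum(c.data["count"].to_numpy() for c in cells)
    black = np.zeros(len(ref.data), dtype=bool)
    for c in cells:
        black |= c.data["blacklisted"].to_numpy()
    out = ref.data.copy()
    out["count"] = total
    out["blacklisted"] = black
    return BinCounts(out, ref.bin_size)
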