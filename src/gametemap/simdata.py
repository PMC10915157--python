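"""Synthetic F1-hybrid gamete data with known truth.

Emulates the data a restriction-fragment single-cell long-read protocol
produces from an F1 hybrid (e.g. C57BL/6 x DBA/2): a dense map of
heterozygous SNPs separating the two parental haplotypes, sparse per-cell
genotype observations with genotyping error (sequencing accuracy ~96.5%,
i.e. 3.5% miscalls) and heavy allele dropout, meiotic crossovers with
interference, contaminating diploid cells, chromatid gain/loss
aneuploidies, and heterozygous structural-variant genotype matrices.
Every generator is deterministic under a fixed seed, so the downstream
callers can be tested against exact ground truth without any sequencing
data.

Crossover interference is modelled as a stationary gamma renewal process:
inter-crossover distances are Gamma(shape, scale) with shape >= 1; shape 1
is a Poisson process (no interference) and larger shapes push adjacent
crossovers apart, reproducing the observed "distances longer than random".

The module also performs in-silico restriction digestion (exact-match,
single strand, linear molecule), used to choose an enzyme whose fragment
lengths concentrate in the 1-3 kb window that amplifies well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import HET, HOM0, HOM1, MISSING

__all__ = [
    "SimConfig",
    "AneuploidySpec",
    "HetSnpMap",
    "CellTruth",
    "GameteCell",
    "SimBundle",
    "DigestResult",
    "simulate_snp_map",
    "simulate_crossovers",
    "simulate_gamete",
    "simulate_nonhaploid_cell",
    "simulate_dataset",
    "SvLocus",
    "SvSimResult",
    "simulate_sv_dataset",
    "digest_sequence",
    "fragment_length_summary",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class AneuploidySpec:
    """One aneuploid event: gain or loss of a chromatid, optionally on a
    sub-interval only (models partial gain/loss on a single chromosome)."""

    chrom: str
    kind: str  # "gain" | "loss"
    interval: tuple[int, int] | None = None  # bp, 1-based inclusive

    def __post_init__(self) -> None:
        if self.kind not in ("gain", "loss"):
            raise ValueError(f"kind must be 'gain' or 'loss', got {self.kind!r}")


@dataclass(frozen=True)
class SimConfig:
    """Conditions of a synthetic gamete experiment.

    Defaults follow the study system this package emulates: genotyping
    error 0.035 (sequencing accuracy 96.5%), heavy site dropout, roughly
    0.0044 expected crossovers per chromatid per Mb (~11 autosomal
    crossovers per gamete at full mouse-genome scale), obligate crossover
    per bivalent and strong interference (gamma shape 5).
    """

    chromosomes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 150_000_000}
    )
    snps_per_chrom: int = 5000
    xo_rate_per_mb: float = 0.0044  # chromatid scale, proportional mode
    xo_expected: float = 0.66  # chromatid scale, fixed mode
    proportional_to_length: bool = True
    obligate: bool = True
    interference_shape: float = 5.0
    error_rate: float = 0.035
    dropout_rate: float = 0.5
    n_haploid: int = 90
    n_diploid: int = 10
    aneuploid_specs: tuple = ()  # one inner tuple of AneuploidySpec per cell
    gain_origin: str = "reciprocal"  # "reciprocal" | "homolog" | "sister"
    n_svs: int = 500
    sv_missing_rate: float = 0.05
    sv_flip_rate: float = 0.02
    sv_pos_jitter: int = 50
    sv_len_jitter: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("error_rate", "dropout_rate", "sv_missing_rate", "sv_flip_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if any(length <= 0 for length in self.chromosomes.values()):
            raise ValueError("chromosome lengths must be positive")
        if self.interference_shape < 1:
            raise ValueError("interference shape must be >= 1")
        if self.gain_origin not in ("reciprocal", "homolog", "sister"):
            raise ValueError("gain_origin must be 'reciprocal', 'homolog' or 'sister'")

    def expected_chromatid_crossovers(self, length_bp: int) -> float:
        if self.proportional_to_length:
            return self.xo_rate_per_mb * length_bp / 1e6
        return self.xo_expected


@dataclass
class HetSnpMap:
    """Informative marker map of the F1 hybrid: per chromosome, sorted
    1-based hetSNP positions and the two parental alleles at each site
    (haplotype 0 = C57/maternal, haplotype 1 = DBA/paternal)."""

    positions: dict[str, np.ndarray]
    allele0: dict[str, np.ndarray]
    allele1: dict[str, np.ndarray]
    lengths: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, pos in self.positions.items():
            if pos.size and np.any(np.diff(pos) <= 0):
                raise ValueError(f"{chrom}: positions must be strictly increasing")
            if np.any(self.allele0[chrom] == self.allele1[chrom]):
                raise ValueError(f"{chrom}: the two alleles must differ at every site")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.positions)

    def n_sites(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return int(self.positions[chrom].size)
        return int(sum(p.size for p in self.positions.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": self.positions[chrom],
                    "allele0": self.allele0[chrom],
                    "allele1": self.allele1[chrom],
                }
            )
            for chrom in self.positions
        ]
        return pd.concat(rows, ignore_index=True)


@dataclass
class CellTruth:
    """Ground truth for one simulated cell."""

    cell_id: str
    ploidy: str  # "haploid" | "diploid" | "aneuploid"
    crossovers: dict[str, np.ndarray]
    start_state: dict[str, int]
    aneuploidies: tuple = ()
    # second chromatid of gained chromosomes: chrom -> (crossovers, start)
    gained: dict[str, tuple[np.ndarray, int]] = field(default_factory=dict)

    def states(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Hidden haplotype state at each marker: the start state flipped
        once at every crossover to the left of the marker."""
        xo = self.crossovers.get(chrom, np.empty(0))
        flips = np.searchsorted(xo, positions)
        return ((self.start_state.get(chrom, 0) + flips) % 2).astype(np.int8)

    def gained_states(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        xo, start = self.gained[chrom]
        flips = np.searchsorted(xo, positions)
        return ((start + flips) % 2).astype(np.int8)


@dataclass
class GameteCell:
    """One cell's sparse observations: per-site parental genotype calls
    with per-allele support counts, plus QC metadata."""

    cell_id: str
    data: pd.DataFrame  # columns: chrom, pos, gt, ad0, ad1
    coverage: float = 0.0
    meta: dict = field(default_factory=dict)


@dataclass
class SimBundle:
    config: SimConfig
    snp_map: HetSnpMap
    cells: list[GameteCell]
    truth: dict[str, CellTruth]


# ---------------------------------------------------------------------------
# hetSNP map


def simulate_snp_map(config: SimConfig, rng: np.random.Generator | None = None) -> HetSnpMap:
    """Draw hetSNP positions uniformly without replacement per chromosome."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    positions: dict[str, np.ndarray] = {}
    a0: dict[str, np.ndarray] = {}
    a1: dict[str, np.ndarray] = {}
    for chrom, length in config.chromosomes.items():
        n = int(config.snps_per_chrom)
        if n < 0:
            raise ValueError("snp count must be >= 0")
        if n > length:
            raise ValueError(f"{chrom}: {n} SNPs exceed chromosome length {length}")
        positions[chrom] = _sample_unique_positions(rng, length, n)
        i0 = rng.integers(0, 4, size=n)
        i1 = (i0 + rng.integers(1, 4, size=n)) % 4  # guaranteed different base
        a0[chrom] = _BASES[i0]
        a1[chrom] = _BASES[i1]
    return HetSnpMap(positions, a0, a1, dict(config.chromosomes))


def _sample_unique_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """Uniform 1-based positions without replacement; avoids materialising
    the full [1, length] range for long chromosomes."""
    if n == 0:
        return np.empty(0, dtype=np.int64)
    if length <= 4 * n:
        return np.sort(rng.choice(length, size=n, replace=False) + 1).astype(np.int64)
    got: np.ndarray = np.empty(0, dtype=np.int64)
    while got.size < n:
        extra = rng.integers(1, length + 1, size=2 * (n - got.size) + 16)
        got = np.unique(np.concatenate([got, extra]))
        if got.size > n:
            got = rng.permutation(got)[:n]
    return np.sort(got)


# ---------------------------------------------------------------------------
# crossovers


def simulate_crossovers(
    length_bp: int,
    expected: float,
    interference_shape: float = 1.0,
    rng: np.random.Generator | int | None = None,
    obligate: bool = False,
    _max_tries: int = 10_000,
) -> np.ndarray:
    """Crossover positions from a stationary gamma renewal process.

    ``expected`` is the expected number of events on ``(0, length_bp)`` of
    the underlying (bivalent-scale) process.  With ``obligate=True`` the
    bivalent is conditioned on receiving at least one crossover and each
    crossover is then inherited by the sampled chromatid independently
    with probability 1/2, so the returned chromatid-scale expectation is
    about half the bivalent one.
    """
    if expected < 0:
        raise ValueError("expected crossover count must be >= 0")
    if interference_shape < 1:
        raise ValueError("interference shape must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if expected == 0 and not obligate:
        return np.empty(0)
    if expected == 0:
        # degenerate obligate case: a single forced crossover
        return _thin(np.array([rng.uniform(0, length_bp)]), rng, keep_one=True)
    mean_gap = length_bp / expected
    for _ in range(_max_tries):
        events = _renewal_events(rng, length_bp, mean_gap, interference_shape)
        if not obligate:
            return events
        if events.size:
            kept = _thin(events, rng)
            return kept
    # extremely low rate with obligate flag: place the forced crossover
    return np.array([rng.uniform(0, length_bp)])


def _renewal_events(
    rng: np.random.Generator, length: float, mean_gap: float, shape: float
) -> np.ndarray:
    """Stationary renewal on (0, length) via burn-in from -10 mean gaps."""
    scale = mean_gap / shape
    start = -10.0 * mean_gap
    t = start
    out = []
    while True:
        t += rng.gamma(shape, scale)
        if t >= length:
            break
        if t > 0:
            out.append(t)
    return np.asarray(out)


def _thin(events: np.ndarray, rng: np.random.Generator, keep_one: bool = False) -> np.ndarray:
    keep = rng.random(events.size) < 0.5
    kept = events[keep]
    if keep_one and kept.size == 0:
        return events
    return kept


# ---------------------------------------------------------------------------
# single cells


def _support_counts(rng: np.random.Generator, n: int) -> np.ndarray:
    """Read support for a called allele: at least one read, light tail."""
    return 1 + rng.poisson(1.0, size=n)


def simulate_gamete(
    snp_map: HetSnpMap,
    truth: CellTruth,
    error_rate: float,
    dropout_rate: float,
    rng: np.random.Generator,
) -> GameteCell:
    """Observe one haploid gamete: per retained site the genotype equals
    the hidden haplotype state with probability 1 - error_rate; a fraction
    ``dropout_rate`` of map sites is unobserved."""
    if not 0 <= error_rate <= 1 or not 0 <= dropout_rate <= 1:
        raise ValueError("rates must be in [0, 1]")
    frames = []
    n_total = 0
    n_seen = 0
    for chrom in snp_map.chromosomes:
        pos = snp_map.positions[chrom]
        n_total += pos.size
        if truth.ploidy == "aneuploid" and _lost_mask(truth, chrom, pos).all():
            continue
        states = truth.states(chrom, pos)
        keep = rng.random(pos.size) >= dropout_rate
        if truth.ploidy == "aneuploid":
            keep &= ~_lost_mask(truth, chrom, pos)
        idx = np.flatnonzero(keep)
        if idx.size == 0:
            continue
        gt = states[idx].astype(np.int8)
        flip = rng.random(idx.size) < error_rate
        gt[flip] = 1 - gt[flip]
        depth = _support_counts(rng, idx.size)
        ad0 = np.where(gt == HOM0, depth, 0)
        ad1 = np.where(gt == HOM1, depth, 0)
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": pos[idx], "gt": gt, "ad0": ad0, "ad1": ad1}
            )
        )
        n_seen += idx.size
    data = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["chrom", "pos", "gt", "ad0", "ad1"])
    )
    coverage = n_seen / n_total if n_total else 0.0
    return GameteCell(truth.cell_id, data, coverage=coverage)


def _lost_mask(truth: CellTruth, chrom: str, pos: np.ndarray) -> np.ndarray:
    lost = np.zeros(pos.size, dtype=bool)
    for spec in truth.aneuploidies:
        if spec.kind == "loss" and spec.chrom == chrom:
            if spec.interval is None:
                lost[:] = True
            else:
                lo, hi = spec.interval
                lost |= (pos >= lo) & (pos <= hi)
    return lost


def _gain_mask(truth: CellTruth, chrom: str, pos: np.ndarray) -> np.ndarray:
    gained = np.zeros(pos.size, dtype=bool)
    for spec in truth.aneuploidies:
        if spec.kind == "gain" and spec.chrom == chrom:
            if spec.interval is None:
                gained[:] = True
            else:
                lo, hi = spec.interval
                gained |= (pos >= lo) & (pos <= hi)
    return gained


def simulate_nonhaploid_cell(
    snp_map: HetSnpMap,
    truth: CellTruth,
    error_rate: float,
    dropout_rate: float,
    rng: np.random.Generator,
) -> GameteCell:
    """Observe a diploid contaminant or an aneuploid meiotic product.

    Diploid: both full-length parental haplotypes are present; each allele
    is captured independently with probability 1 - dropout_rate, so a
    covered site is heterozygous when both alleles survive dropout and a
    random homozygous call when only one does.

    Aneuploid gain: the specified chromosome (or sub-interval) carries a
    second chromatid with its own crossover history; loss: the region
    yields no observations.  Other chromosomes behave like a haploid.
    """
    capture = 1.0 - dropout_rate
    frames = []
    n_total = 0
    n_seen = 0
    for chrom in snp_map.chromosomes:
        pos = snp_map.positions[chrom]
        n_total += pos.size
        if truth.ploidy == "diploid":
            s1 = np.zeros(pos.size, dtype=np.int8)  # maternal genome
            s2 = np.ones(pos.size, dtype=np.int8)  # paternal genome
            two = np.ones(pos.size, dtype=bool)
        else:
            s1 = truth.states(chrom, pos)
            two = _gain_mask(truth, chrom, pos)
            s2 = truth.gained_states(chrom, pos) if chrom in truth.gained else s1
            lost = _lost_mask(truth, chrom, pos)
        cap1 = rng.random(pos.size) < capture
        cap2 = (rng.random(pos.size) < capture) & two
        if truth.ploidy == "aneuploid":
            cap1 &= ~lost
            cap2 &= ~lost
        seen = cap1 | cap2
        idx = np.flatnonzero(seen)
        if idx.size == 0:
            continue
        # one error-prone call per captured chromatid; a site is het only
        # when both chromatids are captured and their calls differ
        call1 = s1[idx].copy()
        flip1 = rng.random(idx.size) < error_rate
        call1[flip1] = 1 - call1[flip1]
        call2 = s2[idx].copy()
        flip2 = rng.random(idx.size) < error_rate
        call2[flip2] = 1 - call2[flip2]
        both = cap1[idx] & cap2[idx]
        a = np.where(cap1[idx], call1, call2).astype(np.int8)
        b = np.where(both, call2, a).astype(np.int8)
        gt = np.where(a == b, a, HET).astype(np.int8)
        d1 = _support_counts(rng, idx.size)
        d2 = _support_counts(rng, idx.size)
        ad0 = np.where(a == HOM0, d1, 0) + np.where((b == HOM0) & (a != b), d2, 0)
        ad1 = np.where(a == HOM1, d1, 0) + np.where((b == HOM1) & (a != b), d2, 0)
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": pos[idx], "gt": gt, "ad0": ad0, "ad1": ad1}
            )
        )
        n_seen += idx.size
    data = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["chrom", "pos", "gt", "ad0", "ad1"])
    )
    coverage = n_seen / n_total if n_total else 0.0
    return GameteCell(truth.cell_id, data, coverage=coverage)


def _meiotic_truth(
    cell_id: str,
    config: SimConfig,
    rng: np.random.Generator,
    ploidy: str = "haploid",
    aneuploidies: tuple = (),
) -> CellTruth:
    crossovers = {}
    start = {}
    gained = {}
    for chrom, length in config.chromosomes.items():
        mu = config.expected_chromatid_crossovers(length)
        bivalent_mu = 2.0 * mu if config.obligate else mu
        crossovers[chrom] = simulate_crossovers(
            length, bivalent_mu, config.interference_shape, rng, config.obligate
        )
        start[chrom] = int(rng.integers(2))
    for spec in aneuploidies:
        if spec.chrom not in config.chromosomes:
            raise ValueError(f"unknown chromosome in aneuploidy spec: {spec.chrom}")
        if spec.kind == "gain":
            length = config.chromosomes[spec.chrom]
            if config.gain_origin == "sister":
                # MII error: the identical sister chromatid is retained
                gained[spec.chrom] = (crossovers[spec.chrom], start[spec.chrom])
            elif config.gain_origin == "reciprocal":
                # MI error: the reciprocal crossover product co-segregates —
                # same exchange points, opposite parental phase everywhere
                gained[spec.chrom] = (crossovers[spec.chrom], 1 - start[spec.chrom])
            else:
                # an independent chromatid with its own crossover history
                mu = config.expected_chromatid_crossovers(length)
                bivalent_mu = 2.0 * mu if config.obligate else mu
                xo = simulate_crossovers(
                    length, bivalent_mu, config.interference_shape, rng, config.obligate
                )
                gained[spec.chrom] = (xo, 1 - start[spec.chrom])
    return CellTruth(cell_id, ploidy, crossovers, start, tuple(aneuploidies), gained)


def simulate_dataset(config: SimConfig) -> SimBundle:
    """Generate a full cell mixture (haploid / diploid / aneuploid) with
    truth, deterministic under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    snp_map = simulate_snp_map(config, rng)
    cells: list[GameteCell] = []
    truth: dict[str, CellTruth] = {}
    k = 0

    def next_id() -> str:
        nonlocal k
        cid = f"cell{k:04d}"
        k += 1
        return cid

    for _ in range(config.n_haploid):
        t = _meiotic_truth(next_id(), config, rng)
        truth[t.cell_id] = t
        cells.append(
            simulate_gamete(snp_map, t, config.error_rate, config.dropout_rate, rng)
        )
    for _ in range(config.n_diploid):
        t = CellTruth(next_id(), "diploid", {}, {})
        truth[t.cell_id] = t
        cells.append(
            simulate_nonhaploid_cell(
                snp_map, t, config.error_rate, config.dropout_rate, rng
            )
        )
    for specs in config.aneuploid_specs:
        t = _meiotic_truth(next_id(), config, rng, "aneuploid", tuple(specs))
        truth[t.cell_id] = t
        cells.append(
            simulate_nonhaploid_cell(
                snp_map, t, config.error_rate, config.dropout_rate, rng
            )
        )
    return SimBundle(config, snp_map, cells, truth)


# ---------------------------------------------------------------------------
# structural variants


@dataclass(frozen=True)
class SvLocus:
    chrom: str
    pos: int
    svtype: str  # "DEL" | "INS"
    length: int
    carrier: int  # truth: which haplotype carries the SV (0 = C57, 1 = DBA)


@dataclass
class SvSimResult:
    loci: list[SvLocus]
    carrier: np.ndarray  # (n_loci,) truth haplotype labels
    matrix: np.ndarray  # (n_loci, n_cells) int8 in {-1, 0, 1}; presence coding
    ancestry: np.ndarray  # (n_loci, n_cells) true parental state at each locus
    cell_ids: list[str]
    cell_calls: dict[str, pd.DataFrame]  # jittered per-cell SV call tables
    covered: np.ndarray  # (n_loci, n_cells) bool


def simulate_sv_dataset(
    config: SimConfig, rng: np.random.Generator | None = None
) -> SvSimResult:
    """Benchmark hetSV loci with truth carrier haplotypes plus per-cell SV
    genotypes that follow each cell's crossover-segmented ancestry.

    The matrix is presence-coded: entry 1 means the cell carries the SV
    (its local ancestry equals the SV's carrier haplotype), 0 means the
    locus is covered with no SV, -1 missing.  Flips and missing entries
    are injected at the configured rates; per-cell call tables carry
    breakpoint/length jitter within the configured bounds.
    """
    if config.n_svs < 1:
        raise ValueError("sv count must be >= 1")
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    total_len = sum(config.chromosomes.values())
    loci: list[SvLocus] = []
    for chrom, length in config.chromosomes.items():
        n = int(round(config.n_svs * length / total_len)) if len(config.chromosomes) > 1 else config.n_svs
        pos = np.sort(rng.integers(1, length + 1, size=n))
        types = np.where(rng.random(n) < 0.5, "DEL", "INS")
        lens = (50 + rng.exponential(130, size=n)).astype(int)
        carriers = rng.integers(0, 2, size=n)
        loci.extend(
            SvLocus(chrom, int(p), str(t), int(ln), int(c))
            for p, t, ln, c in zip(pos, types, lens, carriers)
        )
    carrier = np.array([s.carrier for s in loci], dtype=np.int8)
    n_loci = len(loci)
    n_cells = config.n_haploid
    cell_ids = [f"cell{i:04d}" for i in range(n_cells)]
    ancestry = np.empty((n_loci, n_cells), dtype=np.int8)
    for i in range(n_cells):
        truth = _meiotic_truth(cell_ids[i], config, rng)
        col = []
        for chrom in config.chromosomes:
            pos = np.array([s.pos for s in loci if s.chrom == chrom])
            col.append(truth.states(chrom, pos))
        ancestry[:, i] = np.concatenate(col)
    present = (ancestry == carrier[:, None]).astype(np.int8)
    flips = rng.random(present.shape) < config.sv_flip_rate
    present[flips] = 1 - present[flips]
    covered = rng.random(present.shape) >= config.sv_missing_rate
    matrix = np.where(covered, present, MISSING).astype(np.int8)
    cell_calls: dict[str, pd.DataFrame] = {}
    for i, cid in enumerate(cell_ids):
        rows = []
        for j, locus in enumerate(loci):
            if matrix[j, i] == 1:
                dp = int(rng.integers(-config.sv_pos_jitter, config.sv_pos_jitter + 1))
                dl = int(rng.integers(-config.sv_len_jitter, config.sv_len_jitter + 1))
                rows.append(
                    {
                        "chrom": locus.chrom,
                        "pos": max(1, locus.pos + dp),
                        "svtype": locus.svtype,
                        "length": max(50, locus.length + dl),
                    }
                )
        cell_calls[cid] = pd.DataFrame(rows, columns=["chrom", "pos", "svtype", "length"])
    return SvSimResult(loci, carrier, matrix, ancestry, cell_ids, cell_calls, covered)


# ---------------------------------------------------------------------------
# restriction digestion


@dataclass
class DigestResult:
    """Cuts and fragments of a linear molecule after exact-match digestion."""

    cuts: np.ndarray  # 0-based offsets of cut positions
    fragment_lengths: np.ndarray
    site: str
    cut_offset: int


def digest_sequence(sequence: str, site: str, cut_offset: int = 0) -> DigestResult:
    """Cut at ``site start + cut_offset`` for every exact occurrence of the
    recognition site on the given strand (overlapping occurrences all
    count); fragments are the intervals between successive cuts.

    IUPAC ambiguity codes in the recognition site are rejected — the
    enzymes this simulates (e.g. EcoRI GAATTC) have unambiguous sites.
    """
    site = site.upper()
    if not site or any(b not in "ACGT" for b in site):
        raise ValueError("recognition site must be non-empty and over {A,C,G,T}")
    if not 0 <= cut_offset <= len(site):
        raise ValueError("cut offset must lie within the recognition site")
    seq = sequence.upper()
    cuts = []
    start = seq.find(site)
    while start != -1:
        cut = start + cut_offset
        if 0 < cut < len(seq):  # cuts at the very ends produce no new fragment
            cuts.append(cut)
        start = seq.find(site, start + 1)
    cuts_arr = np.unique(np.asarray(cuts, dtype=np.int64))
    bounds = np.concatenate([[0], cuts_arr, [len(seq)]])
    frags = np.diff(bounds)
    return DigestResult(cuts_arr, frags, site, cut_offset)


@dataclass
class FragmentSummary:
    frac_fragments_in_window: float
    frac_bp_in_window: float
    histogram: tuple[np.ndarray, np.ndarray]  # counts, bin edges


def fragment_length_summary(
    lengths, lo: int = 1000, hi: int = 3000, bins=None
) -> FragmentSummary:
    """Fraction of fragments — and of genome bp — falling in the
    [lo, hi] length window (the window that amplifies efficiently)."""
    arr = np.asarray(lengths, dtype=float)
    if arr.size == 0:
        raise ValueError("lengths must be non-empty")
    if np.any(arr <= 0):
        raise ValueError("fragment lengths must be positive")
    in_win = (arr >= lo) & (arr <= hi)
    frac = float(in_win.mean())
    frac_bp = float(arr[in_win].sum() / arr.sum())
    if bins is None:
        bins = np.logspace(2, 5, 31)
    counts, edges = np.histogram(arr, bins=bins)
    return FragmentSummary(frac, frac_bp, (counts, edges))
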