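"""Readers and writers for the package's standard formats.

Conventions are centralized here: marker and genotype positions are
1-based (VCF), bins and interval outputs are 0-based half-open (BED),
genotypes in text tables use VCF-style strings (0/0, 1/1, 0/1, ./.) and
SV matrices use '.' for missing.  VCF is the canonical interchange for
genotypes and SVs; TSV mirrors exist for every format.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constants import GT_TO_STRING, MISSING, STRING_TO_GT
from .simdata import GameteCell, HetSnpMap, SimConfig
from .svphase import SvGenotypeMatrix

log = logging.getLogger("gametemap")

__all__ = [
    "write_snp_map_tsv",
    "read_snp_map_tsv",
    "write_snp_map_vcf",
    "write_genotype_table",
    "read_genotype_table",
    "write_genotype_vcf",
    "read_genotype_vcf",
    "read_bin_counts_bed",
    "write_bed_counts",
    "write_bedgraph",
    "write_sv_matrix_tsv",
    "read_sv_matrix_tsv",
    "PipelineConfig",
    "load_config",
    "save_config",
]


# ---------------------------------------------------------------------------
# marker map


def write_snp_map_tsv(snp_map: HetSnpMap, path) -> None:
    df = snp_map.to_frame()
    lengths = ",".join(f"{c}:{l}" for c, l in snp_map.lengths.items())
    with open(path, "w") as fh:
        fh.write(f"#lengths={lengths}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_snp_map_tsv(path) -> HetSnpMap:
    with open(path) as fh:
        header = fh.readline().strip()
        lengths = {}
        if header.startswith("#lengths="):
            for item in header.split("=", 1)[1].split(","):
                chrom, length = item.split(":")
                lengths[chrom] = int(length)
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    positions, a0, a1 = {}, {}, {}
    for chrom, grp in df.groupby("chrom", sort=False):
        positions[chrom] = grp["pos"].to_numpy(dtype=np.int64)
        a0[chrom] = grp["allele0"].to_numpy(dtype=object)
        a1[chrom] = grp["allele1"].to_numpy(dtype=object)
        lengths.setdefault(chrom, int(grp["pos"].max()) + 1)
    return HetSnpMap(positions, a0, a1, lengths)


def write_snp_map_vcf(snp_map: HetSnpMap, path) -> None:
    """Marker map as a VCF with two pseudo-samples carrying the parental
    alleles (HAP0 is 0/0 at every site, HAP1 is 1/1)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in snp_map.lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tHAP0\tHAP1\n")
        for chrom in snp_map.chromosomes:
            pos = snp_map.positions[chrom]
            ref = snp_map.allele0[chrom]
            alt = snp_map.allele1[chrom]
            for p, r, a in zip(pos, ref, alt):
                fh.write(f"{chrom}\t{p}\t.\t{r}\t{a}\t.\tPASS\t.\tGT\t0/0\t1/1\n")


# ---------------------------------------------------------------------------
# per-cell genotype observations


def write_genotype_table(cells: list[GameteCell], path) -> None:
    frames = []
    for cell in cells:
        df = cell.data.copy()
        df.insert(0, "cell", cell.cell_id)
        df["gt"] = df["gt"].map(GT_TO_STRING)
        frames.append(df)
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["cell", "chrom", "pos", "gt", "ad0", "ad1"])
    )
    out.to_csv(path, sep="\t", index=False)


def read_genotype_table(path, snp_map: HetSnpMap | None = None) -> list[GameteCell]:
    """Read a per-cell genotype TSV; when a marker map is given, rows at
    positions absent from the map are skipped with a logged count."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        log.warning("%s: empty genotype table", path)
        return []
    required = ["cell", "chrom", "pos", "gt", "ad0", "ad1"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    if len(df) == 0:
        log.warning("%s: no genotype records", path)
        return []
    bad_gt = ~df["gt"].isin(STRING_TO_GT)
    if bad_gt.any():
        first = int(np.flatnonzero(bad_gt.to_numpy())[0]) + 2  # 1-based + header
        raise ValueError(f"{path}: malformed genotype at line {first}")
    df["gt"] = df["gt"].map(STRING_TO_GT).astype(np.int8)
    if snp_map is not None:
        known = pd.MultiIndex.from_frame(
            snp_map.to_frame()[["chrom", "pos"]]
        )
        idx = pd.MultiIndex.from_frame(df[["chrom", "pos"]])
        keep = idx.isin(known)
        dropped = int((~keep).sum())
        if dropped:
            log.warning("%s: %d records at positions not in the marker map", path, dropped)
        df = df.loc[keep]
    cells = []
    n_map = snp_map.n_sites() if snp_map is not None else None
    for cell_id, grp in df.groupby("cell", sort=False):
        data = grp[["chrom", "pos", "gt", "ad0", "ad1"]].reset_index(drop=True)
        cov = (data["gt"] != MISSING).sum() / n_map if n_map else 0.0
        cells.append(GameteCell(str(cell_id), data, coverage=float(cov)))
    return cells


def write_genotype_vcf(cells: list[GameteCell], snp_map: HetSnpMap, path) -> None:
    """Merged multi-sample VCF of the per-cell observations (GT + AD)."""
    by_cell = {
        c.cell_id: c.data.set_index(["chrom", "pos"])[["gt", "ad0", "ad1"]]
        for c in cells
    }
    ids = [c.cell_id for c in cells]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in snp_map.lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(ids) + "\n")
        for chrom in snp_map.chromosomes:
            pos = snp_map.positions[chrom]
            ref = snp_map.allele0[chrom]
            alt = snp_map.allele1[chrom]
            for p, r, a in zip(pos, ref, alt):
                fields = []
                any_seen = False
                for cid in ids:
                    tbl = by_cell[cid]
                    try:
                        row = tbl.loc[(chrom, int(p))]
                    except KeyError:
                        fields.append("./.:0,0")
                        continue
                    any_seen = True
                    fields.append(
                        f"{GT_TO_STRING[int(row['gt'])]}:{int(row['ad0'])},{int(row['ad1'])}"
                    )
                if any_seen:
                    fh.write(
                        f"{chrom}\t{p}\t.\t{r}\t{a}\t.\tPASS\t.\tGT:AD\t" + "\t".join(fields) + "\n"
                    )


def read_genotype_vcf(path, snp_map: HetSnpMap | None = None) -> list[GameteCell]:
    """Read a multi-sample genotype VCF (as written by this package) back
    into per-cell observations."""
    import pysam

    vf = pysam.VariantFile(str(path))
    ids = list(vf.header.samples)
    rows: dict[str, list] = {cid: [] for cid in ids}
    for rec in vf:
        for cid in ids:
            smp = rec.samples[cid]
            gt = smp.get("GT")
            if gt is None or gt[0] is None:
                continue
            ad = smp.get("AD") or (0, 0)
            alleles = sorted(gt)
            if alleles == [0, 0]:
                code = 0
            elif alleles == [1, 1]:
                code = 1
            else:
                code = 2
            rows[cid].append((rec.chrom, rec.pos, code, int(ad[0] or 0), int(ad[1] or 0)))
    vf.close()
    cells = []
    n_map = snp_map.n_sites() if snp_map is not None else None
    for cid in ids:
        data = pd.DataFrame(rows[cid], columns=["chrom", "pos", "gt", "ad0", "ad1"])
        data["gt"] = data["gt"].astype(np.int8)
        cov = (data["gt"] != MISSING).sum() / n_map if n_map else 0.0
        cells.append(GameteCell(cid, data, coverage=float(cov)))
    return cells


# ---------------------------------------------------------------------------
# bins / BED


def read_bin_counts_bed(path, bin_size: int | None = None, blacklist_path=None):
    """Read bin counts from a 4-column BED (chrom, start, end, count);
    optionally mark bins overlapping a blacklist BED."""
    from .uniformity import BinCounts

    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "count"],
        dtype={"chrom": str},
    )
    if bin_size is None:
        bin_size = int((df["end"] - df["start"]).mode().iloc[0])
    df["blacklisted"] = False
    if blacklist_path is not None:
        bl = pd.read_csv(
            path_or_buf=blacklist_path, sep="\t", header=None,
            names=["chrom", "start", "end"], usecols=[0, 1, 2], dtype={"chrom": str},
        )
        for rec in bl.itertuples(index=False):
            hit = (
                (df["chrom"] == rec.chrom)
                & (df["start"] < rec.end)
                & (df["end"] > rec.start)
            )
            df.loc[hit, "blacklisted"] = True
    return BinCounts(df, bin_size)


def write_bed_counts(bins, path) -> None:
    bins.data[["chrom", "start", "end", "count"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_bedgraph(df: pd.DataFrame, value_col: str, path, track_name: str = "") -> None:
    with open(path, "w") as fh:
        if track_name:
            fh.write(f'track type=bedGraph name="{track_name}"\n')
        df[["chrom", "start", "end", value_col]].to_csv(
            fh, sep="\t", header=False, index=False
        )


# ---------------------------------------------------------------------------
# SV matrices


def write_sv_matrix_tsv(matrix: SvGenotypeMatrix, path) -> None:
    df = matrix.loci.copy()
    geno = pd.DataFrame(
        np.where(matrix.data == -1, ".", matrix.data.astype(str)),
        columns=matrix.cell_ids,
    )
    pd.concat([df.reset_index(drop=True), geno], axis=1).to_csv(path, sep="\t", index=False)


def read_sv_matrix_tsv(path) -> SvGenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["chrom", "pos", "svtype", "length"]
    cell_ids = [c for c in df.columns if c not in meta_cols]
    geno = df[cell_ids].replace(".", "-1").astype(np.int8).to_numpy()
    return SvGenotypeMatrix(df[meta_cols], cell_ids, geno)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """All tunables of the pipeline with their published defaults, plus
    input paths.  Overrides relative to the defaults are recorded in the
    run manifest."""

    # inputs (optional when simulate=True)
    marker_map: str | None = None
    genotypes: str | None = None
    bins: str | None = None
    blacklist: str | None = None
    out_dir: str = "gametemap_out"
    simulate: bool = True
    sim: dict = field(default_factory=dict)  # overrides for SimConfig
    # HMM + crossover filters
    hmm_emission: float = 0.99
    hmm_transition: float = 0.2
    min_snps: int = 100
    min_span: int = 500_000
    # screening
    min_coverage: float = 0.01
    doublet_minor_fraction: float = 0.10
    aneuploidy_z: float = 5.0
    sex_upper: float = 0.8
    sex_lower: float = 0.2
    # SV phasing
    framework_min_cells: int = 5
    framework_top_cells: int = 100
    framework_min_support: int = 3
    nspt: int = 2
    cvlink: int = 2
    sv_merge_distance: int = 500
    sv_len_tolerance: int = 100
    sv_min_size: int = 50
    seed: int = 0
    log_level: str = "INFO"

    def sim_config(self) -> SimConfig:
        kwargs = dict(self.sim)
        if "aneuploid_specs" in kwargs:
            from .simdata import AneuploidySpec

            kwargs["aneuploid_specs"] = tuple(
                tuple(AneuploidySpec(**spec) for spec in cell_specs)
                for cell_specs in kwargs["aneuploid_specs"]
            )
        kwargs.setdefault("seed", self.seed)
        return SimConfig(**kwargs)

    def overrides(self) -> dict:
        default = PipelineConfig()
        return {
            k: v for k, v in asdict(self).items() if v != getattr(default, k)
        }


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
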