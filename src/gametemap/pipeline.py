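"""End-to-end pipeline: QC -> diploid screen -> sex assignment ->
aneuploidy -> crossover calling -> summaries -> SNP phasing -> SV phasing.

Stages run in the published order on either a simulated bundle (the
default; the synthetic generator provides ground truth for the manifest)
or on genotype tables read from disk.  Every stage writes its outputs
under ``out_dir`` and the run manifest records the configuration, seed,
package version and per-stage cell counts, which together reproduce a run
exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .constants import HOM0, HOM1, MISSING
from .crossover import (
    call_cell,
    call_dataset,
    crossover_class_distribution,
    frequency_by_chromosome,
    phase_snps_from_gametes,
    phasing_precision,
    resolution_summary,
)
from .hmm import HmmParams, bidirectional_states
from .io import PipelineConfig, read_genotype_table, read_snp_map_tsv, write_genotype_table, write_snp_map_tsv
from .ploidy import (
    autosomes_of,
    call_aneuploidy,
    cell_noncontinuity,
    chromosome_stats,
    non_continuity_score,
    qc_filter,
    screen_diploids,
)
from .simdata import HetSnpMap, simulate_dataset, simulate_sv_dataset
from .svphase import (
    assemble_haplotypes,
    build_sv_matrix,
    impute_missing,
    loo_proofread,
    select_framework,
    sv_phasing_metrics,
)


@dataclass
class PipelineResult:
    manifest: dict
    ploidy: pd.DataFrame
    crossovers: pd.DataFrame
    summaries: dict
    phased_snp_precision: float | None = None
    sv_metrics: tuple | None = None
    extras: dict = field(default_factory=dict)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _consensus_per_map_site(cell, snp_map: HetSnpMap, params: HmmParams):
    """Each cell's decoded parental state expanded onto the full marker
    grid (-1 where unobserved/ambiguous), plus its allele observations in
    reference/alternate coding."""
    from .crossover import prefilter_homozygous

    anc = {}
    obs = {}
    by_chrom = dict(tuple(cell.data.groupby("chrom", sort=False)))
    for chrom in snp_map.chromosomes:
        m = snp_map.n_sites(chrom)
        a = np.full(m, -1, dtype=np.int8)
        o = np.full(m, -1, dtype=np.int8)
        grp = by_chrom.get(chrom)
        if grp is not None and len(grp):
            pos, gts = prefilter_homozygous(grp["gt"].to_numpy(), grp["pos"].to_numpy())
            if pos.size:
                states, amb = bidirectional_states(gts, params=params)
                idx = np.searchsorted(snp_map.positions[chrom], pos)
                keep = ~np.atleast_1d(amb)
                a[idx[keep]] = np.atleast_1d(states)[keep]
                # allele code: 0 = lexicographically smaller base
                h0_code = (
                    snp_map.allele0[chrom][idx] > snp_map.allele1[chrom][idx]
                ).astype(np.int8)
                o[idx] = h0_code ^ gts
        anc[chrom] = a
        obs[chrom] = o
    return anc, obs


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "overrides": config.overrides(),
        "stages": {},
    }
    params = HmmParams(emission=config.hmm_emission, transition=config.hmm_transition)

    # --- inputs
    truth = None
    sv_sim = None
    if config.simulate:
        bundle = simulate_dataset(config.sim_config())
        snp_map, cells, truth = bundle.snp_map, bundle.cells, bundle.truth
        write_snp_map_tsv(snp_map, out / "marker_map.tsv")
        write_genotype_table(cells, out / "genotypes.tsv")
        sv_sim = simulate_sv_dataset(bundle.config)
    else:
        if config.marker_map is None or config.genotypes is None:
            missing = "marker_map" if config.marker_map is None else "genotypes"
            raise StageError("inputs", f"missing required input: {missing}")
        snp_map = read_snp_map_tsv(config.marker_map)
        cells = read_genotype_table(config.genotypes, snp_map)
    manifest["stages"]["inputs"] = {"n_cells": len(cells), "n_sites": snp_map.n_sites()}

    # --- QC
    qc = qc_filter(cells, config.min_coverage)
    kept = [c for c in cells if qc[c.cell_id]]
    manifest["stages"]["qc"] = {"passed": len(kept), "failed": len(cells) - len(kept)}

    # --- diploid screen
    autosomes = autosomes_of(snp_map.chromosomes)
    summed = {}
    per_chrom_rows = []
    for cell in kept:
        stats = chromosome_stats(cell, snp_map)
        scores = {c: (None if np.isnan(v) else v) for c, v in stats["nc_score"].items()}
        try:
            summed[cell.cell_id] = cell_noncontinuity(scores, autosomes)
        except ValueError:
            summed[cell.cell_id] = float("nan")
        for chrom, row in stats.iterrows():
            per_chrom_rows.append(
                {
                    "cell_id": cell.cell_id,
                    "chrom": chrom,
                    "recall": row["recall"],
                    "het_rate": row["het_rate"],
                    "nc_score": row["nc_score"],
                }
            )
    defined = {k: v for k, v in summed.items() if np.isfinite(v)}
    labels, inflection = screen_diploids(defined) if len(defined) >= 5 else ({}, None)
    haploid = [c for c in kept if labels.get(c.cell_id, "haploid") == "haploid"]
    manifest["stages"]["diploid_screen"] = {
        "haploid": len(haploid),
        "diploid": len(kept) - len(haploid),
        "inflection": inflection,
    }

    # --- aneuploidy
    events_rows = []
    aneuploid_ids = set()
    for cell in haploid:
        try:
            result = call_aneuploidy(cell, snp_map, z_thresh=config.aneuploidy_z)
        except ValueError:
            continue
        for ev in result.events:
            events_rows.append(
                {"cell_id": cell.cell_id, "chrom": ev[0], "kind": ev[1]}
            )
            aneuploid_ids.add(cell.cell_id)
        if result.artifact:
            events_rows.append({"cell_id": cell.cell_id, "chrom": ".", "kind": "artifact"})
            aneuploid_ids.add(cell.cell_id)
    euploid = [c for c in haploid if c.cell_id not in aneuploid_ids]
    manifest["stages"]["aneuploidy"] = {
        "events": len(events_rows),
        "euploid": len(euploid),
    }

    # --- crossover calling
    calls = call_dataset(euploid, params, config.min_snps, config.min_span)
    calls.to_csv(out / "crossovers.tsv", sep="\t", index=False)
    summaries: dict = {}
    if len(calls):
        summaries["resolution"] = resolution_summary(calls)
        freq, r = frequency_by_chromosome(calls, len(euploid), snp_map.lengths)
        summaries["frequency_r"] = r
        summaries["mean_crossovers_per_cell"] = float(len(calls) / len(euploid))
        freq.to_csv(out / "crossover_frequency.tsv", sep="\t", index=False)
        classes = crossover_class_distribution(
            calls, [c.cell_id for c in euploid], snp_map.chromosomes
        )
        classes.to_csv(out / "crossover_classes.tsv", sep="\t")
    manifest["stages"]["crossovers"] = {"n_calls": int(len(calls))}

    # --- SNP phasing
    snp_precision = None
    if len(euploid) >= 3:
        per_cell = [_consensus_per_map_site(cell, snp_map, params) for cell in euploid]
        per_chrom_prec = []
        for chrom in snp_map.chromosomes:
            anc_rows = [anc[chrom] for anc, _ in per_cell]
            obs_rows = [obs[chrom] for _, obs in per_cell]
            hap, conf = phase_snps_from_gametes(np.array(obs_rows), np.array(anc_rows))
            if truth is not None:
                h0_truth = (
                    snp_map.allele0[chrom] > snp_map.allele1[chrom]
                ).astype(np.int8)
                try:
                    per_chrom_prec.append(phasing_precision(hap, h0_truth))
                except ValueError:
                    pass
        if per_chrom_prec:
            snp_precision = float(np.mean(per_chrom_prec))
    manifest["stages"]["snp_phasing"] = {"precision": snp_precision}

    # --- SV phasing (simulated bundle only)
    sv_metrics = None
    if sv_sim is not None:
        bench = pd.DataFrame(
            {
                "chrom": [s.chrom for s in sv_sim.loci],
                "pos": [s.pos for s in sv_sim.loci],
                "svtype": [s.svtype for s in sv_sim.loci],
                "length": [s.length for s in sv_sim.loci],
                "carrier": sv_sim.carrier,
            }
        )
        from .svphase import SvGenotypeMatrix

        matrix = SvGenotypeMatrix(
            bench[["chrom", "pos", "svtype", "length"]], sv_sim.cell_ids, sv_sim.matrix
        )
        try:
            fw = select_framework(
                matrix,
                config.framework_min_cells,
                config.framework_top_cells,
                config.framework_min_support,
            )
            proofed, _ = loo_proofread(fw)
            imputed = impute_missing(proofed, config.nspt)
            phased = assemble_haplotypes(imputed, cvlink=config.cvlink)
            sv_metrics = sv_phasing_metrics(phased, bench)
        except ValueError as exc:
            manifest["stages"]["sv_phasing"] = {"error": str(exc)}
        else:
            manifest["stages"]["sv_phasing"] = {
                "precision": sv_metrics[0],
                "recall": sv_metrics[1],
            }

    ploidy_df = pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "coverage": [c.coverage for c in cells],
            "qc_pass": [qc[c.cell_id] for c in cells],
            "summed_nc": [summed.get(c.cell_id, float("nan")) for c in cells],
            "label": [
                ("fail" if not qc[c.cell_id] else labels.get(c.cell_id, "haploid"))
                for c in cells
            ],
        }
    )
    ploidy_df.to_csv(out / "ploidy_report.tsv", sep="\t", index=False)
    pd.DataFrame(per_chrom_rows).to_csv(out / "per_chromosome_stats.tsv", sep="\t", index=False)
    pd.DataFrame(events_rows, columns=["cell_id", "chrom", "kind"]).to_csv(
        out / "aneuploidy_events.tsv", sep="\t", index=False
    )
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=float))
    return PipelineResult(
        manifest,
        ploidy_df,
        calls,
        summaries,
        snp_precision,
        sv_metrics,
    )
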