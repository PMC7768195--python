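"""End-to-end orchestration: consensus -> quartiles -> annotate -> states
-> differential expression -> signature -> association.

Every stage reads and writes flat text files (BED/TSV/JSON) inside one
output directory, so each intermediate is inspectable and diffable, and the
whole bundle is byte-for-byte reproducible for fixed inputs and config.
``run_info.json`` records the effective configuration and its hash.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation import classify_location, cpg_annotation, location_composition
from .breadth import assign_width_quantiles, overlap_by_quantile, quantile_summary
from .config import PipelineConfig
from .consensus import consensus_peaks
from .expression import (
    ExpressionMatrix,
    GeneSignature,
    binding_enrichment,
    breadth_vs_signature,
    peaks_to_genes,
    quantile_binding_fractions,
    two_group_de,
)
from .intervals import (
    GenomicInterval,
    Peak,
    merge_intervals,
    read_bed,
    read_gene_table,
    subtract_blacklist,
    write_bed,
)
from .signal import SignalTrack
from .states import (
    assign_states,
    build_state_matrix,
    reversibility_score,
    state_change_summary,
    state_composition,
)

log = logging.getLogger("bafdomains")


class PipelineError(RuntimeError):
    pass


def read_manifest(path: Path) -> pd.DataFrame:
    manifest = pd.read_csv(path, sep="\t")
    required = {"sample_id", "group", "peaks_path"}
    missing = required - set(manifest.columns)
    if missing:
        raise PipelineError(f"manifest {path}: missing columns {sorted(missing)}")
    for i, row in manifest.iterrows():
        if not (path.parent / row.peaks_path).exists():
            raise PipelineError(
                f"manifest row {i} ({row.sample_id}): missing file {row.peaks_path}"
            )
    return manifest


def run_pipeline(
    data_dir: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> Path:
    """Run every stage on a dataset directory (the simulate-stage layout).

    Expects manifest.tsv, genes.tsv, cpg_islands.bed, blacklist.bed,
    counts.tsv + sample_groups.tsv, and optionally state_sites.bed with
    tracks/<condition>_<mark>.bedgraph triplets for the state stage.
    """
    config = config or PipelineConfig()
    data_dir, out_dir = Path(data_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start: data=%s out=%s config=%s",
             data_dir, out_dir, config.hash())

    manifest = read_manifest(data_dir / "manifest.tsv")
    genes = read_gene_table(data_dir / "genes.tsv")
    blacklist = [p.interval for p in read_bed(data_dir / "blacklist.bed")]
    cpg = [p.interval for p in read_bed(data_dir / "cpg_islands.bed")]

    # stage: per-sample preprocessing (within-sample merge + blacklist filter)
    sample_peaks: dict[str, list] = {}
    for row in manifest.itertuples():
        peaks = read_bed(data_dir / row.peaks_path, sample_id=row.sample_id)
        merged = merge_intervals(
            [p.interval for p in peaks], config.within_sample_merge_gap
        )
        kept = subtract_blacklist(merged, blacklist)
        sample_peaks[row.sample_id] = [Peak(iv, row.sample_id) for iv in kept]
    tumor_ids = [r.sample_id for r in manifest.itertuples() if r.group == "tumor"]

    # stage: consensus
    consensus = consensus_peaks(
        [sample_peaks[s] for s in tumor_ids],
        min_support=min(config.consensus_min_support, len(tumor_ids)),
        merge_gap=config.consensus_merge_gap_baf,
    )
    write_bed(consensus, out_dir / "consensus.bed", bed6=False)
    log.info("consensus: %d regions from %d tumor samples",
             len(consensus), len(tumor_ids))

    # stage: quartiles
    qset = assign_width_quantiles(consensus, config.n_quantiles)
    qsum = quantile_summary(qset)
    qsum.to_csv(out_dir / "quartile_summary.tsv", sep="\t", index_label="quantile")
    with open(out_dir / "consensus_quartiles.bed", "w") as fh:
        for iv, lab in zip(qset.peaks, qset.labels):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{lab}\n")

    # stage: annotation
    promoter_track = None
    k4me3 = data_dir / "tracks" / "induced_H3K4me3.bedgraph"
    if k4me3.exists():
        promoter_track = SignalTrack.from_bedgraph(
            k4me3, total_fragments=10_000_000, normalized=True
        )
    labels = classify_location(consensus, genes, promoter_track, config)
    cpg_flags, cpg_fraction = cpg_annotation(consensus, cpg)
    location_composition(labels).to_csv(
        out_dir / "location_composition.tsv", sep="\t", index_label="class"
    )
    ann = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in consensus],
            "start": [iv.start for iv in consensus],
            "end": [iv.end for iv in consensus],
            "quantile": qset.labels,
            "location": labels,
            "cpg": cpg_flags,
        }
    )
    ann.to_csv(out_dir / "annotated_peaks.tsv", sep="\t", index=False)

    # stage: chromatin states (when tracks are provided)
    state_results = {}
    sites_bed = data_dir / "state_sites.bed"
    if sites_bed.exists() and (data_dir / "tracks").exists():
        sites = [p.interval for p in read_bed(sites_bed)]
        conditions = sorted(
            {f.name.split("_")[0] for f in (data_dir / "tracks").glob("*.bedgraph")}
        )
        profiles = {}
        for cond in conditions:
            tracks = {}
            for f in sorted((data_dir / "tracks").glob(f"{cond}_*.bedgraph")):
                mark = f.stem[len(cond) + 1:]
                tracks[mark] = SignalTrack.from_bedgraph(
                    f, total_fragments=10_000_000, normalized=True
                )
            profile = build_state_matrix(sites, tracks, condition=cond)
            profiles[cond] = assign_states(profile, config.state_high_threshold)
            state_composition(profiles[cond]).to_csv(
                out_dir / f"state_composition_{cond}.tsv", sep="\t",
                index_label="state",
            )
        if {"control", "induced"} <= set(profiles):
            state_change_summary(
                profiles["control"], profiles["induced"], config.log2_pseudocount
            ).to_csv(out_dir / "state_changes.tsv", sep="\t", index_label="state")
        if {"control", "reverted"} <= set(profiles):
            rev = reversibility_score(profiles["control"], profiles["reverted"])
            state_results["reversibility"] = rev.score
            rev.per_state.to_csv(
                out_dir / "reversibility.tsv", sep="\t", index_label="state"
            )

    # stage: differential expression
    counts = pd.read_csv(data_dir / "counts.tsv", sep="\t", index_col="gene_id")
    groups = pd.read_csv(
        data_dir / "sample_groups.tsv", sep="\t", index_col="sample_id"
    )["group"]
    gene_lengths = pd.Series({g.gene_id: g.body.width for g in genes})
    expr = ExpressionMatrix(counts, groups, gene_lengths=gene_lengths)
    de = two_group_de(expr, "tumor", "control", config.de_fold, config.de_alpha)
    de.to_csv(out_dir / "differential_expression.tsv", sep="\t",
              index_label="gene_id")

    # stage: signature + association
    sig_up = set(de.index[de.significant & (de.log2_fold_change > 0)])
    sig_down = set(de.index[de.significant & (de.log2_fold_change < 0)])
    with open(out_dir / "signature.tsv", "w") as fh:
        fh.write("gene_id\tset\n")
        for g in sorted(sig_up):
            fh.write(f"{g}\thigh_tumor\n")
        for g in sorted(sig_down):
            fh.write(f"{g}\thigh_control\n")
    association: dict = {}
    if sig_up and sig_down:
        signature = GeneSignature(sig_up, sig_down, config.de_fold, "tumor_vs_control")
        gene_map = peaks_to_genes(consensus, labels, genes, config.tss_window)
        widths = [iv.width for iv in consensus]
        report = breadth_vs_signature(
            gene_map, widths, signature, config.gene_width_statistic
        )
        association["breadth_vs_signature"] = report.to_dict()
        qbf = quantile_binding_fractions(signature, gene_map, qset)
        qbf.to_csv(out_dir / "quantile_binding.tsv", sep="\t", index_label="set")
        association["quantile_binding"] = qbf.to_dict(orient="index")
        # binding enrichment is about fusion-protein binding specifically;
        # fall back to the consensus map when no fusion peak set is provided
        fusion_bed = data_dir / "fusion_peaks.bed"
        if fusion_bed.exists():
            fusion_peaks = [p.interval for p in read_bed(fusion_bed)]
            fusion_labels = classify_location(fusion_peaks, genes, None, config)
            enrich_map = peaks_to_genes(
                fusion_peaks, fusion_labels, genes, config.tss_window
            )
        else:
            enrich_map = gene_map
        enr = binding_enrichment(de, enrich_map)
        association["binding_enrichment"] = {
            "prop_up_bound": enr.prop_up_bound,
            "prop_down_bound": enr.prop_down_bound,
            "ratio": enr.ratio,
            "n_up": enr.n_up,
            "n_down": enr.n_down,
        }
    association.update(state_results)
    with open(out_dir / "association.json", "w") as fh:
        json.dump(association, fh, indent=1, sort_keys=True, allow_nan=True)
        fh.write("\n")

    with open(out_dir / "run_info.json", "w") as fh:
        json.dump(
            {
                "version": __version__,
                "config": config.to_dict(),
                "config_hash": config.hash(),
                "n_samples": int(len(manifest)),
                "n_consensus": len(consensus),
            },
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")
    log.info("pipeline done: %s", out_dir)
    return out_dir
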