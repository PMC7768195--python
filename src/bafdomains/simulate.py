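"""Synthetic epigenome generator with ground truth.

Emulates the statistical structure the pipeline assumes, so every stage is
testable offline: a multi-chromosome genome with non-overlapping genes and
CpG islands; a "tumor" cell type carrying broad binding domains (lognormal
widths, median 5 kb) planted at a designated tumor-high gene set and narrow
peaks (median 0.6 kb) elsewhere, replicated four times with coordinate
jitter and peak dropout so 3-of-4 consensus is informative; control cell
types with narrow peaks throughout; histone-mark tracks drawn from six
chromatin-state archetypes per condition (control / induced / reverted),
where induction activates repressed states and reversion redraws from the
control archetypes; and a negative-binomial count matrix with planted fold
changes plus a fusion-binding assignment with distinct probabilities for
induced and repressed genes.

Every quantity is drawn from one seeded generator, so a seed reproduces the
dataset byte for byte.  The generator targets the structure of real data —
width contrasts, state archetypes, fold changes — not its absolute counts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    GeneModel,
    GenomicInterval,
    Peak,
    write_bed,
    write_gene_table,
)
from .signal import SignalTrack

MARKS = ("H3K4me1", "H3K4me3", "H3K9ac", "H3K27ac", "H3K27me3")

#: Mean normalized signal per mark for each chromatin-state archetype.
#: Background is 0.2; "high" is well above the 1.0 default threshold.
DEFAULT_ARCHETYPES: dict[str, dict[str, float]] = {
    "active_promoter": {"H3K4me1": 2.0, "H3K4me3": 10.0, "H3K9ac": 6.0,
                        "H3K27ac": 8.0, "H3K27me3": 0.2},
    "active_enhancer": {"H3K4me1": 8.0, "H3K4me3": 0.5, "H3K9ac": 4.0,
                        "H3K27ac": 8.0, "H3K27me3": 0.2},
    "primed_enhancer": {"H3K4me1": 8.0, "H3K4me3": 0.3, "H3K9ac": 0.3,
                        "H3K27ac": 0.3, "H3K27me3": 0.2},
    "bivalent": {"H3K4me1": 0.5, "H3K4me3": 6.0, "H3K9ac": 0.3,
                 "H3K27ac": 0.3, "H3K27me3": 6.0},
    "polycomb_only": {"H3K4me1": 0.3, "H3K4me3": 0.3, "H3K9ac": 0.2,
                      "H3K27ac": 0.2, "H3K27me3": 8.0},
    "no_signal": {"H3K4me1": 0.2, "H3K4me3": 0.2, "H3K9ac": 0.2,
                  "H3K27ac": 0.2, "H3K27me3": 0.2},
}

#: Site-state frequencies mirroring the composition reported for fusion
#: binding sites (polycomb 27.4%, bivalent 17.1%, primed enhancer 28.8%,
#: active promoter 6.0%, active enhancer 11.1%, no signal 9.6%).
DEFAULT_STATE_PROBS: dict[str, float] = {
    "polycomb_only": 0.274,
    "bivalent": 0.171,
    "primed_enhancer": 0.288,
    "active_promoter": 0.060,
    "active_enhancer": 0.111,
    "no_signal": 0.096,
}

#: Induction map: fusion binding activates its targets; repressed and quiet
#: states become active regulatory elements, active states persist.
INDUCTION_MAP: dict[str, str] = {
    "polycomb_only": "active_enhancer",
    "bivalent": "active_promoter",
    "primed_enhancer": "active_enhancer",
    "no_signal": "active_enhancer",
    "active_promoter": "active_promoter",
    "active_enhancer": "active_enhancer",
}


class SimulationError(ValueError):
    pass


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic dataset (all randomness from seed)."""

    seed: int = 0
    # genome
    n_chroms: int = 5
    chrom_length: int = 40_000_000
    n_genes: int = 10_000
    gene_length_log_mean: float = math.log(8_000)
    gene_length_log_sd: float = 0.4
    cpg_promoter_fraction: float = 0.7
    cpg_background_n: int = 100
    n_blacklist: int = 20
    # peak landscape
    n_tumor_high_genes: int = 500
    n_control_high_genes: int = 120
    broad_width_log_mean: float = math.log(5_000)
    broad_width_log_sd: float = 0.4
    narrow_width_log_mean: float = math.log(600)
    narrow_width_log_sd: float = 0.4
    n_tumor_replicates: int = 4
    n_control_types: int = 4
    replicate_jitter: int = 100
    replicate_dropout: float = 0.05
    peak_position_jitter: int = 2_000
    narrow_gene_fraction: float = 0.15
    control_peak_fraction: float = 0.25
    # chromatin states
    noise_sd: float = 0.25
    state_probs: dict = field(default_factory=lambda: dict(DEFAULT_STATE_PROBS))
    archetypes: dict = field(default_factory=lambda: {
        s: dict(v) for s, v in DEFAULT_ARCHETYPES.items()
    })
    # expression
    expression_log_mean: float = math.log(100)
    expression_log_sd: float = 1.0
    dispersion: float = 0.05
    planted_fold: float = 8.0
    n_samples_per_group: int = 6
    binding_prob_up: float = 0.6
    binding_prob_down: float = 0.25
    binding_prob_background: float = 0.3

    def __post_init__(self) -> None:
        for name in ("replicate_dropout", "narrow_gene_fraction",
                     "control_peak_fraction", "cpg_promoter_fraction",
                     "binding_prob_up", "binding_prob_down",
                     "binding_prob_background"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise SimulationError(f"{name} must be in [0, 1]")
        if self.n_tumor_high_genes + self.n_control_high_genes > self.n_genes:
            raise SimulationError("planted gene sets exceed n_genes")
        total = sum(self.state_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationError("state_probs must sum to 1")


@dataclass
class SyntheticDataset:
    config: ScenarioConfig
    chrom_lengths: dict[str, int]
    genes: list[GeneModel]
    cpg_islands: list[GenomicInterval]
    blacklist: list[GenomicInterval]
    peak_sets: dict[str, list[Peak]]  # sample_id -> peaks
    sample_groups: dict[str, str]  # sample_id -> tumor | control
    state_sites: list[GenomicInterval]
    planted_states: dict[str, list[str]]  # condition -> per-site labels
    tracks: dict[str, dict[str, SignalTrack]]  # condition -> mark -> track
    counts: pd.DataFrame
    expr_groups: pd.Series
    gene_lengths: pd.Series
    fusion_peaks: list[GenomicInterval]
    fusion_gene_map: dict[str, list[int]]
    truth: dict


# ---------------------------------------------------------------------------
# genome


def make_genome(config: ScenarioConfig, rng: np.random.Generator):
    """Non-overlapping genes in per-gene slots, CpG islands, blacklist."""
    chrom_lengths = {
        f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)
    }
    chroms = list(chrom_lengths)
    genes: list[GeneModel] = []
    if config.n_genes > 0:
        per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
        for i in range(config.n_genes % config.n_chroms):
            per_chrom[i] += 1
        gid = 0
        for chrom, n in zip(chroms, per_chrom):
            if n == 0:
                continue
            slot = config.chrom_length // n
            if slot < 2_000:
                raise SimulationError(
                    f"cannot pack {n} genes into {chrom}: slot {slot} bp too small"
                )
            for j in range(n):
                length = int(
                    rng.lognormal(config.gene_length_log_mean,
                                  config.gene_length_log_sd)
                )
                length = int(np.clip(length, 200, slot - 1_600))
                lo = j * slot + 500
                hi = (j + 1) * slot - 500 - length
                start = int(rng.integers(lo, max(lo + 1, hi)))
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(
                    GeneModel(f"gene_{gid:05d}", chrom, strand, start, start + length)
                )
                gid += 1
    cpg: list[GenomicInterval] = []
    for g in genes:
        if rng.random() < config.cpg_promoter_fraction:
            start = max(0, g.tss - 200)
            cpg.append(GenomicInterval(g.chrom, start, g.tss + 200))
    for _ in range(config.cpg_background_n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, config.chrom_length - 400))
        cpg.append(GenomicInterval(chrom, start, start + 300))
    cpg.sort()
    blacklist: list[GenomicInterval] = []
    for _ in range(config.n_blacklist):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, config.chrom_length - 1_000))
        blacklist.append(GenomicInterval(chrom, start, start + 1_000))
    blacklist.sort()
    return chrom_lengths, genes, cpg, blacklist


# ---------------------------------------------------------------------------
# peak landscape


def _drop_overlaps(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Sort and drop any interval overlapping the previously kept one."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if out and iv.chrom == out[-1].chrom and iv.start < out[-1].end:
            continue
        out.append(iv)
    return out


def _peak_at(
    gene: GeneModel, width: int, chrom_length: int, offset: int = 0
) -> GenomicInterval:
    """A peak of the given width centered near the gene's TSS.

    A nonzero offset shifts the center so that narrow peaks fall variously
    inside the promoter window, the gene body, or the flanking intergenic
    space — mirroring the mixed location composition of real peak sets.
    """
    center = gene.tss + offset
    start = max(0, center - width // 2)
    end = start + width
    if end > chrom_length:
        end = chrom_length
        start = max(0, end - width)
    return GenomicInterval(gene.chrom, start, end)


def make_peak_landscape(
    config: ScenarioConfig,
    genes: Sequence[GeneModel],
    chrom_lengths: Mapping[str, int],
    rng: np.random.Generator,
):
    """Per-sample peak sets plus the planted-domain ground truth.

    The tumor type plants one broad domain at each tumor-high gene and
    narrow peaks at the control-high genes plus a random fraction of the
    remaining genes; replicates jitter coordinates and drop peaks at the
    configured rates.  Control types carry narrow peaks only.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    ids = [g.gene_id for g in genes]
    n_high = config.n_tumor_high_genes + config.n_control_high_genes
    if n_high > len(ids):
        raise SimulationError("not enough genes for planted sets")
    chosen = rng.choice(len(ids), size=n_high, replace=False)
    tumor_high = [ids[i] for i in chosen[: config.n_tumor_high_genes]]
    control_high = [ids[i] for i in chosen[config.n_tumor_high_genes:]]
    remaining = [g for g in ids if g not in set(tumor_high) | set(control_high)]
    n_narrow = int(round(config.narrow_gene_fraction * len(remaining)))
    narrow_extra = (
        [remaining[i] for i in rng.choice(len(remaining), n_narrow, replace=False)]
        if n_narrow
        else []
    )
    narrow_genes = sorted(set(control_high) | set(narrow_extra))

    def draw_width(log_mean: float, log_sd: float) -> int:
        return max(100, int(rng.lognormal(log_mean, log_sd)))

    def draw_offset() -> int:
        j = config.peak_position_jitter
        return int(rng.integers(-j, j + 1)) if j else 0

    planted_broad: dict[str, GenomicInterval] = {}
    for gid in tumor_high:
        g = gene_by_id[gid]
        w = draw_width(config.broad_width_log_mean, config.broad_width_log_sd)
        planted_broad[gid] = _peak_at(g, w, chrom_lengths[g.chrom], draw_offset())
    planted_narrow: dict[str, GenomicInterval] = {}
    for gid in narrow_genes:
        g = gene_by_id[gid]
        w = draw_width(config.narrow_width_log_mean, config.narrow_width_log_sd)
        planted_narrow[gid] = _peak_at(g, w, chrom_lengths[g.chrom], draw_offset())

    def jitter(iv: GenomicInterval) -> GenomicInterval:
        j = config.replicate_jitter
        ds = int(rng.integers(-j, j + 1)) if j else 0
        de = int(rng.integers(-j, j + 1)) if j else 0
        start = max(0, iv.start + ds)
        end = max(start + 50, iv.end + de)
        return GenomicInterval(iv.chrom, start, end)

    peak_sets: dict[str, list[Peak]] = {}
    sample_groups: dict[str, str] = {}
    for r in range(config.n_tumor_replicates):
        sid = f"tumor_{r + 1}"
        ivs = []
        for iv in list(planted_broad.values()) + list(planted_narrow.values()):
            if rng.random() < config.replicate_dropout:
                continue
            ivs.append(jitter(iv))
        ivs = _drop_overlaps(ivs)
        peak_sets[sid] = [Peak(iv, sid) for iv in ivs]
        sample_groups[sid] = "tumor"
    for c in range(config.n_control_types):
        sid = f"control_{chr(ord('A') + c)}"
        n_pick = int(round(config.control_peak_fraction * len(ids)))
        picked = rng.choice(len(ids), size=n_pick, replace=False)
        ivs = []
        for i in sorted(picked):
            g = gene_by_id[ids[i]]
            w = draw_width(config.narrow_width_log_mean, config.narrow_width_log_sd)
            ivs.append(_peak_at(g, w, chrom_lengths[g.chrom], draw_offset()))
        ivs = _drop_overlaps(ivs)
        peak_sets[sid] = [Peak(iv, sid) for iv in ivs]
        sample_groups[sid] = "control"
    truth = {
        "tumor_high_genes": tumor_high,
        "control_high_genes": control_high,
        "narrow_genes": narrow_genes,
        "planted_broad": {
            gid: [iv.chrom, iv.start, iv.end] for gid, iv in planted_broad.items()
        },
        "planted_broad_widths": {gid: iv.width for gid, iv in planted_broad.items()},
    }
    return peak_sets, sample_groups, truth


# ---------------------------------------------------------------------------
# mark tracks


def plant_states(
    config: ScenarioConfig, n_sites: int, rng: np.random.Generator
) -> list[str]:
    """Draw per-site control states from the configured state frequencies."""
    states = sorted(config.state_probs)
    probs = np.array([config.state_probs[s] for s in states])
    draws = rng.choice(len(states), size=n_sites, p=probs / probs.sum())
    return [states[i] for i in draws]


def induced_states(control: Sequence[str]) -> list[str]:
    return [INDUCTION_MAP[s] for s in control]


def make_mark_tracks(
    config: ScenarioConfig,
    sites: Sequence[GenomicInterval],
    planted_states: Mapping[str, Sequence[str]],
    rng: np.random.Generator,
    noise_sd: float | None = None,
) -> dict[str, dict[str, SignalTrack]]:
    """Per-condition, per-mark normalized tracks over the given sites.

    Within each site a mark's signal is its state archetype mean plus
    truncated (non-negative) Gaussian noise, emitted as one constant run;
    positions outside sites carry no runs (signal 0).  The "reverted"
    condition must be passed with the control labels so its signals are
    redrawn from the control archetypes.
    """
    sd = config.noise_sd if noise_sd is None else noise_sd
    site_list = _drop_overlaps(list(sites))
    if len(site_list) != len(sites):
        raise SimulationError("sites must be non-overlapping")
    tracks: dict[str, dict[str, SignalTrack]] = {}
    for condition, labels in planted_states.items():
        if len(labels) != len(sites):
            raise SimulationError(f"{condition}: one state per site required")
        unknown = set(labels) - set(config.archetypes)
        if unknown:
            raise SimulationError(f"unknown state names: {sorted(unknown)}")
        tracks[condition] = {}
        for mark in MARKS:
            runs: dict[str, list[tuple[int, int, float]]] = {}
            for iv, state in zip(sorted(sites), _sorted_like(sites, labels)):
                mu = config.archetypes[state][mark]
                value = max(0.0, mu + (rng.normal(0.0, sd) if sd > 0 else 0.0))
                runs.setdefault(iv.chrom, []).append((iv.start, iv.end, value))
            tracks[condition][mark] = SignalTrack(
                runs, total_fragments=10_000_000, normalized=True
            )
    return tracks


def _sorted_like(sites: Sequence[GenomicInterval], labels: Sequence[str]) -> list[str]:
    order = sorted(range(len(sites)), key=lambda i: sites[i])
    return [labels[i] for i in order]


# ---------------------------------------------------------------------------
# expression


def make_expression(
    config: ScenarioConfig,
    genes: Sequence[GeneModel],
    truth: Mapping,
    rng: np.random.Generator,
):
    """Negative-binomial counts with planted folds and binding assignment.

    Tumor-high genes get the planted fold in the tumor group; control-high
    genes get its reciprocal.  Fusion binding is assigned per gene with
    probability binding_prob_up (induced), binding_prob_down (repressed) or
    binding_prob_background, and realized as one synthetic fusion peak at
    each bound gene's TSS.
    """
    ids = [g.gene_id for g in genes]
    up = set(truth["tumor_high_genes"])
    down = set(truth["control_high_genes"])
    base = rng.lognormal(config.expression_log_mean, config.expression_log_sd,
                         size=len(ids))
    fold = np.ones(len(ids))
    for i, gid in enumerate(ids):
        if gid in up:
            fold[i] = config.planted_fold
        elif gid in down:
            fold[i] = 1.0 / config.planted_fold
    n_per = config.n_samples_per_group
    samples = [f"tumor_s{i + 1}" for i in range(n_per)] + [
        f"control_s{i + 1}" for i in range(n_per)
    ]
    groups = pd.Series(
        ["tumor"] * n_per + ["control"] * n_per, index=samples, name="group"
    )

    def nb_draw(mu: np.ndarray) -> np.ndarray:
        if config.dispersion <= 0:
            return rng.poisson(mu)
        r = 1.0 / config.dispersion
        p = r / (r + mu)
        return rng.negative_binomial(r, p)

    cols = {}
    for s in samples:
        mu = base * fold if groups[s] == "tumor" else base
        cols[s] = nb_draw(mu)
    counts = pd.DataFrame(cols, index=ids)
    gene_lengths = pd.Series({g.gene_id: g.body.width for g in genes})

    bound: dict[str, bool] = {}
    for gid in ids:
        if gid in up:
            p = config.binding_prob_up
        elif gid in down:
            p = config.binding_prob_down
        else:
            p = config.binding_prob_background
        bound[gid] = bool(rng.random() < p)
    fusion_peaks: list[GenomicInterval] = []
    fusion_gene_map: dict[str, list[int]] = {}
    for g in genes:
        if bound[g.gene_id]:
            start = max(0, g.tss - 250)
            fusion_peaks.append(GenomicInterval(g.chrom, start, g.tss + 250))
            fusion_gene_map[g.gene_id] = [len(fusion_peaks) - 1]
    expr_truth = {
        "planted_fold": config.planted_fold,
        "up_genes": sorted(up),
        "down_genes": sorted(down),
        "bound_genes": sorted(g for g, b in bound.items() if b),
    }
    return counts, groups, gene_lengths, fusion_peaks, fusion_gene_map, expr_truth


# ---------------------------------------------------------------------------
# full dataset


def simulate_dataset(config: ScenarioConfig) -> SyntheticDataset:
    """Generate the complete dataset from one seeded generator."""
    rng = np.random.default_rng(config.seed)
    chrom_lengths, genes, cpg, blacklist = make_genome(config, rng)
    peak_sets, sample_groups, peak_truth = make_peak_landscape(
        config, genes, chrom_lengths, rng
    )
    sites = _drop_overlaps(
        [GenomicInterval(c, s, e) for c, s, e in peak_truth["planted_broad"].values()]
    )
    control_labels = plant_states(config, len(sites), rng)
    states = {
        "control": control_labels,
        "induced": induced_states(control_labels),
        "reverted": control_labels,
    }
    tracks = make_mark_tracks(config, sites, states, rng)
    counts, expr_groups, gene_lengths, fusion_peaks, fusion_map, expr_truth = (
        make_expression(config, genes, peak_truth, rng)
    )
    truth = {
        **peak_truth,
        **expr_truth,
        "planted_states_control": control_labels,
        "planted_states_induced": states["induced"],
        "state_sites": [[s.chrom, s.start, s.end] for s in sites],
    }
    return SyntheticDataset(
        config=config,
        chrom_lengths=chrom_lengths,
        genes=genes,
        cpg_islands=cpg,
        blacklist=blacklist,
        peak_sets=peak_sets,
        sample_groups=sample_groups,
        state_sites=sites,
        planted_states=states,
        tracks=tracks,
        counts=counts,
        expr_groups=expr_groups,
        gene_lengths=gene_lengths,
        fusion_peaks=fusion_peaks,
        fusion_gene_map=fusion_map,
        truth=truth,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> Path:
    """Write the dataset as plain-text files plus a truth manifest.

    Layout: genes.tsv, cpg_islands.bed, blacklist.bed, peaks/<sample>.bed,
    tracks/<condition>_<mark>.bedgraph, counts.tsv, sample_groups.tsv,
    manifest.tsv and truth.json.  Deterministic byte-for-byte for one seed.
    """
    outdir = Path(outdir)
    (outdir / "peaks").mkdir(parents=True, exist_ok=True)
    (outdir / "tracks").mkdir(exist_ok=True)
    write_gene_table(dataset.genes, outdir / "genes.tsv")
    write_bed(dataset.cpg_islands, outdir / "cpg_islands.bed", bed6=False)
    write_bed(dataset.blacklist, outdir / "blacklist.bed", bed6=False)
    with open(outdir / "manifest.tsv", "w") as mf:
        mf.write("sample_id\tgroup\tpeaks_path\n")
        for sid in sorted(dataset.peak_sets):
            path = f"peaks/{sid}.bed"
            write_bed(dataset.peak_sets[sid], outdir / path)
            mf.write(f"{sid}\t{dataset.sample_groups[sid]}\t{path}\n")
    for condition, marks in sorted(dataset.tracks.items()):
        for mark, track in sorted(marks.items()):
            track.to_bedgraph(outdir / "tracks" / f"{condition}_{mark}.bedgraph")
    dataset.counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="gene_id")
    dataset.expr_groups.to_frame().to_csv(
        outdir / "sample_groups.tsv", sep="\t", index_label="sample_id"
    )
    write_bed(dataset.state_sites, outdir / "state_sites.bed", bed6=False)
    write_bed(dataset.fusion_peaks, outdir / "fusion_peaks.bed", bed6=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(dataset.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return outdir
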