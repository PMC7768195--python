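"""Expression transforms, signatures, differential testing, and the
breadth-vs-expression association statistics.

Counts are converted to TPM (length-normalized rates rescaled so each
sample sums to 1e6).  Two-group differential expression is a documented
stand-in for a count-model test: a per-gene Welch t test on log2(TPM + 1)
with Benjamini–Hochberg adjustment, flagged at |log2FC| >= log2(fold) and
adjusted P < alpha; externally produced DE tables in the same schema can be
substituted.  Fold signatures select genes whose group-mean expression
differs by a minimum fold (5x for joint multi-cohort comparisons, 20x for
pairwise ones).  Association statistics link gene sets to the widths of
their mapped peaks: a Welch test on per-gene domain widths, per-set Q4/Q1
binding percentages with Fisher's exact test, and the up- vs down-regulated
binding-enrichment ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .breadth import QuartiledDomainSet
from .intervals import GeneModel, GenomicInterval, Peak, as_interval, nearest_feature
from .annotation import tss_windows


class ExpressionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# containers


@dataclass
class ExpressionMatrix:
    """Gene x sample non-negative expression with group labels.

    ``scale`` is "counts" or "tpm".  ``gene_lengths`` (bp) is required for
    the TPM transform.  ``zero_total_samples`` flags all-zero columns left
    untouched by the transform.
    """

    values: pd.DataFrame  # genes x samples
    groups: pd.Series  # sample -> group label
    gene_lengths: pd.Series | None = None
    scale: str = "counts"
    zero_total_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ExpressionError("expression values must be non-negative")
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ExpressionError(f"samples without group labels: {sorted(missing)}")

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]


@dataclass
class GeneSignature:
    """Two disjoint gene sets: higher in condition A vs higher in condition B."""

    set_high_a: set[str]
    set_high_b: set[str]
    fold_cutoff: float
    comparison: str = ""

    def __post_init__(self) -> None:
        if self.set_high_a & self.set_high_b:
            raise ExpressionError("signature sets must be disjoint")


@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    ci_low: float
    ci_high: float


# ---------------------------------------------------------------------------
# transforms and kernels


def tpm_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Counts -> transcripts per million (per-sample columns sum to 1e6)."""
    if expr.gene_lengths is None:
        raise ExpressionError("gene lengths required for TPM transform")
    lengths = expr.gene_lengths.reindex(expr.values.index)
    if lengths.isna().any():
        raise ExpressionError("gene lengths missing for some genes")
    if (lengths <= 0).any():
        raise ExpressionError("gene lengths must be positive")
    rates = expr.values.div(lengths, axis=0)
    totals = rates.sum(axis=0)
    zero = totals[totals == 0].index.tolist()
    safe = totals.replace(0, np.nan)
    tpm = rates.div(safe, axis=1) * 1e6
    tpm[zero] = 0.0
    return ExpressionMatrix(
        values=tpm,
        groups=expr.groups,
        gene_lengths=expr.gene_lengths,
        scale="tpm",
        zero_total_samples=zero,
    )


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p))):
        raise ExpressionError("p-values must lie in [0, 1]")
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.clip(adjusted, 0, 1)
    out = np.empty(n)
    out[order] = adjusted
    return out


def welch_test(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Welch two-sample t test with Welch–Satterthwaite df and 95% CI.

    Degenerate convention: if both samples have zero variance and equal
    means, returns t=0, p=1 with a zero-width interval.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ExpressionError("welch_test requires at least 2 values per sample")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    diff = x.mean() - y.mean()
    if vx == 0 and vy == 0:
        if diff == 0:
            return WelchResult(t=0.0, df=float(nx + ny - 2), p=1.0,
                               ci_low=0.0, ci_high=0.0)
        raise ExpressionError("both samples constant with unequal means")
    se2 = vx / nx + vy / ny
    se = math.sqrt(se2)
    t = diff / se
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * stats.t.sf(abs(t), df)
    half = stats.t.ppf(0.975, df) * se
    return WelchResult(t=float(t), df=float(df), p=float(p),
                       ci_low=float(diff - half), ci_high=float(diff + half))


def fold_signature(
    expr: ExpressionMatrix,
    group_a: str,
    group_b: str,
    fold_cutoff: float,
    pseudocount: float = 0.1,
) -> GeneSignature:
    """Genes whose pseudocounted group-mean expression differs by >= fold_cutoff."""
    a = expr.samples_in_group(group_a)
    b = expr.samples_in_group(group_b)
    if not a or not b:
        raise ExpressionError(f"empty group among {group_a!r}, {group_b!r}")
    mean_a = expr.values[a].mean(axis=1) + pseudocount
    mean_b = expr.values[b].mean(axis=1) + pseudocount
    high_a = set(expr.values.index[mean_a >= fold_cutoff * mean_b])
    high_b = set(expr.values.index[mean_b >= fold_cutoff * mean_a])
    return GeneSignature(high_a, high_b, fold_cutoff, f"{group_a}_vs_{group_b}")


def two_group_de(
    expr: ExpressionMatrix,
    group_a: str,
    group_b: str,
    fold: float = 4.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Welch test on log2(TPM+1) between two groups, BH-adjusted.

    Returns a table with columns log2_fold_change (A minus B), p_value,
    p_adjusted and significant = (|log2FC| >= log2(fold)) & (p_adjusted <
    alpha).  A stand-in for count-model tests; externally produced tables
    with the same columns slot into all downstream operations.
    """
    a = expr.samples_in_group(group_a)
    b = expr.samples_in_group(group_b)
    if len(a) < 2 or len(b) < 2:
        raise ExpressionError("each group needs at least 2 samples")
    mat = expr.values if expr.scale == "tpm" else tpm_transform(expr).values
    log = np.log2(mat.to_numpy() + 1.0)
    ia = [mat.columns.get_loc(s) for s in a]
    ib = [mat.columns.get_loc(s) for s in b]
    xa, xb = log[:, ia], log[:, ib]
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    va, vb = xa.var(axis=1, ddof=1), xb.var(axis=1, ddof=1)
    na, nb = len(ia), len(ib)
    se2 = va / na + vb / nb
    lfc = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = 2 * stats.t.sf(np.abs(t), df)
    # zero-variance genes: identical within groups; equal means -> p = 1
    degen = se2 == 0
    p = np.where(degen & (lfc == 0), 1.0, p)
    p = np.where(degen & (lfc != 0), 0.0, p)
    padj = bh_adjust(p)
    sig = (np.abs(lfc) >= math.log2(fold)) & (padj < alpha)
    return pd.DataFrame(
        {
            "log2_fold_change": lfc,
            "p_value": p,
            "p_adjusted": padj,
            "significant": sig,
        },
        index=mat.index,
    )


# ---------------------------------------------------------------------------
# peak-to-gene mapping and association statistics


def peaks_to_genes(
    peaks: Sequence[Peak | GenomicInterval],
    labels: Sequence[str],
    genes: Sequence[GeneModel],
    tss_window: int = 1000,
) -> dict[str, list[int]]:
    """Map peaks to genes following the location-class rules.

    Promoter and distal intragenic peaks map to ALL genes whose body or
    ±tss_window TSS window they overlap; distal intergenic peaks map to the
    single nearest gene by body distance.  Returns gene_id -> sorted list
    of peak indices.
    """
    if len(peaks) != len(labels):
        raise ExpressionError("labels must match peaks one-to-one")
    windows = tss_windows(genes, tss_window)
    # per-chromosome arrays for vectorized any-overlap queries
    by_chrom: dict[str, dict] = {}
    for g, w in zip(genes, windows):
        d = by_chrom.setdefault(
            g.chrom, {"ids": [], "bs": [], "be": [], "ws": [], "we": []}
        )
        d["ids"].append(g.gene_id)
        d["bs"].append(g.start)
        d["be"].append(g.end)
        d["ws"].append(w.start)
        d["we"].append(w.end)
    for d in by_chrom.values():
        for key in ("bs", "be", "ws", "we"):
            d[key] = np.asarray(d[key])
    gene_map: dict[str, list[int]] = {}
    for i, (peak, label) in enumerate(zip(peaks, labels)):
        iv = as_interval(peak)
        if label in ("promoter", "distal_intragenic"):
            d = by_chrom.get(iv.chrom)
            if d is None:
                continue
            hit = ((d["bs"] < iv.end) & (d["be"] > iv.start)) | (
                (d["ws"] < iv.end) & (d["we"] > iv.start)
            )
            for j in np.flatnonzero(hit):
                gene_map.setdefault(d["ids"][j], []).append(i)
        elif label == "distal_intergenic":
            gid, _ = nearest_feature(iv, genes)
            gene_map.setdefault(gid, []).append(i)
        else:
            raise ExpressionError(f"unknown location label {label!r}")
    return {g: sorted(ix) for g, ix in gene_map.items()}


def _gene_widths(
    gene_ids: set[str],
    gene_peak_map: Mapping[str, Sequence[int]],
    peak_widths: Sequence[int],
    statistic: str = "max",
) -> tuple[np.ndarray, int]:
    widths, unmapped = [], 0
    for gid in sorted(gene_ids):
        idx = gene_peak_map.get(gid)
        if not idx:
            unmapped += 1
            continue
        ws = [peak_widths[i] for i in idx]
        widths.append(max(ws) if statistic == "max" else float(np.mean(ws)))
    return np.array(widths, dtype=float), unmapped


@dataclass
class AssociationReport:
    """Breadth-vs-signature comparison of per-gene mapped-peak widths."""

    widths_a: np.ndarray
    widths_b: np.ndarray
    median_a: float
    median_b: float
    welch: WelchResult
    unmapped_a: int
    unmapped_b: int

    def to_dict(self) -> dict:
        return {
            "n_a": int(len(self.widths_a)),
            "n_b": int(len(self.widths_b)),
            "median_width_a": self.median_a,
            "median_width_b": self.median_b,
            "welch_t": self.welch.t,
            "welch_df": self.welch.df,
            "welch_p": self.welch.p,
            "ci_low": self.welch.ci_low,
            "ci_high": self.welch.ci_high,
            "unmapped_a": self.unmapped_a,
            "unmapped_b": self.unmapped_b,
        }


def breadth_vs_signature(
    gene_peak_map: Mapping[str, Sequence[int]],
    peak_widths: Sequence[int],
    signature: GeneSignature,
    width_statistic: str = "max",
) -> AssociationReport:
    """Compare mapped-domain widths between the two signature gene sets.

    Each gene's width is the maximum (default) width among its mapped
    peaks; genes with no mapped peak are excluded and counted.  The two
    width samples are compared by medians and a Welch t test.
    """
    wa, ua = _gene_widths(signature.set_high_a, gene_peak_map, peak_widths, width_statistic)
    wb, ub = _gene_widths(signature.set_high_b, gene_peak_map, peak_widths, width_statistic)
    if len(wa) == 0 or len(wb) == 0:
        raise ExpressionError("a signature set has no mapped genes")
    return AssociationReport(
        widths_a=wa,
        widths_b=wb,
        median_a=float(np.median(wa)),
        median_b=float(np.median(wb)),
        welch=welch_test(wa, wb),
        unmapped_a=ua,
        unmapped_b=ub,
    )


def quantile_binding_fractions(
    signature: GeneSignature,
    gene_peak_map: Mapping[str, Sequence[int]],
    qset: QuartiledDomainSet,
) -> pd.DataFrame:
    """Per gene set: % of genes bound by a top-quantile vs bottom-quantile peak.

    "Bound by Qk" means the gene has >= 1 mapped peak labeled Qk.  A
    Fisher's exact test compares the Q-top-bound vs Q-bottom-bound counts
    within each set.  Empty gene sets are skipped.
    """
    top, bottom = f"Q{qset.n_quantiles}", "Q1"
    rows = {}
    for name, gene_set in (("set_high_a", signature.set_high_a),
                           ("set_high_b", signature.set_high_b)):
        if not gene_set:
            continue
        n_top = n_bottom = n = 0
        for gid in sorted(gene_set):
            idx = gene_peak_map.get(gid)
            if not idx:
                continue
            n += 1
            labs = {qset.labels[i] for i in idx}
            n_top += top in labs
            n_bottom += bottom in labs
        if n == 0:
            continue
        table = [[n_top, n - n_top], [n_bottom, n - n_bottom]]
        _, p = stats.fisher_exact(table)
        rows[name] = dict(
            n_genes=n,
            pct_bound_top=100.0 * n_top / n,
            pct_bound_bottom=100.0 * n_bottom / n,
            fisher_p=float(p),
        )
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class BindingEnrichment:
    prop_up_bound: float
    prop_down_bound: float
    ratio: float  # inf when no down-regulated gene is bound
    n_up: int
    n_down: int
    n_up_bound: int
    n_down_bound: int


def binding_enrichment(
    de: pd.DataFrame, gene_peak_map: Mapping[str, Sequence[int]]
) -> BindingEnrichment:
    """How much more often are induced genes bound than repressed genes?

    Takes a DE table (two_group_de schema) and the gene->peak map; returns
    the proportion of significantly up- and down-regulated genes with >= 1
    mapped peak and their ratio (the "x-fold more likely" statistic).
    """
    sig = de[de["significant"]]
    up = sig.index[sig["log2_fold_change"] > 0]
    down = sig.index[sig["log2_fold_change"] < 0]
    if len(up) == 0 or len(down) == 0:
        raise ExpressionError("need at least one up- and one down-regulated gene")
    up_bound = sum(bool(gene_peak_map.get(g)) for g in up)
    down_bound = sum(bool(gene_peak_map.get(g)) for g in down)
    prop_up = up_bound / len(up)
    prop_down = down_bound / len(down)
    ratio = prop_up / prop_down if prop_down > 0 else float("inf")
    return BindingEnrichment(
        prop_up_bound=prop_up,
        prop_down_bound=prop_down,
        ratio=ratio,
        n_up=len(up),
        n_down=len(down),
        n_up_bound=up_bound,
        n_down_bound=down_bound,
    )
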