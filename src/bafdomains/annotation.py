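"""Rule-based genomic-location and CpG-island annotation of peaks.

A peak is a *promoter* if it overlaps the closed ±1 kb window around any
TSS, or if its mean H3K4me3 signal exceeds the promoter threshold
(8 normalized units by default); failing that it is *distal intragenic* if
it overlaps any gene body, and *distal intergenic* otherwise.  Precedence
is promoter > distal_intragenic > distal_intergenic.  CpG annotation flags
a peak that overlaps at least one CpG island by one or more bases.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .intervals import GenomicInterval, GeneModel, Peak, as_interval, overlaps_any
from .signal import SignalError, SignalTrack, mean_signal_many

LOCATION_CLASSES = ("promoter", "distal_intragenic", "distal_intergenic")


def tss_windows(genes: Sequence[GeneModel], tss_window: int) -> list[GenomicInterval]:
    """Half-open spans equivalent to the closed [tss - w, tss + w] windows."""
    out = []
    for g in genes:
        start = max(0, g.tss - tss_window)
        out.append(GenomicInterval(g.chrom, start, g.tss + tss_window + 1))
    return out


def classify_location(
    peaks: Sequence[Peak | GenomicInterval],
    genes: Sequence[GeneModel],
    promoter_track: SignalTrack | None = None,
    config: PipelineConfig | None = None,
) -> list[str]:
    """Label each peak promoter / distal_intragenic / distal_intergenic.

    ``promoter_track`` (H3K4me3) is optional; without it only the TSS-window
    rule defines promoters.  When given it must be depth-normalized.
    """
    config = config or PipelineConfig()
    if not genes:
        raise ValueError("classify_location requires a non-empty gene set")
    if promoter_track is not None and not promoter_track.normalized:
        raise SignalError("promoter track must be normalized")
    near_tss = overlaps_any(peaks, tss_windows(genes, config.tss_window))
    in_body = overlaps_any(peaks, [g.body for g in genes])
    if promoter_track is not None:
        marks = mean_signal_many(
            promoter_track, [as_interval(p) for p in peaks], missing_chrom="lenient"
        )
        strong = marks > config.promoter_signal_threshold
    else:
        strong = np.zeros(len(peaks), dtype=bool)
    labels = []
    for i in range(len(peaks)):
        if near_tss[i] or strong[i]:
            labels.append("promoter")
        elif in_body[i]:
            labels.append("distal_intragenic")
        else:
            labels.append("distal_intergenic")
    return labels


def location_composition(labels: Sequence[str]) -> pd.DataFrame:
    """Counts and fractions per location class (fractions sum to 1)."""
    if len(labels) == 0:
        raise ValueError("location_composition requires at least one peak")
    counts = {c: 0 for c in LOCATION_CLASSES}
    for l in labels:
        if l not in counts:
            raise ValueError(f"unknown location label {l!r}")
        counts[l] += 1
    n = len(labels)
    return pd.DataFrame(
        {
            "count": pd.Series(counts),
            "fraction": pd.Series({c: counts[c] / n for c in counts}),
        }
    )


def cpg_annotation(
    peaks: Sequence[Peak | GenomicInterval],
    cpg_islands: Sequence[GenomicInterval],
) -> tuple[list[bool], float]:
    """Per-peak CpG flag (any-overlap with an island) and the flagged fraction."""
    if len(peaks) == 0:
        return [], float("nan")
    flags = overlaps_any(peaks, cpg_islands) if cpg_islands else [False] * len(peaks)
    return flags, float(np.mean(flags))
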