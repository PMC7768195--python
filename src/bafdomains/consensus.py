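"""Multi-sample consensus peaks and fusion-protein binding sites.

Consensus regions are the maximal spans where per-base support — the number
of sample peak sets covering a base, each sample counted once — reaches a
minimum (e.g. 3 of 4 tumor replicates), subsequently merged within a fixed
gap (2 kb for BAF ATPase domains, 5 kb for polycomb H3K27me3 domains).
Fusion-protein sites additionally require the ChIP signal in the fusion
sample to exceed the control by a minimum fold over the candidate region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .intervals import GenomicInterval, Peak, as_interval, merge_intervals
from .signal import SignalError, SignalTrack, mean_signal


class ConsensusError(ValueError):
    pass


def consensus_peaks(
    peak_sets: Sequence[Sequence[Peak | GenomicInterval]],
    min_support: int,
    merge_gap: int,
) -> list[GenomicInterval]:
    """Regions covered by >= ``min_support`` sets, merged within ``merge_gap``.

    Each sample's peak set must be internally non-overlapping (each sample
    then contributes support 0 or 1 at every base).  The result is sorted
    and deterministic.
    """
    if min_support < 1:
        raise ConsensusError("min_support must be >= 1")
    if min_support > len(peak_sets):
        raise ConsensusError(
            f"min_support {min_support} exceeds number of peak sets {len(peak_sets)}"
        )
    # boundary sweep: +1 at each start, -1 at each end, per chromosome
    events: dict[str, list[tuple[int, int]]] = {}
    for peaks in peak_sets:
        ivs = sorted(as_interval(p) for p in peaks)
        for prev, cur in zip(ivs, ivs[1:]):
            if cur.chrom == prev.chrom and cur.start < prev.end:
                raise ConsensusError(
                    f"peak set not internally merged: {prev} overlaps {cur}"
                )
        for iv in ivs:
            events.setdefault(iv.chrom, []).append((iv.start, +1))
            events[iv.chrom].append((iv.end, -1))
    regions: list[GenomicInterval] = []
    for chrom in sorted(events):
        depth = 0
        region_start = None
        for pos, delta in sorted(events[chrom]):
            new_depth = depth + delta
            if depth < min_support <= new_depth and region_start is None:
                region_start = pos
            elif new_depth < min_support <= depth and region_start is not None:
                if pos > region_start:
                    regions.append(GenomicInterval(chrom, region_start, pos))
                region_start = None
            depth = new_depth
    return merge_intervals(regions, merge_gap)


@dataclass
class FusionSiteReport:
    """Per-candidate region: replicate-consensus span, signal means, verdict."""

    table: pd.DataFrame  # chrom, start, end, fusion_mean, control_mean, fold, kept

    @property
    def kept(self) -> list[GenomicInterval]:
        rows = self.table[self.table["kept"]]
        return [
            GenomicInterval(r.chrom, int(r.start), int(r.end))
            for r in rows.itertuples()
        ]


def fusion_sites(
    replicate_sets: Sequence[Sequence[Peak | GenomicInterval]],
    fusion_track: SignalTrack,
    control_track: SignalTrack,
    min_fold: float = 2.0,
    pseudocount: float = 1.0,
    merge_gap: int = 200,
) -> FusionSiteReport:
    """Replicate-common regions with >= ``min_fold`` more fusion than control signal.

    Candidates are the 2-of-2 consensus of the replicate peak sets (merged
    within ``merge_gap``); a candidate is kept iff
    ``(fusion_mean + pc) / (control_mean + pc) >= min_fold``.  Both tracks
    must be depth-normalized so the fold is meaningful.
    """
    if len(replicate_sets) != 2:
        raise ConsensusError("fusion_sites expects exactly two replicate sets")
    if not (fusion_track.normalized and control_track.normalized):
        raise SignalError("fusion_sites requires normalized tracks")
    candidates = consensus_peaks(replicate_sets, min_support=2, merge_gap=merge_gap)
    rows = []
    for iv in candidates:
        fm = mean_signal(fusion_track, iv, missing_chrom="lenient")
        cm = mean_signal(control_track, iv, missing_chrom="lenient")
        fold = (fm + pseudocount) / (cm + pseudocount)
        rows.append((iv.chrom, iv.start, iv.end, fm, cm, fold, fold >= min_fold))
    table = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "fusion_mean", "control_mean", "fold", "kept"],
    )
    return FusionSiteReport(table)
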