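"""Width-quartile ("broad domain") analytics.

Peak sets are partitioned into width quantiles Q1 (narrowest) .. Qn
(broadest) by rank; Q4 of a quartiled set is the operational definition of
a broad domain.  The partition is width-monotone and balanced: group sizes
differ by at most n_quantiles - 1, and every peak in Qi is at most as wide
as every peak in Qi+1 (ties broken by coordinate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, Peak, as_interval, overlaps_any


class BreadthError(ValueError):
    pass


@dataclass
class QuartiledDomainSet:
    """Peaks with per-peak width-quantile labels Q1..Qn (input order preserved)."""

    peaks: list
    labels: list[str]
    n_quantiles: int

    def __post_init__(self) -> None:
        if len(self.peaks) != len(self.labels):
            raise BreadthError("labels must match peaks one-to-one")

    @property
    def quantile_names(self) -> list[str]:
        return [f"Q{i}" for i in range(1, self.n_quantiles + 1)]

    def group(self, label: str) -> list:
        return [p for p, l in zip(self.peaks, self.labels) if l == label]

    def widths(self, label: str | None = None) -> np.ndarray:
        ps = self.peaks if label is None else self.group(label)
        return np.array([as_interval(p).width for p in ps])


def assign_width_quantiles(
    peaks: Sequence[Peak | GenomicInterval], n_quantiles: int = 4
) -> QuartiledDomainSet:
    """Partition peaks into n width quantiles by rank.

    Peaks are ranked by (width, chrom, start) ascending; the peak of rank r
    (1-based, out of n peaks) is labeled Q⌈n_quantiles·r/n⌉.  This yields
    balanced groups (sizes differ by at most n_quantiles − 1) and a
    width-monotone partition with a deterministic tie-break.
    """
    peaks = list(peaks)
    n = len(peaks)
    if n_quantiles < 1:
        raise BreadthError("n_quantiles must be >= 1")
    if n < n_quantiles:
        raise BreadthError(f"need at least {n_quantiles} peaks, got {n}")
    order = sorted(
        range(n),
        key=lambda i: (
            as_interval(peaks[i]).width,
            as_interval(peaks[i]).chrom,
            as_interval(peaks[i]).start,
        ),
    )
    labels = [""] * n
    for rank0, i in enumerate(order):
        r = rank0 + 1
        labels[i] = f"Q{math.ceil(n_quantiles * r / n)}"
    return QuartiledDomainSet(peaks, labels, n_quantiles)


def quantile_summary(qset: QuartiledDomainSet) -> pd.DataFrame:
    """Per-quantile width summary (n, median, quartiles, min, max) plus overall."""
    rows = {}
    for label in qset.quantile_names + ["overall"]:
        w = qset.widths(None if label == "overall" else label)
        if len(w) == 0:
            rows[label] = dict(n=0, median=np.nan, q1=np.nan, q3=np.nan,
                               min=np.nan, max=np.nan)
            continue
        rows[label] = dict(
            n=len(w),
            median=float(np.median(w)),
            q1=float(np.percentile(w, 25)),
            q3=float(np.percentile(w, 75)),
            min=int(w.min()),
            max=int(w.max()),
        )
    return pd.DataFrame.from_dict(rows, orient="index")


def overlap_by_quantile(
    qset: QuartiledDomainSet, reference: Sequence[GenomicInterval]
) -> pd.Series:
    """Per-quantile fraction of peaks sharing >= 1 base with any reference interval."""
    flags = overlaps_any(qset.peaks, reference) if reference else [False] * len(qset.peaks)
    out = {}
    for label in qset.quantile_names:
        idx = [i for i, l in enumerate(qset.labels) if l == label]
        out[label] = float(np.mean([flags[i] for i in idx])) if idx else 0.0
    return pd.Series(out, name="overlap_fraction")


def denovo_classification(
    after: QuartiledDomainSet, before: Sequence[GenomicInterval]
) -> pd.DataFrame:
    """Per-quantile fractions of preexisting vs de novo domains.

    An "after" domain is preexisting iff it overlaps (>= 1 base) any
    "before" interval, otherwise de novo; the two fractions sum to 1 in
    every non-empty quantile.
    """
    flags = overlaps_any(after.peaks, before) if before else [False] * len(after.peaks)
    rows = {}
    for label in after.quantile_names:
        idx = [i for i, l in enumerate(after.labels) if l == label]
        if not idx:
            rows[label] = dict(n=0, preexisting=np.nan, de_novo=np.nan)
            continue
        pre = float(np.mean([flags[i] for i in idx]))
        rows[label] = dict(n=len(idx), preexisting=pre, de_novo=1.0 - pre)
    return pd.DataFrame.from_dict(rows, orient="index")
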