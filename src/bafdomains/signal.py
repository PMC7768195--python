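"""Depth-normalized signal tracks and the aggregation behind every display.

A :class:`SignalTrack` stores per-chromosome piecewise-constant coverage as
sorted, non-overlapping runs of ``(start, end, value)``; positions not
covered by any run have signal 0.  Normalization rescales coverage to a
per-10-million-fragment scale, so thresholds such as "average normalized
signal above eight" are comparable across libraries.  Aggregation is always
length-weighted, so the mean over an interval is the integral of the track
divided by interval width.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalError, as_interval


class SignalError(ValueError):
    pass


@dataclass
class _ChromRuns:
    starts: np.ndarray  # int64, sorted
    ends: np.ndarray
    values: np.ndarray  # float64, >= 0
    # prefix[i] = integral of runs 0..i-1
    prefix: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        areas = self.values * (self.ends - self.starts)
        self.prefix = np.concatenate([[0.0], np.cumsum(areas)])

    def integral(self, x: np.ndarray) -> np.ndarray:
        """Integral of the track over (-inf, x), vectorized over positions x."""
        x = np.asarray(x, dtype=np.int64)
        k = np.searchsorted(self.starts, x, side="right") - 1
        k_safe = np.clip(k, 0, len(self.starts) - 1)
        inside = np.clip(x - self.starts[k_safe], 0, self.ends[k_safe] - self.starts[k_safe])
        contrib = np.where(k >= 0, self.values[k_safe] * inside, 0.0)
        base = np.where(k >= 0, self.prefix[k_safe], 0.0)
        return base + contrib


class SignalTrack:
    """Piecewise-constant per-base coverage with a declared sequencing depth."""

    def __init__(
        self,
        runs: Mapping[str, Sequence[tuple[int, int, float]]],
        total_fragments: int = 0,
        normalized: bool = False,
    ):
        self._chroms: dict[str, _ChromRuns] = {}
        for chrom, rs in runs.items():
            if len(rs) == 0:
                continue
            arr = sorted(rs)
            starts = np.array([r[0] for r in arr], dtype=np.int64)
            ends = np.array([r[1] for r in arr], dtype=np.int64)
            values = np.array([r[2] for r in arr], dtype=np.float64)
            if np.any(starts >= ends) or np.any(starts < 0):
                raise SignalError(f"{chrom}: runs must satisfy 0 <= start < end")
            if np.any(values < 0):
                raise SignalError(f"{chrom}: negative signal values")
            if np.any(starts[1:] < ends[:-1]):
                raise SignalError(f"{chrom}: overlapping runs")
            self._chroms[chrom] = _ChromRuns(starts, ends, values)
        self.total_fragments = int(total_fragments)
        self.normalized = bool(normalized)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._chroms)

    def runs(self, chrom: str) -> list[tuple[int, int, float]]:
        cr = self._chroms.get(chrom)
        if cr is None:
            return []
        return list(zip(cr.starts.tolist(), cr.ends.tolist(), cr.values.tolist()))

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._chroms

    def _require(self, chrom: str, strict: bool) -> _ChromRuns | None:
        cr = self._chroms.get(chrom)
        if cr is None and strict:
            raise SignalError(f"chromosome {chrom!r} absent from track")
        return cr

    # -- io ---------------------------------------------------------------
    @classmethod
    def from_bedgraph(
        cls, path: str | Path, total_fragments: int = 0, normalized: bool = False
    ) -> "SignalTrack":
        runs: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith(("track", "browser", "#")):
                    continue
                f = line.split("\t")
                if len(f) < 4:
                    raise SignalError(f"{path}:{lineno}: need 4 bedGraph columns")
                try:
                    runs.setdefault(f[0], []).append((int(f[1]), int(f[2]), float(f[3])))
                except ValueError as exc:
                    raise SignalError(f"{path}:{lineno}: {exc}") from exc
        return cls(runs, total_fragments=total_fragments, normalized=normalized)

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in self.chroms:
                for start, end, value in self.runs(chrom):
                    fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def normalize_track(
    track: SignalTrack, normalization_depth: int = 10_000_000
) -> SignalTrack:
    """Rescale coverage to the per-``normalization_depth``-fragments scale."""
    if track.normalized:
        raise SignalError("track is already normalized")
    if track.total_fragments <= 0:
        raise SignalError("total_fragments must be positive to normalize")
    scale = normalization_depth / track.total_fragments
    runs = {
        chrom: [(s, e, v * scale) for s, e, v in track.runs(chrom)]
        for chrom in track.chroms
    }
    return SignalTrack(runs, total_fragments=track.total_fragments, normalized=True)


def mean_signal(
    track: SignalTrack, interval: GenomicInterval, missing_chrom: str = "strict"
) -> float:
    """Length-weighted mean of the track over a half-open interval.

    Uncovered positions contribute 0.  A chromosome entirely absent from the
    track raises (``missing_chrom="strict"``, the default) or returns 0
    (``"lenient"``).
    """
    iv = as_interval(interval)
    cr = track._require(iv.chrom, strict=(missing_chrom == "strict"))
    if cr is None:
        return 0.0
    lo, hi = cr.integral(np.array([iv.start, iv.end]))
    return float((hi - lo) / iv.width)


def mean_signal_many(
    track: SignalTrack,
    intervals: Sequence[GenomicInterval],
    missing_chrom: str = "strict",
) -> np.ndarray:
    """Vectorized :func:`mean_signal` over many intervals."""
    out = np.zeros(len(intervals))
    by_chrom: dict[str, list[int]] = {}
    for i, iv in enumerate(intervals):
        by_chrom.setdefault(as_interval(iv).chrom, []).append(i)
    for chrom, idx in by_chrom.items():
        cr = track._require(chrom, strict=(missing_chrom == "strict"))
        if cr is None:
            continue
        starts = np.array([as_interval(intervals[i]).start for i in idx])
        ends = np.array([as_interval(intervals[i]).end for i in idx])
        out[idx] = (cr.integral(ends) - cr.integral(starts)) / (ends - starts)
    return out


def binned_window(
    track: SignalTrack, chrom: str, center: int, span: int, bin: int
) -> np.ndarray:
    """Length-weighted bin means over ``[center - span/2, center + span/2)``.

    Returns ``span // bin`` values left to right.  Bins beyond the covered
    part of the chromosome (including negative coordinates) are 0.
    """
    if span % bin != 0:
        raise SignalError(f"span {span} not divisible by bin {bin}")
    n = span // bin
    cr = track._chroms.get(chrom)
    if cr is None:
        return np.zeros(n)
    edges = center - span // 2 + bin * np.arange(n + 1)
    edges_clipped = np.clip(edges, 0, None)
    integ = cr.integral(edges_clipped)
    return np.diff(integ) / bin


def log2_change(after: float, before: float, pseudocount: float = 1.0) -> float:
    """log2((after + pc) / (before + pc)); symmetric pseudocount tames zeros."""
    if pseudocount <= 0:
        raise SignalError("pseudocount must be > 0")
    if after < 0 or before < 0:
        raise SignalError("signal values must be >= 0")
    return float(np.log2((after + pseudocount) / (before + pseudocount)))


@dataclass
class SignalMatrix:
    """A site x bin (or site x mark) matrix of normalized signal.

    Metadata records how it was built — bin width, window span, whether the
    values are log2-scaled, and any percentile cap already applied — so the
    exported table is self-describing.
    """

    values: pd.DataFrame
    bin_width: int | None = None
    span: int | None = None
    log2_scaled: bool = False
    cap_percentile_applied: float | None = None

    def __post_init__(self) -> None:
        if self.bin_width and self.span:
            if self.values.shape[1] != self.span // self.bin_width:
                raise SignalError(
                    f"expected {self.span // self.bin_width} columns for "
                    f"span {self.span} / bin {self.bin_width}"
                )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# bin_width={self.bin_width} span={self.span} "
                f"log2={self.log2_scaled} cap_percentile={self.cap_percentile_applied}\n"
            )
            self.values.to_csv(fh, sep="\t")


def window_matrix(
    track: SignalTrack,
    sites: Sequence[GenomicInterval],
    span: int,
    bin: int,
    site_ids: Sequence[str] | None = None,
) -> SignalMatrix:
    """Stack binned windows centered on each site's midpoint into a matrix."""
    rows = []
    for iv in sites:
        iv = as_interval(iv)
        center = (iv.start + iv.end) // 2
        rows.append(binned_window(track, iv.chrom, center, span, bin))
    ids = list(site_ids) if site_ids is not None else [
        f"{as_interval(s).chrom}:{as_interval(s).start}-{as_interval(s).end}"
        for s in sites
    ]
    df = pd.DataFrame(np.array(rows).reshape(len(rows), span // bin), index=ids)
    return SignalMatrix(df, bin_width=bin, span=span)


def cap_at_percentile(matrix: SignalMatrix, percentile: float = 99.0) -> SignalMatrix:
    """Cap all values above the matrix-wide empirical percentile.

    The cap is the upper order statistic (``method="higher"``) rather than
    an interpolated quantile: an interpolated cap moves every time it is
    reapplied, whereas the order statistic makes capping idempotent.
    """
    if not (0 < percentile <= 100):
        raise SignalError("percentile must be in (0, 100]")
    if matrix.values.size == 0:
        raise SignalError("cannot cap an empty matrix")
    cap = float(
        np.percentile(matrix.values.to_numpy().ravel(), percentile, method="higher")
    )
    capped = matrix.values.clip(upper=cap)
    return SignalMatrix(
        capped,
        bin_width=matrix.bin_width,
        span=matrix.span,
        log2_scaled=matrix.log2_scaled,
        cap_percentile_applied=percentile,
    )
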