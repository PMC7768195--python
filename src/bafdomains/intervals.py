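"""Genomic interval primitives and interval algebra.

All coordinates are 0-based, half-open (BED convention): an interval
``[start, end)`` covers bases ``start .. end-1`` and must satisfy
``0 <= start < end``.  Zero-width intervals are rejected.  These intervals
are the atoms of every downstream analytic — a ChIP-seq "peak", a "broad
domain", a binding "site", a gene body, a CpG island and a blacklist region
are all plain :class:`GenomicInterval` spans.
"""

from __future__ import annotations

from dataclasses import dataclass
from numbers import Integral
from pathlib import Path
from typing import Iterable, Sequence


class IntervalError(ValueError):
    """Raised when an interval or interval file violates its invariants."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not isinstance(self.start, Integral) or not isinstance(self.end, Integral):
            raise IntervalError(f"coordinates must be integers: {self!r}")
        object.__setattr__(self, "start", int(self.start))
        object.__setattr__(self, "end", int(self.end))
        if self.start < 0 or self.start >= self.end:
            raise IntervalError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two spans share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance(self, other: "GenomicInterval") -> int:
        """Gap in bases between two spans on the same chromosome (0 if overlapping)."""
        if self.chrom != other.chrom:
            raise IntervalError("distance undefined across chromosomes")
        return max(0, self.start - other.end, other.start - self.end)


@dataclass(frozen=True)
class Peak:
    """A called binding site: an interval plus provenance and optional BED6 extras."""

    interval: GenomicInterval
    sample_id: str = ""
    name: str = "."
    score: float = 0.0
    strand: str = "."

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def width(self) -> int:
        return self.interval.width


@dataclass(frozen=True)
class GeneModel:
    """A gene body with strand and transcription start site.

    The TSS is the 5' end of the body: ``start`` on the + strand and
    ``end - 1`` on the − strand (0-based base position).
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise IntervalError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.start < 0 or self.start >= self.end:
            raise IntervalError(
                f"gene {self.gene_id}: invalid body {self.start}-{self.end}"
            )

    @property
    def body(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


def as_interval(x) -> GenomicInterval:
    """Coerce a Peak or GenomicInterval to its GenomicInterval."""
    return x.interval if isinstance(x, Peak) else x


# ---------------------------------------------------------------------------
# interval algebra


def merge_intervals(
    intervals: Iterable[GenomicInterval], max_gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose inter-interval gap is at most ``max_gap`` bases.

    Overlapping and abutting intervals always merge; two intervals separated
    by a gap of exactly ``max_gap`` merge, a gap of ``max_gap + 1`` does not.
    Intervals on different chromosomes never merge.  Output is sorted by
    (chrom, start) and pairwise non-overlapping.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    ivs = sorted(as_interval(x) for x in intervals)
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and iv.chrom == out[-1].chrom and iv.start - out[-1].end <= max_gap:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def subtract_blacklist(
    peaks: Sequence[Peak | GenomicInterval],
    blacklist: Sequence[GenomicInterval],
) -> list:
    """Drop every peak sharing at least one base with any blacklist interval.

    A peak exactly abutting a blacklist interval (``peak.end == bl.start``)
    shares no base and is kept.  Input order is preserved; peaks are dropped
    whole, never trimmed.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for b in blacklist:
        by_chrom.setdefault(b.chrom, []).append(as_interval(b))
    for lst in by_chrom.values():
        lst.sort()
    kept = []
    for p in peaks:
        iv = as_interval(p)
        if not any(iv.overlaps(b) for b in by_chrom.get(iv.chrom, ())):
            kept.append(p)
    return kept


def nearest_feature(
    query: GenomicInterval, features: Sequence[GeneModel]
) -> tuple[str, int]:
    """Return (gene_id, gap in bp) of the gene body nearest to ``query``.

    Distance is to the gene body (0 when overlapping).  Ties break first by
    smaller body start, then lexicographically by gene id.  Raises if no
    feature lies on the query's chromosome.
    """
    best: tuple[int, int, str] | None = None
    for g in features:
        if g.chrom != query.chrom:
            continue
        d = query.distance(g.body)
        key = (d, g.start, g.gene_id)
        if best is None or key < best:
            best = key
    if best is None:
        raise IntervalError(f"no gene on chromosome {query.chrom}")
    return best[2], best[0]


def overlaps_any(
    queries: Sequence[Peak | GenomicInterval],
    reference: Sequence[Peak | GenomicInterval],
) -> list[bool]:
    """Per-query flag: does it share >= 1 base with any reference interval?"""
    import numpy as np

    merged = merge_intervals([as_interval(r) for r in reference], max_gap=0)
    by_chrom: dict[str, tuple] = {}
    for r in merged:
        by_chrom.setdefault(r.chrom, ([], []))
        by_chrom[r.chrom][0].append(r.start)
        by_chrom[r.chrom][1].append(r.end)
    arrays = {
        c: (np.array(s), np.array(e)) for c, (s, e) in by_chrom.items()
    }
    flags = np.zeros(len(queries), dtype=bool)
    q_by_chrom: dict[str, list[int]] = {}
    for i, q in enumerate(queries):
        q_by_chrom.setdefault(as_interval(q).chrom, []).append(i)
    for chrom, idx in q_by_chrom.items():
        if chrom not in arrays:
            continue
        starts, ends = arrays[chrom]
        q_starts = np.array([as_interval(queries[i]).start for i in idx])
        q_ends = np.array([as_interval(queries[i]).end for i in idx])
        # merged refs are disjoint and sorted, so only the last ref starting
        # before each query's end can overlap it
        k = np.searchsorted(starts, q_ends - 1, side="right") - 1
        hit = (k >= 0) & (ends[np.clip(k, 0, None)] > q_starts)
        flags[idx] = hit
    return flags.tolist()


# ---------------------------------------------------------------------------
# BED input/output

_HEADER_PREFIXES = ("track", "browser", "#")


def read_bed(path: str | Path, sample_id: str | None = None) -> list[Peak]:
    """Read a BED3/BED6 file into Peaks.

    Track/browser/comment header lines are skipped.  Records are validated
    (a malformed line raises with its line number) and returned sorted by
    (chrom, start, end) regardless of input order.
    """
    path = Path(path)
    sid = sample_id if sample_id is not None else path.stem
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_HEADER_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise IntervalError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            except (ValueError, IntervalError) as exc:
                raise IntervalError(f"{path}:{lineno}: {exc}") from exc
            name = fields[3] if len(fields) > 3 else "."
            try:
                score = float(fields[4]) if len(fields) > 4 else 0.0
            except ValueError as exc:
                raise IntervalError(f"{path}:{lineno}: bad score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            peaks.append(Peak(iv, sid, name, score, strand))
    peaks.sort(key=lambda p: (p.chrom, p.start, p.end))
    return peaks


def write_bed(
    peaks: Iterable[Peak | GenomicInterval], path: str | Path, bed6: bool = True
) -> None:
    """Write peaks as BED6 (default) or BED3, tab-separated."""
    with open(path, "w") as fh:
        for p in peaks:
            iv = as_interval(p)
            if bed6 and isinstance(p, Peak):
                score = int(p.score) if float(p.score).is_integer() else p.score
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t{score}\t{p.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a gene-model TSV with header gene_id, chrom, strand, start, end."""
    path = Path(path)
    genes: list[GeneModel] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["gene_id", "chrom", "strand", "start", "end"]
        if [c for c in required if c not in header]:
            raise IntervalError(f"{path}: header must contain {required}")
        idx = {c: header.index(c) for c in required}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            try:
                genes.append(
                    GeneModel(
                        gene_id=f[idx["gene_id"]],
                        chrom=f[idx["chrom"]],
                        strand=f[idx["strand"]],
                        start=int(f[idx["start"]]),
                        end=int(f[idx["end"]]),
                    )
                )
            except (ValueError, IndexError, IntervalError) as exc:
                raise IntervalError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\tstart\tend\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.start}\t{g.end}\n")


def read_gtf_genes(path: str | Path) -> list[GeneModel]:
    """Read 'gene' feature lines from a GTF subset (gene_id attribute required).

    GTF is 1-based closed; coordinates are converted to 0-based half-open.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = f[8]
            gene_id = None
            for part in attrs.split(";"):
                part = part.strip()
                if part.startswith("gene_id"):
                    gene_id = part.split(None, 1)[1].strip('"')
                    break
            if gene_id is None:
                raise IntervalError(f"{path}:{lineno}: gene line without gene_id")
            try:
                genes.append(
                    GeneModel(gene_id, f[0], f[6], int(f[3]) - 1, int(f[4]))
                )
            except (ValueError, IntervalError) as exc:
                raise IntervalError(f"{path}:{lineno}: {exc}") from exc
    return genes
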