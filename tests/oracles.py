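"""Independent brute-force oracles used to validate the interval algebra and
statistical kernels.  These deliberately avoid the package's own sweep-line
and vectorized code paths: everything here works per base or by exhaustive
enumeration on small instances."""

from __future__ import annotations

import itertools
import math

import numpy as np

from bafdomains import GenomicInterval


def _bool_runs(covered):
    """(start, end) runs of True in a per-base boolean array."""
    padded = np.concatenate([[False], covered, [False]]).astype(np.int8)
    d = np.diff(padded)
    return list(zip(np.flatnonzero(d == 1).tolist(),
                    np.flatnonzero(d == -1).tolist()))


def merge_oracle(intervals, max_gap):
    """Per-base union after padding ends by max_gap, then trim.

    Extending every end by g makes two intervals' padded per-base spans
    touch (and thus union) exactly when their gap is <= g, since abutting
    runs coalesce in a boolean array; the union runs are then trimmed back.
    """
    by_chrom = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out = []
    pad = max_gap
    for chrom in sorted(by_chrom):
        ivs = by_chrom[chrom]
        hi = max(iv.end for iv in ivs) + pad + 2
        covered = np.zeros(hi, dtype=bool)
        for iv in ivs:
            covered[iv.start : iv.end + pad] = True
        for s, e in _bool_runs(covered):
            out.append(GenomicInterval(chrom, s, e - pad))
    return sorted(out)


def consensus_oracle(peak_sets, min_support, merge_gap):
    """Per-base support depth (each set counted once per base), thresholded,
    then merged with merge_oracle."""
    chroms = sorted(
        {iv.chrom for peaks in peak_sets for iv in peaks}
    )
    regions = []
    for chrom in chroms:
        hi = max(
            iv.end for peaks in peak_sets for iv in peaks if iv.chrom == chrom
        ) + 2
        depth = np.zeros(hi, dtype=int)
        for peaks in peak_sets:
            cov = np.zeros(hi, dtype=bool)
            for iv in peaks:
                if iv.chrom == chrom:
                    cov[iv.start : iv.end] = True
            depth += cov
        for s, e in _bool_runs(depth >= min_support):
            regions.append(GenomicInterval(chrom, s, e))
    return merge_oracle(regions, merge_gap) if regions else []


def nearest_oracle(query, genes):
    """Exhaustive distance scan with the documented tie-break."""
    best = None
    for g in genes:
        if g.chrom != query.chrom:
            continue
        d = max(0, query.start - g.end, g.start - query.end)
        key = (d, g.start, g.gene_id)
        if best is None or key < best:
            best = key
    if best is None:
        raise ValueError("no gene on chromosome")
    return best[2], best[0]


def welch_oracle(x, y):
    """Textbook Welch statistic, Welch-Satterthwaite df, and two-sided p."""
    from scipy.stats import t as tdist

    x, y = list(map(float, x)), list(map(float, y))
    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, df, p


def bh_oracle(p):
    """Closed-form step-up by definition: q_(i) = min_{j >= i} (n/j) p_(j)."""
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q = [0.0] * n
    for pos, i in enumerate(order):
        rank = pos + 1
        q[i] = min(
            min((n / (later + 1)) * p[order[later]] for later in range(pos, n)),
            1.0,
        )
    return q


def two_partition_oracle(X):
    """Best 2-partition of rows of X minimizing total within-cluster SS."""
    n = len(X)
    best, best_assign = None, None
    for bits in range(1, 2 ** (n - 1)):  # fix row 0 in cluster 0
        assign = [(bits >> i) & 1 for i in range(n)]
        ss = 0.0
        for c in (0, 1):
            rows = X[[i for i in range(n) if assign[i] == c]]
            if len(rows) == 0:
                ss = math.inf
                break
            ss += ((rows - rows.mean(axis=0)) ** 2).sum()
        if best is None or ss < best:
            best, best_assign = ss, assign
    return best_assign
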