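"""Chromatin-state classification of binding sites from histone-mark signals.

Six states are distinguished from four core marks, evaluated as ordered
rules on per-site mean normalized signal:

1. H3K27me3 high and H3K4me3 high      -> bivalent
2. H3K27me3 high                       -> polycomb_only
3. H3K4me3 high and H3K27ac high       -> active_promoter
4. H3K4me1 high and H3K27ac high       -> active_enhancer
5. H3K4me1 high, H3K27ac not high      -> primed_enhancer
6. otherwise                           -> no_signal

Hierarchical clustering of the same signal matrix is provided for
exploration and heat-map row ordering; the state labels themselves come
from the deterministic rules, which keeps the classification reproducible.
State-change summaries (per-state mean log2 fold change per mark) and a
reversibility score (fraction of sites whose label returns to the control
label after the perturbation is removed) quantify perturbation effects.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .intervals import GenomicInterval, as_interval
from .signal import SignalTrack, log2_change, mean_signal_many

STATES = (
    "active_promoter",
    "active_enhancer",
    "primed_enhancer",
    "bivalent",
    "polycomb_only",
    "no_signal",
)
REQUIRED_MARKS = ("H3K4me1", "H3K4me3", "H3K27ac", "H3K27me3")


class StateError(ValueError):
    pass


@dataclass
class StateProfile:
    """Site x mark mean-signal matrix, optionally with per-site state labels."""

    sites: list
    marks: list[str]
    signal: np.ndarray  # shape (n_sites, n_marks), >= 0
    labels: list[str] | None = None
    condition: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.shape != (len(self.sites), len(self.marks)):
            raise StateError("signal matrix shape must be (n_sites, n_marks)")
        if np.any(self.signal < 0):
            raise StateError("signal values must be >= 0")
        if self.labels is not None and len(self.labels) != len(self.sites):
            raise StateError("labels must match sites one-to-one")

    def mark_column(self, mark: str) -> np.ndarray:
        try:
            return self.signal[:, self.marks.index(mark)]
        except ValueError as exc:
            raise StateError(f"mark {mark!r} not in profile") from exc

    def to_frame(self) -> pd.DataFrame:
        ids = [
            f"{as_interval(s).chrom}:{as_interval(s).start}-{as_interval(s).end}"
            for s in self.sites
        ]
        df = pd.DataFrame(self.signal, index=ids, columns=self.marks)
        if self.labels is not None:
            df["state"] = self.labels
        return df


def build_state_matrix(
    sites: Sequence[GenomicInterval],
    tracks: Mapping[str, SignalTrack],
    condition: str = "",
    required: Sequence[str] = REQUIRED_MARKS,
) -> StateProfile:
    """Mean normalized signal of each mark over each site (unlabeled profile)."""
    missing = [m for m in required if m not in tracks]
    if missing:
        raise StateError(f"missing required marks: {', '.join(missing)}")
    for mark, track in tracks.items():
        if not track.normalized:
            raise StateError(f"track for {mark} is not normalized")
    marks = list(tracks)
    cols = [mean_signal_many(tracks[m], list(sites)) for m in marks]
    return StateProfile(
        sites=list(sites),
        marks=marks,
        signal=np.column_stack(cols) if cols else np.zeros((len(sites), 0)),
        condition=condition,
    )


def hcluster_sites(profile: StateProfile, k: int) -> np.ndarray:
    """Ward/Euclidean agglomerative clustering into k groups.

    Signals are log2(1 + x) transformed and per-mark standardized (zero-
    variance marks left centered) before clustering.  Returns integer
    cluster ids 1..k; deterministic for a fixed site order.
    """
    n = len(profile.sites)
    if k < 1:
        raise StateError("k must be >= 1")
    if k > n:
        raise StateError(f"k={k} exceeds number of sites {n}")
    if k == 1:
        return np.ones(n, dtype=int)
    if k == n:
        return np.arange(1, n + 1)
    x = np.log2(1.0 + profile.signal)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    tree = linkage(z, method="ward", metric="euclidean")
    return fcluster(tree, t=k, criterion="maxclust")


def assign_states(
    profile: StateProfile, thresholds: Mapping[str, float] | float = 1.0
) -> StateProfile:
    """Label each site with one of the six chromatin states (total function).

    ``thresholds`` gives the per-mark "high" cutoff in normalized units;
    a scalar applies the same cutoff to every required mark.
    """
    if not isinstance(thresholds, Mapping):
        thresholds = {m: float(thresholds) for m in REQUIRED_MARKS}
    missing = [m for m in REQUIRED_MARKS if m not in thresholds]
    if missing:
        raise StateError(f"missing thresholds for marks: {', '.join(missing)}")
    high = {m: profile.mark_column(m) > thresholds[m] for m in REQUIRED_MARKS}
    labels = []
    for i in range(len(profile.sites)):
        if high["H3K27me3"][i] and high["H3K4me3"][i]:
            labels.append("bivalent")
        elif high["H3K27me3"][i]:
            labels.append("polycomb_only")
        elif high["H3K4me3"][i] and high["H3K27ac"][i]:
            labels.append("active_promoter")
        elif high["H3K4me1"][i] and high["H3K27ac"][i]:
            labels.append("active_enhancer")
        elif high["H3K4me1"][i]:
            labels.append("primed_enhancer")
        else:
            labels.append("no_signal")
    return replace(profile, labels=labels)


def state_composition(profile: StateProfile) -> pd.DataFrame:
    """Counts and fractions of sites per state."""
    if profile.labels is None:
        raise StateError("profile is unlabeled")
    counts = pd.Series(profile.labels).value_counts().reindex(STATES, fill_value=0)
    return pd.DataFrame({"count": counts, "fraction": counts / counts.sum()})


def _check_aligned(a: StateProfile, b: StateProfile) -> None:
    if a.sites != b.sites:
        raise StateError("profiles cover different sites")
    if a.marks != b.marks:
        raise StateError("profiles carry different marks")


def state_change_summary(
    before: StateProfile, after: StateProfile, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Per before-state group, mean log2 fold change of each mark (after vs before)."""
    _check_aligned(before, after)
    if before.labels is None:
        raise StateError("before profile must be labeled")
    lfc = np.log2(
        (after.signal + pseudocount) / (before.signal + pseudocount)
    )
    rows = {}
    lab = np.array(before.labels)
    for state in STATES:
        mask = lab == state
        if mask.any():
            rows[state] = lfc[mask].mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=before.marks)


@dataclass
class ReversibilityReport:
    score: float
    per_state: pd.DataFrame  # per control state: n, fraction reverted


def reversibility_score(
    control: StateProfile, perturbed_removed: StateProfile
) -> ReversibilityReport:
    """Fraction of sites whose label returns to the control label."""
    _check_aligned(control, perturbed_removed)
    if control.labels is None or perturbed_removed.labels is None:
        raise StateError("both profiles must be labeled")
    ctrl = np.array(control.labels)
    rev = np.array(perturbed_removed.labels)
    match = ctrl == rev
    rows = {}
    for state in STATES:
        mask = ctrl == state
        if mask.any():
            rows[state] = dict(n=int(mask.sum()), reverted=float(match[mask].mean()))
    return ReversibilityReport(
        score=float(match.mean()),
        per_state=pd.DataFrame.from_dict(rows, orient="index"),
    )


def label_agreement(a: StateProfile, b: StateProfile) -> float:
    """Fraction of sites with identical labels in two profiles over the same sites."""
    _check_aligned(a, b)
    if a.labels is None or b.labels is None:
        raise StateError("both profiles must be labeled")
    return float(np.mean(np.array(a.labels) == np.array(b.labels)))
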