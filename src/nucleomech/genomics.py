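"""Genomic-interval post-processing for chromatin occupancy profiling.

Implements the downstream stages applied to antibody-directed chromatin
profiling peak sets (CUT&RUN / CUT&Tag): noise filters (reproducibility,
size, signal), sub-kilobase merging, blacklist exclusion, promoter vs
enhancer classification against TSS windows, reference-condition scaling
with log2 transform, and Ward clustering of the condition matrix.

All coordinates are 0-based half-open (BED dialect).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pyranges as pr
from scipy.cluster import hierarchy

__all__ = [
    "PeakTable",
    "ConditionMatrix",
    "ClusterResult",
    "merge_within",
    "exclude_blacklist",
    "reproducibility_filter",
    "size_signal_filter",
    "classify_tss",
    "scale_and_log",
    "ward_cluster",
]


def _check_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    for col in ("chrom", "start", "end"):
        if col not in intervals.columns:
            raise ValueError(f"interval table missing column {col!r}")
    bad = (intervals["start"] < 0) | (intervals["start"] >= intervals["end"])
    if bad.any():
        idx = intervals.index[bad][0]
        raise ValueError(f"malformed interval at record {idx}")
    return intervals


@dataclass
class PeakTable:
    """Peak intervals with per-sample signal and call status.

    ``intervals``: DataFrame (chrom, start, end, name); ``signal``:
    DataFrame indexed by peak name, one column per sample; ``sample_meta``:
    DataFrame indexed by sample with columns (condition, replicate);
    ``called_in``: boolean DataFrame, same shape as ``signal``.
    """

    intervals: pd.DataFrame
    signal: pd.DataFrame
    sample_meta: pd.DataFrame
    called_in: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_intervals(self.intervals)
        if "name" not in self.intervals.columns:
            raise ValueError("intervals need a 'name' column")
        names = self.intervals["name"]
        if not names.is_unique:
            raise ValueError("peak names must be unique")
        if not set(names) <= set(self.signal.index):
            raise ValueError("signal matrix missing peaks")
        if (self.signal.to_numpy() < 0).any():
            raise ValueError("signal must be non-negative")
        if not set(self.signal.columns) <= set(self.sample_meta.index):
            raise ValueError("sample metadata missing samples")
        if self.called_in is not None:
            if self.called_in.shape != self.signal.shape:
                raise ValueError("called_in must match signal shape")

    @property
    def conditions(self) -> list[str]:
        return list(pd.unique(self.sample_meta["condition"]))

    def subset(self, names: pd.Index | list[str]) -> "PeakTable":
        keep = self.intervals["name"].isin(set(names))
        iv = self.intervals[keep].reset_index(drop=True)
        order = iv["name"]
        return PeakTable(
            iv,
            self.signal.loc[order],
            self.sample_meta,
            None if self.called_in is None else self.called_in.loc[order],
        )

    def condition_means(self) -> pd.DataFrame:
        """Arithmetic mean signal over replicates, per condition."""
        groups = self.sample_meta.groupby("condition").groups
        return pd.DataFrame({
            cond: self.signal[list(samples)].mean(axis=1)
            for cond, samples in groups.items()
        })


@dataclass
class ConditionMatrix:
    """log2(condition mean / reference mean) per interval × condition."""

    values: pd.DataFrame
    reference: str
    n_dropped: int = 0


@dataclass
class ClusterResult:
    assignment: np.ndarray  # labels 1..k per interval
    linkage: np.ndarray
    cutoff: float
    index: pd.Index


def merge_within(table: PeakTable, gap: int = 1000) -> PeakTable:
    """Transitively merge peaks separated by less than ``gap`` bp.

    Merging is per chromosome on sorted intervals; two peaks merge when
    (start of next − end of previous) < gap, strictly — a gap of exactly
    ``gap`` bp stays unmerged.  Signal of a merged peak is the
    length-weighted mean of its constituents (a proxy for re-counting
    reads, which requires the alignments).
    """
    iv = _check_intervals(self_iv := table.intervals).sort_values(
        ["chrom", "start", "end"]).reset_index(drop=True)
    merged_rows = []
    signal_rows = []
    called_rows = []
    sig = table.signal
    called = table.called_in
    for chrom, grp in iv.groupby("chrom", sort=True):
        start = end = None
        members: list[str] = []

        def flush() -> None:
            if not members:
                return
            name = members[0] if len(members) == 1 else f"{chrom}:{start}-{end}"
            merged_rows.append((chrom, start, end, name))
            lengths = iv.set_index("name").loc[members]
            w = (lengths["end"] - lengths["start"]).to_numpy(float)
            w = w / w.sum()
            signal_rows.append(pd.Series(
                (sig.loc[members].to_numpy(float) * w[:, None]).sum(axis=0),
                index=sig.columns, name=name))
            if called is not None:
                called_rows.append(pd.Series(
                    called.loc[members].any(axis=0), name=name))

        for row in grp.itertuples(index=False):
            if start is None:
                start, end, members = row.start, row.end, [row.name]
            elif row.start - end < gap:
                end = max(end, row.end)
                members.append(row.name)
            else:
                flush()
                start, end, members = row.start, row.end, [row.name]
        flush()
    out_iv = pd.DataFrame(merged_rows, columns=["chrom", "start", "end", "name"])
    out_sig = pd.DataFrame(signal_rows)
    out_called = pd.DataFrame(called_rows) if called is not None else None
    return PeakTable(out_iv, out_sig, table.sample_meta, out_called)


def _to_ranges(intervals: pd.DataFrame) -> pr.PyRanges:
    return pr.PyRanges(chromosomes=intervals["chrom"],
                       starts=intervals["start"], ends=intervals["end"])


def exclude_blacklist(table: PeakTable, blacklist: pd.DataFrame) -> PeakTable:
    """Drop peaks overlapping any blacklist interval by ≥ 1 bp."""
    if blacklist is None or blacklist.empty:
        return table
    _check_intervals(blacklist)
    peaks = table.intervals
    bl = _to_ranges(blacklist)
    df = peaks.rename(columns={"chrom": "Chromosome", "start": "Start",
                               "end": "End", "name": "Name"})
    kept = pr.PyRanges(df).overlap(bl, invert=True)
    names = [] if kept.empty else list(kept.df["Name"])
    return table.subset(names)


def reproducibility_filter(table: PeakTable, min_samples: int = 2,
                           scope: str = "same_condition") -> PeakTable:
    """Keep peaks called in at least ``min_samples`` samples.

    ``scope="same_condition"`` requires the count within a single
    condition (the strict reading of "called in more than one sample of
    the same condition"); ``scope="any"`` counts across all samples.
    """
    if table.called_in is None:
        raise ValueError("called_in matrix not populated")
    if min_samples > table.called_in.shape[1]:
        raise ValueError("min_samples exceeds sample count")
    called = table.called_in
    if scope == "any":
        ok = called.sum(axis=1) >= min_samples
    elif scope == "same_condition":
        groups = table.sample_meta.groupby("condition").groups
        per_cond = pd.DataFrame({
            cond: called[list(samples)].sum(axis=1)
            for cond, samples in groups.items()
        })
        ok = (per_cond >= min_samples).any(axis=1)
    else:
        raise ValueError(f"unknown scope: {scope!r}")
    names = ok.index[ok]
    return table.subset(list(names))


def size_signal_filter(table: PeakTable, min_size: int = 1000,
                       min_mean_signal: float = 0.075) -> PeakTable:
    """Keep peaks wider than ``min_size`` bp AND whose mean signal over
    replicates exceeds ``min_mean_signal`` in at least one condition.
    Both comparisons are strict."""
    iv = table.intervals.set_index("name")
    width_ok = (iv["end"] - iv["start"]) > min_size
    cond_means = table.condition_means()
    signal_ok = (cond_means > min_mean_signal).any(axis=1)
    keep = width_ok & signal_ok.reindex(width_ok.index)
    return table.subset(list(keep.index[keep]))


def classify_tss(intervals: pd.DataFrame, tss: pd.DataFrame,
                 window: int = 1000) -> pd.DataFrame:
    """Label peaks promoter/enhancer against TSS ± window regions.

    A peak overlapping [tss − window, tss + window) (clipped at 0) of any
    TSS is a promoter; all others are putative enhancers annotated with
    their nearest gene by minimal interval-to-TSS distance (ties broken
    by lexicographically smallest gene id).  ``tss`` needs columns
    (chrom, position, gene).
    """
    if tss.empty:
        raise ValueError("empty TSS list")
    _check_intervals(intervals)
    windows = pd.DataFrame({
        "chrom": tss["chrom"],
        "start": (tss["position"] - window).clip(lower=0),
        "end": tss["position"] + window,
    })
    win = _to_ranges(windows)
    df = intervals.rename(columns={"chrom": "Chromosome", "start": "Start",
                                   "end": "End", "name": "Name"})
    hits = pr.PyRanges(df).overlap(win)
    promoter_names = set() if hits.empty else set(hits.df["Name"])
    labels = []
    genes = []
    tss_by_chrom = {c: g for c, g in tss.groupby("chrom")}
    for row in intervals.itertuples(index=False):
        if row.name in promoter_names:
            labels.append("promoter")
            genes.append("")
            continue
        labels.append("enhancer")
        cand = tss_by_chrom.get(row.chrom)
        if cand is None:
            genes.append("")
            continue
        pos = cand["position"].to_numpy()
        dist = np.where(pos < row.start, row.start - pos,
                        np.where(pos >= row.end, pos - row.end + 1, 0))
        best = dist.min()
        tied = sorted(cand["gene"].to_numpy()[dist == best])
        genes.append(tied[0])
    return pd.DataFrame({
        "name": intervals["name"].to_numpy(),
        "class": labels,
        "nearest_gene": genes,
    })


def scale_and_log(table: PeakTable, reference: str,
                  pseudocount: float = 0.0) -> ConditionMatrix:
    """Scale condition means to the reference condition and log2-transform.

    value(i, c) = log2(mean(i, c) / mean(i, reference)); the reference
    column is identically zero.  Intervals with zero reference signal are
    dropped (counted in ``n_dropped``) unless a ``pseudocount`` is given,
    in which case it is added to every mean.
    """
    means = table.condition_means()
    if reference not in means.columns:
        raise ValueError(f"reference condition {reference!r} not present")
    means = means + pseudocount
    ref = means[reference]
    keep = ref > 0
    n_dropped = int((~keep).sum())
    if pseudocount == 0 and n_dropped == means.shape[0]:
        raise ValueError("all intervals have zero reference signal")
    means = means[keep]
    with np.errstate(divide="ignore"):
        values = np.log2(means.div(means[reference], axis=0))
    return ConditionMatrix(values=values, reference=reference,
                           n_dropped=n_dropped)


def ward_cluster(matrix: ConditionMatrix, cutoff: float = 7.0) -> ClusterResult:
    """Ward-linkage hierarchical clustering of the condition matrix.

    Agglomeration uses Euclidean distance over condition columns; the
    flat assignment cuts the merge tree at ``cutoff`` (every within-
    cluster merge height ≤ cutoff).  Labels are contiguous from 1.
    """
    vals = matrix.values.to_numpy(float)
    if vals.shape[0] < 2:
        raise ValueError("need at least 2 intervals to cluster")
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite values in condition matrix")
    linkage = hierarchy.linkage(vals, method="ward", metric="euclidean")
    labels = hierarchy.fcluster(linkage, t=cutoff, criterion="distance")
    return ClusterResult(assignment=labels, linkage=linkage, cutoff=cutoff,
                         index=matrix.values.index)
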