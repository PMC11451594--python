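"""Synthetic peak tables with planted filter violations and cluster structure.

Generates non-overlapping intervals on a toy genome with per-replicate
signal drawn lognormally around condition means, plus controlled
fractions of peaks that violate each downstream noise filter (too short,
too weak, non-reproducible).  Ground truth records every planted flag
and the differential-occupancy cluster of each clean peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..config import SimConfig
from ..genomics import PeakTable

__all__ = ["OccupancyTruth", "gen_peak_table"]


@dataclass
class OccupancyTruth:
    """Planted structure of a generated peak table.

    ``condition_means``: (n_clusters, n_conditions) array of mean signal
    per cluster and condition; ``replicate_cv``: lognormal coefficient of
    variation across replicates.  After generation, ``flags`` holds a
    per-peak DataFrame (cluster, fails_size, fails_signal, fails_repro).
    """

    condition_means: np.ndarray
    replicate_cv: float = 0.1
    flags: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.condition_means = np.atleast_2d(np.asarray(self.condition_means,
                                                        dtype=float))
        if (self.condition_means < 0).any():
            raise ValueError("condition means must be non-negative")
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be non-negative")


def gen_peak_table(
    config: SimConfig,
    n_peaks: int,
    conditions: list[str],
    n_replicates: int,
    truth: OccupancyTruth,
    genome_length: int = 10_000_000,
    mean_width: int = 1500,
    min_gap: int = 500,
    frac_short: float = 0.0,
    frac_weak: float = 0.0,
    frac_nonreproducible: float = 0.0,
    weak_signal: float = 0.03,
) -> PeakTable:
    """Generate a peak table on a single toy chromosome.

    Clean peaks are wider than 1 kb and assigned round-robin to the truth
    clusters; planted violators are narrower than 1 kb (``frac_short``),
    below the signal floor in every condition (``frac_weak``), or called
    in only one replicate (``frac_nonreproducible``).  Replicate signal is
    lognormal around the condition mean with CV ``replicate_cv``.
    """
    if truth.condition_means.shape[1] != len(conditions):
        raise ValueError("condition_means width must match conditions")
    rng = config.rng("peaks")
    n_clusters = truth.condition_means.shape[0]

    n_short = int(round(frac_short * n_peaks))
    n_weak = int(round(frac_weak * n_peaks))
    n_nonrep = int(round(frac_nonreproducible * n_peaks))
    if n_short + n_weak + n_nonrep > n_peaks:
        raise ValueError("violation fractions exceed 1")

    kind = np.array(
        ["short"] * n_short + ["weak"] * n_weak + ["nonrep"] * n_nonrep
        + ["clean"] * (n_peaks - n_short - n_weak - n_nonrep)
    )
    rng.shuffle(kind)

    widths = np.where(
        kind == "short",
        rng.integers(300, 1000, n_peaks),
        (1001 + rng.exponential(mean_width - 1001, n_peaks)).astype(int),
    )
    spare = genome_length - int(widths.sum()) - n_peaks * min_gap
    if spare < 0:
        raise ValueError("peaks do not fit on the genome")
    gaps = min_gap + (rng.random(n_peaks) * spare / n_peaks).astype(int)
    starts = np.cumsum(gaps) + np.concatenate([[0], np.cumsum(widths)[:-1]])
    ends = starts + widths
    assert ends[-1] <= genome_length

    names = [f"peak_{i:05d}" for i in range(n_peaks)]
    intervals = pd.DataFrame({
        "chrom": "chr1", "start": starts, "end": ends, "name": names,
    })

    samples = [f"{c}_r{r+1}" for c in conditions for r in range(n_replicates)]
    sample_meta = pd.DataFrame(
        {
            "condition": [c for c in conditions for _ in range(n_replicates)],
            "replicate": [r + 1 for _ in conditions for r in range(n_replicates)],
        },
        index=pd.Index(samples, name="sample"),
    )

    cluster = rng.integers(0, n_clusters, n_peaks)
    base = truth.condition_means[cluster]  # (n_peaks, n_cond)
    base = np.where((kind == "weak")[:, None], weak_signal, base)

    cv = truth.replicate_cv
    if cv > 0:
        sigma = np.sqrt(np.log(1.0 + cv * cv))
        mu = -0.5 * sigma * sigma  # unit-mean lognormal
        noise = rng.lognormal(mu, sigma, (n_peaks, len(conditions), n_replicates))
    else:
        noise = np.ones((n_peaks, len(conditions), n_replicates))
    signal = base[:, :, None] * noise
    signal_df = pd.DataFrame(
        signal.reshape(n_peaks, -1), index=pd.Index(names, name="name"),
        columns=samples,
    )

    called = np.ones((n_peaks, len(conditions), n_replicates), dtype=bool)
    nonrep = kind == "nonrep"
    if nonrep.any() and n_replicates > 1:
        called[nonrep] = False
        which_cond = rng.integers(0, len(conditions), int(nonrep.sum()))
        which_rep = rng.integers(0, n_replicates, int(nonrep.sum()))
        called[np.nonzero(nonrep)[0], which_cond, which_rep] = True
    called_df = pd.DataFrame(
        called.reshape(n_peaks, -1), index=pd.Index(names, name="name"),
        columns=samples,
    )

    truth.flags = pd.DataFrame({
        "cluster": cluster,
        "fails_size": kind == "short",
        "fails_signal": kind == "weak",
        "fails_repro": kind == "nonrep",
    }, index=pd.Index(names, name="name"))

    return PeakTable(intervals, signal_df, sample_meta, called_df)
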