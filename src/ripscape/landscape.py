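"""Windowed GC/AT landscape scanning and genome-level composition summaries.

Local base composition is measured as the G+C fraction of non-overlapping
windows (default 500 bp) tiled from position 0 of each sequence; trailing
partial windows are dropped.  The AT fraction of a window is the complement
of its GC fraction once Ns are excluded, so a single track serves both
views.  Genome summaries report mean +/- SD of window GC (the presentation
used for cross-species architecture comparisons) alongside the raw base
fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union
from pathlib import Path

import numpy as np

from .seqio import SequenceRecord

__all__ = [
    "GCProfile",
    "ATHistogram",
    "GenomeSummary",
    "gc_windows",
    "at_histogram",
    "genome_summary",
    "write_bedgraph",
]

_GC = (ord("G"), ord("C"))
_N = ord("N")


@dataclass
class GCProfile:
    """Per-window GC fraction track for one sequence.

    ``values[i]`` is the GC fraction of window ``[i*window, (i+1)*window)``
    computed over non-N bases; all-N windows are NaN (undefined).
    """

    seq_id: str
    window: int
    values: np.ndarray
    trailing_bp_dropped: int = 0

    @property
    def n_windows(self) -> int:
        return len(self.values)

    def at_values(self) -> np.ndarray:
        """AT fraction per window (NaN preserved)."""
        return 1.0 - self.values

    def window_interval(self, i: int) -> tuple[int, int]:
        return i * self.window, (i + 1) * self.window


@dataclass
class ATHistogram:
    """Counts of windows binned by AT percentage."""

    bin_width: float
    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class GenomeSummary:
    """Genome-level composition and block statistics."""

    genome_size: int
    n_sequences: int
    gc_mean: float  # mean of window GC, percent
    gc_sd: float
    at_mean: float
    gc_base_fraction: float  # whole-genome GC over non-N bases, percent
    long_block_count: int
    group: str = "unassigned"


def gc_windows(seq: SequenceRecord, window: int = 500) -> GCProfile:
    """GC fraction in non-overlapping windows anchored at position 0.

    The GC fraction of each window is (#G + #C) / (window - #N); a window
    consisting entirely of Ns is flagged undefined (NaN).  The trailing
    partial window is dropped and its size reported.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if seq.length < window:
        raise ValueError(
            f"sequence {seq.id!r} ({seq.length} bp) shorter than one "
            f"window ({window} bp)"
        )
    codes = np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8)
    n_win = seq.length // window
    tiled = codes[: n_win * window].reshape(n_win, window)
    gc_count = ((tiled == _GC[0]) | (tiled == _GC[1])).sum(axis=1)
    n_count = (tiled == _N).sum(axis=1)
    denom = (window - n_count).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(denom > 0, gc_count / denom, np.nan)
    return GCProfile(
        seq_id=seq.id,
        window=window,
        values=values,
        trailing_bp_dropped=seq.length - n_win * window,
    )


def at_histogram(profiles: Sequence[GCProfile],
                 bin_width: float = 5.0) -> ATHistogram:
    """Bin per-window AT percentages into fixed-width bins over [0, 100].

    Bins are [0, w), [w, 2w), ..., [100-w, 100]; undefined (all-N) windows
    are excluded.  Counts sum to the number of defined windows tallied.
    """
    if not profiles:
        raise ValueError("no profiles supplied")
    if 100.0 % bin_width != 0:
        raise ValueError("bin_width must divide 100")
    at = np.concatenate([100.0 * p.at_values() for p in profiles])
    at = at[~np.isnan(at)]
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    counts, _ = np.histogram(at, bins=edges)
    return ATHistogram(bin_width=bin_width, bin_edges=edges, counts=counts)


def genome_summary(genome: Sequence[SequenceRecord], blocks: Sequence,
                   window: int = 500) -> GenomeSummary:
    """Summarize a genome's composition and its long AT-rich block count.

    ``gc_mean``/``gc_sd`` are computed over fixed windows (the unit of the
    architecture comparison); ``gc_base_fraction`` is the plain base
    fraction over non-N positions.  ``blocks`` must have been called on the
    same genome; blocks of length >= 3 kb count as long.
    """
    values = []
    gc_total = 0
    non_n_total = 0
    for seq in genome:
        if seq.length >= window:
            values.append(gc_windows(seq, window).values)
        gc_total += seq.residues.count("G") + seq.residues.count("C")
        non_n_total += seq.length - seq.residues.count("N")
    if not values:
        raise ValueError("no sequence long enough for one window")
    all_values = 100.0 * np.concatenate(values)
    gc_mean = float(np.nanmean(all_values))
    return GenomeSummary(
        genome_size=sum(s.length for s in genome),
        n_sequences=len(genome),
        gc_mean=gc_mean,
        gc_sd=float(np.nanstd(all_values)),
        at_mean=100.0 - gc_mean,
        gc_base_fraction=100.0 * gc_total / non_n_total if non_n_total else 0.0,
        long_block_count=sum(
            1 for b in blocks if b.interval.length >= 3000
        ),
    )


def write_bedgraph(profiles: Sequence[GCProfile],
                   path: Union[str, Path]) -> None:
    """Export profiles as bedGraph (chrom, start, end, GC fraction)."""
    with open(path, "w", encoding="utf-8") as fh:
        for p in profiles:
            for i, v in enumerate(p.values):
                if np.isnan(v):
                    continue
                s, e = p.window_interval(i)
                fh.write(f"{p.seq_id}\t{s}\t{e}\t{v:.4f}\n")
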