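"""AT-rich block calling, classification and chromosome-architecture metrics.

An AT-rich block is a maximal run of consecutive scan windows whose GC
content falls a stated margin below the genome (and optionally the gene)
average.  Blocks are the unit of chromosome architecture here: the longest
non-terminal block of each chromosome is the operational centromere, blocks
touching a chromosome end are subtelomeres, and everything else is
interspersed.  This module also detects terminal telomeric repeat tracts,
counts tandem-repeat units (e.g. an rDNA array), and assigns genomes to
architecture groups by AT content and long-block count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import numpy as np
import pandas as pd

from .landscape import GCProfile
from .seqio import GenomicInterval, SequenceRecord, revcomp

logger = logging.getLogger(__name__)

BLOCK_CLASSES = ("centromere", "subtelomere", "interspersed", "unclassified")

#: Length-bin edges (kb) used for cross-species block-size comparisons.
LENGTH_BIN_EDGES_KB = (0.5, 1, 3, 5, 10, 15, 20, 50, 100, float("inf"))
LENGTH_BIN_LABELS = (
    "0.5<=L<1", "1<=L<3", "3<=L<5", "5<=L<10", "10<=L<15",
    "15<=L<20", "20<=L<50", "50<=L<100", "100<=L",
)

#: Blocks at least this long (bp) count as "long" for genome grouping.
LONG_BLOCK_MIN_BP = 3000


@dataclass
class ATBlock:
    """A maximal AT-rich interval."""

    interval: GenomicInterval
    at_mean: float  # percent AT over the run's windows
    blocklass: str = "unclassified"

    def __post_init__(self) -> None:
        if self.blocklass not in BLOCK_CLASSES:
            raise ValueError(f"unknown block class {self.blocklass!r}")

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class BlockThresholds:
    """Dual-rule GC cutoff for block calling.

    A window qualifies when its GC is at least ``genome_delta`` percentage
    points below the genome-wide mean, and — when a gene-level mean is
    supplied — also at least ``gene_delta`` points below the mean GC of
    predicted genes.
    """

    genome_gc_mean: float
    genome_delta: float = 6.0
    gene_gc_mean: Optional[float] = None
    gene_delta: float = 12.0

    def __post_init__(self) -> None:
        if self.genome_delta <= 0 or self.gene_delta <= 0:
            raise ValueError("deltas must be positive")
        if self.gc_cutoff() < 0:
            raise ValueError("thresholds yield a negative GC cutoff")

    def gc_cutoff(self) -> float:
        """Effective GC cutoff (percent); a window qualifies at GC <= cutoff."""
        cutoff = self.genome_gc_mean - self.genome_delta
        if self.gene_gc_mean is not None:
            cutoff = min(cutoff, self.gene_gc_mean - self.gene_delta)
        return cutoff


@dataclass
class TelomereReport:
    """Tandem telomeric-repeat counts at the two termini of a sequence."""

    seq_id: str
    five_prime_repeats: int
    three_prime_repeats: int


def call_at_blocks(profile: GCProfile, thresholds: BlockThresholds,
                   max_gap_windows: int = 0) -> list[ATBlock]:
    """Call maximal runs of AT-rich windows as blocks.

    Runs of qualifying windows separated by at most ``max_gap_windows``
    sub-threshold windows are merged (default: zero tolerance, one
    sub-threshold window splits a block).  Undefined (all-N) windows never
    qualify.  The block's AT percentage is the mean over the run's defined
    windows.
    """
    if max_gap_windows < 0:
        raise ValueError("max_gap_windows must be >= 0")
    cutoff = thresholds.gc_cutoff()
    gc_pct = 100.0 * profile.values
    qualifies = np.where(np.isnan(gc_pct), False, gc_pct <= cutoff)
    idx = np.nonzero(qualifies)[0]
    if idx.size == 0:
        return []
    # split qualifying window indices into runs allowing small gaps
    breaks = np.nonzero(np.diff(idx) > max_gap_windows + 1)[0] + 1
    blocks: list[ATBlock] = []
    for run in np.split(idx, breaks):
        first, last = int(run[0]), int(run[-1])
        at = 100.0 - gc_pct[first:last + 1]
        blocks.append(
            ATBlock(
                interval=GenomicInterval(
                    profile.seq_id,
                    first * profile.window,
                    (last + 1) * profile.window,
                ),
                at_mean=float(np.nanmean(at)),
            )
        )
    return blocks


def classify_blocks(blocks: Sequence[ATBlock], chrom_lengths: dict,
                    subtelomere_margin: int = 1000) -> list[ATBlock]:
    """Label blocks as subtelomere, centromere or interspersed, in place.

    Any block starting within ``subtelomere_margin`` of a chromosome 5'
    end, or ending within the margin of the 3' end, is a subtelomere.  The
    single longest remaining block per chromosome is the centromere (ties
    broken by leftmost start); all others are interspersed.  A chromosome
    with no non-subtelomeric block gets no centromere (logged).
    """
    by_chrom: dict[str, list[ATBlock]] = {}
    for b in blocks:
        by_chrom.setdefault(b.interval.seq_id, []).append(b)
    for seq_id, chrom_blocks in by_chrom.items():
        length = chrom_lengths[seq_id]
        candidates = []
        for b in chrom_blocks:
            if (b.interval.start < subtelomere_margin
                    or b.interval.end > length - subtelomere_margin):
                b.blocklass = "subtelomere"
            else:
                b.blocklass = "interspersed"
                candidates.append(b)
        if candidates:
            cen = max(candidates,
                      key=lambda b: (b.length, -b.interval.start))
            cen.blocklass = "centromere"
        else:
            logger.warning("no centromere candidate on %s", seq_id)
    return list(blocks)


def bin_block_lengths(blocks: Sequence[ATBlock]) -> pd.Series:
    """Count blocks (L >= 0.5 kb) per standard length bin.

    Returns a Series indexed by bin label; the long-block count is the sum
    of the seven bins at and above 3 kb.
    """
    lengths_kb = np.array([b.length / 1000.0 for b in blocks])
    lengths_kb = lengths_kb[lengths_kb >= LENGTH_BIN_EDGES_KB[0]]
    counts, _ = np.histogram(lengths_kb, bins=LENGTH_BIN_EDGES_KB)
    return pd.Series(counts, index=list(LENGTH_BIN_LABELS), name="n_blocks")


def long_block_count(blocks: Sequence[ATBlock],
                     min_bp: int = LONG_BLOCK_MIN_BP) -> int:
    """Number of blocks with length >= min_bp (inclusive boundary)."""
    return sum(1 for b in blocks if b.length >= min_bp)


@dataclass
class NeighborDistances:
    """Gap distances between consecutive interspersed blocks per arm."""

    per_arm: dict
    distances: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.distances.mean()) if self.distances.size else np.nan

    @property
    def median(self) -> float:
        return float(np.median(self.distances)) if self.distances.size else np.nan


def neighbor_distances(blocks: Sequence[ATBlock],
                       chrom_lengths: dict) -> NeighborDistances:
    """Distances between neighboring interspersed blocks along arms.

    An arm is the region between a chromosome end and the centromere
    (the whole chromosome when no centromere was assigned).  Centromere and
    subtelomere blocks delimit arms but contribute no gaps; a distance is
    the gap from the end of one interspersed block to the start of the
    next, within one arm.
    """
    per_arm: dict = {}
    by_chrom: dict[str, list[ATBlock]] = {}
    for b in blocks:
        by_chrom.setdefault(b.interval.seq_id, []).append(b)
    for seq_id, chrom_blocks in by_chrom.items():
        chrom_blocks.sort(key=lambda b: b.interval.start)
        cen = next((b for b in chrom_blocks if b.blocklass == "centromere"),
                   None)
        if cen is None:
            arms = [(seq_id, "whole", 0, chrom_lengths[seq_id])]
        else:
            arms = [
                (seq_id, "L", 0, cen.interval.start),
                (seq_id, "R", cen.interval.end, chrom_lengths[seq_id]),
            ]
        for seq, arm_name, lo, hi in arms:
            members = [
                b for b in chrom_blocks
                if b.blocklass == "interspersed"
                and b.interval.start >= lo and b.interval.end <= hi
            ]
            gaps = [
                members[i + 1].interval.start - members[i].interval.end
                for i in range(len(members) - 1)
            ]
            per_arm[(seq, arm_name)] = gaps
    all_gaps = np.array(
        [g for gaps in per_arm.values() for g in gaps], dtype=float
    )
    return NeighborDistances(per_arm=per_arm, distances=all_gaps)


def _tandem_run_at(residues: str, unit: str, end: int) -> int:
    """Count uninterrupted tandem copies of ``unit`` ending exactly at ``end``."""
    k, n = len(unit), 0
    while end - (n + 1) * k >= 0 and \
            residues[end - (n + 1) * k: end - n * k] == unit:
        n += 1
    return n


def detect_telomere_repeats(seq: SequenceRecord, unit_3p: str = "TTAGGG",
                            max_offset: int = 50) -> TelomereReport:
    """Count terminal tandem telomeric repeats at both ends of a sequence.

    Counts the maximal uninterrupted tandem run of ``unit_3p`` ending
    within ``max_offset`` bp of the 3' terminus, and of its reverse
    complement beginning within ``max_offset`` bp of the 5' terminus.
    """
    if seq.length < len(unit_3p):
        raise ValueError("sequence shorter than the repeat unit")
    unit_5p = revcomp(unit_3p)
    res = seq.residues
    three = max(
        _tandem_run_at(res, unit_3p, seq.length - off)
        for off in range(0, max_offset + 1)
    )
    rev = res[::-1]
    unit_5p_rev = unit_5p[::-1]
    five = max(
        _tandem_run_at(rev, unit_5p_rev, seq.length - off)
        for off in range(0, max_offset + 1)
    )
    return TelomereReport(seq_id=seq.id, five_prime_repeats=five,
                          three_prime_repeats=three)


def _identity(a: str, b: str) -> float:
    x = np.frombuffer(a.encode(), dtype=np.uint8)
    y = np.frombuffer(b.encode(), dtype=np.uint8)
    return float((x == y).mean())


def count_tandem_units(seq: SequenceRecord, unit: SequenceRecord,
                       min_identity: float = 0.9
                       ) -> tuple[int, GenomicInterval]:
    """Count head-to-tail tandem copies of a repeat unit in a sequence.

    Seeds on the best match of the unit anywhere in the sequence, then
    greedily extends the array in both directions in unit-length steps,
    accepting each step when the ungapped identity (substitutions only)
    is at least ``min_identity``.  Returns the copy number and the interval
    spanned by the array.
    """
    m, n = unit.length, seq.length
    if m > n:
        raise ValueError("unit longer than sequence")
    if m < 100:
        raise ValueError("unit must be >= 100 bp for identity-based matching")
    hit = edlib.align(unit.residues, seq.residues, mode="HW",
                      task="locations")
    start = hit["locations"][0][0]
    start = max(0, min(start, n - m))
    if _identity(seq.residues[start:start + m], unit.residues) < min_identity:
        return 0, GenomicInterval(seq.id, start, start + m)
    lo = start
    while lo - m >= 0 and \
            _identity(seq.residues[lo - m:lo], unit.residues) >= min_identity:
        lo -= m
    hi = start + m
    while hi + m <= n and \
            _identity(seq.residues[hi:hi + m], unit.residues) >= min_identity:
        hi += m
    return (hi - lo) // m, GenomicInterval(seq.id, lo, hi)


def classify_genome_group(summary, at_rich_threshold: float = 58.0,
                          long_block_min: int = 50) -> str:
    """Assign a genome to architecture group I, II or III.

    Group III: overall AT-rich genomes (mean window AT >= threshold).
    Group I: moderate AT content but many long (>= 3 kb) AT-rich blocks.
    Group II: moderate AT content and few or no long blocks.
    Thresholds are the widest margins separating the published reference
    genomes (see ``ripscape.datasets``).
    """
    if summary.at_mean >= at_rich_threshold:
        return "III"
    if summary.long_block_count >= long_block_min:
        return "I"
    return "II"


def blocks_to_bed_records(blocks: Sequence[ATBlock]) -> list[tuple]:
    """BED records (interval, class label, round(at_mean*10)) for blocks."""
    return [
        (b.interval, b.blocklass, int(round(b.at_mean * 10)))
        for b in blocks
    ]
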