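"""Dinucleotide statistics and RIP indices.

Repeat-induced point mutation (RIP) converts C to T in duplicated DNA with
a strong dinucleotide preference, which skews dinucleotide frequencies in
a characteristic way.  Two classical indices quantify this from sequence
alone: TpA/ApT (rises under RIP, because CpA -> TpA transitions create TpA
dinucleotides) and (CpA+TpG)/(ApC+GpT) (falls under RIP, because the
numerator dinucleotides are the preferred substrates).  Both are strand
symmetric: {TpA} and {ApT} are self-complementary and {CpA, TpG} /
{ApC, GpT} are complement-closed, so single-strand counting suffices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .seqio import GenomicInterval, SequenceRecord

DINUCLEOTIDES = tuple(a + b for a in "ACGT" for b in "ACGT")

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


@dataclass
class DinucCounts:
    """Overlapping dinucleotide counts on the given strand."""

    counts: dict[str, int]
    total: int

    def __getitem__(self, dinuc: str) -> int:
        return self.counts[dinuc]


@dataclass
class RipIndices:
    """The index pair; ``None`` marks an undefined (zero-denominator) ratio."""

    tpa_apt: Optional[float]
    composite: Optional[float]

    @property
    def defined(self) -> bool:
        return self.tpa_apt is not None and self.composite is not None


def dinuc_counts(seq: Union[SequenceRecord, str]) -> DinucCounts:
    """Count the 16 overlapping dinucleotides of a sequence.

    Pairs containing an N are skipped and excluded from the total, so
    ``total == length - 1`` holds exactly for N-free input.
    """
    residues = seq if isinstance(seq, str) else seq.residues
    if len(residues) < 2:
        raise ValueError("need at least 2 residues for dinucleotide counts")
    codes = _CODE[np.frombuffer(residues.upper().encode("ascii"),
                                dtype=np.uint8)]
    a, b = codes[:-1], codes[1:]
    ok = (a >= 0) & (b >= 0)
    pair_ids = 4 * a[ok].astype(np.int64) + b[ok]
    tallies = np.bincount(pair_ids, minlength=16)
    counts = {d: int(tallies[i]) for i, d in enumerate(DINUCLEOTIDES)}
    return DinucCounts(counts=counts, total=int(tallies.sum()))


def rip_indices(counts: DinucCounts) -> RipIndices:
    """Compute TpA/ApT and (CpA+TpG)/(ApC+GpT) from dinucleotide counts."""
    apt = counts["AT"]
    tpa = counts["TA"]
    num = counts["CA"] + counts["TG"]
    den = counts["AC"] + counts["GT"]
    return RipIndices(
        tpa_apt=tpa / apt if apt else None,
        composite=num / den if den else None,
    )


def rip_indices_of(seq: Union[SequenceRecord, str]) -> RipIndices:
    """Convenience: indices straight from a sequence."""
    return rip_indices(dinuc_counts(seq))


def scan_rip_regions(seq: SequenceRecord, window: int = 500, step: int = 500,
                     tpa_apt_min: float = 0.89,
                     composite_max: float = 1.03) -> list[GenomicInterval]:
    """Scan a sequence for RIP-affected regions.

    A window is RIP-affected iff both indices are defined, TpA/ApT >=
    ``tpa_apt_min`` and the composite index <= ``composite_max`` (the
    classical cutoffs for RIP'd sequence).  Overlapping or adjacent
    affected windows are merged; the complement of the result is the
    "no RIP" track.
    """
    if window < 100:
        raise ValueError("window must be >= 100")
    if step < 1:
        raise ValueError("step must be >= 1")
    affected: list[list[int]] = []
    for start in range(0, seq.length - window + 1, step):
        idx = rip_indices_of(seq.residues[start:start + window])
        if (idx.defined and idx.tpa_apt >= tpa_apt_min
                and idx.composite <= composite_max):
            if affected and start <= affected[-1][1]:
                affected[-1][1] = max(affected[-1][1], start + window)
            else:
                affected.append([start, start + window])
    return [GenomicInterval(seq.id, s, e) for s, e in affected]
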