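"""RIP mutation calling between a parental sequence and a post-cross allele.

A duplicated marker (e.g. a resistance cassette present in two copies
before a sexual cross) accumulates C-to-T transitions during RIP.  Given
the parental allele and a re-sequenced progeny allele, this module aligns
the pair, calls C->T events (and their strand-mirrored G->A counterparts),
records each event's dinucleotide context — the mutated C plus its 3'
neighbor on the strand carrying the C, read from the parent — and ranks
the per-context mutation rates with explicit ``~`` / ``>`` / ``>>``
relations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from scipy.stats import norm
from statsmodels.stats.proportion import proportions_ztest

from .seqio import SequenceRecord

CONTEXTS = ("CA", "CG", "CT", "CC")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _pretty(context: str) -> str:
    return f"Cp{context[1]}"


@dataclass
class PairAlignment:
    """A global pairwise alignment of parent and progeny alleles."""

    parent_id: str
    progeny_id: str
    aligned_parent: str
    aligned_progeny: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_parent) != len(self.aligned_progeny):
            raise ValueError("aligned strings differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.aligned_parent)

    @property
    def identity(self) -> float:
        matches = sum(
            a == b and a != "-"
            for a, b in zip(self.aligned_parent, self.aligned_progeny)
        )
        return matches / self.n_columns


@dataclass(frozen=True)
class MutationCall:
    """One C->T event (strand ``+``) or its G->A mirror (strand ``-``)."""

    parent_position: int  # 0-based in the ungapped parent
    ref: str
    alt: str
    strand: str
    context: Optional[str]  # CpN context from the parent; None at an edge
    neighbor_mutated: bool = False


@dataclass
class CallResult:
    """RIP calls plus the non-RIP substitutions seen in the same alignment."""

    rip_calls: list[MutationCall]
    non_rip_substitutions: list[tuple[int, str, str]]


@dataclass
class ContextTally:
    """Per-context mutation counts, availabilities, rates and ranking."""

    counts: dict[str, int]
    availability: dict[str, int]
    rates: dict[str, Optional[float]]
    ranking: list[tuple[str, str]]  # [(context, relation-to-next), ...]

    @property
    def ranking_str(self) -> str:
        parts: list[str] = []
        for ctx, rel in self.ranking:
            parts.append(_pretty(ctx))
            if rel:
                parts.append({"eq": "≈", "gt": ">", "ggt": "≫"}[rel])
        return "".join(parts)


def align_pair(parent: SequenceRecord, progeny: SequenceRecord,
               match: float = 1.0, mismatch: float = -2.0,
               gap_open: float = -8.0,
               gap_extend: float = -2.0) -> PairAlignment:
    """Globally align two high-identity alleles.

    Scoring defaults suit Sanger-sequenced alleles of a common parent
    (expected identity well above 50%).  The first optimal traceback is
    taken, which is deterministic and prefers the diagonal.  Alignments
    below 50% identity raise an error.
    """
    if not parent.length or not progeny.length:
        raise ValueError("sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(parent.residues, progeny.residues)[0]
    pair = PairAlignment(
        parent_id=parent.id,
        progeny_id=progeny.id,
        aligned_parent=str(aln[0]),
        aligned_progeny=str(aln[1]),
        score=float(aln.score),
    )
    if pair.identity < 0.5:
        raise ValueError("sequences not homologous")
    return pair


def call_c_to_t(aln: PairAlignment,
                parent: Optional[SequenceRecord] = None) -> CallResult:
    """Call RIP-style transitions from an alignment.

    Parent ``C`` aligned to progeny ``T`` is a call on strand ``+`` with
    context C plus its 3' neighbor in the ungapped parent; parent ``G``
    aligned to progeny ``A`` is the same event on the reverse strand, with
    context C plus the complement of the parent's 5' neighbor.  Columns
    adjacent to gap columns yield no RIP call, and any other substitution
    is reported separately as a non-RIP change.  ``neighbor_mutated``
    flags calls whose context neighbor is itself substituted in the
    progeny.
    """
    ap, aq = aln.aligned_parent, aln.aligned_progeny
    n = aln.n_columns
    parent_residues = ap.replace("-", "")
    if parent is not None and parent.residues != parent_residues:
        raise ValueError("alignment does not match the supplied parent")

    is_gap = [a == "-" or b == "-" for a, b in zip(ap, aq)]
    # progeny base aligned against each ungapped parent position
    progeny_at: dict[int, str] = {}
    ppos = -1
    parent_pos_of_col: list[int] = []
    for i in range(n):
        if ap[i] != "-":
            ppos += 1
            progeny_at[ppos] = aq[i]
        parent_pos_of_col.append(ppos)

    rip: list[MutationCall] = []
    other: list[tuple[int, str, str]] = []
    for i in range(n):
        a, b = ap[i], aq[i]
        if a == "-" or b == "-" or a == b:
            continue
        pos = parent_pos_of_col[i]
        gap_adjacent = (i > 0 and is_gap[i - 1]) or \
                       (i < n - 1 and is_gap[i + 1])
        if (a, b) == ("C", "T") and not gap_adjacent:
            if pos + 1 < len(parent_residues):
                neighbor = parent_residues[pos + 1]
                context = "C" + neighbor
                flagged = progeny_at.get(pos + 1, neighbor) != neighbor
            else:
                context, flagged = None, False
            rip.append(MutationCall(pos, "C", "T", "+",
                                    context if context in CONTEXTS or
                                    context is None else None,
                                    flagged))
        elif (a, b) == ("G", "A") and not gap_adjacent:
            if pos > 0:
                neighbor = parent_residues[pos - 1]
                context = "C" + _COMP[neighbor]
                flagged = progeny_at.get(pos - 1, neighbor) != neighbor
            else:
                context, flagged = None, False
            rip.append(MutationCall(pos, "G", "A", "-",
                                    context if context in CONTEXTS or
                                    context is None else None,
                                    flagged))
        else:
            other.append((pos, a, b))
    return CallResult(rip_calls=rip, non_rip_substitutions=other)


def context_availability(parent: SequenceRecord) -> dict[str, int]:
    """Count parental cytosines per CpN context on both strands.

    Plus strand: every C with a 3' neighbor; minus strand: every G with a
    5' neighbor (its complement read 5'->3' on the minus strand).  Edge
    bases without the needed neighbor, and N neighbors, are skipped.
    """
    res = parent.residues
    avail = {c: 0 for c in CONTEXTS}
    for i, base in enumerate(res):
        if base == "C" and i + 1 < len(res):
            ctx = "C" + res[i + 1]
            if ctx in avail:
                avail[ctx] += 1
        elif base == "G" and i > 0:
            ctx = "C" + _COMP[res[i - 1]]
            if ctx in avail:
                avail[ctx] += 1
    return avail


def _ratio_lower_bound(c1: int, n1: int, c2: int, n2: int,
                       conf: float = 0.95) -> float:
    """Lower confidence limit of the rate ratio (c1/n1)/(c2/n2) (Katz log CI)."""
    if c2 == 0:
        return np.inf if c1 > 0 else 0.0
    if c1 == 0:
        return 0.0
    rr = (c1 / n1) / (c2 / n2)
    se = np.sqrt(1 / c1 - 1 / n1 + 1 / c2 - 1 / n2)
    z = norm.ppf(0.5 + conf / 2)
    return float(rr * np.exp(-z * se))


def context_tally_and_rank(calls: Sequence[MutationCall],
                           parent: SequenceRecord, alpha: float = 0.05,
                           strong_ratio: float = 3.0) -> ContextTally:
    """Tally calls per context, normalize by availability, and rank.

    Contexts are ordered by decreasing rate.  Adjacent contexts are
    related by a two-proportion z-test: ``~`` when not significant at
    ``alpha``; ``>`` when significant; ``>>`` when significant and the
    lower 95% confidence bound of the rate ratio is at least
    ``strong_ratio``.  Contexts with zero availability are excluded from
    the ranking.
    """
    counts = {c: 0 for c in CONTEXTS}
    for call in calls:
        if call.context in counts:
            counts[call.context] += 1
    avail = context_availability(parent)
    rates: dict[str, Optional[float]] = {
        c: (counts[c] / avail[c] if avail[c] else None) for c in CONTEXTS
    }
    ranked = sorted(
        (c for c in CONTEXTS if rates[c] is not None),
        key=lambda c: (-rates[c], CONTEXTS.index(c)),
    )
    ranking: list[tuple[str, str]] = []
    for i, ctx in enumerate(ranked):
        if i == len(ranked) - 1:
            ranking.append((ctx, ""))
            break
        nxt = ranked[i + 1]
        c1, n1 = counts[ctx], avail[ctx]
        c2, n2 = counts[nxt], avail[nxt]
        if c1 == 0 and c2 == 0:
            rel = "eq"
        else:
            _, pvalue = proportions_ztest([c1, c2], [n1, n2])
            if not np.isfinite(pvalue) or pvalue >= alpha:
                rel = "eq"
            elif _ratio_lower_bound(c1, n1, c2, n2) >= strong_ratio:
                rel = "ggt"
            else:
                rel = "gt"
        ranking.append((ctx, rel))
    return ContextTally(counts=counts, availability=avail, rates=rates,
                        ranking=ranking)
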