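"""Readers, writers and domain types for the formats the pipeline touches.

One coordinate convention rules everywhere: 0-based, half-open intervals.
GFF3 and RepeatMasker ``.out`` files (both 1-based, fully closed) are
converted on ingest; BED is emitted natively.  Sequences are uppercased on
ingest and restricted to the alphabet {A, C, G, T, N}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord
import gffutils

logger = logging.getLogger(__name__)

VALID_RESIDUES = frozenset("ACGTN")
GENE_TYPES = ("protein_coding", "rRNA", "tRNA", "other")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(residues: str) -> str:
    """Reverse complement of an {A,C,G,T,N} string."""
    return residues.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named chromosome or contig over the alphabet {A,C,G,T,N}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            pos = next(i for i, c in enumerate(self.residues) if c in bad)
            raise ValueError(
                f"illegal residue {self.residues[pos]!r} at position {pos} "
                f"in sequence {self.id!r}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


def check_interval_on(interval: GenomicInterval, seq_lengths: dict) -> None:
    """Assert the global invariant 0 <= start < end <= sequence length."""
    n = seq_lengths[interval.seq_id]
    if interval.end > n:
        raise ValueError(
            f"interval [{interval.start}, {interval.end}) exceeds length {n} "
            f"of {interval.seq_id}"
        )


@dataclass
class GeneModel:
    """A gene with its location and broad functional type."""

    gene_id: str
    interval: GenomicInterval
    type: str = "protein_coding"
    systematic_name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.type not in GENE_TYPES:
            raise ValueError(f"unknown gene type {self.type!r}")


@dataclass
class RepeatHit:
    """One RepeatMasker alignment line, in internal coordinates."""

    sw_score: int
    pct_div: float
    interval: GenomicInterval
    repeat_family: str
    repeat_class: str

    def __post_init__(self) -> None:
        if self.sw_score < 0:
            raise ValueError("sw_score must be >= 0")
        if not 0.0 <= self.pct_div <= 100.0:
            raise ValueError("pct_div must be within [0, 100]")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: Union[str, Path]) -> list[SequenceRecord]:
    """Read a multi-record FASTA file into validated sequence records.

    Residues are uppercased; any character outside {A,C,G,T,N} raises an
    error naming the offending record and position.  Duplicate ids and
    empty files are rejected.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq)))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: Union[str, Path],
                width: int = 80) -> None:
    bio = [
        _BioRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    with open(path, "w", encoding="utf-8") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# GFF3


def _gene_type_of(db: gffutils.FeatureDB, feature: gffutils.Feature) -> str:
    if feature.featuretype in ("rRNA", "tRNA"):
        return feature.featuretype
    biotype = feature.attributes.get("biotype") or feature.attributes.get(
        "gene_biotype"
    )
    if biotype:
        if biotype[0] in ("rRNA", "tRNA"):
            return biotype[0]
        if biotype[0] not in ("protein_coding",):
            return "other"
        return "protein_coding"
    child_types = {c.featuretype for c in db.children(feature, level=1)}
    for t in ("rRNA", "tRNA"):
        if t in child_types:
            return t
    return "protein_coding"


def read_gff(path: Union[str, Path],
             known_seq_ids: Optional[Iterable[str]] = None) -> list[GeneModel]:
    """Read gene models from a GFF3 file.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    Gene type is resolved from the feature type, a ``biotype`` attribute,
    or child features (rRNA/tRNA).  An unknown seq_id is retained but
    logged.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    known = set(known_seq_ids) if known_seq_ids is not None else None
    genes: list[GeneModel] = []
    claimed: set[str] = set()
    for feature in db.features_of_type("gene"):
        for child in db.children(feature, level=1):
            claimed.add(child.id)
        genes.append(_feature_to_gene(db, feature, known))
    # standalone rRNA/tRNA features that are not children of a gene
    for ftype in ("rRNA", "tRNA"):
        for feature in db.features_of_type(ftype):
            if feature.id in claimed or any(True for _ in db.parents(feature)):
                continue
            genes.append(_feature_to_gene(db, feature, known))
    genes.sort(key=lambda g: (g.interval.seq_id, g.interval.start))
    return genes


def _feature_to_gene(db, feature, known) -> GeneModel:
    if feature.end < feature.start:
        raise ValueError(
            f"feature {feature.id!r}: end {feature.end} < start {feature.start}"
        )
    if known is not None and feature.seqid not in known:
        logger.warning("gene %s on unknown sequence %s", feature.id,
                       feature.seqid)
    name = feature.attributes.get("Name")
    return GeneModel(
        gene_id=feature.id,
        interval=GenomicInterval(
            feature.seqid, feature.start - 1, feature.end,
            feature.strand if feature.strand in ("+", "-") else ".",
        ),
        type=_gene_type_of(db, feature),
        systematic_name=name[0] if name else None,
    )


def write_gff(genes: Sequence[GeneModel], path: Union[str, Path]) -> None:
    """Write gene models as bare GFF3 ``gene`` features."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.interval.seq_id,
                                              g.interval.start)):
            attrs = f"ID={g.gene_id};biotype={g.type}"
            if g.systematic_name:
                attrs += f";Name={g.systematic_name}"
            fh.write(
                "\t".join(
                    [
                        g.interval.seq_id,
                        "ripscape",
                        "gene",
                        str(g.interval.start + 1),
                        str(g.interval.end),
                        ".",
                        g.interval.strand if g.interval.strand != "." else ".",
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED6

BedRecord = tuple  # (GenomicInterval, name, score)


def write_bed(records: Iterable[Union[GenomicInterval, BedRecord]],
              path: Union[str, Path]) -> None:
    """Write labelled/scored intervals as BED6.

    Each record is a ``GenomicInterval`` or a ``(interval, name, score)``
    tuple.  Output is sorted by (seq_id, start); an empty input produces an
    empty file.
    """
    rows = []
    for rec in records:
        if isinstance(rec, GenomicInterval):
            iv, name, score = rec, ".", 0
        else:
            iv, name, score = (tuple(rec) + (".", 0))[:3]
        rows.append((iv.seq_id, iv.start, iv.end, str(name), int(score),
                     iv.strand))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w", encoding="utf-8") as fh:
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")


def read_bed(path: Union[str, Path]) -> list[BedRecord]:
    """Read BED (3-6 columns) back into (interval, name, score) tuples."""
    out: list[BedRecord] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            name = cols[3] if len(cols) > 3 else "."
            score = int(cols[4]) if len(cols) > 4 else 0
            strand = cols[5] if len(cols) > 5 else "."
            out.append(
                (GenomicInterval(cols[0], int(cols[1]), int(cols[2]), strand),
                 name, score)
            )
    return out


# ---------------------------------------------------------------------------
# RepeatMasker .out


def read_repeatmasker_out(path: Union[str, Path]) -> list[RepeatHit]:
    """Parse a RepeatMasker ``.out`` table (3 header lines).

    Query coordinates (1-based inclusive) become 0-based half-open; the
    complement flag ``C`` maps to strand ``-``.
    """
    hits: list[RepeatHit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= 3 or not line.strip():
                continue
            cols = line.split()
            if not 14 <= len(cols) <= 16:
                raise ValueError(
                    f"{path}: line {lineno}: expected 14-16 columns, "
                    f"got {len(cols)}"
                )
            strand = "-" if cols[8] == "C" else "+"
            hits.append(
                RepeatHit(
                    sw_score=int(cols[0]),
                    pct_div=float(cols[1]),
                    interval=GenomicInterval(
                        cols[4], int(cols[5]) - 1, int(cols[6]), strand
                    ),
                    repeat_family=cols[9],
                    repeat_class=cols[10],
                )
            )
    return hits


def filter_repeats(hits: Sequence[RepeatHit], min_length: int = 140,
                   min_score: int = 450) -> list[RepeatHit]:
    """Keep hits with interval length >= min_length AND score >= min_score.

    Both thresholds are inclusive; input order is preserved.
    """
    if min_length < 0 or min_score < 0:
        raise ValueError("thresholds must be non-negative")
    return [
        h for h in hits
        if h.interval.length >= min_length and h.sw_score >= min_score
    ]
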