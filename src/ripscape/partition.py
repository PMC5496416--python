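"""Gene-cluster compartmentation and expression summarization.

Interspersed AT-rich blocks fall between the genes of many annotated gene
clusters, splitting each cluster into smaller compartments — maximal runs
of consecutive genes with no AT-rich block (or telomere) between them.
This module performs that split, computes TPM expression values from raw
read counts, classifies per-gene induction between two conditions, and
summarizes expression coherence per compartment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .atblocks import ATBlock
from .seqio import GeneModel, GenomicInterval

INDUCTION_CLASSES = (
    "highly_induced", "significantly_upregulated", "unchanged", "repressed",
)

#: Fold-change thresholds: >=20x highly induced, 5-20x significantly
#: upregulated, <=1/5x repressed.
HIGH_FOLD = 20.0
SIG_FOLD = 5.0


@dataclass
class Compartment:
    """A maximal run of cluster genes uninterrupted by an AT-rich block."""

    genes: list[GeneModel]
    span: GenomicInterval
    left_boundary: Union[ATBlock, str]  # an ATBlock, "telomere" or "cluster-edge"
    right_boundary: Union[ATBlock, str]
    flagged_genes: list[str] = field(default_factory=list)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


def compartmentalize(cluster: Sequence[GeneModel], blocks: Sequence[ATBlock],
                     chrom_length: Optional[int] = None,
                     telomere_margin: int = 1000) -> list[Compartment]:
    """Split an ordered gene cluster into compartments at AT-rich blocks.

    A block of any class whose interval lies entirely between two
    consecutive cluster genes separates them; a gene overlapping a block
    does not split there — the gene is assigned to the compartment on its
    5' side and flagged.  With no gene/block overlap the number of
    compartments is the number of internal separating blocks plus one.
    Cluster edges are labelled "telomere" when they fall within
    ``telomere_margin`` of a chromosome end (requires ``chrom_length``),
    otherwise by the nearest flanking block or "cluster-edge".
    """
    if not cluster:
        raise ValueError("empty cluster")
    genes = sorted(cluster, key=lambda g: g.interval.start)
    seq_id = genes[0].interval.seq_id
    if any(g.interval.seq_id != seq_id for g in genes):
        raise ValueError("cluster genes must lie on one chromosome")
    chrom_blocks = sorted(
        (b for b in blocks if b.interval.seq_id == seq_id),
        key=lambda b: b.interval.start,
    )

    overlapped = {
        g.gene_id
        for g in genes
        for b in chrom_blocks
        if g.interval.overlaps(b.interval)
    }

    def separators(left: GeneModel, right: GeneModel) -> list[ATBlock]:
        lo, hi = left.interval.end, right.interval.start
        return [
            b for b in chrom_blocks
            if b.interval.start >= lo and b.interval.end <= hi
        ]

    def edge_boundary(position: int, side: str) -> Union[ATBlock, str]:
        if chrom_length is not None:
            if side == "left" and position <= telomere_margin:
                return "telomere"
            if side == "right" and position >= chrom_length - telomere_margin:
                return "telomere"
        if side == "left":
            flanking = [b for b in chrom_blocks if b.interval.end <= position]
            return flanking[-1] if flanking else "cluster-edge"
        flanking = [b for b in chrom_blocks if b.interval.start >= position]
        return flanking[0] if flanking else "cluster-edge"

    compartments: list[Compartment] = []
    current: list[GeneModel] = [genes[0]]
    left_bound = edge_boundary(genes[0].interval.start, "left")
    for prev, gene in zip(genes, genes[1:]):
        between = separators(prev, gene)
        if between:
            compartments.append(
                _make_compartment(current, left_bound, between[0], overlapped)
            )
            left_bound = between[-1]
            current = [gene]
        else:
            current.append(gene)
    compartments.append(
        _make_compartment(
            current, left_bound,
            edge_boundary(genes[-1].interval.end, "right"), overlapped,
        )
    )
    return compartments


def _make_compartment(genes, left, right, overlapped) -> Compartment:
    return Compartment(
        genes=list(genes),
        span=GenomicInterval(
            genes[0].interval.seq_id,
            genes[0].interval.start,
            genes[-1].interval.end,
        ),
        left_boundary=left,
        right_boundary=right,
        flagged_genes=[g.gene_id for g in genes if g.gene_id in overlapped],
    )


def compute_tpm(counts: pd.DataFrame, count_col: str = "count",
                length_col: str = "length", type_col: str = "type",
                exclude: frozenset = frozenset({"rRNA", "tRNA"})
                ) -> pd.DataFrame:
    """Transcripts-per-million from raw read counts.

    RPK = read count / transcript length; TPM = RPK / sum(RPK) * 1e6.
    Genes whose type is in ``exclude`` (ribosomal and transfer RNA by
    default) are removed before normalization, so the TPM of the remaining
    genes sums to one million.
    """
    df = counts.copy()
    if (df[length_col] <= 0).any():
        raise ValueError("transcript lengths must be positive")
    if (df[count_col] < 0).any():
        raise ValueError("read counts must be non-negative")
    if type_col in df.columns and exclude:
        df = df[~df[type_col].isin(exclude)].copy()
    if df.empty or df[count_col].sum() == 0:
        raise ValueError("no expressed genes")
    df["rpk"] = df[count_col] / df[length_col]
    df["tpm"] = df["rpk"] / df["rpk"].sum() * 1e6
    return df


def classify_induction(tpm_a: pd.Series, tpm_b: pd.Series,
                       pseudo: float = 0.1) -> pd.DataFrame:
    """Classify per-gene induction between two conditions by fold change.

    fold = (TPM_b + pseudo) / (TPM_a + pseudo); the pseudo-count keeps
    zero-expression genes finite and "unchanged".  Classes: >=20x highly
    induced, 5-20x significantly upregulated, <=1/5x repressed, otherwise
    unchanged.
    """
    a, b = tpm_a.align(tpm_b, join="inner")
    fold = (b + pseudo) / (a + pseudo)
    cls = pd.Series("unchanged", index=fold.index, dtype=object)
    cls[fold >= HIGH_FOLD] = "highly_induced"
    cls[(fold >= SIG_FOLD) & (fold < HIGH_FOLD)] = "significantly_upregulated"
    cls[fold <= 1.0 / SIG_FOLD] = "repressed"
    return pd.DataFrame({"fold_change": fold, "induction_class": cls})


@dataclass
class CompartmentExpression:
    """Induction classes of one compartment's genes and their coherence."""

    gene_ids: list[str]
    classes: list[str]
    concordant: bool


def compartment_expression(compartments: Sequence[Compartment],
                           classes: Mapping[str, str]
                           ) -> list[CompartmentExpression]:
    """Summarize induction classes per compartment.

    A compartment is concordant when all member genes share one induction
    class.  Coherence is reported, not asserted: intergenic AT-rich blocks
    do not always produce differential expression.
    """
    out = []
    for comp in compartments:
        cls = [classes[g] for g in comp.gene_ids]
        out.append(
            CompartmentExpression(
                gene_ids=comp.gene_ids,
                classes=cls,
                concordant=len(set(cls)) <= 1,
            )
        )
    return out
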