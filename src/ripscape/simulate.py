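"""Synthetic genomes with planted AT-rich-block architecture and RIP truth.

The generator emulates the statistical structure the analysis assumes:
chromosomes of gene-like GC-rich segments (~56.5% GC) and intergenic
background (~51% GC), terminal telomeric repeat tracts, one
centromere-scale tandem repeat array per chromosome, interspersed
duplicated elements spaced ~13 kb apart along arms, an rDNA-like tandem
array on one chromosome, and per-gene read counts for expression tests.
AT-rich blocks are not planted directly: duplicated regions are driven
AT-rich by a forward, context-biased C->T mutation process (RIP), so the
causal chain the pipeline is meant to recover (duplication -> RIP ->
AT-rich block) is present in the data.  Every planted feature is recorded
in a machine-readable truth table.

Background sequence is drawn from a first-order Markov chain with mild
dinucleotide bias (TpA depletion, CpA/TpG enrichment) so that un-mutated
DNA scores like real euchromatin on the RIP indices rather than like an
i.i.d. coin flip; see the methods note for the factors used.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .seqio import (GeneModel, GenomicInterval, SequenceRecord, revcomp,
                    write_fasta, write_gff)

BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(BASES)}
_C, _G, _T, _A = (np.uint8(ord(b)) for b in "CGTA")
_COMP_CODE = np.zeros(256, dtype=np.uint8)
for _x, _y in zip(b"ACGT", b"TGCA"):
    _COMP_CODE[_x] = _y

#: Dinucleotide bias factors (previous base, next base) -> multiplier.
#: TpA is depleted and CpA/TpG enriched, mimicking real fungal euchromatin
#: (and keeping the statistics strand symmetric: the CpA/ApC factors equal
#: their complements TpG/GpT).
DINUC_BIAS = {
    ("T", "A"): 0.5,
    ("C", "A"): 1.3,
    ("T", "G"): 1.3,
    ("A", "C"): 0.85,
    ("G", "T"): 0.85,
}


@dataclass
class RipConfig:
    """Forward RIP process: per-cycle, per-context C->T probabilities."""

    cycles: int = 20
    rates: dict = field(
        default_factory=lambda: {"CA": 0.10, "CG": 0.10, "CT": 0.02,
                                 "CC": 0.005}
    )

    def __post_init__(self) -> None:
        for ctx, p in self.rates.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"rate for {ctx} outside [0, 1]")
        if self.cycles < 0:
            raise ValueError("cycles must be >= 0")


@dataclass
class ExpressionConfig:
    """Poisson read-count model for two conditions.

    Effect fractions are kept small so that TPM renormalization (which
    divides by the library-wide RPK sum, inflated by induced genes) leaves
    a 40x count multiplier safely above the 20-fold induction threshold
    and a 10x multiplier inside the 5-20-fold band.
    """

    base_mean: float = 200.0
    conditions: tuple = ("glucose", "straw")
    induced_fraction: float = 0.01
    induced_multiplier: float = 40.0
    mid_fraction: float = 0.02
    mid_multiplier: float = 10.0
    repressed_fraction: float = 0.02
    repressed_multiplier: float = 0.1


@dataclass
class SimConfig:
    """Study conditions for one synthetic genome."""

    seed: int = 0
    chromosome_lengths: tuple = (300_000, 260_000)
    window: int = 500
    gene_gc_target: float = 56.5      # percent, mean GC of genes
    intergenic_gc_target: float = 51.0  # percent, background GC
    gene_length: int = 1500
    intergenic_length: int = 1000
    trna_every: int = 25              # every k-th gene is a tRNA
    telomere_unit: str = "TTAGGG"
    telomere_repeat_count: int = 14
    subtelomere_length: int = 2500
    interspersed_length: int = 2500
    interspersed_gap_range: tuple = (9_000, 17_000)  # mean ~13 kb
    centromere_unit_length: int = 2000
    centromere_copies: int = 10
    rdna_unit_length: int = 1000
    rdna_copies: int = 9
    rip: RipConfig = field(default_factory=RipConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.chromosome_lengths):
            raise ValueError("chromosome lengths must be positive")
        minimum = (
            2 * (6 * self.telomere_repeat_count + self.subtelomere_length)
            + self.centromere_unit_length * self.centromere_copies
            + self.rdna_unit_length * self.rdna_copies
            + 20_000
        )
        if min(self.chromosome_lengths) < minimum:
            raise ValueError(
                f"chromosomes must be >= {minimum} bp to hold all features"
            )


@dataclass
class PlantedDuplication:
    seq_id: str
    start: int
    end: int
    family: str
    kind: str  # centromere | subtelomere | interspersed
    pre_rip: Optional[str] = None
    post_rip: Optional[str] = None


@dataclass
class PlantedMutation:
    seq_id: str
    position: int
    strand: str
    context_parent: str   # CpN context in the pre-RIP sequence
    context_at_event: str  # CpN context when the mutation occurred
    cycle: int


@dataclass
class TruthTable:
    """Ground truth for every planted feature of one simulated genome."""

    blocks: list = field(default_factory=list)      # (seq_id,start,end,kind)
    duplications: list[PlantedDuplication] = field(default_factory=list)
    mutations: list[PlantedMutation] = field(default_factory=list)
    telomeres: dict = field(default_factory=dict)   # seq_id -> repeat count
    rdna: Optional[dict] = None
    expression_multipliers: dict = field(default_factory=dict)

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "blocks": self.blocks,
            "duplications": [asdict(d) for d in self.duplications],
            "mutations": [asdict(m) for m in self.mutations],
            "telomeres": self.telomeres,
            "rdna": self.rdna,
            "expression_multipliers": self.expression_multipliers,
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")


@dataclass
class SimResult:
    config: SimConfig
    genome: list[SequenceRecord]
    genes: list[GeneModel]
    truth: TruthTable
    counts: pd.DataFrame


# ---------------------------------------------------------------------------
# Markov background sampler


def _cumulative_transitions(gc_percent: float) -> np.ndarray:
    gc = gc_percent / 100.0
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    M = np.tile(base_p, (4, 1))
    for (prev, nxt), f in DINUC_BIAS.items():
        M[_IDX[prev], _IDX[nxt]] *= f
    M /= M.sum(axis=1, keepdims=True)
    return np.cumsum(M, axis=1)


def markov_sequence(length: int, gc_percent: float,
                    rng: np.random.Generator,
                    start_base: Optional[str] = None) -> str:
    """Sample a dinucleotide-biased sequence at a target GC content."""
    if length <= 0:
        return ""
    cum = _cumulative_transitions(gc_percent)
    u = rng.random(length)
    out = np.empty(length, dtype=np.uint8)
    prev = _IDX[start_base] if start_base else int(
        np.searchsorted(np.array([0.25, 0.5, 0.75, 1.0]), u[0])
    )
    out[0] = ord(BASES[prev])
    for i in range(1, length):
        prev = int(np.searchsorted(cum[prev], u[i]))
        out[i] = ord(BASES[prev])
    return out.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Genome assembly


def _chrom_name(i: int) -> str:
    return f"chr{'I' * (i + 1)}" if i < 3 else f"chr{i + 1}"


def make_genome(config: SimConfig
                ) -> tuple[list[SequenceRecord], list[GeneModel], TruthTable]:
    """Build the pre-RIP genome, its annotation and the truth table.

    Layout per chromosome (left to right): 5' telomeric tract, a
    subtelomeric duplicated element, alternating intergenic/gene segments
    punctuated by interspersed duplicated elements at gaps drawn uniformly
    from ``interspersed_gap_range``, a central centromeric tandem array,
    more gene territory, a 3' subtelomeric element and the 3' telomeric
    tract.  The rDNA-like array sits on the right arm of the last
    chromosome and is *not* registered as RIP-exposed (tandem rDNA escapes
    RIP in vivo).
    """
    rng = np.random.default_rng(config.seed)
    truth = TruthTable()
    tel3 = config.telomere_unit * config.telomere_repeat_count
    tel5 = revcomp(config.telomere_unit) * config.telomere_repeat_count

    # shared duplicated-family units: exact copies are planted genome-wide
    inter_unit = markov_sequence(config.interspersed_length,
                                 config.intergenic_gc_target, rng)
    subtel_unit = markov_sequence(config.subtelomere_length,
                                  config.intergenic_gc_target, rng)
    cen_unit = markov_sequence(config.centromere_unit_length,
                               config.intergenic_gc_target, rng)
    rdna_unit = markov_sequence(config.rdna_unit_length,
                                config.gene_gc_target, rng)

    genome: list[SequenceRecord] = []
    genes: list[GeneModel] = []

    for ci, chrom_len in enumerate(config.chromosome_lengths):
        seq_id = _chrom_name(ci)
        parts: list[str] = []
        cursor = 0
        gene_counter = 0

        def emit(s: str) -> int:
            nonlocal cursor
            parts.append(s)
            start = cursor
            cursor += len(s)
            return start

        def emit_duplication(unit: str, kind: str, family: str) -> None:
            start = emit(unit)
            truth.duplications.append(
                PlantedDuplication(seq_id, start, start + len(unit),
                                   family, kind)
            )
            truth.blocks.append((seq_id, start, start + len(unit), kind))

        def fill_genes(target: int) -> None:
            """Alternate intergenic/gene segments up to position ``target``."""
            nonlocal gene_counter
            while cursor < target:
                ig = min(config.intergenic_length, target - cursor)
                emit(markov_sequence(ig, config.intergenic_gc_target, rng))
                if target - cursor < config.gene_length:
                    if target > cursor:
                        emit(markov_sequence(target - cursor,
                                             config.intergenic_gc_target,
                                             rng))
                    break
                gene_counter += 1
                gtype = ("tRNA" if gene_counter % config.trna_every == 0
                         else "protein_coding")
                strand = "+" if gene_counter % 2 else "-"
                start = emit(markov_sequence(config.gene_length,
                                             config.gene_gc_target, rng))
                genes.append(
                    GeneModel(
                        gene_id=f"{seq_id}_g{gene_counter:04d}",
                        interval=GenomicInterval(seq_id, start,
                                                 start + config.gene_length,
                                                 strand),
                        type=gtype,
                    )
                )

        emit(tel5)
        emit_duplication(subtel_unit, "subtelomere", "subtel")
        truth.telomeres[f"{seq_id}:5p"] = config.telomere_repeat_count
        truth.telomeres[f"{seq_id}:3p"] = config.telomere_repeat_count

        cen_len = config.centromere_unit_length * config.centromere_copies
        cen_start_target = chrom_len // 2 - cen_len // 2
        tail = len(tel3) + config.subtelomere_length
        rdna_len = config.rdna_unit_length * config.rdna_copies
        is_last = ci == len(config.chromosome_lengths) - 1
        rdna_target = (chrom_len * 3) // 4 if is_last else None

        placed_cen = False
        placed_rdna = not is_last
        while True:
            gap = int(rng.integers(config.interspersed_gap_range[0],
                                   config.interspersed_gap_range[1] + 1))
            nxt = cursor + gap
            if not placed_cen and nxt >= cen_start_target:
                fill_genes(cen_start_target)
                cen_start = emit(cen_unit * config.centromere_copies)
                truth.duplications.append(
                    PlantedDuplication(seq_id, cen_start, cen_start + cen_len,
                                       f"cen{ci + 1}", "centromere")
                )
                truth.blocks.append(
                    (seq_id, cen_start, cen_start + cen_len, "centromere")
                )
                placed_cen = True
                continue
            if not placed_rdna and nxt >= rdna_target:
                fill_genes(rdna_target)
                rdna_start = emit(rdna_unit * config.rdna_copies)
                truth.rdna = {
                    "seq_id": seq_id,
                    "start": rdna_start,
                    "end": rdna_start + rdna_len,
                    "unit_length": config.rdna_unit_length,
                    "copies": config.rdna_copies,
                }
                for k in range(config.rdna_copies):
                    genes.append(
                        GeneModel(
                            gene_id=f"{seq_id}_rrna{k + 1:02d}",
                            interval=GenomicInterval(
                                seq_id,
                                rdna_start + k * config.rdna_unit_length,
                                rdna_start + k * config.rdna_unit_length
                                + 800,
                                "+",
                            ),
                            type="rRNA",
                        )
                    )
                placed_rdna = True
                continue
            if nxt + config.interspersed_length >= chrom_len - tail - 2000:
                break
            fill_genes(nxt)
            emit_duplication(inter_unit, "interspersed", "inter")
        fill_genes(chrom_len - tail)
        emit_duplication(subtel_unit, "subtelomere", "subtel")
        emit(tel3)
        residues = "".join(parts)
        if len(residues) != chrom_len:
            raise AssertionError("layout does not sum to chromosome length")
        genome.append(SequenceRecord(seq_id, residues))

    return genome, genes, truth


# ---------------------------------------------------------------------------
# Forward RIP


def apply_rip(genome: Sequence[SequenceRecord], truth: TruthTable,
              rip: RipConfig, rng: np.random.Generator
              ) -> list[SequenceRecord]:
    """Mutate duplicated regions with the context-biased C->T process.

    Each cycle is synchronous: every C (on either strand) inside a
    duplicated region mutates independently with the probability of its
    current CpN context, evaluated on the sequence as it stood at the
    start of the cycle.  Region-edge bases without an in-region neighbor
    are never mutated.  Mutations are recorded with their position,
    strand, the context at the event and the context in the original
    (pre-RIP) parent.
    """
    arrays = {
        s.id: np.frombuffer(s.residues.encode("ascii"),
                            dtype=np.uint8).copy()
        for s in genome
    }
    rate = np.zeros(256)
    for ctx, p in rip.rates.items():
        rate[ord(ctx[1])] = p

    for dup in truth.duplications:
        arr = arrays[dup.seq_id]
        region = arr[dup.start:dup.end]
        parent = region.copy()
        dup.pre_rip = parent.tobytes().decode("ascii")
        for cycle in range(rip.cycles):
            snapshot = region.copy()
            # plus strand: C with an in-region 3' neighbor
            c_pos = np.nonzero(snapshot[:-1] == _C)[0]
            c_ctx = snapshot[c_pos + 1]
            c_hit = c_pos[rng.random(c_pos.size) < rate[c_ctx]]
            # minus strand: G with an in-region 5' neighbor
            g_pos = np.nonzero(snapshot[1:] == _G)[0] + 1
            g_ctx = _COMP_CODE[snapshot[g_pos - 1]]
            g_hit = g_pos[rng.random(g_pos.size) < rate[g_ctx]]
            region[c_hit] = _T
            region[g_hit] = _A
            for pos in c_hit:
                truth.mutations.append(
                    PlantedMutation(
                        dup.seq_id, dup.start + int(pos), "+",
                        "C" + chr(parent[pos + 1]),
                        "C" + chr(snapshot[pos + 1]), cycle,
                    )
                )
            for pos in g_hit:
                truth.mutations.append(
                    PlantedMutation(
                        dup.seq_id, dup.start + int(pos), "-",
                        "C" + chr(_COMP_CODE[parent[pos - 1]]),
                        "C" + chr(_COMP_CODE[snapshot[pos - 1]]), cycle,
                    )
                )
        dup.post_rip = region.tobytes().decode("ascii")
    return [
        SequenceRecord(s.id, arrays[s.id].tobytes().decode("ascii"))
        for s in genome
    ]


# ---------------------------------------------------------------------------
# Expression counts


def make_counts(genes: Sequence[GeneModel], expression: ExpressionConfig,
                rng: np.random.Generator,
                truth: Optional[TruthTable] = None) -> pd.DataFrame:
    """Poisson read counts per gene for each configured condition.

    A deterministic slice of genes (by position in the list) receives the
    induced / mid / repressed multiplier in the second condition; the rest
    are unchanged.  Multipliers are recorded in the truth table.
    """
    n = len(genes)
    multipliers = np.ones(n)
    n_ind = int(round(expression.induced_fraction * n))
    n_mid = int(round(expression.mid_fraction * n))
    n_rep = int(round(expression.repressed_fraction * n))
    multipliers[:n_ind] = expression.induced_multiplier
    multipliers[n_ind:n_ind + n_mid] = expression.mid_multiplier
    multipliers[n_ind + n_mid:n_ind + n_mid + n_rep] = \
        expression.repressed_multiplier
    cond_a, cond_b = expression.conditions
    rows = []
    for gene, mult in zip(genes, multipliers):
        mean_a = expression.base_mean
        rows.append(
            {
                "gene_id": gene.gene_id,
                "length": gene.interval.length,
                "type": gene.type,
                f"count_{cond_a}": int(rng.poisson(mean_a)),
                f"count_{cond_b}": int(rng.poisson(mean_a * mult)),
            }
        )
        if truth is not None and mult != 1.0:
            truth.expression_multipliers[gene.gene_id] = float(mult)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Top level


def simulate_study(config: Optional[SimConfig] = None,
                   seed: Optional[int] = None) -> SimResult:
    """Generate a full synthetic study: genome, annotation, truth, counts."""
    if config is None:
        config = SimConfig(seed=seed if seed is not None else 0)
    elif seed is not None:
        config = replace(config, seed=seed)
    genome, genes, truth = make_genome(config)
    rip_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 1]))
    genome = apply_rip(genome, truth, config.rip, rip_rng)
    counts_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 2]))
    counts = make_counts(genes, config.expression, counts_rng, truth)
    return SimResult(config=config, genome=genome, genes=genes, truth=truth,
                     counts=counts)


def write_outputs(result: SimResult, outdir: Union[str, Path]) -> None:
    """Emit genome.fa, genes.gff3, truth.json and counts.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(result.genome, outdir / "genome.fa")
    write_gff(result.genes, outdir / "genes.gff3")
    result.truth.to_json(outdir / "truth.json")
    result.counts.to_csv(outdir / "counts.tsv", sep="\t", index=False)
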