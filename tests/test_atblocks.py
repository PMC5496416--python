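import numpy as np
import pytest

from ripscape import atblocks, landscape
from ripscape.atblocks import ATBlock, BlockThresholds
from ripscape.datasets import FUNGAL_GENOME_TABLE
from ripscape.seqio import GenomicInterval, SequenceRecord


def profile_from_at(at_percents, seq_id="s", window=500):
    values = 1.0 - np.asarray(at_percents, dtype=float) / 100.0
    return landscape.GCProfile(seq_id, window, values)


def brute_force_blocks(at_percents, at_cutoff, window=500):
    """Independent oracle: scan every window, group consecutive runs."""
    blocks = []
    run = None
    for i, at in enumerate(list(at_percents) + [-1.0]):
        if at >= at_cutoff:
            run = [i, i] if run is None else [run[0], i]
        elif run is not None:
            blocks.append((run[0] * window, (run[1] + 1) * window))
            run = None
    return blocks


class TestCallAtBlocks:
    def test_uniform_profile_yields_no_blocks(self):
        profile = profile_from_at([50.0] * 10)
        thresholds = BlockThresholds(genome_gc_mean=50.0, genome_delta=6.0)
        assert atblocks.call_at_blocks(profile, thresholds) == []

    def test_hand_traced_runs(self):
        # AT series [50,70,72,55,71] with cutoff AT >= 60 (GC <= 40)
        profile = profile_from_at([50, 70, 72, 55, 71])
        thresholds = BlockThresholds(genome_gc_mean=46.0, genome_delta=6.0)
        blocks = atblocks.call_at_blocks(profile, thresholds)
        spans = [(b.interval.start, b.interval.end) for b in blocks]
        assert spans == [(500, 1500), (2000, 2500)]
        assert blocks[0].length == 1000 and blocks[1].length == 500
        assert blocks[0].at_mean == pytest.approx(71.0)

    def test_gap_tolerance_merges_across_single_window(self):
        profile = profile_from_at([70, 50, 70])
        thresholds = BlockThresholds(genome_gc_mean=46.0)
        assert len(atblocks.call_at_blocks(profile, thresholds)) == 2
        merged = atblocks.call_at_blocks(profile, thresholds,
                                         max_gap_windows=1)
        assert [(b.interval.start, b.interval.end) for b in merged] == \
            [(0, 1500)]

    def test_dual_rule_takes_the_stricter_cutoff(self):
        profile = profile_from_at([58.0])  # GC 42
        loose = BlockThresholds(genome_gc_mean=50.0, genome_delta=6.0)
        assert len(atblocks.call_at_blocks(profile, loose)) == 1
        strict = BlockThresholds(genome_gc_mean=50.0, genome_delta=6.0,
                                 gene_gc_mean=52.0, gene_delta=12.0)
        assert atblocks.call_at_blocks(profile, strict) == []

    def test_negative_cutoff_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            BlockThresholds(genome_gc_mean=3.0, genome_delta=6.0)

    def test_matches_brute_force_oracle_on_random_profiles(self, rng):
        thresholds = BlockThresholds(genome_gc_mean=50.0, genome_delta=6.0)
        at_cutoff = 100.0 - thresholds.gc_cutoff()
        for _ in range(20):
            at = rng.uniform(30, 75, size=100)
            called = atblocks.call_at_blocks(profile_from_at(at), thresholds)
            spans = [(b.interval.start, b.interval.end) for b in called]
            assert spans == brute_force_blocks(at, at_cutoff)

    def test_blocks_disjoint_sorted_window_sized(self, rng):
        thresholds = BlockThresholds(genome_gc_mean=50.0)
        blocks = atblocks.call_at_blocks(
            profile_from_at(rng.uniform(30, 75, size=200)), thresholds
        )
        for a, b in zip(blocks, blocks[1:]):
            assert a.interval.end < b.interval.start + 1
        assert all(b.length >= 500 and b.length % 500 == 0 for b in blocks)


class TestClassifyBlocks:
    def _block(self, start, end, seq_id="chr1"):
        return ATBlock(GenomicInterval(seq_id, start, end), 70.0)

    def test_rule_application(self):
        blocks = [
            self._block(0, 5000),
            self._block(1_000_000, 1_200_000),
            self._block(2_000_000, 2_010_000),
        ]
        atblocks.classify_blocks(blocks, {"chr1": 3_000_000})
        assert [b.blocklass for b in blocks] == [
            "subtelomere", "centromere", "interspersed",
        ]

    def test_terminal_only_block_gives_no_centromere(self, caplog):
        blocks = [self._block(2_999_000, 3_000_000)]
        atblocks.classify_blocks(blocks, {"chr1": 3_000_000})
        assert blocks[0].blocklass == "subtelomere"

    def test_centromere_tie_broken_leftmost(self):
        blocks = [self._block(100_000, 110_000),
                  self._block(500_000, 510_000)]
        atblocks.classify_blocks(blocks, {"chr1": 1_000_000})
        assert blocks[0].blocklass == "centromere"
        assert blocks[1].blocklass == "interspersed"

    def test_at_most_one_centromere_and_it_is_longest(self, sim_blocks):
        by_chrom = {}
        for b in sim_blocks:
            by_chrom.setdefault(b.interval.seq_id, []).append(b)
        for chrom_blocks in by_chrom.values():
            cens = [b for b in chrom_blocks if b.blocklass == "centromere"]
            assert len(cens) <= 1
            if cens:
                others = [b.length for b in chrom_blocks
                          if b.blocklass == "interspersed"]
                assert all(cens[0].length >= L for L in others)


class TestBinBlockLengths:
    def test_boundary_placement(self):
        blocks = [
            ATBlock(GenomicInterval("s", 0, 500), 70.0),
            ATBlock(GenomicInterval("s", 1000, 3999), 70.0),
            ATBlock(GenomicInterval("s", 5000, 8000), 70.0),
        ]
        bins = atblocks.bin_block_lengths(blocks)
        assert bins["0.5<=L<1"] == 1
        assert bins["1<=L<3"] == 1
        assert bins["3<=L<5"] == 1
        assert atblocks.long_block_count(blocks) == 1

    def test_empty_blocks_all_zero(self):
        assert atblocks.bin_block_lengths([]).sum() == 0

    def test_bins_sum_to_total(self, sim_blocks):
        bins = atblocks.bin_block_lengths(sim_blocks)
        eligible = sum(1 for b in sim_blocks if b.length >= 500)
        assert bins.sum() == eligible


class TestNeighborDistances:
    def _classified(self, spans, classes, seq_id="chr1"):
        blocks = [ATBlock(GenomicInterval(seq_id, s, e), 70.0)
                  for s, e in spans]
        for b, c in zip(blocks, classes):
            b.blocklass = c
        return blocks

    def test_gap_definition(self):
        blocks = self._classified(
            [(10_000, 11_000), (24_000, 25_000)],
            ["interspersed", "interspersed"],
        )
        nd = atblocks.neighbor_distances(blocks, {"chr1": 100_000})
        assert list(nd.distances) == [13_000.0]

    def test_single_block_arm_contributes_nothing(self):
        blocks = self._classified([(10_000, 11_000)], ["interspersed"])
        nd = atblocks.neighbor_distances(blocks, {"chr1": 100_000})
        assert nd.distances.size == 0 and np.isnan(nd.mean)

    def test_centromere_delimits_arms(self):
        blocks = self._classified(
            [(10_000, 11_000), (40_000, 60_000), (90_000, 91_000)],
            ["interspersed", "centromere", "interspersed"],
        )
        nd = atblocks.neighbor_distances(blocks, {"chr1": 200_000})
        # one interspersed block per arm: no gap spans the centromere
        assert nd.distances.size == 0

    def test_recovers_planted_spacing(self, default_sim, sim_blocks):
        nd = atblocks.neighbor_distances(
            sim_blocks, {s.id: s.length for s in default_sim.genome}
        )
        lo, hi = default_sim.config.interspersed_gap_range
        planted_mean = (lo + hi) / 2
        assert abs(nd.mean - planted_mean) / planted_mean < 0.10


class TestTelomeres:
    def test_three_prime_count(self):
        seq = SequenceRecord("s", "ACGT" * 30 + "TTAGGG" * 3)
        report = atblocks.detect_telomere_repeats(seq)
        assert report.three_prime_repeats == 3
        assert report.five_prime_repeats == 0

    def test_five_prime_count_uses_reverse_complement(self):
        seq = SequenceRecord("s", "CCCTAA" * 4 + "ACGT" * 30)
        report = atblocks.detect_telomere_repeats(seq)
        assert report.five_prime_repeats == 4

    def test_no_repeats_is_zero(self):
        report = atblocks.detect_telomere_repeats(
            SequenceRecord("s", "ACGT" * 10)
        )
        assert (report.five_prime_repeats, report.three_prime_repeats) == (0, 0)

    def test_offset_tolerance(self):
        seq = SequenceRecord("s", "ACGT" * 30 + "TTAGGG" * 5 + "A" * 10)
        assert atblocks.detect_telomere_repeats(seq).three_prime_repeats == 5
        far = SequenceRecord("s", "ACGT" * 30 + "TTAGGG" * 5 + "A" * 60)
        assert atblocks.detect_telomere_repeats(far).three_prime_repeats == 0


class TestTandemUnits:
    def test_exact_tandem(self):
        unit = SequenceRecord("u", "ACGT" * 50)
        seq = SequenceRecord("s", "TTTT" * 30 + unit.residues * 3
                             + "GGGG" * 30)
        copies, interval = atblocks.count_tandem_units(seq, unit)
        assert copies == 3
        assert interval.length == 600

    def test_mutated_tandem_at_90_percent_identity(self, rng):
        unit = "".join(rng.choice(list("ACGT"), size=200))
        copies_true = 3
        mutated = []
        for _ in range(copies_true):
            arr = list(unit)
            for i in rng.choice(200, size=10, replace=False):  # 5% subs
                arr[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[i]]
            mutated.append("".join(arr))
        seq = SequenceRecord("s", "T" * 100 + "".join(mutated) + "G" * 100)
        copies, _ = atblocks.count_tandem_units(
            seq, SequenceRecord("u", unit), min_identity=0.9
        )
        assert copies == copies_true

    def test_unit_longer_than_sequence_rejected(self):
        with pytest.raises(ValueError):
            atblocks.count_tandem_units(
                SequenceRecord("s", "ACGT" * 30),
                SequenceRecord("u", "ACGT" * 31),
            )


class TestGenomeGroups:
    @pytest.mark.parametrize(
        "at_mean,long_blocks,expected",
        [
            (48.9, 167, "I"),   # filamentous-ascomycete pattern
            (46.0, 1, "II"),    # basidiomycete pattern
            (61.7, 0, "III"),   # AT-rich yeast pattern
        ],
    )
    def test_decision_rule(self, at_mean, long_blocks, expected):
        summary = landscape.GenomeSummary(
            genome_size=0, n_sequences=0, gc_mean=100 - at_mean, gc_sd=0,
            at_mean=at_mean, gc_base_fraction=0,
            long_block_count=long_blocks,
        )
        assert atblocks.classify_genome_group(summary) == expected

    def test_reproduces_published_twelve_genome_grouping(self):
        for row in FUNGAL_GENOME_TABLE.itertuples():
            summary = landscape.GenomeSummary(
                genome_size=0, n_sequences=row.n_chromosomes,
                gc_mean=row.gc_mean, gc_sd=row.gc_sd,
                at_mean=100.0 - row.gc_mean, gc_base_fraction=row.gc_mean,
                long_block_count=row.long_blocks,
            )
            assert atblocks.classify_genome_group(summary) == row.group, \
                row.species
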