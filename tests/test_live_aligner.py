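"""Engine unit tests: parameter presets, error budget, seeding, extension,
best-alignment selection, streaming equivalence and checkpointing."""

from __future__ import annotations

import numpy as np
import pytest

from livemapper.basecall_io import RunLayout
from livemapper.live_aligner import (
    AlignerError,
    AlignmentSettings,
    CheckpointError,
    TileState,
    allowed_errors,
    auto_configure,
    checkpoint_resume,
    checkpoint_save,
    min_score,
    placement,
    process_cycle,
    select_best,
)
from livemapper.reference_index import ReferenceGenome, build_index, revcomp

from oracles import oracle_align


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def feed_reads(index, settings, reads, read_length):
    """Drive a single-tile, single-end run directly from read strings."""
    layout = RunLayout(lanes=(1,), tiles=(1,), reads=(read_length,))
    tile = TileState(1, 1, layout)
    for cycle in range(1, read_length + 1):
        calls = [(r[cycle - 1], 30) for r in reads]
        process_cycle(tile, calls, index, settings, cycle)
    return tile


@pytest.fixture(scope="module")
def unique_genome():
    rng = np.random.default_rng(2024)
    genome = ReferenceGenome((("ref", random_seq(rng, 50_000)),))
    return genome, build_index(genome)


class TestAutoConfigure:
    def test_fast_preset_long_reads(self):
        s = auto_configure("fast", 10_000_000, 100)
        assert (s.anchor_length, s.seeding_interval, s.error_interval) == (12, 8, 20)
        assert s.min_as_fraction == 0.5

    def test_short_reads_get_adapted_parameters(self):
        s = auto_configure("fast", 10_000_000, 50)
        assert (s.anchor_length, s.seeding_interval, s.error_interval) == (10, 6, 16)
        assert s.output_cycles[0] == 30  # first output already at cycle 30

    def test_accurate_is_strictly_tighter_than_fast(self):
        fast = auto_configure("fast", 10_000_000, 100)
        acc = auto_configure("accurate", 10_000_000, 100)
        assert acc.seeding_interval < fast.seeding_interval
        assert acc.error_interval < fast.error_interval

    def test_all_modes_satisfy_invariants(self):
        for mode in ("very-fast", "fast", "balanced", "accurate", "very-accurate"):
            for rlen in (36, 50, 76, 100, 150):
                s = auto_configure(mode, 3_000_000, rlen)
                assert s.anchor_length >= 8
                assert s.seeding_interval <= s.anchor_length
                assert s.error_interval >= 1

    def test_rejections(self):
        with pytest.raises(AlignerError):
            auto_configure("warp", 1000, 100)
        with pytest.raises(AlignerError):
            auto_configure("fast", 1000, 10)


class TestErrorBudgetAndScore:
    @pytest.mark.parametrize(
        "L,expected", [(12, 0), (31, 0), (32, 1), (52, 2), (100, 4)]
    )
    def test_allowed_errors_schedule(self, L, expected):
        s = AlignmentSettings(anchor_length=12, error_interval=20)
        assert allowed_errors(s, L) == expected

    def test_allowed_errors_rejects_below_anchor(self):
        s = AlignmentSettings()
        with pytest.raises(AlignerError):
            allowed_errors(s, 11)

    def test_min_score_values(self):
        s = AlignmentSettings(min_as_fraction=0.5, match_score=1)
        assert min_score(s, 40) == 20
        # the anchor alone always passes for any fraction <= 1
        for f in (0.3, 0.5, 1.0):
            s2 = AlignmentSettings(min_as_fraction=f)
            assert s2.anchor_length * s2.match_score >= min_score(
                s2, s2.anchor_length
            )


class TestSeedingAndExtension:
    def test_error_free_read_single_seed_full_match(self, unique_genome):
        genome, index = unique_genome
        seq = genome.sequences[0][1]
        read = seq[1000:1100]
        settings = auto_configure("fast", genome.total_length, 100)
        tile = feed_reads(index, settings, [read], 100)
        rs = tile.fragments[0][0]
        best, ties = select_best(rs, settings, index)
        assert ties == 1
        assert best.cigar_string() == "100M"
        assert best.errors == 0 and best.score == 100
        assert placement(best, index) == ("ref", 1000, "+")

    def test_reverse_strand_read_places_correctly(self, unique_genome):
        genome, index = unique_genome
        seq = genome.sequences[0][1]
        read = revcomp(seq[2000:2100])
        settings = auto_configure("fast", genome.total_length, 100)
        tile = feed_reads(index, settings, [read], 100)
        best, _ = select_best(tile.fragments[0][0], settings, index)
        assert placement(best, index) == ("ref", 2000, "-")
        assert best.score == 100

    def test_early_error_rescued_by_noninitial_anchor_with_softclip(
        self, unique_genome
    ):
        genome, index = unique_genome
        seq = genome.sequences[0][1]
        read = list(seq[3000:3100])
        read[5] = "ACGT".replace(read[5], "")[0]  # error at read position 5
        read = "".join(read)
        settings = auto_configure("fast", genome.total_length, 100)
        tile = feed_reads(index, settings, [read], 100)
        best, _ = select_best(tile.fragments[0][0], settings, index)
        # initial anchor (cycles 1-12) is poisoned; rescue at cycle 20
        assert best.softclip == settings.anchor_length + settings.seeding_interval - settings.anchor_length
        assert best.cigar_string() == "8S92M"
        assert placement(best, index) == ("ref", 3008, "+")
        result, unique = oracle_align(read, index.indexed, settings)
        assert unique
        assert (placement(best, index), best.score) == (
            result.placement,
            result.score,
        )

    def test_midread_mismatch_survives_budget(self, unique_genome):
        genome, index = unique_genome
        seq = genome.sequences[0][1]
        read = list(seq[4000:4100])
        read[60] = "ACGT".replace(read[60], "")[0]
        read = "".join(read)
        settings = auto_configure("fast", genome.total_length, 100)
        tile = feed_reads(index, settings, [read], 100)
        best, _ = select_best(tile.fragments[0][0], settings, index)
        assert best.cigar_string() == "100M"
        assert best.errors == 1
        assert best.score == 99 - 2  # 99 matches at +1, one mismatch at -2

    def test_deletion_in_read_yields_d_run(self, unique_genome):
        genome, index = unique_genome
        seq = genome.sequences[0][1]
        # read skips 2 reference bases at offset 50
        read = seq[5000:5050] + seq[5052:5102]
        settings = auto_configure("fast", genome.total_length, 100)
        tile = feed_reads(index, settings, [read], 100)
        best, _ = select_best(tile.fragments[0][0], settings, index)
        assert "2D" in best.cigar_string()
        assert best.ref_span() == 102  # aligned read length + deletion
        result, unique = oracle_align(read, index.indexed, settings)
        assert unique
        assert best.score == result.score

    def test_insertion_in_read_yields_i_run(self, unique_genome):
        genome, index = unique_genome
        seq = genome.sequences[0][1]
        read = seq[6000:6050] + "GG" + seq[6050:6098]
        settings = auto_configure("fast", genome.total_length, 100)
        tile = feed_reads(index, settings, [read], 100)
        best, _ = select_best(tile.fragments[0][0], settings, index)
        result, unique = oracle_align(read, index.indexed, settings)
        assert unique
        assert (placement(best, index), best.score) == (
            result.placement,
            result.score,
        )
        assert "2I" in best.cigar_string()

    def test_cigar_conservation_every_cycle(self, unique_genome):
        # S + M + I runs must sum to the sequenced length at every cycle
        genome, index = unique_genome
        seq = genome.sequences[0][1]
        read = list(seq[7000:7100])
        read[5] = "ACGT".replace(read[5], "")[0]
        read[40] = "ACGT".replace(read[40], "")[0]
        read = "".join(read)
        settings = auto_configure("fast", genome.total_length, 100)
        layout = RunLayout(lanes=(1,), tiles=(1,), reads=(100,))
        tile = TileState(1, 1, layout)
        for cycle in range(1, 101):
            process_cycle(tile, [(read[cycle - 1], 30)], index, settings, cycle)
            rs = tile.fragments[0][0]
            for seed in rs.seeds.values():
                consumed = sum(l for op, l in seed.cigar if op in "SMI")
                assert consumed == cycle
                aligned = cycle - seed.softclip
                assert seed.errors <= allowed_errors(settings, aligned)

    def test_n_in_kmer_blocks_seeding(self, unique_genome):
        genome, index = unique_genome
        read = "N" * 100
        settings = auto_configure("fast", genome.total_length, 100)
        tile = feed_reads(index, settings, [read], 100)
        rs = tile.fragments[0][0]
        assert not rs.seeds
        assert select_best(rs, settings, index) == (None, 0)


class TestSelectBest:
    def test_tie_count_and_position_break_on_duplicated_locus(self):
        rng = np.random.default_rng(77)
        core = random_seq(rng, 300)
        pad = random_seq(rng, 200)
        genome = ReferenceGenome((("dup", core + pad + core),))
        index = build_index(genome)
        settings = auto_configure("fast", genome.total_length, 100)
        read = core[100:200]
        tile = feed_reads(index, settings, [read], 100)
        best, ties = select_best(tile.fragments[0][0], settings, index)
        assert ties == 2
        assert placement(best, index) == ("dup", 100, "+")  # leftmost wins

    def test_no_qualifying_seed_means_unmapped(self, unique_genome):
        genome, index = unique_genome
        rng = np.random.default_rng(123)
        read = random_seq(rng, 100)  # random read, almost surely unplaceable
        settings = auto_configure("fast", genome.total_length, 100)
        tile = feed_reads(index, settings, [read], 100)
        best, ties = select_best(tile.fragments[0][0], settings, index)
        assert best is None and ties == 0


class TestDriverContracts:
    def test_out_of_order_cycle_rejected(self, unique_genome):
        genome, index = unique_genome
        settings = auto_configure("fast", genome.total_length, 100)
        layout = RunLayout(lanes=(1,), tiles=(1,), reads=(100,))
        tile = TileState(1, 1, layout)
        process_cycle(tile, [("A", 30)], index, settings, 1)
        with pytest.raises(AlignerError, match="cycle"):
            process_cycle(tile, [("A", 30)], index, settings, 3)

    def test_empty_tile_is_noop(self, unique_genome):
        genome, index = unique_genome
        settings = auto_configure("fast", genome.total_length, 100)
        layout = RunLayout(lanes=(1,), tiles=(1,), reads=(100,))
        tile = TileState(1, 1, layout)
        for cycle in range(1, 101):
            process_cycle(tile, [], index, settings, cycle)
        assert tile.fragments == []

    def test_tile_independence(self, unique_genome):
        genome, index = unique_genome
        seq = genome.sequences[0][1]
        settings = auto_configure("fast", genome.total_length, 100)
        reads_a = [seq[1000:1100], seq[2000:2100]]
        reads_b = [seq[3000:3100]]
        # process A then B vs B then A: per-tile results identical
        results = {}
        for order in ("ab", "ba"):
            tiles = {}
            for label in order:
                reads = reads_a if label == "a" else reads_b
                tiles[label] = feed_reads(index, settings, reads, 100)
            results[order] = {
                label: [
                    (placement(s, index), s.score)
                    for frag in tile.fragments
                    for s in [select_best(frag[0], settings, index)[0]]
                ]
                for label, tile in tiles.items()
            }
        assert results["ab"] == results["ba"]


class TestMonotoneMapping:
    def test_mapped_set_non_decreasing_without_sequencing_errors(self, tmp_path):
        """On an error-free run no seed can die, so the set of reads
        reported mapped at each output cycle only ever grows (with
        sequencing errors a read can drop out at the min-score boundary,
        which is why this property is stated for the clean fixture)."""
        import pysam

        from livemapper.basecall_io import RunLayout
        from livemapper.live_aligner import run_mapping
        from livemapper.run_simulator import PairedRead, TimingModel, simulate_run
        from livemapper.synthetic_data import (
            DonorSpec,
            RepeatSpec,
            generate_reference,
            mutate_donor,
            simulate_reads,
        )
        from livemapper.reference_index import build_index

        # reads drawn from the reference itself: donor variants would act as
        # mismatches and can push rescued seeds across the min-score boundary
        spec = DonorSpec(
            length=10_000, snp_rate=0.0, indel_rate=0.0, seed=13,
            repeats=RepeatSpec(count=0),
        )
        ref, tracts = generate_reference(spec)
        donor, _, _ = mutate_donor(ref, spec, tracts)
        pairs = simulate_reads(donor, 4.0, (100, 100), error_rates=(0.0, 0.0), seed=13)
        reads = [PairedRead(n, ((s1, q1), (s2, q2))) for n, s1, q1, s2, q2 in pairs]
        layout = RunLayout(lanes=(1,), tiles=(1,), reads=(100, 100))
        simulate_run(reads, layout, TimingModel(0), tmp_path / "run")
        index = build_index(ref)
        settings = auto_configure("fast", ref.total_length, 100)
        written = run_mapping(index, settings, layout, tmp_path / "run", tmp_path / "sam")

        def mapped_set(path):
            with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
                return {
                    (r.query_name, r.is_read2)
                    for r in fh
                    if not r.is_unmapped and not r.is_secondary
                }

        prev: set = set()
        for cycle in sorted(c for c in written if c <= 100):
            cur = mapped_set(written[cycle])
            assert prev <= cur  # tolerance 0
            prev = cur
        prev = set()
        for cycle in sorted(c for c in written if c > 100):
            cur = mapped_set(written[cycle])
            assert prev <= cur
            prev = cur


class TestCheckpoint:
    def test_settings_digest_mismatch_rejected(self, unique_genome, tmp_path):
        genome, index = unique_genome
        seq = genome.sequences[0][1]
        settings = auto_configure("fast", genome.total_length, 100)
        tile = feed_reads(index, settings, [seq[1000:1100]], 100)
        path = tmp_path / "t.ckpt"
        checkpoint_save(tile, settings, path)
        other = auto_configure("accurate", genome.total_length, 100)
        with pytest.raises(CheckpointError, match="settings"):
            checkpoint_resume(path, other)

    def test_reemit_all_alignments_from_checkpoint(self, tmp_path):
        """A stored checkpoint can re-produce a cycle's output with the
        all-mapper option, without recomputing, matching a direct write."""
        from livemapper.alignment_output import write_cycle_output
        from livemapper.live_aligner import reemit_output

        rng = np.random.default_rng(17)
        core = random_seq(rng, 300)
        genome = ReferenceGenome((("dup", core + random_seq(rng, 150) + core),))
        index = build_index(genome)
        settings = auto_configure("fast", genome.total_length, 40)
        tile = feed_reads(index, settings, [core[30:70], core[200:240]], 40)
        ckpt = tmp_path / "c40.ckpt"
        checkpoint_save(tile, settings, ckpt)

        direct = tmp_path / "direct.sam"
        write_cycle_output([tile], index, settings, 40, direct, mode="all")
        reemitted = tmp_path / "reemit.sam"
        reemit_output([ckpt], index, settings, 40, reemitted, mode="all")
        assert direct.read_bytes() == reemitted.read_bytes()
        # and it differs from one-best output (secondary records present)
        best = tmp_path / "best.sam"
        write_cycle_output([tile], index, settings, 40, best, mode="best")
        assert best.read_bytes() != direct.read_bytes()

    def test_resume_reproduces_final_state(self, unique_genome, tmp_path):
        genome, index = unique_genome
        seq = genome.sequences[0][1]
        read = list(seq[8000:8100])
        read[30] = "ACGT".replace(read[30], "")[0]
        read = "".join(read)
        settings = auto_configure("fast", genome.total_length, 100)
        layout = RunLayout(lanes=(1,), tiles=(1,), reads=(100,))

        tile = TileState(1, 1, layout)
        for cycle in range(1, 56):
            process_cycle(tile, [(read[cycle - 1], 30)], index, settings, cycle)
        path = tmp_path / "c55.ckpt"
        checkpoint_save(tile, settings, path)
        for cycle in range(56, 101):
            process_cycle(tile, [(read[cycle - 1], 30)], index, settings, cycle)

        resumed = checkpoint_resume(path, settings)
        for cycle in range(56, 101):
            process_cycle(resumed, [(read[cycle - 1], 30)], index, settings, cycle)

        b1, t1 = select_best(tile.fragments[0][0], settings, index)
        b2, t2 = select_best(resumed.fragments[0][0], settings, index)
        assert (placement(b1, index), b1.score, b1.cigar_string(), t1) == (
            placement(b2, index),
            b2.score,
            b2.cigar_string(),
            t2,
        )
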