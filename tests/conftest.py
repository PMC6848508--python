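from __future__ import annotations

import pytest

from livemapper.basecall_io import RunLayout
from livemapper.live_aligner import auto_configure, run_mapping
from livemapper.reference_index import build_index
from livemapper.run_simulator import PairedRead, TimingModel, simulate_run
from livemapper.synthetic_data import (
    DonorSpec,
    RepeatSpec,
    generate_reference,
    mutate_donor,
    simulate_reads,
    write_bed,
    write_truth_vcf,
)


class World:
    """A complete synthetic study: genome, donor, truth, run folder, SAMs."""

    def __init__(self, spec, coverage, layout, root, *, error_rates=(0.001, 0.01)):
        self.spec = spec
        self.layout = layout
        self.root = root
        self.reference, self.tracts = generate_reference(spec)
        self.donor, self.variants, self.regions = mutate_donor(
            self.reference, spec, self.tracts
        )
        read_lens = layout.reads
        self.pairs = simulate_reads(
            self.donor,
            coverage,
            (read_lens[0], read_lens[-1]),
            error_rates=error_rates,
            seed=spec.seed,
        )
        self.reads = [
            PairedRead(n, ((s1, q1), (s2, q2))) for n, s1, q1, s2, q2 in self.pairs
        ]
        self.run_dir = root / "run"
        simulate_run(self.reads, layout, TimingModel(0), self.run_dir)
        self.index = build_index(self.reference)
        self.settings = auto_configure(
            "fast", self.reference.total_length, max(read_lens)
        )
        self.truth_vcf = root / "truth.vcf"
        write_truth_vcf(
            self.variants,
            self.truth_vcf,
            [(n, len(b)) for n, b in self.reference.sequences],
        )
        self.bed = root / "regions.bed"
        write_bed(self.regions, self.bed)
        self.sams: dict = {}

    def map_run(self, out_name="sam", **kwargs):
        out = run_mapping(
            self.index, self.settings, self.layout, self.run_dir,
            self.root / out_name, **kwargs,
        )
        if out_name == "sam":
            self.sams = out
        return out


@pytest.fixture(scope="session")
def small_world(tmp_path_factory) -> World:
    """20 kb donor at 8x, 2 tiles, 2x100 — the cheap shared end-to-end run."""
    root = tmp_path_factory.mktemp("small_world")
    spec = DonorSpec(
        length=20_000,
        snp_rate=0.002,
        seed=11,
        repeats=RepeatSpec(count=1, unit_length=100, copies=3),
    )
    layout = RunLayout(lanes=(1,), tiles=(1, 2), reads=(100, 100))
    world = World(spec, 8.0, layout, root)
    world.map_run()
    return world


@pytest.fixture(scope="session")
def study_world(tmp_path_factory) -> World:
    """The standard study conditions: 100 kb, snp_rate 0.002, 30x, 2x100,
    64 tiles, seed 7 — shared by the end-to-end acceptance checks."""
    root = tmp_path_factory.mktemp("study_world")
    spec = DonorSpec(seed=7)
    layout = RunLayout(lanes=(1,), tiles=tuple(range(1, 65)), reads=(100, 100))
    world = World(spec, 30.0, layout, root)
    world.map_run()
    return world
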