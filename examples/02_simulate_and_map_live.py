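"""Simulate a sequencing run writing base calls over time and map it live.

A writer thread plays the sequencer, emitting one BCL file per (tile,
cycle) on a fixed seconds-per-cycle clock; the aligner polls the run folder
and consumes each cycle as soon as every tile's file is complete, writing a
SAM at each output cycle.  Batch replay of the same folder would produce
byte-identical output.
"""

import tempfile
import threading
from pathlib import Path

import pysam

from livemapper import RunLayout, build_index
from livemapper.live_aligner import auto_configure, run_mapping
from livemapper.run_simulator import PairedRead, TimingModel, simulate_run
from livemapper.synthetic_data import DonorSpec, RepeatSpec, generate_reference, simulate_reads

spec = DonorSpec(length=20_000, seed=1, repeats=RepeatSpec(count=0))
reference, _ = generate_reference(spec)
pairs = simulate_reads(reference, 4.0, (100, 100), seed=1)
reads = [PairedRead(n, ((s1, q1), (s2, q2))) for n, s1, q1, s2, q2 in pairs]

layout = RunLayout(lanes=(1,), tiles=(1, 2), reads=(100, 100))
work = Path(tempfile.mkdtemp())
index = build_index(reference)
settings = auto_configure("fast", reference.total_length, 100)

writer = threading.Thread(
    target=simulate_run,
    args=(reads, layout, TimingModel(seconds_per_cycle=0.02), work / "run"),
)
writer.start()
sams = run_mapping(
    index, settings, layout, work / "run", work / "sam", live=True
)
writer.join()

for cycle, path in sorted(sams.items()):
    with pysam.AlignmentFile(str(path), "r") as fh:
        recs = [r for r in fh if not r.is_unmapped]
    print(f"cycle {cycle:3d}: {len(recs):4d} reads mapped -> {path.name}")

# mapped counts grow with cycle number: longer reads clear the minimum
# alignment score and erroneous reads get rescued by later anchors
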