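"""Build an FM-index over a small genome and locate k-mers on both strands.

The index stores the forward sequence plus its reverse complement, so one
backward search finds placements on either strand; reverse-strand hits are
reported in forward coordinates with strand '-'.
"""

import numpy as np

from livemapper import ReferenceGenome, build_index

rng = np.random.default_rng(0)
bases = "".join("ACGT"[i] for i in rng.integers(0, 4, 5_000))
genome = ReferenceGenome((("chr1", bases),))
index = build_index(genome)

for pattern in (bases[100:112], bases[2000:2010], "ACGTACGT"):
    interval = index.backward_search(pattern)
    hits, repetitive = index.locate(interval, cap=100)
    print(f"{pattern}: {interval.width} occurrence(s) -> {hits}")

# interval width counts occurrences over both strands; each hit is
# (sequence name, forward-strand 0-based position, strand)
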