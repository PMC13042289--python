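"""Hierarchical seed bookkeeping.

Every stochastic step of a simulation draws from its own substream, keyed by
(replicate, purpose, cycle, program, group, ...). Keyed substreams make runs
bit-reproducible, let replicates run in parallel in any order, and put
different program structures on common random numbers wherever the keys
coincide (e.g. the founder population and genetic landscape of a replicate
are shared across structures).
"""

from __future__ import annotations

import numpy as np

# purpose codes
LANDSCAPE = 0
FOUNDERS = 1
PARTITION = 2
TPE = 3
MET = 4
TESTERS = 5
NOISE = 6
CONTRIB = 7
CROSSES = 8
ADVANCE = 9
GCACORR = 10
PCTGCA = 11


def substream(master_seed: int, *key: int) -> np.random.Generator:
    """Independent random stream for (master_seed, key...)."""
    return np.random.default_rng(
        np.random.SeedSequence(int(master_seed), spawn_key=tuple(int(k) for k in key))
    )


def subseed(master_seed: int, *key: int) -> int:
    """A 32-bit integer seed derived from (master_seed, key...)."""
    return int(
        np.random.SeedSequence(
            int(master_seed), spawn_key=tuple(int(k) for k in key)
        ).generate_state(1)[0]
    )
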