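"""Germplasm-exchange bookkeeping between ranked programs.

Three programs A > B > C with Pmax = 25% and the C-to-A performance gap twice
the C-to-B gap. The best program uses no external parents; the worst sources
a quarter of its breeding crosses externally, split across donors in
proportion to the performance gaps (here 2:1, i.e. about 17% from A and 8%
from B).
"""

import numpy as np

from enksim.engine import external_proportions

performance = np.array([0.60, 0.55, 0.50])  # A, B, C
x, shares = external_proportions(performance, p_max=0.25)

for r, label in enumerate("ABC"):
    donors = ", ".join(
        f"{100 * shares[r, q]:.1f}% from {'ABC'[q]}" for q in range(r)
    )
    print(f"program {label}: {100 * x[r]:5.1f}% external crosses"
          + (f"  ({donors})" if donors else ""))
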