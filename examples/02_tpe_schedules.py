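"""Target-population-of-environments change scenarios.

Samples the per-cycle environment-type frequencies of the gradual and sudden
change schedules and prints the center of mass of the distribution and its
effective number of ETs (inverse Simpson index) for selected cycles. Under
gradual change the center slides from ET1 to ET12; under sudden change it
jumps from the ET1-6 block to the ET7-12 block after cycle 20. Roughly 5-6 of
the 12 ETs have an effective presence at any time.
"""

import numpy as np

from enksim.environment import TPESchedule, effective_number, sample_tpe

rng = np.random.default_rng(2)
for scenario in ("gradual", "sudden"):
    sch = TPESchedule(scenario, n_cycles=30)
    print(f"\n{scenario} change:")
    print("cycle   center of mass   effective # ET")
    effs = []
    for cycle in range(1, 31):
        b = sample_tpe(sch, cycle, rng)
        effs.append(effective_number(b))
        if cycle in (1, 10, 20, 21, 30):
            com = float(np.arange(1, 13) @ b)
            print(f"{cycle:5d}   {com:14.2f}   {effs[-1]:14.2f}")
    print(f"cycle-averaged effective # ET: {np.mean(effs):.2f}")
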