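"""Repeats that extend through the unsequenced middle of the insert.

When the same motif ends both mates' fragment-interior (3') termini, the
repeat almost certainly continues through the gap, so its observed unit
count is only a lower bound.  This example plants gap-crossing repeats and
shows the detector flagging them.
"""

from palfinder import ScanConfig, detect_spanning, find_perfect_ssrs
from palfinder.simdata import PlantingPlan, spanning_fixture

cfg = ScanConfig()
pairs, truth = spanning_fixture(PlantingPlan(seed=4), n_pairs=5)
for pair in pairs:
    l1 = find_perfect_ssrs(pair.mate1, cfg)
    l2 = find_perfect_ssrs(pair.mate2, cfg)
    spanning = detect_spanning(pair, l1, l2, cfg)
    print(f"{pair.mate1.read_id}: mate1 ends ...{pair.mate1.bases[-12:]}, "
          f"mate2 ends ...{pair.mate2.bases[-12:]} -> spanning={spanning} "
          f"(motif {l1[0].motif.canonical}, >= {l1[0].units} units visible)")
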