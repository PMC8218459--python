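"""Scan merged reads for microsatellite tracts and apply candidate filters.

Builds a small batch of synthetic merged reads — some carrying a clean
tetranucleotide tract with long flanks, some with disqualifying features —
and runs the marker-discovery stage over them.
"""

import numpy as np

from ssrgbas import discovery as dv
from ssrgbas import simdata as sd

rng = np.random.default_rng(0)

reads = []
# clean candidates: single perfect tract, >=30 bp flanks
for i in range(5):
    left = sd._clean_flank(rng, 40, "TGTT")
    right = sd._clean_flank(rng, 40, "TGTT")
    reads.append((f"clean{i}", left + "TGTT" * (5 + i) + right))
# a read with a 7-base mononucleotide run in the flank
left = sd._clean_flank(rng, 40, "TTTG")
reads.append(("monorun", "AAAAAAA" + left[7:] + "TTTG" * 6 + left[::-1]))
# a read with two distinct qualifying tracts
mid = sd._clean_flank(rng, 40, "CTTT")
reads.append(("double", mid + "CTTT" * 5 + mid[::-1] + "ATCC" * 5 + mid))

retained, tally, _ = dv.scan_reads(reads)

print(f"{len(reads)} reads scanned, {len(retained)} retained")
for rid, cand in retained.items():
    flag = dv.assess_amplicon_placement(cand)
    print(f"  {rid}: motif {cand.motif} x{cand.repeat_count}, "
          f"flanks {cand.left_flank_len}/{cand.right_flank_len}, "
          f"placeable={flag}")
print("rejection tally:", {k: v for k, v in tally.items() if v})
# Retained reads are usable SSR marker candidates: one perfect tract, both
# flanks long enough to design primers, and no confounding repeats.
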