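"""How undigested tandem copies bias ddPCR copy-number estimates.

Poisson quantification assumes every target copy partitions into
droplets independently.  Tandemly repeated copies sit on one DNA
fragment unless restriction digestion separates them; a droplet holding
a 3-copy block still lights up only once.  Sweeping the linked fraction
L at true CN 6 shows the estimate collapsing from 6 toward 2 (two
indivisible allelic units against the diploid reference).
"""

import numpy as np

import ddcnv
from ddcnv.pipeline import simulate_and_quantify
from ddcnv.sim import SimConfig

for L in (0.0, 0.25, 0.5, 0.75, 1.0):
    estimates = [
        simulate_and_quantify(
            SimConfig(n_droplets=20000, lambda_ref=0.5, true_cn=6.0,
                      linkage_fraction=L, seed=s)
        ).cn_estimate
        for s in ddcnv.spawn_seeds(int(L * 100), 25)
    ]
    print(f"linked fraction {L:.2f}: mean CN estimate "
          f"{np.mean(estimates):.3f} (25 wells)")

# At L=1 the six copies travel as two 3-copy blocks per genome, matching
# the reference rate, so the estimate is ~2.0 — a 3-fold underestimate.
# Incomplete digestion therefore biases CN low, never high.
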