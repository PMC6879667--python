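"""Re-estimate slices of the published type-I error and power grids.

Runs the simulation harness at desk scale (a fraction of the original
100,000 replicates) for one null cell and one power cell, and prints the
estimate, its Monte-Carlo standard error, and the reference value the
harness mirrors. The `flag` column marks cells more than 3 combined
standard errors from the reference.
"""

import pandas as pd

from artcombine import reproduce_table

pd.set_option("display.width", 120)

print("Type-I error at (k=10, L=100), 10,000 replicates per cell:")
t1 = reproduce_table("T1", scale=0.1, seed=1, methods=["rtp", "art", "simes"],
                     max_L=100, max_k=10)
print(t1[["method", "alpha", "estimate", "se", "printed", "flag"]]
      .to_string(index=False))

print("\nPower, constant effect 0.5 at (k=10, L=100), 5,000 replicates:")
t4 = reproduce_table("T4", scale=0.05, seed=1, methods=["rtp", "art", "simes"],
                     max_L=100, max_k=10)
print(t4[["method", "estimate", "se", "printed", "flag"]]
      .to_string(index=False))

print(
    "\nNull cells sit at the nominal level; under a shared moderate effect "
    "the\naugmented statistic (ART) edges out RTP and both dominate Simes."
)
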