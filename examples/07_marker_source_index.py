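"""Estimating a RIL population's source index from marker data.

A RIL generation enters the design with source index ~0 (half the genome
from each parent).  The realized value can be checked from a lines x
markers matrix of parental-origin calls: theta_S = 2 * (P1 alleles / total
alleles) - 1, counting two alleles per homozygous call and one per
heterozygous call, skipping missing data.  Deviation from zero indicates
segregation distortion.
"""

import numpy as np
import pandas as pd

from rilcross import MarkerMatrix, estimate_source_index_from_markers

rng = np.random.default_rng(3)
lines = [f"RIL{i:03d}" for i in range(120)]
markers = [f"m{j:02d}" for j in range(40)]
# balanced Mendelian segregation with 2% residual heterozygosity, 3% missing
calls = rng.choice(["P1", "P2", "HET", "NA"], p=[0.48, 0.47, 0.02, 0.03],
                   size=(len(lines), len(markers)))
m = MarkerMatrix(pd.DataFrame(calls, index=lines, columns=markers))

est = estimate_source_index_from_markers(m)
print(f"P1 alleles: {est.p1_alleles} of {est.total_alleles}")
print(f"estimated theta_S = {float(est.theta_S):+.4f}")
print("A value near zero supports using the idealized RIL row "
      "(theta_S = 0, theta_H = -1) in the design matrix.")
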