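"""Generation indices and the design matrix of a line cross.

Each generation of a biparental cross is summarised by a source index
(theta_S: share of the genome from parent 1, on a -1..+1 scale) and a
hybridity index (theta_H: expected heterozygosity on the same scale).  The
coefficient of an effect with a additive and d dominance factors in a
generation's expected mean is theta_S^a * theta_H^d, computed exactly.
"""

from rilcross import (ALL_NAMES, FULL_MODEL, STANDARD_GENERATIONS,
                      build_design_matrix, finite_selfing_hybridity)

print(f"{'line':>4} {'S':>4} {'H':>4} {'th_S':>5} {'th_H':>5}   "
      + "  ".join(f"{t:>4}" for t in FULL_MODEL.labels))
X = build_design_matrix(ALL_NAMES, FULL_MODEL)
for name, row in zip(ALL_NAMES, X):
    g = STANDARD_GENERATIONS[name]
    print(f"{name:>4} {str(g.S):>4} {str(g.H):>4} {str(g.theta_S):>5} "
          f"{str(g.theta_H):>5}   "
          + "  ".join(f"{str(c):>4}" for c in row))

print("\nReal RIL populations only approach full homozygosity; after t"
      " selfing generations the hybridity index is 2*(1/2)^t - 1:")
for t in (1, 4, 6, 8):
    g = finite_selfing_hybridity(t)
    print(f"  t={t}: H={float(g.H):.4f}  theta_H={float(g.theta_H):+.4f}")
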