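"""Build and compare the linear (GB) and Gaussian (GK) genomic kernels.

The linear kernel K = XX'/p is the genomic relationship matrix of GBLUP;
the Gaussian kernel exp(-h d²/median(d²)) decays with marker distance and
can express non-additive similarity.  Both are symmetric PSD matrices over
the same lines.
"""

import numpy as np

import kernelgp as kg

cfg = kg.SimConfig(n_parents=25, n_hybrids=80, p=400, s=2, seed=2)
founders, crosses = kg.simulate_founders_and_hybrids(cfg)
X = kg.standardize_markers(kg.make_hybrid_genotypes(founders, crosses))

GB = kg.linear_kernel(X)
GK = kg.gaussian_kernel(X, h=1.0)
GB.validate()
GK.validate()

print(f"GB: mean diagonal {np.diag(GB.values).mean():.3f} (≈1 by construction), "
      f"off-diagonal range [{GB.values.min():.3f}, "
      f"{GB.values[~np.eye(GB.n, dtype=bool)].max():.3f}]")
off = GK.values[np.triu_indices(GK.n, k=1)]
print(f"GK: diagonal exactly 1; off-diagonal median {np.median(off):.4f} "
      f"(= exp(-1) = {np.exp(-1):.4f} — the median pairwise distance maps there)")

# per-environment kernel: the subset for lines observed in one environment
some_lines = X.line_ids[:10]
K1 = kg.subset_kernel(GB, some_lines)
print(f"subset kernel for {len(some_lines)} lines: shape {K1.values.shape}, "
      "used as the within-environment block of the G×E covariance")
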