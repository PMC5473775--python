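"""Simulate a hybrid trial, then QC and standardize the marker matrix.

Builds founder inbreds, crosses them into F1 hybrids, filters markers on
call rate and minor allele frequency, and standardizes the surviving
columns — the input form both kernels expect.
"""

import numpy as np

import kernelgp as kg

cfg = kg.SimConfig(n_parents=30, n_hybrids=100, p=500, s=3, seed=1)
founders, crosses = kg.simulate_founders_and_hybrids(cfg)
print(f"founders: {founders.n_lines} lines x {founders.n_markers} markers "
      f"(dosages in {sorted(int(v) for v in np.unique(founders.dosages))} — "
      "inbreds are homozygous)")

# knock out a few calls so the QC has something to do
rng = np.random.default_rng(1)
founders.dosages[rng.random(founders.dosages.shape) < 0.01] = np.nan

filtered, report = kg.qc_filter_markers(
    founders, maf_threshold=0.05, call_rate_threshold=0.95, return_report=True
)
print(f"QC: {report.n_input} markers in, {report.n_removed_call_rate} removed by "
      f"call rate, {report.n_removed_maf} by MAF, {report.n_retained} retained")

imputed = kg.impute_missing(filtered)
hybrids = kg.make_hybrid_genotypes(imputed, crosses)
print(f"hybrids: {hybrids.n_lines} x {hybrids.n_markers}, dosage range "
      f"[{hybrids.dosages.min():.1f}, {hybrids.dosages.max():.1f}] "
      "(half-integers = heterozygous F1 loci)")

X = kg.standardize_markers(hybrids)
print(f"standardized X: {X.n_lines} x {X.n_markers}; "
      f"max |column mean| = {abs(X.dosages.mean(axis=0)).max():.2e}, "
      f"max |column SD - 1| = {abs(X.dosages.std(axis=0, ddof=1) - 1).max():.2e}")
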