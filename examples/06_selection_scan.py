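"""Structure-corrected outlier scan with POD-calibrated thresholds.

Population frequencies are standardized, their covariance (Omega)
absorbs shared drift, and each locus is scored by XtX (chi-square-like
differentiation) plus a whitened correlation with each climatic
covariate. Thresholds come from 20,000 neutral pseudo-observed loci.
"""

import numpy as np

import tetrapop as tp

truth, reads = tp.simulate_dataset(
    n_localities=16, n_per_pop=9, n_loci=5000,
    n_adaptive=50, effect_size=0.8, seed=23,
)
genotypes, _ = tp.call_genotypes(reads)
result = tp.scan(
    genotypes, truth.membership, truth.pops.covariates(), n_pods=20000, seed=24
)

thr = result.thresholds
print(f"XtX thresholds: 99% = {thr['xtx_99']:.1f}, 99.9% = {thr['xtx_999']:.1f}")
outliers = result.outliers("conservative")
adaptive = {f"site{j + 1}" for j in np.flatnonzero(truth.adaptive_flags)}
hits = sum(s in adaptive for s in outliers.index)
print(f"conservative outliers (XtX > 99% and |assoc| > 99.9%): {len(outliers)}")
print(f"  of which truly adaptive: {hits}")
base = len(adaptive) / len(result.table)
if len(outliers):
    print(f"  enrichment over genome-wide rate: "
          f"{hits / len(outliers) / base:.0f}-fold")
# With 1% of loci adaptive at a strong cline (effect 0.8 per covariate
# SD), the intersection criterion recovers a small, highly enriched
# outlier set - the behaviour expected of a well-calibrated scan.
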