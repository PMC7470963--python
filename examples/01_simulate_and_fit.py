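"""Simulate a BruChase-seq cohort and recover per-gene decay rates.

Generates 200 genes with known spliced/intron-retained decay rates,
simulates chase libraries at 0.5 h and 2 h (depth 1e6), normalizes by
housekeeping genes, fits the two-component mixture model, and compares
the fitted rates with the generative truth.
"""

import numpy as np
from scipy import stats

from brudecay import analyze_condition, simulate_cohort, simulate_experiment

cohort = simulate_cohort(n_genes=200, seed=42)
libraries, manifest = simulate_experiment(cohort, depth=1e6, seed=42)
result = analyze_condition(libraries, manifest, "resting")

truth = cohort.truth
genes = [g for g in result.expressed if not truth.loc[g, "is_housekeeping"]]
beta_s_hat = np.array([result.fits_mixture[g].beta_s for g in genes])
beta_s_true = truth.loc[genes, "beta_s_rest"].to_numpy()
rel_err = np.abs(beta_s_hat - beta_s_true) / beta_s_true

print(f"expressed genes (IRI <= 1, determinable rates): {len(result.expressed)}/200")
print(f"median beta_S: fitted {np.median(beta_s_hat):.3f} /h, "
      f"true {np.median(beta_s_true):.3f} /h")
print(f"median relative error of beta_S: {100 * np.median(rel_err):.1f}%")
print(f"Spearman rank correlation with truth: "
      f"{stats.spearmanr(beta_s_hat, beta_s_true).statistic:.3f}")

g = genes[0]
fit = result.fits_mixture[g]
print(f"\nexample gene {g}: beta_S = {fit.beta_s:.3f} /h, "
      f"beta_IR = {fit.beta_ir:.3f} /h, "
      f"spliced-transcript half-life = {fit.half_life:.2f} h")
print("beta_IR > beta_S: intron-retained transcripts of this gene decay "
      "faster than the spliced ones.")
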