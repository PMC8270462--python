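"""Simulate a tumor cohort and decompose it with a fixed background.

Draws a 116-sample prostate-like cohort (one dense clock-like background
plus three sparse signatures), runs the penalized decomposition at the
generating K, and scores how well the true signatures were recovered.
"""

import numpy as np

from sparsesig import (
    fit,
    fit_diagnostics,
    load_preset,
    match_signatures,
    preset,
    simulate,
)

data = simulate(preset("sim1", seed=42))
print(f"cohort: {data.counts.n_samples} samples, "
      f"{data.counts.counts.sum():.0f} mutations total")

background = load_preset("germline")
result = fit(data.counts, background, K=3, lambda_fraction=0.05, seed=42)
print(f"fit: reconstruction MSE = {result.mse:.2f}, "
      f"effective K = {result.effective_k}, lambda_max = {result.lambda_max_:.1f}")

report = match_signatures(data.true_signatures, result.signatures)
print("recovery cosine per true signature:",
      np.round(report.cosines, 4).tolist())
print("  -> values near 1 mean each generating signature was found almost exactly")

diag = fit_diagnostics(data.counts, result, sparsity_threshold=1e-3)
s = diag.summary()
print(f"explained variance = {s['explained_variance']:.4f}, "
      f"sparsity@1e-3 = {s['sparsity']:.3f}")
print(f"background contamination = {s['background_contamination']:.3f} "
      "(low = clean separation from the fixed background)")
print(f"median per-patient correlation = {s['median_per_patient_correlation']:.4f}")
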