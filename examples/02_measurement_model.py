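"""Fit the single-factor measurement model by FIML and read its fit.

The five task scores (with missing entries) load on one latent cognitive
factor; FIML uses every partially observed row.  Prints the standardized
loadings and the usual fit indices.
"""

import mimicsem as ms

cfg = ms.partial_overlap_config(n_participants=8000, seed=1)
ds = ms.generate_dataset(cfg)

spec = ms.MimicModelSpec(ds.cognition.task_names)
est = ms.fit_model(ds.cognition.scores, spec, method="fiml")
fx = ms.fit_index_set(ds.cognition.scores, spec, est)

print("standardized loadings:")
for task in ds.cognition.task_names:
    print(f"  {task:12s} {est.standardized[f'lambda:{task}']:.3f}")
print(f"chi2 = {fx.chi2:.2f}, df = {fx.df}, RMSEA = {fx.rmsea:.3f} "
      f"({fx.rmsea_lo:.3f}-{fx.rmsea_hi:.3f}), CFI = {fx.cfi:.3f}, SRMR = {fx.srmr:.3f}")
# Loadings recover the generating values (0.74 ... 0.41); the model fits
# essentially perfectly because the data follow the one-factor structure.
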