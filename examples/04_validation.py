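"""Goodness-of-fit diagnostics and model-choice calibration.

Shows the two fit diagnostics (observed P value from GLM marginal
likelihood ranking; randomized Tukey half-space depth with its P value)
on a retained cloud, then a small p_ABC vs p_empirical calibration run of
the full coalescent pipeline.
"""

import numpy as np

from invasionabc.abcfit import model_posterior
from invasionabc.popstats import SELECTED6, compute_stat_vector
from invasionabc.synthdata import make_pseudo_observed
from invasionabc.validate import (
    calibrate_model_choice,
    colonization_study,
    observed_p_value,
    tukey_p_value,
)

rng = np.random.default_rng(3)
ds, truth = make_pseudo_observed("M2", rng)
study = colonization_study()
tables = study.build_tables(800, seed=21)

sv = compute_stat_vector(ds)
idx = {n: i for i, n in enumerate(study.stat_names)}
obs = sv.values[[idx[n] for n in SELECTED6]]
post = model_posterior(tables, obs, SELECTED6, k=100)

print("fit diagnostics per model (high values = the model reproduces the data):")
for m in study.models:
    ret = post.retained[m]
    if ret.indices.size < 40:
        print(f"  {m}: too few retained simulations")
        continue
    table = tables[m]
    z = (table.stat_columns(SELECTED6)[ret.indices] - ret.center) / ret.scale
    zo = (obs - ret.center) / ret.scale
    obs_p = observed_p_value(z, table.params[ret.indices], zo)
    depth, tukey_p = tukey_p_value(zo, z, n_directions=3000, rng=np.random.default_rng(1))
    print(f"  {m}: observed P = {obs_p:.3f}, Tukey depth = {depth:.3f}, "
          f"Tukey P = {tukey_p:.3f}")

print("\nmodel-choice calibration (desk scale, 90 pods):")
report = calibrate_model_choice(
    study, n_sims=800, k=100, n_pods=90, seed=8, stat_subset=list(SELECTED6)
)
print("  bin        n   p_ABC  p_empirical")
for row in report.as_rows():
    if row["n"] == 0:
        continue
    flag = "  (<20 pods: unreliable)" if row["flagged"] else ""
    print(f"  {row['bin_lo']:.1f}-{row['bin_hi']:.1f} {row['n']:4d}  "
          f"{row['p_abc']:.2f}   {row['p_empirical']:.2f}{flag}")
print(f"  weighted slope p_empirical ~ p_ABC: {report.slope():.2f} "
      "(1.0 = perfectly calibrated)")
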