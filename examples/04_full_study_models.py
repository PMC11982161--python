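"""A full synthetic study through the dyad-level statistical stage.

Simulates dyads x 3 conversation tasks with trait-driven coupling,
computes all measures, fits the two-level mixed model (task effects with
a dyad random intercept) and one appraisal GLM, and applies
Benjamini-Hochberg correction.
"""

import pandas as pd

from speechcoord import (
    StudySimConfig,
    assemble_measures_table,
    fit_appraisal_model,
    fit_mixed_model,
    simulate_study,
    study_measures,
)

cfg = StudySimConfig(n_dyads=20, seed=42)
data = simulate_study(cfg)
table = assemble_measures_table(study_measures(data), data.traits)
print(f"measures table: {len(table)} rows ({cfg.n_dyads} dyads x 3 tasks)")

fit = fit_mixed_model(table, "rr_los", ("task",))
pd.set_option("display.width", 120)
print("\nRR_LOS ~ task + (1 | dyad):")
print(fit.coefficients.round(4).to_string(index=False))
print(f"ICC = {fit.icc:.2f}  marginal R2 = {fit.marginal_r2:.3f}  "
      f"conditional R2 = {fit.conditional_r2:.3f}  AIC = {fit.aic:.1f}")

# Appraisals: per-participant items against traits and dyad-mean coordination.
merged = (
    table.groupby("dyad_id", observed=True)[["rr_los"]].mean().reset_index()
    .merge(data.appraisals, on="dyad_id")
    .merge(data.traits, on=["dyad_id", "participant_id"])
)
afit = fit_appraisal_model(merged, "enjoyment", ("extraversion", "rr_los"), adjust=True)
print("\nenjoyment ~ extraversion + dyad-mean RR_LOS (OLS, BH-adjusted):")
print(afit.coefficients.round(4).to_string(index=False))
print("Positive betas: extraverts and well-coordinated dyads report more enjoyment,")
print("matching the effect structure the generator encodes.")
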