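"""Generate a synthetic SCLC-like cohort and compute WE scores.

Builds a 120-sample cohort with three planted DDR phenotypes, converts
TPM to per-gene z-scores, and aggregates them into per-pathway weighted
expression (WE) scores.
"""

from ddr_wescore import CohortSpec, generate_cohort, load_default_panel, we_score_pipeline

panel = load_default_panel(warn=False)
cohort = generate_cohort(CohortSpec(seed=7))
z, we = we_score_pipeline(cohort.expression, panel)

print(f"cohort: {cohort.expression.values.shape[0]} genes x "
      f"{cohort.expression.values.shape[1]} samples (TPM)")
print(f"WE scores: {we.raw.shape[0]} pathways x {we.raw.shape[1]} samples")
print("\nScaled WE scores, first 4 samples:")
print(we.scaled.iloc[:, :4].round(2))
print("\nEach cell is a pathway's standardized weighted-mean z-score for one "
      "sample;\npositive values mean the pathway's genes are expressed above "
      "the cohort average.")
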