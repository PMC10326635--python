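"""Prognostic evaluation of a candidate gene in a simulated prostatectomy cohort.

Simulates progression-free survival for 500 patients where the top expression
quartile carries a true hazard ratio of 2, then runs the full evaluation:
third-quartile dichotomization, Kaplan-Meier with log-rank, a Gleason-
stratified Cox model with categorized PSA/age/pT, and the proportional-
hazards check.
"""

from lncscreen import simulate as sim, surv

records = sim.simulate_survival_cohort(n=500, hr_expression=2.0,
                                       censor_rate=0.3, seed=42)
result = surv.evaluate_gene(records, records["expression"])

print(f"log-rank: chi2 = {result['logrank_chi2']:.2f}, "
      f"p = {result['logrank_p']:.2g}")
print("\nstratified Cox model (reference levels carry HR = 1):")
print(result["cox_table"].to_string(index=False,
                                    float_format=lambda x: f"{x:.3f}"))
print("\nproportional-hazards check (scaled Schoenfeld residuals):")
print(result["ph_check"].to_string(index=False))
# The high-expression hazard ratio should land near the simulated truth of
# 2.0; PSA > 20 and pT 5-6 carry their own planted risk. Gleason shifts only
# the baseline hazard, which the stratified fit absorbs without a coefficient.
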