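"""Why inverse-probability-of-attrition weights matter.

A frailty mixture makes some individuals both sicker and far more likely
to drop out.  Complete-case analysis then sees a too-healthy sample and
overstates disability-free life expectancy; weighting complete cases by
the inverse of their modeled completeness probability restores the
baseline composition.
"""

from cohortmslt import (AnalysisSpec, generate_panel, ipw_validation_config,
                        run_estimate, true_estimates)

config = ipw_validation_config(n=20_000)
truth = true_estimates(config)
data = generate_panel(config, seed=3)
print(f"lost to follow-up: {data.individuals['lost'].mean():.1%}")

weighted = run_estimate(data, AnalysisSpec(window=(80, 89), microsim_n=100_000,
                                           use_ipw=True), seed=4)
unweighted = run_estimate(data, AnalysisSpec(window=(80, 89), microsim_n=100_000,
                                             use_ipw=False), seed=4)

print(f"true DFLE (ages 80-89):        {truth.dfle:.3f} years")
print(f"IP-weighted estimate:          {weighted.dfle:.3f}")
print(f"unweighted estimate:           {unweighted.dfle:.3f}")
print("The unweighted estimate is biased upward because the frail leave "
      "the study; the weighted one sits much closer to the truth.")
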