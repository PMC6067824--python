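"""Construct the priors for prevalence and diagnostic sensitivity.

The prevalence chain discounts a 0.5% national 1-year schizophrenia
prevalence for homelessness (20% of true cases never contact the system) and
treatment adherence (50% attend visits), giving the prevalence one could hope
to observe in claims. The shortfall of the documented rate (0.13%) against
that observable rate implies the sensitivity of the recorded diagnosis.
"""

from underdx import (PrevalenceChain, derive_prevalence_chain,
                     elicit_prevalence_prior, elicit_sensitivity_prior,
                     reference_scenarios)

chain = derive_prevalence_chain(PrevalenceChain(
    national_prevalence=0.005, homeless_fraction=0.20,
    adherence_fraction=0.50, documented_prevalence=0.0013))
print(f"treated prevalence:    {chain.treated_prevalence:.2%}")
print(f"observable prevalence: {chain.observable_prevalence:.2%}")
print(f"underreporting gap:    {chain.underreporting_gap:.2%}")
print(f"sensitivity:           {chain.sensitivity:.0%}")
print(f"underdiagnosis rate:   {chain.underdiagnosis_rate:.0%}")
# -> 0.20% observable, 0.07% gap: only 65% of true cases carry the code.

# Beta priors: sensitivity by mean + effective sample size (30 pseudo-
# observations, mildly informative); prevalence as Beta(1, b) for small rates.
s_prior = elicit_sensitivity_prior(mean=chain.sensitivity, ess=30)
theta_prior = elicit_prevalence_prior(mean=chain.observable_prevalence)
print(f"\nsensitivity prior: Beta({s_prior.alpha:g}, {s_prior.beta:g})")
print(f"prevalence prior:  Beta({theta_prior.alpha:g}, {theta_prior.beta:g})")

print("\nbuilt-in scenarios (prevalence / sensitivity prior means):")
for name, sc in reference_scenarios().items():
    print(f"  {name:<9} theta ~ Beta({sc.prevalence_prior.alpha:g}, "
          f"{sc.prevalence_prior.beta:g}) mean {sc.prevalence_prior.mean:.4%}; "
          f"s ~ Beta({sc.sensitivity_prior.alpha:g}, {sc.sensitivity_prior.beta:g}) "
          f"mean {sc.sensitivity_prior.mean:.0%}")
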