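"""Fit the two competing models to one simulated sample.

Simulates n=500 continuous indicator vectors under the single-trait--
multistate population model, computes the Pearson correlation matrix, and
fits both the multistate model (no trait, no threat; orthogonal states)
and the single-trait--multistate model (trait f0 on all states, threat T
on states 3-4) by maximum likelihood.
"""

import validitysim as vs

params = vs.default_params()
data = vs.simulate_sample(params, n=500, seed=42)
r = vs.pearson_matrix(data)

fit1 = vs.fit(vs.model1_spec(), r, n=500)
fit2 = vs.fit(vs.model2_spec(), r, n=500)
delta = vs.delta_chi2_test(fit1, fit2)

for label, f in (("Model 1 (multistate)", fit1),
                 ("Model 2 (trait + threat)", fit2)):
    print(f"{label}: chi2({f.df}) = {f.chi2:.2f}, p = {f.p_value:.4f}, "
          f"RMSEA = {f.rmsea:.4f}")
print(f"Delta chi2({delta.delta_df}) = {delta.delta_chi2:.2f}, "
      f"p = {delta.p_value:.2e}, significant: {delta.significant}")

print()
print("Model 1 ignores the trait/threat covariance across states, so its")
print("exact-fit test rejects; Model 2 is correctly specified and fits.")
print("The significant chi-square difference says the threat-augmented")
print("model explains the data significantly better.")
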