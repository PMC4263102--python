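"""Decompose a decay-constant distribution into Gaussian subpopulations.

Samples 2000 decay constants from the published EGFP- generative mixture,
fits the erf-sum cumulative model, lets the order-selection procedure
choose the number of components, and compares the two cell populations
with a Kolmogorov-Smirnov test.
"""

import numpy as np

from ipsckit import (
    f_test_extra_component, fit_mixture_cdf, ks_two_sample,
    sample_decay_mixture, select_mixture_order,
)
from ipsckit import params as P

taus_neg = sample_decay_mixture(P.MIXTURE_EGFP_NEG, 2000, seed=1)
taus_pos = sample_decay_mixture(P.MIXTURE_EGFP_POS, 2000, seed=2)

model = select_mixture_order(taus_neg, max_n=4, alpha=1e-4, seed=0)
print(f"order selection on EGFP- sample: n = {model.n} components")
print("  component   weight   mean(ms)   sd(ms)     generative")
for i in range(model.n):
    gen = (P.MIXTURE_EGFP_NEG.weights[i], P.MIXTURE_EGFP_NEG.means[i],
           P.MIXTURE_EGFP_NEG.sds[i])
    print(f"       {i+1}      {model.weights[i]:5.2f}   {model.means[i]:8.1f} "
          f"{model.sds[i]:8.1f}     {gen}")

m2 = fit_mixture_cdf(taus_neg, 2, seed=0)
m3 = fit_mixture_cdf(taus_neg, 3, seed=0)
ft = f_test_extra_component(m2, m3)
print(f"F-test, 2 vs 3 components: F = {ft.F:.1f}, p = {ft.p:.2e} "
      f"(third component {'accepted' if ft.accept_extra else 'rejected'})")

d, p = ks_two_sample(taus_neg, taus_pos)
print(f"KS comparison of the two cell populations: D = {d:.3f}, p = {p:.2e}")
print("the shift reflects the heavier slow subpopulation in inhibitory "
      "(EGFP+) interneurons (weight 0.39 at 249 ms vs 0.20 at 184 ms)")
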