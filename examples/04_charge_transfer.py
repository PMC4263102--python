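"""Fast/slow charge-transfer analysis of a simulated drug experiment.

Emulates the benzodiazepine-site experiment: miniature events are split at
the 100-ms weighted-decay boundary into fast and slow categories, and the
summed charge over matched 10-minute windows is compared between control
and drug conditions.  Here the simulated drug selectively potentiates the
slow subpopulation (charge x1.4 via slower decay).
"""

import numpy as np
import pandas as pd

from ipsckit import categorize_events, delta_charge, sample_decay_mixture
from ipsckit import params as P

rng = np.random.default_rng(0)
n = 120
tau_w = sample_decay_mixture(P.MIXTURE_EGFP_NEG, n, seed=3)
amp = rng.lognormal(np.log(18.0), 0.3, n)
ctrl = pd.DataFrame({
    "onset_ms": np.sort(rng.uniform(0, 600e3, n)),
    "amplitude_pA": amp,
    "tau_w_ms": tau_w,
    "charge_pA_ms": amp * tau_w,   # monoexponential events carry A*tau
    "event_id": np.arange(n),
})

drug = ctrl.copy()
slow = drug["tau_w_ms"] > 100.0
drug.loc[slow, "tau_w_ms"] *= 1.4
drug.loc[slow, "charge_pA_ms"] *= 1.4

fast_ev, slow_ev = categorize_events(ctrl)
print(f"control: {len(fast_ev)} fast / {len(slow_ev)} slow events "
      "(boundary 100 ms on the weighted decay constant)")

rep = delta_charge(ctrl, drug, window_s=600.0)
for cat in ("fast", "slow"):
    r = rep[cat]
    print(f"{cat:>5}: delta charge {r.delta_charge:.2f}  "
          f"(frequency x{r.frequency_ratio:.2f}, amplitude x{r.amplitude_ratio:.2f}, "
          f"mean tau x{r.mean_tau_ratio:.2f})")
print(f"category migration (tau_w crossing 100 ms): {rep['migration']} events")
print("a delta charge > 1 confined to the slow category is the signature of "
      "a drug acting on the receptors behind the slow subpopulation")
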