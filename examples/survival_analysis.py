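"""Force-clamp survival analysis on synthetic lifetime data.

Draws bond lifetimes from the exact stochastic kinetics at two clamp
forces, estimates the survival probability with the product-limit
estimator (events outliving the 10 s clamp are right-censored), fits
mono- and bi-exponential decays and lets an F-test pick between them.
"""

import numpy as np

from tipbond import empirical_survival, fit_exponential, select_model_ftest
from tipbond.params import INTERFACE_WT
from tipbond.synth import generate_lifetime_dataset

datasets = generate_lifetime_dataset(
    INTERFACE_WT, forces=[28.0, 103.0], n_per_force=200, seed=7,
    bi_exp_highforce=True, max_duration=10.0,
)

for ds in datasets:
    surv = empirical_survival(ds)
    fit1 = fit_exponential(surv, order=1)
    fit2 = fit_exponential(surv, order=2)
    order = select_model_ftest(fit1, fit2, alpha=0.05)
    print(f"clamp force {ds.clamp_force:5.0f} pN: {ds.n_events} events, "
          f"{int(ds.censored.sum())} censored")
    print(f"  mono-exponential tau = {fit1.taus[0]:.3f} s (rss {fit1.rss:.4f})")
    print(f"  bi-exponential  taus = {fit2.taus[0]:.3f}, {fit2.taus[1]:.3f} s "
          f"(amplitudes {fit2.amplitudes[0]:.2f}/{fit2.amplitudes[1]:.2f}, "
          f"rss {fit2.rss:.4f})")
    print(f"  F-test picks order {order}\n")

print("At low force a single decay suffices; at high force the short-lived "
      "second component (failed rebinding) makes the bi-exponential win.")
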