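"""The simulate-fit-extrapolate route, checked against the closed form.

Values like P*(1000) ~ 1e-262 cannot be counted by any simulation; the
published procedure fits the exponential decay of P(C,n) and sums the
fitted geometric tail.  Here the route is run twice for the in vitro model:

* on a Monte Carlo ensemble (4e5 pili, bins with >= 10 correct counts),
  mirroring what can actually be measured from simulation output; and
* on the exact P(C,n) over the asymptotic window n in [20, 60], where the
  fitted slope has the closed form ln p_AA = ln(45.8/83.9).

Extrapolations are then compared with the exact tail sums.  The MC-window
fit sits on the shallow, pre-asymptotic part of the decay (its bins stop
near n ~ 20), so its far extrapolation overshoots; the analytic-window fit
reproduces the exact P*(100) to two decimals in log10.
"""

import math
from pathlib import Path

import pandas as pd

from pilusim import (
    builtin_table,
    correct_pmf,
    empirical_pmf,
    extrapolate_p_star,
    fit_decay,
    p_star_closed_form,
    simulate_ensemble,
    transition_model,
)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

model = transition_model(builtin_table("in_vitro"))
exact = {m: p_star_closed_form(model, m).log10_p_star for m in (100, 1000)}

rows = []

summary = simulate_ensemble(model, 400_000, seed=99)
mc_fit = fit_decay(empirical_pmf(summary))
for m in (100, 1000):
    res = extrapolate_p_star(mc_fit, m)
    rows.append(
        {"fit": "monte_carlo_bins", "n_lo": mc_fit.n_lo, "n_hi": mc_fit.n_hi,
         "slope": mc_fit.slope, "n_min": m,
         "log10_p_star": res.log10_p_star, "log10_se": res.log10_se,
         "log10_exact": exact[m]}
    )

an_fit = fit_decay(correct_pmf(model, 80), n_range=(20, 60))
for m in (100, 1000):
    res = extrapolate_p_star(an_fit, m)
    rows.append(
        {"fit": "analytic_window", "n_lo": an_fit.n_lo, "n_hi": an_fit.n_hi,
         "slope": an_fit.slope, "n_min": m,
         "log10_p_star": res.log10_p_star, "log10_se": res.log10_se,
         "log10_exact": exact[m]}
    )

frame = pd.DataFrame(rows)
frame.to_csv(OUT / "fit_extrapolation.tsv", sep="\t", index=False)
print(frame.to_string(index=False, float_format=lambda v: f"{v:.4g}"))

slope_exact = math.log(45.8 / 83.9)
print(
    f"\nAsymptotic slope: analytic-window fit {an_fit.slope:.5f} vs "
    f"ln(45.8/83.9) = {slope_exact:.5f} "
    f"({abs(an_fit.slope/slope_exact-1)*100:.2f}% off); MC-window fit "
    f"{mc_fit.slope:.4f} over n in [{mc_fit.n_lo}, {mc_fit.n_hi}] is "
    "shallower because counted bins end before the asymptote. "
    f"Exact tails: log10 P*(100) = {exact[100]:.2f}, "
    f"log10 P*(1000) = {exact[1000]:.2f}."
)
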