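"""How long does a 100-subunit pilus take under the in vitro rates?

Three routes to the same quantity:

* closed form along the canonical correct path (one PapE, then PapA rod);
* the exact conditional expectation over all paths that reach 100 subunits;
* conditioned kinetic Monte Carlo (1e4 pili sampled from the exact
  conditional path law, exponential waiting times at the unconditioned
  exit rates).

All three land at 1.3-1.4e3 h — the same order as the published ~2000 h
estimate and five orders of magnitude slower than the minutes observed in
vivo, which is the quantitative case for a catalytic usher.
"""

from pathlib import Path

import pandas as pd

from pilusim import (
    builtin_table,
    conditional_mean_reaching_time,
    expected_assembly_time,
    reaching_probability,
    transition_model,
)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

model = transition_model(builtin_table("in_vitro"))
target = 100

correct_path = expected_assembly_time(model, target, mode="correct_path")
exact_cond = conditional_mean_reaching_time(model, target)
mc = expected_assembly_time(
    model, target, mode="simulated_reachers", n_pili=10_000, seed=2024
)
reach_p = reaching_probability(model, target)

frame = pd.DataFrame(
    [
        {"route": "correct_path_closed_form", "mean_h": correct_path.mean_h, "se_h": 0.0},
        {"route": "conditional_expectation", "mean_h": exact_cond, "se_h": 0.0},
        {"route": "conditioned_monte_carlo", "mean_h": mc.mean_h, "se_h": mc.se_h},
    ]
)
frame.to_csv(OUT / "assembly_time.tsv", sep="\t", index=False)
print(frame.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print(
    f"\nOnly a fraction {reach_p:.3g} of unconditioned pili ever reach "
    f"{target} subunits, so the Monte Carlo samples the exact conditional "
    "path law instead of rejection-sampling. "
    f"Mean time to {target} subunits: {mc.mean_h:.0f} +- {mc.se_h:.0f} h "
    "(~2 months), versus minutes in vivo."
)
assert abs(mc.mean_h - exact_cond) < 4 * mc.se_h
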