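"""Reproduce the headline table of tail probabilities P*.

P* is the probability that a pilus is correctly ordered (G F E+ K A+ H) and
at least n_min subunits long.  The closed form on the embedded chain is
exact; a Monte Carlo cross-check is run for the one case where P* is large
enough to count directly (the fast/slow scheme R at n_min = 100).
"""

import math
from pathlib import Path

from pilusim import p_star_closed_form, run_table1, simulate_ensemble
from pilusim.scenarios import CASES, build_model

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

frame = run_table1(method="closed_form")
frame.to_csv(OUT / "table1.tsv", sep="\t", index=False)
print(frame.to_string(index=False, float_format=lambda v: f"{v:.4g}"))

# Monte Carlo cross-check of case R, n_min = 100
model = build_model(CASES["R"])
n = 200_000
summary = simulate_ensemble(model, n, seed=12345, length_cap=20_000)
cc = summary.correct_count_by_length
frac = cc[cc.index >= 100].sum() / n
exact = p_star_closed_form(model, 100).p_star
se = math.sqrt(exact * (1 - exact) / n)
print(
    f"\nMC cross-check, case R n_min=100: {frac:.5f} vs closed form "
    f"{exact:.5f} (binomial SE {se:.5f}, deviation {(frac-exact)/se:+.2f} SE)"
)
assert abs(frac - exact) < 4 * se

print(
    "\nReading: random growth (equal) and the measured in vitro rates leave "
    "P* negligible at any biologically useful length; a 1000-fold cognate "
    "preference (R) or a 200-fold PapA excess (C) rescues it."
)
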