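"""Exact length and correct-sequence distributions (the two decay curves).

For the equal-rates and in vitro conditions, tabulates P(n) and P(C,n) up
to n = 300 and reports the asymptotic per-subunit decay of each: both decay
exponentially, and P(C,n) always decays faster than P(n) because a correct
pilus must avoid every out-of-order donation while any pilus merely has to
avoid the terminator.
"""

import math
from pathlib import Path

import numpy as np

from pilusim import builtin_table, distributions, transition_model

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

for name in ("equal", "in_vitro"):
    model = transition_model(builtin_table(name))
    table = distributions(model, 300)
    table.write_tsv(OUT / f"distributions_{name}.tsv")
    slope_pn = (table.log_P_n[-1] - table.log_P_n[-51]) / 50 / math.log(10)
    slope_pcn = (table.log_P_Cn[-1] - table.log_P_Cn[-51]) / 50 / math.log(10)
    total = np.exp(table.log_P_n).sum()
    print(
        f"{name:9s} sum P(n<=300) = {total:.6f}  "
        f"asymptotic d log10/dn: P(n) {slope_pn:.4f}, P(C,n) {slope_pcn:.4f}"
    )
    assert slope_pcn <= slope_pn + 1e-12

print(
    "\nUnder equal rates the correct-pilus curve falls ~0.7 decades per "
    "subunit (a factor 1/5 each step); the in vitro rates soften that to "
    f"{math.log10(45.8/83.9):.3f} decades per subunit (ln p_AA), which is "
    "still hopeless at rod lengths of hundreds of subunits."
)
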