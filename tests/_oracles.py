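"""Independent brute-force oracles used across the test suite.

The enumeration oracle walks every donor sequence of a given total length
and accumulates path probabilities directly from the transition matrix; it
shares nothing with the closed-form or propagation code paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

SUB = ("G", "F", "E", "K", "A", "H")
H = 5


def pattern_is_correct(seq: str) -> bool:
    """Plain-loop check of G F E+ K A+ H (independent of the package regex)."""
    if len(seq) < 6 or seq[0] != "G" or seq[1] != "F" or seq[-1] != "H":
        return False
    body = seq[2:-1]
    i = 0
    while i < len(body) and body[i] == "E":
        i += 1
    if i == 0:
        return False
    if i >= len(body) or body[i] != "K":
        return False
    j = i + 1
    if j >= len(body):
        return False
    return all(c == "A" for c in body[j:])


def enumerate_pmfs(p: np.ndarray, max_len: int) -> tuple[dict, dict]:
    """Exact P(n) and P(C,n) for n in [2, max_len] by path enumeration.

    ``p`` is the 6x6 embedded-chain matrix.  Sequences with PapH anywhere
    but last get probability zero automatically (the PapH row is zero).
    """
    P_n: dict[int, float] = {}
    P_Cn: dict[int, float] = {}
    donors = np.arange(1, 6)  # F, E, K, A, H (G never donates)
    for n in range(2, max_len + 1):
        combos = np.array(
            list(itertools.product(donors, repeat=n - 1)), dtype=np.int64
        ).reshape(-1, n - 1)
        states = np.concatenate(
            [np.zeros((combos.shape[0], 1), dtype=np.int64), combos[:, :-1]], axis=1
        )
        probs = p[states, combos].prod(axis=1)
        ends_h = combos[:, -1] == H
        P_n[n] = float(probs[ends_h].sum())
        total_c = 0.0
        for row, pr in zip(combos[ends_h], probs[ends_h]):
            if pr > 0 and pattern_is_correct("G" + "".join(SUB[d] for d in row)):
                total_c += float(pr)
        P_Cn[n] = total_c
    return P_n, P_Cn


def log_or_neg_inf(x: float) -> float:
    return math.log(x) if x > 0 else -math.inf
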