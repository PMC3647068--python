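"""Exact analytics on the embedded Markov chain of pilus growth.

Growth is a competition of first-order DSE events: a pilus ending in acceptor
``A`` is extended by donor ``D`` at rate ``[D] * k_AD``.  Because competing
exponential clocks are memoryless, the identity of the next subunit and the
waiting time are independent: the embedded (discrete-time) chain has

    p[A][D] = [D] k_AD / sum_D' [D'] k_AD',

and the waiting time in state ``A`` is exponential with the total exit rate
``sum_D' [D'] k_AD'`` (in 1/h; rate tables are stored in 1e-3/h).  PapH is
absorbing: once it caps the pilus, growth stops.

The chain starts with PapG already assembled at position 1 (the adhesin
initiates the fiber); the pilus length ``n`` counts every subunit including
the terminal PapH.  A pilus is "correct" when its sequence reads
``G F E^i K A^j H`` with ``i, j >= 1``.

All probability arithmetic is carried out in natural-log space so that tail
probabilities down to 1e-700 remain representable; results are reported in
log10.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .rate_model import ConcentrationProfile, RateTable, uniform_profile
from .subunits import INDEX, SUBUNITS, TRANSIENT

__all__ = [
    "TransitionModel",
    "DistributionTable",
    "PStarResult",
    "AssemblyTime",
    "StallWarning",
    "transition_model",
    "length_pmf",
    "correct_pmf",
    "distributions",
    "p_star_closed_form",
    "expected_assembly_time",
    "conditional_mean_reaching_time",
    "reaching_probability",
]

LOG10 = math.log(10.0)


class StallWarning(UserWarning):
    """A reachable acceptor state has zero total exit rate (growth stalls)."""


@dataclass(frozen=True)
class TransitionModel:
    """Embedded-chain transition probabilities and exit rates.

    ``p`` is a 6x6 acceptor x donor matrix of next-subunit probabilities
    (PapH row all zero: absorbing).  ``exit_rate`` is the total DSE event
    rate per acceptor in 1/h.  ``stalled`` lists non-PapH acceptors whose
    effective rate row is zero; growth reaching them terminates without a
    terminator and is never counted as correct.
    """

    p: pd.DataFrame
    exit_rate: pd.Series
    stalled: tuple[str, ...] = ()
    initial: str = "G"
    name: str = "custom"

    def prob(self, acceptor: str, donor: str) -> float:
        return float(self.p.at[acceptor, donor])

    def matrix(self) -> np.ndarray:
        return self.p.to_numpy(dtype=float)

    def rates(self) -> np.ndarray:
        return self.exit_rate.to_numpy(dtype=float)


def transition_model(
    table: RateTable,
    conc: ConcentrationProfile | None = None,
    name: str | None = None,
) -> TransitionModel:
    """Build the embedded chain from a rate table and a concentration profile.

    Exit rates are converted to 1/h (table values are in 1e-3/h, multiplied
    by the dimensionless relative concentration of the donor).  Rescaling the
    whole profile by a common factor changes exit rates but leaves every
    transition probability unchanged.
    """
    conc = conc or uniform_profile()
    eff = table.values() * conc.values()[None, :]
    row = eff.sum(axis=1)
    p = np.zeros_like(eff)
    nz = row > 0
    p[nz] = eff[nz] / row[nz, None]
    stalled = tuple(s for s in TRANSIENT if row[INDEX[s]] == 0)
    if stalled:
        warnings.warn(
            f"stall state(s) {', '.join(stalled)}: zero total DSE rate; growth "
            "reaching them terminates without PapH",
            StallWarning,
            stacklevel=2,
        )
    return TransitionModel(
        p=pd.DataFrame(p, index=list(SUBUNITS), columns=list(SUBUNITS)),
        exit_rate=pd.Series(row * 1e-3, index=list(SUBUNITS)),
        stalled=stalled,
        name=name or table.name,
    )


@dataclass
class DistributionTable:
    """Log-space pilus length distribution P(n) and correct-and-length P(C,n).

    Natural-log probabilities indexed by length ``n`` from 2 to ``n_max``;
    ``-inf`` marks exact zeros.  Either column may be absent (None) when only
    one of the two distributions was computed.
    """

    n: np.ndarray
    log_P_n: np.ndarray | None = None
    log_P_Cn: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"n": self.n})
        if self.log_P_n is not None:
            frame["P_n"] = np.exp(self.log_P_n)
            frame["log10_P_n"] = self.log_P_n / LOG10
        if self.log_P_Cn is not None:
            frame["P_Cn"] = np.exp(self.log_P_Cn)
            frame["log10_P_Cn"] = self.log_P_Cn / LOG10
        return frame

    def write_tsv(self, path) -> None:
        frame = self.to_frame()
        cols = ["n", "P_n", "P_Cn", "log10_P_n", "log10_P_Cn"]
        frame.reindex(columns=[c for c in cols if c in frame]).to_csv(
            path, sep="\t", index=False
        )


@dataclass(frozen=True)
class PStarResult:
    """Log10 probability that a pilus is correct and at least n_min long."""

    log10_p_star: float
    n_min: int
    method: str
    log10_se: float | None = None

    @property
    def p_star(self) -> float:
        return 10.0 ** self.log10_p_star


def _log_transient_matrix(model: TransitionModel) -> tuple[np.ndarray, np.ndarray]:
    """(log transient-to-transient matrix, log transition-to-H vector)."""
    p = model.matrix()
    with np.errstate(divide="ignore"):
        log_tt = np.log(p[:5, :5])
        log_h = np.log(p[:5, INDEX["H"]])
    return log_tt, log_h


def length_pmf(model: TransitionModel, n_max: int) -> DistributionTable:
    """Exact P(n) for n in [2, n_max] by log-space state-vector propagation.

    P(n) is the probability that PapH is first appended at position n, with
    PapG occupying position 1.  Mass lost to stall states simply never
    reaches PapH, so the column can sum to less than one.
    """
    if n_max < 2:
        raise ValueError("n_max must be >= 2")
    log_tt, log_h = _log_transient_matrix(model)
    log_v = np.full(5, -np.inf)
    log_v[INDEX[model.initial]] = 0.0
    out = np.empty(n_max - 1)
    for i in range(n_max - 1):
        out[i] = logsumexp(log_v + log_h)
        if i < n_max - 2:
            log_v = logsumexp(log_v[:, None] + log_tt, axis=0)
    return DistributionTable(n=np.arange(2, n_max + 1), log_P_n=out)


def _correct_chain_logs(model: TransitionModel) -> tuple[float, float, float]:
    """(log c0, log p[E][E], log p[A][A]) for the correct-sequence family.

    c0 is the probability product along the obligatory transitions
    G->F, F->E, E->K, K->A, A->H of a correct pilus.
    """
    with np.errstate(divide="ignore"):
        log_c0 = sum(
            math.log(model.prob(a, d)) if model.prob(a, d) > 0 else -math.inf
            for a, d in (("G", "F"), ("F", "E"), ("E", "K"), ("K", "A"), ("A", "H"))
        )
    pee = model.prob("E", "E")
    paa = model.prob("A", "A")
    log_pee = math.log(pee) if pee > 0 else -math.inf
    log_paa = math.log(paa) if paa > 0 else -math.inf
    return log_c0, log_pee, log_paa


def _log_composition_sum(m: np.ndarray, log_a: float, log_b: float) -> np.ndarray:
    """log sum_{i+j=m+1, i,j>=1} a^(j-1) b^(i-1), vectorised over m >= 1.

    Closed form (a^m - b^m)/(a - b), or m * a^(m-1) in the degenerate a == b
    case.  ``a`` denotes the larger of the two stay probabilities.
    """
    m = np.asarray(m, dtype=float)
    if log_b > log_a:
        log_a, log_b = log_b, log_a
    if log_a == -math.inf:  # both zero: only m == 1 contributes
        return np.where(m == 1, 0.0, -np.inf)
    a = math.exp(log_a)
    b = math.exp(log_b)
    if a - b < 1e-12 * a:  # degenerate: equal stay probabilities
        return np.log(m) + (m - 1) * log_a
    with np.errstate(divide="ignore"):
        ratio = m * (log_b - log_a)  # log (b/a)^m, -inf when b == 0
        return m * log_a + np.log1p(-np.exp(ratio)) - math.log(a - b)


def correct_pmf(model: TransitionModel, n_max: int) -> DistributionTable:
    """Exact P(C,n) for n in [2, n_max] from the closed-form composition sum.

    A correct pilus of length n >= 6 decomposes as G F E^i K A^j H with
    i + j = n - 4; its probability is c0 * p_EE^(i-1) * p_AA^(j-1) summed
    over compositions.  Lengths below 6 have probability zero.
    """
    if n_max < 6:
        raise ValueError("n_max must be >= 6")
    log_c0, log_pee, log_paa = _correct_chain_logs(model)
    n = np.arange(2, n_max + 1)
    out = np.full(n.shape, -np.inf)
    mask = n >= 6
    out[mask] = log_c0 + _log_composition_sum(n[mask] - 5, log_paa, log_pee)
    return DistributionTable(n=n, log_P_Cn=out)


def distributions(model: TransitionModel, n_max: int) -> DistributionTable:
    """P(n) and P(C,n) on a common length grid."""
    table = length_pmf(model, n_max)
    table.log_P_Cn = correct_pmf(model, n_max).log_P_Cn
    return table


def p_star_closed_form(model: TransitionModel, n_min: int) -> PStarResult:
    """Exact log10 of P* = sum_{n >= n_min} P(C,n), no truncation error.

    Summing the composition closed form over n gives, with a = p_AA,
    b = p_EE and M = max(n_min, 6) - 5,

        P* = c0 * [a^M/(1-a) - b^M/(1-b)] / (a - b),

    with the obvious degenerate limit when a == b.  Requires a, b < 1
    (otherwise PapH is unreachable and the chain never terminates).
    """
    if n_min < 2:
        raise ValueError("n_min must be >= 2")
    log_c0, log_pee, log_paa = _correct_chain_logs(model)
    if log_pee >= 0.0 or log_paa >= 0.0:
        raise ValueError(
            "non-terminating chain: p[E][E] and p[A][A] must be < 1 for the "
            "geometric tails to converge"
        )
    m_min = max(n_min, 6) - 5
    log_a, log_b = max(log_paa, log_pee), min(log_paa, log_pee)
    if log_a == -math.inf:
        # only the minimal pilus GFEKAH exists
        log_sum = 0.0 if m_min <= 1 else -math.inf
    else:
        a, b = math.exp(log_a), math.exp(log_b)
        if a - b < 1e-12 * a:
            # sum_{m >= M} m a^(m-1) = a^(M-1) (M (1-a) + a) / (1-a)^2
            log_sum = (
                (m_min - 1) * log_a
                + math.log(m_min * (1 - a) + a)
                - 2 * math.log1p(-a)
            )
        else:
            # log [a^M/(1-a)] and log [b^M/(1-b)]
            t_a = m_min * log_a - math.log1p(-a)
            t_b = m_min * log_b - math.log1p(-b) if log_b > -math.inf else -math.inf
            log_sum = t_a + math.log1p(-math.exp(t_b - t_a)) - math.log(a - b)
    log10_p = (log_c0 + log_sum) / LOG10
    return PStarResult(log10_p_star=log10_p, n_min=n_min, method="closed_form")


# ---------------------------------------------------------------------------
# Assembly times
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssemblyTime:
    """Mean time (hours) to assemble a pilus of a target length."""

    mean_h: float
    target_length: int
    mode: str
    se_h: float = 0.0
    n_pili: int | None = None


def _canonical_states(target_length: int) -> list[str]:
    """Acceptor states waited in along the minimal-PapE correct sequence,
    truncated to ``target_length`` subunits: G F E K A A ... (one wait per
    subunit addition, i.e. target_length - 1 waits)."""
    seq = ["G", "F", "E", "K"] + ["A"] * max(0, target_length - 5)
    return seq[: target_length - 1]


def expected_assembly_time(
    model: TransitionModel,
    target_length: int,
    mode: str = "correct_path",
    n_pili: int = 10_000,
    seed: int = 0,
) -> AssemblyTime:
    """Mean time for a pilus to reach ``target_length`` subunits.

    ``correct_path``
        Closed form: the sum of mean exponential waiting times 1/exit_rate
        along the canonical correct sequence (single PapE, then PapA run).
    ``simulated_reachers``
        Monte Carlo mean over simulated pili conditioned on reaching at
        least ``target_length`` subunits (see ``growth.simulate_reaching_times``),
        with its standard error.
    """
    if target_length < 2:
        raise ValueError("target_length must be >= 2")
    if mode == "correct_path":
        rates = model.exit_rate
        states = _canonical_states(target_length)
        stalled = [s for s in states if rates[s] == 0]
        if stalled:
            raise ValueError(
                f"target length {target_length} unreachable: stall state(s) "
                f"{', '.join(sorted(set(stalled)))} on the canonical path"
            )
        total = float(sum(1.0 / rates[s] for s in states))
        return AssemblyTime(mean_h=total, target_length=target_length, mode=mode)
    if mode == "simulated_reachers":
        from .growth import simulate_reaching_times

        times = simulate_reaching_times(model, target_length, n_pili, seed)
        return AssemblyTime(
            mean_h=float(times.mean()),
            se_h=float(times.std(ddof=1) / math.sqrt(len(times))),
            target_length=target_length,
            mode=mode,
            n_pili=n_pili,
        )
    raise ValueError(f"unknown mode {mode!r}")


def _survival_profile(model: TransitionModel, target_length: int) -> np.ndarray:
    """S[k, s]: probability of reaching length >= target_length given the
    chain occupies transient state s at position k (k = 1..target_length-1).

    Positions 2..target-1 must be transient; the target-position subunit may
    be anything, including the terminator, so S at position target-1 is one
    for every state that can exit at all (zero for stall states, whose
    all-zero rows also propagate zeros backwards).
    """
    p_tt = model.matrix()[:5, :5]
    L = target_length
    S = np.zeros((L, 5))
    S[L - 1] = (model.rates()[:5] > 0).astype(float)
    for k in range(L - 2, 0, -1):
        S[k] = p_tt @ S[k + 1]
    return S


def reaching_probability(model: TransitionModel, target_length: int) -> float:
    """Probability an unconditioned pilus reaches ``target_length`` subunits."""
    if target_length < 2:
        return 1.0
    S = _survival_profile(model, target_length)
    return float(S[1, INDEX[model.initial]])


def conditional_mean_reaching_time(
    model: TransitionModel, target_length: int
) -> float:
    """Exact E[time to reach target | pilus reaches target], in hours.

    Waiting times are independent of the path event, so the conditional mean
    is the sum over positions of the conditional state occupancy divided by
    the exit rate.  Used as the analytic cross-check of the conditioned
    Monte Carlo in ``growth.simulate_reaching_times``.
    """
    if target_length < 2:
        raise ValueError("target_length must be >= 2")
    S = _survival_profile(model, target_length)
    if S[1, INDEX[model.initial]] <= 0:
        raise ValueError(f"target length {target_length} unreachable")
    rates = model.rates()[:5]
    p_tt = model.matrix()[:5, :5]
    q = np.zeros(5)
    q[INDEX[model.initial]] = 1.0
    total = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_rates = np.where(rates > 0, 1.0 / np.where(rates > 0, rates, 1.0), 0.0)
    for k in range(1, target_length):
        total += float(q @ inv_rates)
        if k < target_length - 1:
            w = p_tt * S[k + 1][None, :]
            rows = w.sum(axis=1)
            denom = np.where(rows[:, None] > 0, rows[:, None], 1.0)
            q = q @ np.where(rows[:, None] > 0, w / denom, 0.0)
    return total
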