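# Methods

## Model

P-pilus growth is modelled as a competition of first-order donor-strand-
exchange (DSE) events.  A growing pilus ending in acceptor subunit *A*
(as a chaperone:subunit complex) is extended by donor *D* at rate
[*D*]·k<sub>AD</sub>, where k<sub>AD</sub> is the apparent pseudo-first-order DSE rate
constant (stored in the printed unit 10⁻³ h⁻¹ and converted to h⁻¹ only
where waiting times are computed) and [*D*] is a dimensionless relative
concentration.  The model assumes:

* irreversible DSE (subunit–subunit complexes are kinetically stable);
* rates independent of the pilus history (only the terminal subunit
  matters);
* unlimited subunit pools (concentrations are not depleted by growth);
* two structural zeros — PapG never donates and PapH never accepts — so
  PapH is absorbing and terminates growth.

Competing exponential clocks make the embedded chain explicit: the next
subunit is *D* with probability

p(A→D) = [D]·k<sub>AD</sub> / Σ<sub>D′</sub> [D′]·k<sub>AD′</sub>,

independent of the waiting time, which is exponential with the row's total
rate.  The chain starts with PapG already assembled at position 1, and the
length *n* counts every subunit including the terminal PapH.  A pilus is
*correct* when its sequence reads G F Eⁱ K Aʲ H with i, j ≥ 1.  These three
conventions (initiation, length, correctness) are the ones under which the
closed form reproduces the published fast/slow-scheme tail probabilities
(0.17 at n_min = 100) exactly; the source text does not state them
explicitly, and its equal-rates entries are not consistent with any single
choice (see Limitations).

Concentration profiles are never normalised: transition probabilities
depend only on ratios, and a global rescaling changes only the time scale.
"Longer than n_min" is implemented as n ≥ n_min.

## Exact quantities

All probability arithmetic is in natural-log space (log-sum-exp
reductions); tail probabilities down to 10⁻⁷⁰⁰ stay representable and are
reported in log₁₀.

* **P(n)** — probability the pilus is exactly *n* subunits long — by
  log-space propagation of the transient state vector; no underflow up to
  n = 10⁵.
* **P(C,n)** — correct *and* exactly *n* long — in closed form: with
  a = p(A→A), b = p(E→E) and c₀ the product of the five obligatory
  transition probabilities (G→F, F→E, E→K, K→A, A→H),
  P(C,n) = c₀ · (a^m − b^m)/(a − b) with m = n − 5 (the degenerate a = b
  case uses m·a^(m−1); n < 6 gives zero).
* **P\*** = Σ_{n ≥ n_min} P(C,n) — by the geometric tail sums
  c₀·[a^M/(1−a) − b^M/(1−b)]/(a−b), M = max(n_min, 6) − 5, exact up to
  floating precision.  a = 1 or b = 1 (no reachable terminator) is an
  error, not a number.
* **Assembly times** — closed form along the canonical correct path
  (one PapE, then the PapA rod: Σ 1/exit_rate), and the exact conditional
  expectation over all paths reaching a target length (below).

Stall states (acceptors whose whole effective rate row is zero, possible
only in user-supplied tables) are flagged with a warning; growth reaching
them terminates without PapH and is never counted correct.  The a ≈ b
branch of the composition sum switches to the degenerate formula below a
relative gap of 10⁻¹²; between ~10⁻¹² and ~10⁻⁹ the difference formula
loses a few digits to cancellation, which is irrelevant at the reported
precision.

## Simulation

Two kinetic Monte Carlo engines, both exact (embedded chain + exponential
waiting times, not small-dt rejection):

* a per-pilus reference engine that records full sequences, with one
  independent counter-based stream per pilus (`SeedSequence.spawn`), used
  for sequence-level output and fixtures;
* a vectorised lock-step engine for ensembles of 10⁵–10⁶ pili that tracks
  correctness with a running finite automaton instead of storing
  sequences, driven by a single counter-based Philox stream keyed by the
  root seed.  Summaries are bit-exact reproducible for fixed
  (model, seed, n_pili, cap).

The default length cap is 10⁵; capped pili are recorded as truncated and
never counted correct.

**Conditioned sampling.**  Under the in vitro rates only ~10⁻¹² of pili
reach 100 subunits, so the mean assembly time of "reachers" cannot be
estimated by rejection.  The sampler instead draws paths from the exact
conditional law given that the target length is attained — a positionwise
Doob h-transform whose harmonic function is the survival probability
S(k, s), computed by one backward recursion (the subunit at the target
position itself is unconstrained and may be the terminator).  Conditioning
acts on the path event only; waiting-time distributions given the visited
states are unchanged, so attaching exponential waits with the original
exit rates yields exact conditional assembly times.  The analytic
conditional mean Σ_k E[1/exit_rate at position k | reach] is computed by a
forward pass and used as a cross-check.

## Decay fitting and extrapolation

ln P(C,n) is asymptotically linear in *n* with slope ln max(a, b).  The
fit is weighted least squares of ln P(C,n) against *n*: empirical bins are
weighted by their correct counts (the variance of the log of a rare
binomial proportion is ≈ 1/count) and bins with fewer than 10 counts are
dropped; analytic input is fitted unweighted over a stated window.  By
default lengths below 10 are excluded — there the number of (i, j)
compositions still grows and the decay is shallower than geometric.

Extrapolated tails are the fitted geometric series
exp(intercept + slope·n_min)/(1 − e^slope), with a delta-method standard
error from the fit covariance.  Far extrapolations are meaningful only to
order of magnitude; the error band says how far.  Two practical regimes:

* fitting the *exact* P(C,n) over n ∈ [20, 60] recovers the asymptotic
  slope to <0.1% and reproduces exact tail sums essentially perfectly;
* fitting *counted* bins stops near n ≈ 20 even at 4×10⁵ pili (the
  correct-pilus probability is ~10⁻⁵ there), on the shallow pre-asymptotic
  part, so far extrapolations overshoot by design.  Parameter-recovery
  tests therefore compare simulated slopes against the exact decay fitted
  over the same bins with the same weights, which is unbiased; the
  asymptote itself is checked on the analytic window.

## Scenarios

Four named conditions: `equal` (every permitted rate equal — random
growth), `in_vitro` (the published measured rates), `R` (hypothetical
fast/slow scheme: cognate pairs G→F, F→E, E→E, E→K, K→A, A→A at 1000,
everything else permitted at 1), and `C` (in vitro rates with [PapA]
×200).  The published text for case C (1.4%, 0.22%) contradicts its own
table (4.9×10⁻⁵, 2.6×10⁻⁷); the tabulated definition is implemented and
the conflict is surfaced in the run log, not adjudicated.  Sweeps vary the
fast/slow ratio (with an optional PapE-self-rate-slow variant) or one
pilin's concentration; every run is reproducible from its config + seed.

## Synthetic data

The generator emulates the structure of measured DSE tables: cognate cells
fast, all other permitted cells slower by a tunable ratio, optional
multiplicative lognormal noise (mean 1, CV `noise_cv`) so entries stay
positive and validation always passes.  Ratio 1 degenerates to the equal
table; ratio 1000 at k_fast = 1000 reproduces the fast/slow scheme
bit-exactly.  Concentration patterns: uniform, PapA-dominant, or
PapH-depleted.  What it does **not** emulate: correlated measurement
errors across cells, acceptor-dominated rate structure (real tables show
rates depending mostly on the acceptor complex), second-order donor
kinetics, or finite subunit pools — so passing tests demonstrate
correctness of the machinery under the model's assumptions, not fidelity
to in vivo growth.

Noise robustness is resolution-limited by the tail amplification: at
n_min = 100 a per-entry CV of 5% propagates to ~0.007 decades of
log₁₀ p_AA noise amplified ~95-fold, i.e. ~0.7 decades (1σ) at fast/slow
ratio 10, shrinking to <0.1 decades at ratio 100 and above.

## Problem sizes

Analyses and tests use closed forms wherever they exist (milliseconds).
Monte Carlo sizes: 10⁵ pili for distribution agreement checks, 2×10⁴ per
seed for slope-recovery replicates, 4×10⁵ for the fit-extrapolation
illustration, 10⁴ conditioned reachers for assembly times.  The
enumeration oracle walks all donor sequences up to length 9 (~5⁸ paths).

## Known limitations

* The equal-rates published tail values (3.5×10⁻⁶⁸, 5.8×10⁻⁶⁹²) differ
  from the closed form (7.5×10⁻⁶⁸ → log₁₀ = −67.12, and −695.18) by
  factors that no initiation/length convention removes while keeping the
  fast/slow row exact; agreement there is order-of-magnitude only.
* The published in vitro pair (1.1×10⁻²⁷, 1.2×10⁻²⁷⁴) implies a decay
  slope of −0.632 per subunit, steeper than the −0.6053 the measured rate
  table itself yields; a single-exponential extrapolation from the true
  slope gives log₁₀ P\*(1000) ≈ −262, not −274.
* P\* is not monotone in the PapA enrichment factor: it peaks near ×20
  (log₁₀ P\*(100) ≈ −4.1) and declines mildly toward ×200 (−5.2), because
  excess PapA also dilutes the tip transitions.
* Second-order DSE kinetics at low donor concentration, chaperone
  recycling, usher mechanics and any length-regulation mechanism are out
  of scope.
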