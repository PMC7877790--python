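# Methods

## The model and its assumptions

`glycoqc` models ER glycoprotein quality control as a well-mixed
mass-action network over eight protein pools. A protein enters tagged
(monoglucosylated, `P_g`), binds a chaperone (`P_c`, bimolecular with the
available chaperone `C_A`), folds (`P_cf`) or is released with (`k_-c`) or
without (`k_r`) its tag, may be re-tagged by reglucosylation (`k_g`) or
de-tagged directly (`k_-g`, the "safety valve"), and is degraded from the
untagged pool (`k_d`). Terminally misfolded proteins (`P_g*`, `P_c*`,
`P*`) traverse the same network with the same rate constants but a folding
rate of zero — the cycle's enzymes cannot tell them apart from foldable
proteins. Background proteins bind chaperones only through the untagged
route (`k_-r`) and are treated as a fixed reservoir `P_b`: their free
concentration is not depleted by binding, only the bound form `P_cb` is
tracked. Chaperones bind one protein at a time and are conserved:
`P_c + P_cf + P_c* + P_cb + C_A = 1`.

Everything is dimensionless: times are scaled by the glucose-trimming
release rate (`k_r = 1`) and concentrations by total chaperone
(`C_tot = 1`). Performance is always evaluated at steady state, on the
assumption that production parameters vary slowly compared with one cycle
turn.

One sign convention worth stating explicitly: degradation enters the
untagged-pool balance as a loss,
`dP/dt = k_r P_c + k_-g P_g − (k_g + k_-r C_A + k_d) P` (and likewise for
`P*`) — grouping it with the opposite sign would violate the steady-state
flux balance `k_p = k_f P_c + k_d P`.

## Analytic steady state

At steady state the network reduces exactly. Summing the foldable
balances gives `k_p = k_f P_c + k_d P`; the folded and background pools
give `P_cf = k_f P_c / (k_r + k_-c)` and `P_cb = k_-r P_b C_A / k_r`; the
misfolded flux balance gives `P* = k_p*/k_d`. What remains are two 2×2
linear systems for `(P_g, P_c)` and `(P_g*, P_c*)` with coefficients
depending on `C_A`; their Cramer solutions are rational in `C_A`, and
substituting into the conservation law and clearing denominators yields a
quartic polynomial in `C_A`. The elimination is carried out with `k_r`
kept symbolic so the same code path covers the no-tag-memory variant
(`k_r = 0`, `k_-c = 1`); setting `k_r = 1` recovers the physiological
form. The construction is verified in the test suite against an
independent sympy elimination of the same balance equations.

Numerics: the polynomial's degree drops when rates vanish (`k_-r = 0`
kills the quartic term); numerically-zero leading coefficients (relative
threshold 1e-13) are trimmed and the reduced polynomial solved. Real
roots in (0, 1] are polished by secant iteration on the well-conditioned
rational closure equation before back-substitution. A root is feasible if
every concentration is ≥ −1e-10 (then clamped to zero) and the max-norm
of the dynamics at the reconstructed state is below 1e-8. If several
roots survive, the branch matching stiff ODE integration from the empty
state is selected and a multiplicity warning emitted; in optimizer inner
loops (no ODE check) the largest-`C_A` branch — the one reached from an
initially empty system — is used.

The ODE oracle integrates with LSODA (rtol 1e-10, atol 1e-13; rate
constants span six orders of magnitude, so a stiff method is required)
over doubling time windows (initial 50, cap 2e6) until the right-hand
side max-norm falls below 1e-9. Non-existence is diagnosed either
analytically (no feasible root) or dynamically (total unfolded protein
rising monotonically with a non-vanishing derivative across ≥ 4
successive windows — production outrunning the chaperone release
capacity). `steady_state_exists` combines both, since a mathematically
feasible root can be dynamically unreachable.

## Architectures

Seven variants mask the adjustable rates {k_c, k_-c, k_-r, k_g, k_-g,
k_d}: FULL (all free, finite driving energy), PHYS (consensus cycle,
`k_-c = k_-r = 0`), WB (weak binding: `k_-r = k_g = k_-g = 0`), WBSV (WB
plus safety valve `k_-g`), OS (one shot: only `k_c`, `k_d`), NTM (no tag
memory: `k_r = 0`, `k_-c = 1`, release never trims the tag), CNSV (the
cycle without its safety valve). The exact membership of the tag-toggle
rates in OS/WB/NTM is a modeling choice where the architecture
descriptions are qualitative; the masks used here reproduce each
variant's described behavior (one-visit folding caps for WB/WBSV/OS,
NTM ≈ PHYS at low misfolding, CNSV clogging above `k_pt = 1`) and are
defined in one place (`model.VARIANTS`) so alternates can be swapped in.

Throughput ceilings follow from the masks: CNSV must release every
protein through glucose trimming (capacity `k_r C_tot = 1`), so no steady
state exists for `k_pt > 1`; WB also exits folded proteins through
`k_-c`, raising its ceiling to `k_f + k_r` (= 2 at `k_f = 1`).

## Optimization protocols

All searches run in log10-rate space within bounds [1e-3, 1e3], using
SLSQP under seeded Latin-hypercube multistarts (default 20; rate sets
with no steady state receive a penalty objective). Protocols:

* **Maximum folding fraction** — unconstrained maximization of `f`.
* **Pareto point** — minimize `log10 P_unfolded` subject to
  `f = f_target` (equality tolerance 1e-4, a choice; results are
  insensitive to it well below the acceptance window width).
* **Folding efficiency `f*max`** — bisection on `f_target` until the
  minimized `P_unfolded` lands in (0.99, 1.01), at most 60 iterations,
  warm-starting each step from the bracket optima. Two edge cases: if
  the minimal load at the unconstrained maximum `f` is already below the
  window, the load constraint is slack and `f*max` equals that maximum;
  and because some variants have a floor on achievable `f` (without a
  safety valve every protein passes the chaperone and folds with
  probability ≥ `k_f/(k_f+k_r)`), the lower bisection bracket is found by
  scanning upward from tiny `f` rather than assumed.
* **Energy-constrained efficiency** — maximize `f` subject to
  `P_unfolded = 1` and fixed driving energy `E`; the energy constraint is
  linear in log-rates and starts are projected onto it. Accepted when
  `|E_achieved − E| ≤ 1e-3` and `P_unfolded ∈ (0.99, 1.01)`.
* **Degradation-only adaptation** — bisection on `k_d ∈ [1e-3, 1e3]`
  targeting `P_unfolded ∈ (0.99, 1.01)`. Monotonicity of `P_unfolded` in
  `k_d` is checked at the bracket endpoints (grid-search fallback if
  violated). When the window is unreachable, the `k_d` minimizing
  `|P_unfolded − 1|` is returned: the upper bound when the load is too
  high everywhere, the lower bound when it is too low everywhere (the
  latter arises when production falls below the anchor point).

Identical problem + seed reproduce bit-identically. Optima are local:
multistart coverage and the test suite's ±5% perturbation audit are the
safeguards, and the seed is echoed in every result.

## Fixture generation

The seeded fixture generator draws free rates log-uniformly over the
bounds and pairs them with conditions spanning the regimes of interest:
production `k_pt` log-uniform in [0.01, 10] (excess-chaperone through
overwhelmed), misfolded fraction in {1e-3, 0.4} (trace vs heavy
misfolding), folding rate log-uniform in [0.03, 3] (slow to fast
folders), background level in {0, 1, 10}. These fixtures drive the
oracle-equivalence and conservation-law suites. They emulate the model's
own parameter space, not measured rate constants; passing tests certify
the mathematics and the optimization machinery, not agreement with any
particular experimental system.

## Problem sizes and defaults

Sweeps default to 12 log-spaced points per decade-spanning grid
(overridable). The robustness analyses use anchor production rates
{0.1, 1, 10} with `k_f = 1` and `m_f = 0.001`; the low-production regime
for variant comparison is evaluated at `k_pt = 0.3`. The acceptance
script uses 20 multistarts and a 25-point production grid on [0.1, 2] for
the adaptation boundary. Test-suite optimizations use 4–8 multistarts,
which the warm-started bisection makes sufficient for the qualitative
claims they check.

## Known limitations

* No unfolded-protein-response feedback, no time-dependent production, no
  sequential mannose trimming, no spatial organization, no stochastic
  copy-number effects: the model is deterministic, well-mixed, and
  steady-state.
* Enzyme concentrations (glucosidase II, UGGT) are folded into rate
  constants; there is no dimensional/SI mode.
* Optimization results are local optima under a fixed multistart budget;
  different budgets can land in different basins near plateaus.
* `P_unfolded` comparisons near non-existence boundaries are sensitive to
  the integrator's unbounded-growth heuristic; the analytic
  no-feasible-root check is authoritative where both apply.
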