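# Methods

## Model

Two phenotypes interact in a large, well-mixed population: migraineurs
(hypersensitive, early predator detection) and non-migraineurs (less
sensitive, able-bodied during a migraineur's attack). All games are
symmetric 2×2 games; payoffs are interpreted as fitness (reproductive
success). `payoff(actor, partner, p)` is oriented actor-by-partner, and
`p` always denotes the frequency of the *focal* strategy — dove in the
Hawk–Dove game, migraineur in the migraine games — so every expected
payoff is `EV_s(p) = p·a(s, focal) + (1−p)·a(s, other)`. Self-pairing
is ignored (infinite-population limit).

### Hawk–Dove construction

From scoring primitives (win w, loss l, injury i, time cost t, all in
payoff points, with i < l ≤ w): symmetric contests are decided by a
fair coin flip and booked as expectations, giving cells
a_HH = (w+i)/2, a_HD = w, a_DH = l, a_DD = (w+l)/2 + t. The classic
+50/0/−100/−10 scoring yields (−25, +50, 0, +15), mixed ESS at dove
fraction 5/12 with common payoff +6.25.

### Migraineur game, cost form

With baseline d_m ≡ 1 (the fitness of a rescued migraineur; any
rescaling is multiplicative), costs c_m > c_n > 0, and betrayal level
d_m′ < 1 − c_m, the cells are

- (m,m) = 1 + c_n − (1−p)·p·(c_m − c_n)
- (m,n) = 1, (n,m) = 1 + c_n, (n,n) = 1 − (c_m − c_n)

The (m,m) cell carries a frequency-dependent gap below f_n = 1 + c_n.
`c_m == c_n` is accepted as the degenerate equal-cost boundary: the gap
vanishes and the game loses frequency dependence entirely.

**Identity audit.** The non-migraineur's expected payoff satisfies
EV_n(p) = 1 − c_m(1−p) + c_n *exactly*, an algebraic identity we test
to 10⁻¹² on 10,000 random (c_m, c_n, p) triples. The migraineur's does
not: symbolic expansion (cross-checked with sympy in the test suite)
gives EV_m(p) − [1 − c_m(1−p) + c_n] = (1−p)²(1+p)(c_m − c_n), which is
strictly positive in the interior whenever c_m > c_n. Consequently the
cost-form game has **no interior equilibrium**: migraineurs are weakly
favoured at every p and the solver reports the p = 1 boundary (or a
degenerate game at c_m = c_n). `verify_paper_identity` reports both
residuals; nothing is "corrected". A gap term of the form
(1−p)(c_m−c_n)/p would make the common-value identity exact, but the
package does not substitute it. Also deliberately unreconciled: the
cost/benefit record defines c_m and b_n as the same fitness span
f_n − d_n, read off the diagram from the two sides of the exchange.

### Migraineur game, constant-fitness form

Four constant levels with the crossing ordering f_n > f_m > d_m > d_n
and cells (m,m)=f_m, (m,n)=d_m, (n,m)=f_n, (n,n)=d_n. The payoff gap is
linear with g(0) = d_m − d_n > 0 and g(1) = f_m − f_n < 0, so a unique
interior equilibrium exists, p* = (d_m−d_n)/((d_m−d_n)+(f_n−f_m)), and
is stable (each phenotype favoured when rare). Comparative statics
follow: ∂p*/∂d_n < 0 (more vulnerable non-migraineurs → more
migraineurs) and ∂p*/∂(f_n−f_m) < 0.

## Equilibrium solving

Constant games: closed form on the linear gap (`method="analytic"`).
Frequency-dependent games: gap evaluated on a grid of step 10⁻³, each
sign-change bracket refined with Brent's method to xtol 10⁻¹⁰; all
interior roots are returned with stability flags and the first stable
root is primary. No interior root → result at the dominating boundary
with a one-sided invasion classification; gap numerically zero
everywhere (max |g| < 10⁻¹⁴) → explicit `degenerate` status, p* = 0.5
as a conventional representative. Stability uses a probe half-width
ε = 10⁻⁶ (configurable): stable iff g(p*−ε) > 0 > g(p*+ε). Invasion
payoffs are exact boundary evaluations, not small-ε approximations.

## Dynamics

**Replicator.** dp/dt = p(1−p)·g(p), integrated by fixed-step classical
RK4 with defaults dt = 0.01, t_max = 10⁴, convergence when
|dp/dt| < 10⁻⁸. Monotone, overshoot-free approach requires dt below
roughly 1/L with L = sup|d(dp/dt)/dp| (L ≈ 31 for the Hawk–Dove
payoffs, L < 1 for the migraine games), which the defaults satisfy with
a wide margin. Frequency-dependent cells are re-evaluated at the
current p at every stage evaluation.

**Moran.** Per elementary step, one birth is drawn with probability
proportional to count × exp(intensity·EV) and one uniform death; a
generation is N steps. The exponential fitness map accommodates
negative payoffs (hawk–hawk −25) without shifting; default intensity
0.1. Optional symmetric mutation keeps long runs off the absorbing
boundaries (off by default). Constant games run in a compiled numba
kernel (the headline check uses 50 replicates × 500 generations ×
N = 1000 ≈ 25 M steps); frequency-dependent games use a pure-Python
loop with cells evaluated at the current frequency. All randomness
derives from one `numpy.random.Generator` per run; identical seeds give
bit-identical trajectories. At neutrality (intensity 0) the process is
a martingale, which the suite checks against replicate means. The
stochastic checks are statistical by design: replicate means are
compared to the analytic ESS within three standard errors of the
replicate sample, not a hand-set band.

## Agent-based reciprocity model

The study population is a small foraging band (default 24 agents, 14%
migraineurs — the contemporary prevalence used as the initial
composition, 1,000 rounds). Each round agents pair uniformly at random;
with probability 0.2 a predator threatens a pair, and a migraineur in
the pair is mid-attack with probability 0.25. Bookkeeping is additive
per event *relative to each phenotype's no-agreement baseline* (d_m′
for migraineurs, d_n for non-migraineurs): a warn books −c_m to the
warner and +b_n to the warned; a rescue books −c_n to the rescuer and
+b_m to the rescued; rounds without exchanges book zero. With the
agreement disabled both phenotypes therefore sit exactly at baseline,
and with it enabled each *completed* warn→rescue cycle nets b_m − c_m
and b_n − c_n, both required positive for the simulation to run at all.
The ledger also records the absolute per-encounter level of each
outcome (f_n warned, f_m self-escape, d_m rescued, d_n unwarned, d_m′
unhelped/betrayed), so the crossing ordering is observable in simulated
event categories.

Design choices where the model was open:

- Warnings are extended as *credit*: a migraineur does not warn a
  partner who already owes it an unpaid rescue (credit limit one per
  partner). Without this, warning on every encounter — warnings being
  roughly four times as frequent as rescue opportunities — would sink
  migraineurs below baseline no matter how favourable b_m − c_m is;
  with it, uncollected credit is bounded by the number of partners.
- Repayment is per-debt and single (one rescue cancels one warning),
  and requires the debtor to be the attacked migraineur's current pair
  partner.
- A migraineur in attack cannot warn; migraineurs do not rescue
  migraineurs.
- Defection applies only to the repayment decision; a betrayed
  migraineur is left at the d_m′ level, and two betrayals by the same
  remembered partner end the agreement with that partner (no further
  warnings to them).
- Knockouts: *repeat interaction* off → repayment disabled outright
  (debts can never be collected); *recognition* off → the rescuer still
  pays c_n but the b_m benefit lands on a uniformly random band member;
  *memory* off → no debts are ever recorded, so no rescue occurs and
  warnings are indiscriminate.

Because single-run migraineur margins are thin at these event rates,
headline comparisons average a few seeded replicates (the acceptance
check uses four) — a replication choice, not a parameter change.

## Random scenario generation

Fixture parameters are drawn uniformly within documented ranges and
ordered by construction (base level plus positive gaps), so every draw
satisfies its type's invariants without rejection: generalized games
draw d_n ∈ [0.6, 0.9] and the three gaps in [0.05, 0.3]; cost-form
parameters draw c_n ∈ [0.05, 0.4], c_m − c_n ∈ [0.01, 0.4]; Hawk–Dove
draws keep injury < loss ≤ win. The gap floor of 0.05 keeps equilibria
away from the boundaries and convergence rates bounded below, which is
what makes the 100-game replicator/equilibrium agreement checks sharp
at 10⁻⁶/10⁻⁹.

What the generator emulates — and does not. It produces parameter sets,
not data: there is no measurement noise, no demography, no kin
structure, no environmental variation, and the ABM band has fixed
composition (phenotype evolution is the dynamics module's job, by
design). Passing tests therefore demonstrate internal consistency of
the model and solver — not that real migraine prevalence arises from
these mechanisms; the model's equilibrium is never calibrated to the
observed ~14% prevalence.

## Problem sizes

The default suite uses 1,000 random constant games for the
closed-form/grid-scan agreement check, 10,000 triples for the identity
audit, 100–300 games for replicator-convergence and comparative-statics
properties, 50 Moran replicates at N = 1,000 for the ESS bracket, and
600–1,000-round ABM runs; the full suite runs in well under a minute on
one core.

## Known limitations

- Only symmetric 2×2 games; no >2-strategy, asymmetric-role, spatial or
  n-player structure.
- The Moran implementation offers no Wright–Fisher variant, diffusion
  approximation, or closed-form fixation probabilities.
- The ABM does not evolve phenotypes (no mutation/learning); it
  measures payoffs under a fixed composition.
- Verbal claims of the underlying hypothesis (latitude gradients, sex
  differences, prevalence levels) are outside the computable scope and
  are represented only as sweep directions (e.g. d_n presets), not
  fitted magnitudes.
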