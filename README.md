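# sensgame

Evolutionary game models of why migraine persists under natural
selection, built for researchers exploring frequency-dependent selection
on sensory hypersensitivity.

Migraine-associated genes make sensory organs and cortex hypersensitive,
which is costly today but would have made carriers exceptionally good at
detecting predators. The hypothesis modelled here is a reciprocal
exchange in ancestral foraging bands: a hypersensitive *migraineur*
detects danger early and warns a less sensitive *non-migraineur*
(paying cost c_m, conferring benefit b_n); the non-migraineur later
repays by rescuing the migraineur if a predator appears during an
incapacitating attack (paying c_n, conferring b_m). Reciprocity is
viable only when b_m − c_m > 0 and b_n − c_n > 0. If both phenotypes
then compete for cooperation, the pairing fitness values cross like the
Hawk–Dove game's (f_n > f_m > d_m > d_n), and the population settles at
a mixed evolutionarily stable state: an interior frequency p\* of
migraineurs at which both phenotypes earn equal expected payoff,

p\* = (d_m − d_n) / [(d_m − d_n) + (f_n − f_m)],

stable because each phenotype does better while rare. The package
implements:

- **games** — the Hawk–Dove game from contest scoring primitives, and
  the migraineur/non-migraineur game in both its frequency-dependent
  cost form (cells built from c_m, c_n with the gap term
  (1−p)p(c_m−c_n)) and the constant-fitness generalisation above;
- **equilibrium** — expected payoffs, mixed-ESS solving (closed form for
  constant games, grid scan + Brent refinement otherwise), invasion
  payoffs, stability classification, and an audit of the claimed common
  equilibrium payoff 1 − c_m(1−p) + c_n;
- **dynamics** — replicator ODE integration and a finite-population
  Moran birth–death process with exponential payoff-to-fitness mapping;
- **altruism** — an agent-based simulation of the warn/rescue exchange,
  with toggles for the three prerequisites of reciprocal altruism
  (repeated interaction, individual recognition, memory of past help)
  and for defection;
- **sweeps** — comparative statics of p\* in d_n, f_n, f_m, c_m, c_n
  (e.g. a population with more vulnerable members has lower d_n, hence
  a higher equilibrium migraineur fraction).

## Worked example

```python
import sensgame as sg

game = sg.hawk_dove_game(sg.ContestRules(win_value=50, loss_value=0,
                                         injury_value=-100, time_cost=-10))
eq = sg.mixed_equilibrium(game)
print(f"dove fraction p* = {eq.p_star:.6f}")
print(f"payoff at ESS    = {eq.payoff_at_eq:.4f}")
print(f"all-dove mean    = {sg.population_mean_payoff(game, 1.0):.2f}")

traj = sg.simulate_moran(game, N=1000, p0=0.5, generations=500, seed=1)
print(f"Moran time-averaged dove fraction = "
      f"{sg.time_averaged_frequency(traj, burn_in=100):.4f}")

d = sg.verify_paper_identity(
    sg.MigraineGameParams(c_m=0.3, c_n=0.2, d_m_prime=0.5), p=0.5)
print(f"EV_m = {d.ev_m:.4f}, EV_n = {d.ev_n:.4f}, "
      f"residual_m = {d.residual_m:.4f}")
```

prints

```
dove fraction p* = 0.416667
payoff at ESS    = 6.2500
all-dove mean    = 15.00
Moran time-averaged dove fraction = 0.4160
EV_m = 1.0875, EV_n = 1.0500, residual_m = 0.0375
```

The Hawk–Dove contest scored +50/0/−100/−10 has its mixed ESS at a dove
fraction of 5/12 where both strategies average +6.25 — far below the
+15 an all-dove population would enjoy, the classic gap between group
optimum and evolutionary stability. A stochastic population of 1,000
individuals fluctuates around the same fraction. In the cost-form
migraineur game the non-migraineur's expected payoff matches the
claimed common value 1 − c_m(1−p) + c_n exactly, while the migraineur's
exceeds it by (1−p)²(1+p)(c_m−c_n) (here 0.0375): the two expected
payoffs only meet at the boundary, a discrepancy the package surfaces
rather than hides (see `docs/methods.md`).

Comparative statics on the constant-fitness game, `sweep_equilibrium`
over d_n ∈ {0.80 … 0.95} with (f_n, f_m, d_m) = (1.2, 1.1, 1.0):

```
 param_value   p_star   payoff  stable   status
        0.80 0.666667 1.066667    True interior
        0.85 0.600000 1.060000    True interior
        0.90 0.500000 1.050000    True interior
        0.95 0.333333 1.033333    True interior
```

Lower unaided fitness d_n (a more vulnerable population) raises the
equilibrium migraineur fraction.

A CLI mirrors the library: `sensgame ess`, `audit-identity`,
`replicator`, `moran`, `altruism`, `sweep`, `fixtures` (see
`sensgame --help`); runs are configured by JSON files and every output
embeds the config hash and seed for exact reruns.

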