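"""Agent-based model of reciprocal altruism between migraineurs and non-migraineurs.

The model plays out the warn/rescue exchange in a small foraging band.
Each round, agents are paired at random; with some probability a
predator threatens a pair.  A hypersensitive migraineur who is not
incapacitated detects the predator first and warns its partner, paying
cost ``c_m`` while the partner gains ``b_n``.  A migraineur caught
mid-attack is helpless and must be rescued by a partner repaying past
help: the rescuer pays ``c_n`` and the migraineur gains ``b_m``.
Fitness is booked additively per event, measured relative to the
no-agreement baseline of each phenotype (the betrayed level d_m' for
migraineurs, the unaided level d_n for non-migraineurs), so a round
without exchanges changes nothing.

The three classical prerequisites of reciprocal altruism are explicit
toggles:

* ``repeat_interaction`` -- without repeated meetings a debt can never
  be collected; disabling it disables repayment altogether.
* ``recognition`` -- without individual recognition, repayment cannot be
  targeted: the rescuer still pays but the benefit lands on a uniformly
  random band member.
* ``memory`` -- without memory of past help no debt is ever recorded
  and no rescue occurs; migraineurs also cannot track who already owes
  them and warn indiscriminately.

With all three enabled, a migraineur extends credit (a warning) to a
partner only while that partner holds no outstanding debt to it, so
each completed warn->rescue cycle nets ``b_m - c_m`` to the migraineur
and ``b_n - c_n`` to the non-migraineur, both required positive for the
agreement to run at all.  A partner who defects twice (refuses a
rescue) is blacklisted: the migraineur stops warning them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .games import GeneralizedMigraineGame, derive_costs_benefits

__all__ = [
    "Agent",
    "EncounterConfig",
    "AltruismResult",
    "KnockoutReport",
    "init_population",
    "simulate_encounters",
    "condition_knockout",
]

MIGRAINEUR = "migraineur"
NON_MIGRAINEUR = "non_migraineur"


@dataclass
class Agent:
    """One band member with its interaction bookkeeping.

    The per-partner maps (``helped``, ``was_helped``, ``betrayed_by``,
    ``owed_by``) are populated only when the memory condition is on.
    """

    id: int
    phenotype: str
    fitness: float = 0.0
    in_attack: bool = False
    helped: dict[int, int] = field(default_factory=dict)
    was_helped: dict[int, int] = field(default_factory=dict)
    betrayed_by: dict[int, int] = field(default_factory=dict)
    owed_by: dict[int, int] = field(default_factory=dict)  # debtor -> open debts
    debts: dict[int, int] = field(default_factory=dict)  # creditor -> open debts
    blacklist: set[int] = field(default_factory=set)


@dataclass(frozen=True)
class EncounterConfig:
    """Study conditions for the encounter simulation.

    Defaults describe a small foraging band: 24 members of whom 14% are
    migraineurs, a predator threatening a given pair once every five
    rounds, and a migraineur being mid-attack at a quarter of those
    moments.
    """

    game: GeneralizedMigraineGame
    seed: int
    n_agents: int = 24
    migraineur_fraction: float = 0.14
    n_rounds: int = 1000
    predator_prob: float = 0.2
    attack_prob: float = 0.25
    defect_prob: float = 0.0
    agreement: bool = True
    repeat_interaction: bool = True
    recognition: bool = True
    memory: bool = True

    def __post_init__(self) -> None:
        for name in (
            "migraineur_fraction",
            "predator_prob",
            "attack_prob",
            "defect_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_agents < 2:
            raise ValueError(f"n_agents must be >= 2, got {self.n_agents}")
        if self.n_rounds < 1:
            raise ValueError(f"n_rounds must be >= 1, got {self.n_rounds}")

    def replace(self, **kw) -> "EncounterConfig":
        from dataclasses import replace as _replace

        return _replace(self, **kw)


def init_population(config: EncounterConfig) -> list[Agent]:
    """Create round(n_agents * migraineur_fraction) migraineurs, rest non-."""
    n_mig = int(round(config.n_agents * config.migraineur_fraction))
    return [
        Agent(id=i, phenotype=MIGRAINEUR if i < n_mig else NON_MIGRAINEUR)
        for i in range(config.n_agents)
    ]


@dataclass(frozen=True)
class AltruismResult:
    """Outcome of one encounter simulation."""

    per_round: pd.DataFrame  # round, mean cumulative fitness per phenotype
    ledger: pd.DataFrame  # round, agent_id, partner_id, event, delta_fitness, level
    agents: list[Agent]
    rescues_received_by_migraineurs: int

    def mean_final_fitness(self, phenotype: str) -> float:
        members = [a for a in self.agents if a.phenotype == phenotype]
        return float(np.mean([a.fitness for a in members])) if members else float("nan")

    def mean_per_round_fitness(self, phenotype: str) -> float:
        n_rounds = int(self.per_round["round"].iloc[-1]) if len(self.per_round) else 1
        return self.mean_final_fitness(phenotype) / n_rounds


def simulate_encounters(config: EncounterConfig) -> AltruismResult:
    """Run the round-robin encounter model; fully reproducible by seed.

    Raises if ``agreement`` is requested while either side's exchange is
    not worthwhile (b_m - c_m <= 0 or b_n - c_n <= 0): the cooperation
    pact only exists when both parties gain from a completed cycle.
    """
    cb = derive_costs_benefits(config.game)
    if config.agreement and not (
        cb.migraineur_gain_positive and cb.non_migraineur_gain_positive
    ):
        raise ValueError(
            "agreement requires b_m - c_m > 0 and b_n - c_n > 0; got "
            f"b_m-c_m={cb.b_m - cb.c_m:.6g}, b_n-c_n={cb.b_n - cb.c_n:.6g}"
        )
    g = config.game
    rng = np.random.default_rng(config.seed)
    agents = init_population(config)
    ledger_rows: list[tuple] = []
    per_round_rows: list[tuple] = []
    migraineur_rescues = 0

    def log(rnd, agent, partner_id, event, delta, level):
        agent.fitness += delta
        ledger_rows.append((rnd, agent.id, partner_id, event, delta, level))

    for rnd in range(1, config.n_rounds + 1):
        order = rng.permutation(config.n_agents)
        for a in agents:
            a.in_attack = False
        for k in range(config.n_agents // 2):
            a, b = agents[order[2 * k]], agents[order[2 * k + 1]]
            if rng.random() >= config.predator_prob:
                continue
            for x in (a, b):
                if x.phenotype == MIGRAINEUR:
                    x.in_attack = rng.random() < config.attack_prob
            _resolve_predator_event(config, cb, g, rng, agents, rnd, a, b, log)
        mig = [x.fitness for x in agents if x.phenotype == MIGRAINEUR]
        non = [x.fitness for x in agents if x.phenotype == NON_MIGRAINEUR]
        per_round_rows.append(
            (
                rnd,
                float(np.mean(mig)) if mig else np.nan,
                float(np.mean(non)) if non else np.nan,
            )
        )

    ledger = pd.DataFrame(
        ledger_rows,
        columns=["round", "agent_id", "partner_id", "event", "delta_fitness", "level"],
    )
    mig_ids = {x.id for x in agents if x.phenotype == MIGRAINEUR}
    if len(ledger):
        migraineur_rescues = int(
            (
                ledger["event"].isin(
                    ["rescue_received", "rescue_misdirected_received"]
                )
                & ledger["agent_id"].isin(mig_ids)
            ).sum()
        )
    per_round = pd.DataFrame(
        per_round_rows,
        columns=["round", "mean_fitness_migraineur", "mean_fitness_non_migraineur"],
    )
    return AltruismResult(
        per_round=per_round,
        ledger=ledger,
        agents=agents,
        rescues_received_by_migraineurs=migraineur_rescues,
    )


def _resolve_predator_event(config, cb, g, rng, agents, rnd, a, b, log):
    """Resolve one predator appearance for the pair (a, b)."""
    phen = (a.phenotype, b.phenotype)
    if phen == (MIGRAINEUR, MIGRAINEUR):
        # both sense danger themselves; an attacked migraineur has no rescuer
        for x, other in ((a, b), (b, a)):
            if x.in_attack:
                log(rnd, x, other.id, "unhelped", 0.0, g.d_m_prime)
            else:
                log(rnd, x, other.id, "self_escape", 0.0, g.f_m)
        return
    if phen == (NON_MIGRAINEUR, NON_MIGRAINEUR):
        for x, other in ((a, b), (b, a)):
            log(rnd, x, other.id, "unwarned", 0.0, g.d_n)
        return
    m, n = (a, b) if a.phenotype == MIGRAINEUR else (b, a)

    if not m.in_attack:
        # migraineur detects the predator first: warn, or stay silent
        willing = config.agreement and n.id not in m.blacklist
        if willing and config.memory and config.recognition:
            # extend no further credit to a partner already in debt
            willing = m.owed_by.get(n.id, 0) == 0
        if willing:
            log(rnd, m, n.id, "warn_given", -cb.c_m, g.f_m)
            log(rnd, n, m.id, "warn_received", cb.b_n, g.f_n)
            if config.memory:
                m.helped[n.id] = m.helped.get(n.id, 0) + 1
                n.was_helped[m.id] = n.was_helped.get(m.id, 0) + 1
                m.owed_by[n.id] = m.owed_by.get(n.id, 0) + 1
                n.debts[m.id] = n.debts.get(m.id, 0) + 1
        else:
            log(rnd, m, n.id, "self_escape", 0.0, g.f_m)
            log(rnd, n, m.id, "unwarned", 0.0, g.d_n)
        return

    # migraineur mid-attack: repayment is its only way out
    repay_possible = config.agreement and config.repeat_interaction and config.memory
    if repay_possible:
        if config.recognition:
            repay_possible = n.debts.get(m.id, 0) > 0
        else:
            repay_possible = sum(n.debts.values()) > 0
    if not repay_possible:
        log(rnd, m, n.id, "unhelped", 0.0, g.d_m_prime)
        log(rnd, n, m.id, "self_escape_n", 0.0, g.d_n)
        return
    if rng.random() < config.defect_prob:
        # betrayal: the debtor refuses; the migraineur is left at d_m'
        log(rnd, m, n.id, "betrayed", 0.0, g.d_m_prime)
        log(rnd, n, m.id, "betrayal_committed", 0.0, np.nan)
        if config.memory:
            m.betrayed_by[n.id] = m.betrayed_by.get(n.id, 0) + 1
            if m.betrayed_by[n.id] >= 2:
                m.blacklist.add(n.id)
        return
    if config.recognition:
        log(rnd, n, m.id, "rescue_given", -cb.c_n, np.nan)
        log(rnd, m, n.id, "rescue_received", cb.b_m, g.d_m)
        n.debts[m.id] -= 1
        if n.debts[m.id] == 0:
            del n.debts[m.id]
        m.owed_by[n.id] = m.owed_by.get(n.id, 1) - 1
        if m.owed_by.get(n.id) == 0:
            del m.owed_by[n.id]
        n.helped[m.id] = n.helped.get(m.id, 0) + 1
        m.was_helped[n.id] = m.was_helped.get(n.id, 0) + 1
    else:
        # repayment cannot be targeted: help goes to a random band member
        target = agents[int(rng.integers(len(agents)))]
        log(rnd, n, m.id, "rescue_given", -cb.c_n, np.nan)
        log(rnd, target, n.id, "rescue_misdirected_received", cb.b_m, np.nan)
        if target.id != m.id:
            log(rnd, m, n.id, "unhelped", 0.0, g.d_m_prime)
        creditor = next(iter(n.debts))
        n.debts[creditor] -= 1
        if n.debts[creditor] == 0:
            del n.debts[creditor]


@dataclass(frozen=True)
class KnockoutReport:
    """Effect of disabling each prerequisite of reciprocal altruism."""

    table: pd.DataFrame  # scenario, migraineur/non-migraineur fitness, drops

    def drop(self, scenario: str) -> float:
        row = self.table.set_index("scenario").loc[scenario]
        return float(row["migraineur_drop"])


def condition_knockout(config: EncounterConfig) -> KnockoutReport:
    """Re-run the simulation with each prerequisite disabled in turn.

    The report quantifies, per knockout, the change in migraineur mean
    fitness and in the number of rescues migraineurs actually received,
    against the fully enabled configuration (same seed).
    """
    if not config.agreement:
        raise ValueError("condition_knockout requires agreement=True")
    scenarios = {
        "full": {},
        "no_repeat_interaction": {"repeat_interaction": False},
        "no_recognition": {"recognition": False},
        "no_memory": {"memory": False},
    }
    rows = []
    base: AltruismResult | None = None
    for name, overrides in scenarios.items():
        res = simulate_encounters(config.replace(**overrides))
        if name == "full":
            base = res
        rows.append(
            (
                name,
                res.mean_final_fitness(MIGRAINEUR),
                res.mean_final_fitness(NON_MIGRAINEUR),
                res.rescues_received_by_migraineurs,
                base.mean_final_fitness(MIGRAINEUR) - res.mean_final_fitness(MIGRAINEUR),
            )
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "scenario",
            "migraineur_fitness",
            "non_migraineur_fitness",
            "migraineur_rescues",
            "migraineur_drop",
        ],
    )
    return KnockoutReport(table=table)
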