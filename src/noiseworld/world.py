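"""The NoiseWorld engine.

A world is a toroidal grid of islands, each a bounded 2-D expanse
(|x| < 20, |y| < 20) carrying a constant-size population of agents.  Per
timestep every agent hears the previous output of its current nearest
neighbour, evaluates its equation trees synchronously, and moves a fixed
distance ``a * dt`` in the direction given by its heading tree.  Two
agents closer than the reproduction distance ``rho`` produce one
offspring; each viable birth is matched by one death, so island
populations are constant at every era boundary.  Rare migration at birth
(probability ``p_b``) carries offspring to one of the four border-sharing
neighbour islands; migrants are exchanged at the 10,000-step sync points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genetics import (
    IslandGeneticsState,
    MutationConfig,
    compute_beta,
    make_offspring,
)
from .genome import (
    AgentState,
    CompiledGenome,
    Genome,
    TagAllocator,
    genome_to_dict,
    primordial_genome,
)

__all__ = [
    "WorldConfig",
    "Agent",
    "Island",
    "World",
    "nearest_neighbor",
    "place_agent",
    "step_island",
    "reproduce_event",
    "exchange_migrants",
    "run_world",
]


@dataclass
class WorldConfig:
    """Geometry, rates and run length of one simulation.

    Defaults are the standard setup: 100 islands of 50 agents, reproduction
    distance 0.139, timestep 0.0005, birth placement inside a radius-1.13
    disc, migration probability 0.001 per birth, sync every 10,000 steps
    and an era of 100,000 steps.
    """

    n_islands: int = 100
    agents_per_island: int = 50
    domain_halfwidth: float = 20.0
    rho: float = 0.139
    dt: float = 0.0005
    a_mean: float = 1.0
    a_sigma: float = 0.025
    p_b: float = 0.001
    birth_radius: float = 1.13
    sync_interval: int = 10_000
    era_length: int = 100_000
    max_eras: int = 1
    sigma_noise: float = 0.1
    comm_enabled: bool = True
    angle_reference: str = "east"  # heading measured from +x ("east") or +y ("north")
    seed: int = 0
    mutation: MutationConfig = field(default_factory=MutationConfig)

    def validate(self) -> None:
        if not (self.rho < self.birth_radius < self.domain_halfwidth):
            raise ValueError("need rho < birth_radius < domain_halfwidth")
        for name in ("p_b",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.angle_reference not in ("east", "north"):
            raise ValueError("angle_reference must be 'east' or 'north'")
        if self.n_islands < 1 or self.agents_per_island < 2:
            raise ValueError("need >= 1 island and >= 2 agents per island")
        if self.era_length % self.sync_interval != 0:
            raise ValueError("era_length must be a multiple of sync_interval")


class Agent:
    """One agent: genome, compiled evaluator and runtime state."""

    __slots__ = ("genome", "compiled", "st")

    def __init__(self, genome: Genome, st: AgentState):
        self.genome = genome
        self.compiled = CompiledGenome(genome)
        self.st = st


def fresh_state(genome: Genome, x: float, y: float, a: float) -> AgentState:
    svals = [genome.v0[v] for v in genome.evolved_vars]
    return AgentState(x=x, y=y, svals=svals, a=a)


def reinitialize(agent: Agent, x: float, y: float) -> None:
    """Reset evolved state to v0 and zero the signal channel; keep ``a``."""
    st = agent.st
    st.x = x
    st.y = y
    st.svals = [agent.genome.v0[v] for v in agent.genome.evolved_vars]
    st.theta = 0.0
    st.omega_out = 0.0
    st.omega_in = 0.0


def nearest_neighbor(positions, i: int):
    """Index of the agent closest (Euclidean) to agent ``i``, or None.

    Ties break to the lowest index; a single-agent list has no neighbour.
    """
    n = len(positions)
    if n < 2:
        return None
    xi, yi = positions[i]
    best = None
    best_d2 = math.inf
    for j in range(n):
        if j == i:
            continue
        dx = positions[j][0] - xi
        dy = positions[j][1] - yi
        d2 = dx * dx + dy * dy
        if d2 < best_d2:
            best_d2 = d2
            best = j
    return best


def place_agent(rng, occupied, radius: float = 1.13, min_dist: float = 0.139,
                max_attempts: int = 1000):
    """Uniform point in the disc of ``radius`` about the origin, at least
    ``min_dist`` from every occupied point.

    Rejection sampling; after ``max_attempts`` failures the best candidate
    seen (largest clearance) is returned so placement always terminates.
    """
    best = None
    best_clearance = -1.0
    for _ in range(max_attempts):
        r = radius * math.sqrt(rng.random())
        phi = 2.0 * math.pi * rng.random()
        x = r * math.cos(phi)
        y = r * math.sin(phi)
        clearance = math.inf
        for ox, oy in occupied:
            dx, dy = ox - x, oy - y
            d2 = dx * dx + dy * dy
            if d2 < clearance:
                clearance = d2
        if clearance >= min_dist * min_dist:
            return (x, y)
        if clearance > best_clearance:
            best_clearance = clearance
            best = (x, y)
    return best


class Island:
    """One subpopulation with its own RNG stream and genetics state."""

    __slots__ = (
        "id",
        "agents",
        "genetics",
        "rng",
        "outgoing",
        "pending_deaths",
        "births_window",
        "births_era",
    )

    def __init__(self, island_id: int, rng):
        self.id = island_id
        self.agents: list[Agent] = []
        self.genetics = IslandGeneticsState()
        self.rng = rng
        self.outgoing: list[tuple[int, Agent]] = []  # (destination id, migrant)
        self.pending_deaths = 0
        self.births_window = 0
        self.births_era = 0

    def positions(self):
        return [(a.st.x, a.st.y) for a in self.agents]


def _grid_shape(n: int):
    rows = int(math.isqrt(n))
    while n % rows != 0:
        rows -= 1
    return rows, n // rows


class World:
    """Grid of islands plus the global tag counter and event log."""

    def __init__(self, cfg: WorldConfig):
        cfg.validate()
        self.cfg = cfg
        self.t = 0
        self.tag_alloc = TagAllocator()
        self.rng = np.random.default_rng([cfg.seed, 2**20])  # migration shuffle
        self.rows, self.cols = _grid_shape(cfg.n_islands)
        self.islands = [
            Island(i, np.random.default_rng([cfg.seed, i])) for i in range(cfg.n_islands)
        ]
        self.events: list[str] = []
        self.birth_log: list[tuple[int, int, int]] = []  # (era, island, births)
        self._seed_population()

    # -- topology ----------------------------------------------------------
    def border_neighbors(self, island_id: int) -> list[int]:
        """The (up to) four border-sharing islands; diagonals excluded."""
        r, c = divmod(island_id, self.cols)
        cand = [
            ((r - 1) % self.rows) * self.cols + c,
            ((r + 1) % self.rows) * self.cols + c,
            r * self.cols + (c - 1) % self.cols,
            r * self.cols + (c + 1) % self.cols,
        ]
        out = []
        for k in cand:
            if k != island_id and k not in out:
                out.append(k)
        return out

    # -- setup -------------------------------------------------------------
    def _seed_population(self) -> None:
        cfg = self.cfg
        for isl in self.islands:
            occupied = []
            for _ in range(cfg.agents_per_island):
                g = primordial_genome(self.tag_alloc, isl.rng)
                x, y = place_agent(isl.rng, occupied, cfg.birth_radius, cfg.rho)
                occupied.append((x, y))
                a = cfg.a_mean + cfg.a_sigma * isl.rng.standard_normal()
                isl.agents.append(Agent(g, fresh_state(g, x, y, a)))

    # -- death bookkeeping --------------------------------------------------
    def _kill_one(self, isl: Island, exclude: Agent | None = None) -> None:
        """Remove one agent: a marked (overflow / fell-off) agent when any
        is pending, otherwise a uniformly random agent; never the newborn."""
        pool = [a for a in isl.agents if a.st.marked_for_death and a is not exclude]
        if not pool:
            pool = [a for a in isl.agents if a is not exclude]
        if not pool:
            return
        victim = pool[int(isl.rng.integers(len(pool)))]
        isl.agents.remove(victim)
        self.events.append(f"{self.t}\tdeath\t{isl.id}")

    # -- per-step dynamics ---------------------------------------------------
    def step(self) -> None:
        for isl in self.islands:
            step_island(isl, self)
        self.t += 1
        if self.t % self.cfg.sync_interval == 0:
            exchange_migrants(self)
            for isl in self.islands:
                isl.genetics.beta = compute_beta(isl.births_window, self.cfg.mutation)
                isl.births_window = 0

    def era_snapshot(self, era: int, isl: Island) -> dict:
        return {
            "era": era,
            "island_id": isl.id,
            "agents": [
                {
                    "genome": genome_to_dict(a.genome),
                    "a": a.st.a,
                    "position": [a.st.x, a.st.y],
                }
                for a in isl.agents
            ],
        }


def step_island(isl: Island, world: World) -> None:
    """Advance one island by one timestep (see module docstring for order)."""
    cfg = world.cfg
    # Deaths owed from migrant arrivals at the previous sync point.
    while isl.pending_deaths > 0:
        world._kill_one(isl)
        isl.pending_deaths -= 1

    agents = isl.agents
    n = len(agents)
    if n == 0:
        return
    pos = [(a.st.x, a.st.y) for a in agents]

    # (1) signal routing from current positions, previous-step outputs
    if cfg.comm_enabled and n >= 2:
        prev_out = [a.st.omega_out for a in agents]
        for i in range(n):
            j = nearest_neighbor(pos, i)
            agents[i].st.omega_in = prev_out[j] if j is not None else 0.0
    else:
        for a in agents:
            a.st.omega_in = 0.0

    # (2)-(6) synchronous evaluation, state update, overflow and edge checks
    dt = cfg.dt
    east = cfg.angle_reference == "east"
    sigma_noise = cfg.sigma_noise
    hw = cfg.domain_halfwidth
    rng = isl.rng
    for a in agents:
        st = a.st
        comp = a.compiled
        noise = sigma_noise * rng.standard_normal() if comp.uses_noise and sigma_noise else 0.0
        out = comp.step(st.x, st.y, st.omega_in, noise, *st.svals)
        theta = out[0]
        omega = out[1]
        if not math.isfinite(theta):
            theta = rng.uniform(-1.0, 1.0)
            st.marked_for_death = True
        if not math.isfinite(omega):
            omega = rng.uniform(-1.0, 1.0)
            st.marked_for_death = True
        if comp.n_state:
            svals = st.svals
            for k in range(comp.n_state):
                v = svals[k] + out[2 + k]
                if not math.isfinite(v):
                    v = rng.uniform(-1.0, 1.0)
                    st.marked_for_death = True
                svals[k] = v
        st.theta = theta
        st.omega_out = omega
        step_len = st.a * dt
        if east:
            st.x += step_len * math.cos(theta)
            st.y += step_len * math.sin(theta)
        else:
            st.x += step_len * math.sin(theta)
            st.y += step_len * math.cos(theta)
        if abs(st.x) > hw or abs(st.y) > hw:
            if not st.marked_for_death:
                st.marked_for_death = True
                world.events.append(f"{world.t}\tfell_off\t{isl.id}")

    # (7) reproduction scan on post-move positions, ascending distance
    rho2 = cfg.rho * cfg.rho
    pairs = []
    for i in range(n):
        if agents[i].st.marked_for_death:
            continue  # pending deaths never parent; they die at the event
        xi, yi = agents[i].st.x, agents[i].st.y
        for j in range(i + 1, n):
            if agents[j].st.marked_for_death:
                continue
            dx = agents[j].st.x - xi
            dy = agents[j].st.y - yi
            d2 = dx * dx + dy * dy
            if d2 < rho2:
                pairs.append((d2, i, j))
    if pairs:
        pairs.sort()
        used = set()
        snapshot = list(agents)
        for _, i, j in pairs:
            ai, aj = snapshot[i], snapshot[j]
            if ai in used or aj in used:
                continue
            if ai not in isl.agents or aj not in isl.agents:
                continue  # removed by a death in an earlier event this step
            used.add(ai)
            used.add(aj)
            reproduce_event(isl, ai, aj, world)


def reproduce_event(isl: Island, parent1: Agent, parent2: Agent, world: World) -> None:
    """One birth: offspring pipeline, compensating death, relocations.

    A node-cap stillbirth triggers no compensating death, keeping the
    population constant.  With probability ``p_b`` the offspring is queued
    as a migrant to a uniformly chosen border-sharing island (delivered at
    the next sync point); in that case the home island sees no birth and
    therefore no death.
    """
    cfg = world.cfg
    rng = isl.rng
    isl.births_window += 1
    isl.births_era += 1
    res = make_offspring(
        parent1.genome, parent2.genome, isl.genetics, cfg.mutation, rng, world.tag_alloc
    )
    for p in (parent1, parent2):
        p.st.repro_count += 1

    newborn = None
    if res.genome is not None:
        a = cfg.a_mean + cfg.a_sigma * rng.standard_normal()
        newborn = Agent(res.genome, fresh_state(res.genome, 0.0, 0.0, a))
        neighbors = world.border_neighbors(isl.id)
        if neighbors and rng.random() < cfg.p_b:
            dest = neighbors[int(rng.integers(len(neighbors)))]
            isl.outgoing.append((dest, newborn))
            world.events.append(f"{world.t}\tmigrate\t{isl.id}\t{dest}")
            newborn = None  # not part of this island
        else:
            world._kill_one(isl, exclude=None)
    else:
        world.events.append(f"{world.t}\tstillbirth\t{isl.id}")

    # Parents move to fresh random spots and restart from v0.
    for p in (parent1, parent2):
        occupied = [(a.st.x, a.st.y) for a in isl.agents if a is not p]
        x, y = place_agent(rng, occupied, cfg.birth_radius, cfg.rho)
        reinitialize(p, x, y)

    if newborn is not None:
        occupied = [(a.st.x, a.st.y) for a in isl.agents]
        x, y = place_agent(rng, occupied, cfg.birth_radius, cfg.rho)
        newborn.st.x = x
        newborn.st.y = y
        isl.agents.append(newborn)
        world.events.append(f"{world.t}\tbirth\t{isl.id}")


def exchange_migrants(world: World) -> None:
    """Deliver all queued migrants in randomized order at a sync point.

    Each delivery is treated as a birth on the receiving island: the
    migrant is placed there immediately and one compensating random death
    is owed at the island's next timestep.
    """
    queue = []
    for isl in world.islands:
        queue.extend(isl.outgoing)
        isl.outgoing = []
    if not queue:
        return
    order = world.rng.permutation(len(queue))
    for k in order:
        dest_id, migrant = queue[int(k)]
        dest = world.islands[dest_id]
        occupied = [(a.st.x, a.st.y) for a in dest.agents]
        x, y = place_agent(dest.rng, occupied, world.cfg.birth_radius, world.cfg.rho)
        migrant.st.x = x
        migrant.st.y = y
        dest.agents.append(migrant)
        dest.pending_deaths += 1
        world.events.append(f"{world.t}\tmigrant_arrival\t{dest.id}")


@dataclass
class RunResult:
    """Everything a run produces: snapshots, per-era birth counts, events."""

    config: WorldConfig
    snapshots: dict  # (era, island_id) -> snapshot dict
    birth_log: list  # (era, island_id, births)
    events: list


def run_world(cfg: WorldConfig) -> RunResult:
    """Simulate ``max_eras`` eras and snapshot every island once per era."""
    world = World(cfg)
    snapshots = {}
    steps_per_era = cfg.era_length
    for era in range(1, cfg.max_eras + 1):
        for _ in range(steps_per_era):
            world.step()
        for isl in world.islands:
            # A sync point can coincide with the era boundary; settle any
            # death owed for a just-delivered migrant before snapshotting
            # (no dynamics occur in between, so behaviour is unchanged).
            while isl.pending_deaths > 0:
                world._kill_one(isl)
                isl.pending_deaths -= 1
            snapshots[(era, isl.id)] = world.era_snapshot(era, isl)
            world.birth_log.append((era, isl.id, isl.births_era))
            isl.births_era = 0
    return RunResult(cfg, snapshots, world.birth_log, world.events)
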