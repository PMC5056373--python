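"""Non-evolving control tests of a snapshot population.

A control test replays a frozen set of genomes for one era: when two
agents meet within the reproduction distance the event is only counted
(no offspring genome is ever created) and both are moved to fresh random
spots and reinitialized, so nothing evolves.  Population turnover is
emulated by relocating each agent with a small per-step probability.
Every agent's inputs (x, y) and output signal are recorded at every
timestep; the Pearson correlation between position and output of the top
reproducing agent is the summary statistic.  Disabling the communication
channel simply forces ``omega_in = 0`` for all t.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genome import CompiledGenome, Genome
from .world import nearest_neighbor, place_agent

__all__ = [
    "ControlTestConfig",
    "ControlTestResult",
    "run_control_test",
    "pearson_r",
    "top_reproducer",
]


@dataclass
class ControlTestConfig:
    """Settings for one control run (defaults mirror the live world)."""

    duration: int = 100_000          # timesteps; one era
    comm_enabled: bool = True
    relocation_prob: float = 0.001   # per robot per timestep
    rho: float = 0.139
    dt: float = 0.0005
    birth_radius: float = 1.13
    sigma_noise: float = 0.1
    angle_reference: str = "east"
    seed: int = 0

    def validate(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 0.0 <= self.relocation_prob <= 1.0:
            raise ValueError("relocation_prob must be in [0, 1]")


@dataclass
class ControlTestResult:
    """Counts and the recorded series of the top reproducing agent."""

    reproduction_events: int
    per_agent_counts: list
    top_index: int
    samples: np.ndarray       # (duration, 3): x, y, omega_out of the top agent
    r_x: float | None
    r_y: float | None


def pearson_r(v, omega):
    """Pearson product-moment correlation, or None when undefined.

    ``r`` is undefined when the output series is constant (zero variance);
    such points are omitted from downstream series.
    """
    v = np.asarray(v, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if v.shape != omega.shape:
        raise ValueError("sample series must have equal length")
    if v.size < 2:
        raise ValueError("need at least two samples")
    dv = v - v.mean()
    dw = omega - omega.mean()
    sw = math.sqrt(float(dw @ dw))
    if sw == 0.0 or not math.isfinite(sw):
        return None
    sv = math.sqrt(float(dv @ dv))
    if sv == 0.0 or not math.isfinite(sv):
        return None
    r = float((dv @ dw) / (sv * sw))
    # rounding can push a perfectly linear series a few ulp past +/-1
    return max(-1.0, min(1.0, r))


def top_reproducer(counts) -> int:
    """Index with the most counted reproduction events; ties -> lowest."""
    best = 0
    for i, c in enumerate(counts):
        if c > counts[best]:
            best = i
    return best


class _ControlAgent:
    __slots__ = ("genome", "compiled", "a", "x", "y", "svals", "omega_out", "omega_in")

    def __init__(self, genome: Genome, a: float):
        self.genome = genome
        self.compiled = CompiledGenome(genome)
        self.a = a
        self.x = 0.0
        self.y = 0.0
        self.svals = []
        self.omega_out = 0.0
        self.omega_in = 0.0

    def reinit(self, x: float, y: float) -> None:
        self.x = x
        self.y = y
        self.svals = [self.genome.v0[v] for v in self.genome.evolved_vars]
        self.omega_out = 0.0
        self.omega_in = 0.0


def run_control_test(population, cfg: ControlTestConfig, rng=None) -> ControlTestResult:
    """Run one control test over a frozen population.

    ``population`` is a sequence of ``(genome, a)`` pairs (see
    :func:`noiseworld.io.population_from_snapshot` to build one from a
    snapshot file).  Genomes are never copied or modified; the caller can
    hash them before and after to confirm the no-evolution guarantee.

    Every agent's input position and output signal are recorded each
    timestep; at the end the top reproducer is selected (it cannot be
    known in advance) and its full series is returned together with the
    Pearson correlations of output against x and against y.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    agents = [_ControlAgent(g, a) for g, a in population]
    n = len(agents)
    if n < 2:
        raise ValueError("control test needs at least 2 agents")

    occupied: list[tuple[float, float]] = []
    for ag in agents:
        x, y = place_agent(rng, occupied, cfg.birth_radius, cfg.rho)
        occupied.append((x, y))
        ag.reinit(x, y)

    T = cfg.duration
    xs = np.empty((T, n))
    ys = np.empty((T, n))
    ws = np.empty((T, n))
    counts = [0] * n

    comm = cfg.comm_enabled
    dt = cfg.dt
    east = cfg.angle_reference == "east"
    sigma_noise = cfg.sigma_noise
    rho2 = cfg.rho * cfg.rho
    reloc_p = cfg.relocation_prob
    uniform = rng.random
    normal = rng.standard_normal

    for t in range(T):
        # population-turnover lottery
        for ag in agents:
            if uniform() < reloc_p:
                occupied = [(b.x, b.y) for b in agents if b is not ag]
                x, y = place_agent(rng, occupied, cfg.birth_radius, cfg.rho)
                ag.reinit(x, y)

        pos = [(ag.x, ag.y) for ag in agents]
        if comm:
            prev = [ag.omega_out for ag in agents]
            for i in range(n):
                j = nearest_neighbor(pos, i)
                agents[i].omega_in = prev[j] if j is not None else 0.0
        else:
            for ag in agents:
                ag.omega_in = 0.0

        for i, ag in enumerate(agents):
            comp = ag.compiled
            noise = sigma_noise * normal() if comp.uses_noise and sigma_noise else 0.0
            out = comp.step(ag.x, ag.y, ag.omega_in, noise, *ag.svals)
            theta = out[0]
            omega = out[1]
            if not math.isfinite(theta):
                theta = rng.uniform(-1.0, 1.0)
            if not math.isfinite(omega):
                omega = rng.uniform(-1.0, 1.0)
            if comp.n_state:
                svals = ag.svals
                for k in range(comp.n_state):
                    v = svals[k] + out[2 + k]
                    if not math.isfinite(v):
                        v = rng.uniform(-1.0, 1.0)
                    svals[k] = v
            # record the inputs used this step with the output they produced
            xs[t, i] = ag.x
            ys[t, i] = ag.y
            ws[t, i] = omega
            ag.omega_out = omega
            step_len = ag.a * dt
            if east:
                ag.x += step_len * math.cos(theta)
                ag.y += step_len * math.sin(theta)
            else:
                ag.x += step_len * math.sin(theta)
                ag.y += step_len * math.cos(theta)

        # meetings: count, relocate, reinitialize -- never reproduce
        pairs = []
        for i in range(n):
            xi, yi = agents[i].x, agents[i].y
            for j in range(i + 1, n):
                dx = agents[j].x - xi
                dy = agents[j].y - yi
                d2 = dx * dx + dy * dy
                if d2 < rho2:
                    pairs.append((d2, i, j))
        if pairs:
            pairs.sort()
            used = set()
            for _, i, j in pairs:
                if i in used or j in used:
                    continue
                used.add(i)
                used.add(j)
                counts[i] += 1
                counts[j] += 1
                for k in (i, j):
                    ag = agents[k]
                    occupied = [(b.x, b.y) for b in agents if b is not ag]
                    x, y = place_agent(rng, occupied, cfg.birth_radius, cfg.rho)
                    ag.reinit(x, y)

    top = top_reproducer(counts)
    samples = np.column_stack([xs[:, top], ys[:, top], ws[:, top]])
    return ControlTestResult(
        reproduction_events=sum(counts) // 2,
        per_agent_counts=counts,
        top_index=top,
        samples=samples,
        r_x=pearson_r(xs[:, top], ws[:, top]),
        r_y=pearson_r(ys[:, top], ws[:, top]),
    )
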