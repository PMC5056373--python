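"""Handcrafted genomes exercising every downstream stage without evolution.

Three fixtures mirror the three communication regimes:

* non-communicating: constant output, heading independent of the channel;
* indexical: the output broadcasts latitude one-to-one (omega = 4.36 y)
  and the heading steers north or south from the sign of the difference
  between the heard signal and the agent's own broadcast;
* symbolic: a synthetic era history (correlation collapse plus rate jump)
  paired with a genome whose output equation listens to ``win``.

Fixture contracts are exact, so the noise terminal is disabled
(sigma_noise = 0) whenever fixtures are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import EraSeries
from .genome import (
    OMEGA,
    THETA,
    EquationTree,
    Genome,
    branch,
    const,
    validate_genome,
    var,
)

__all__ = [
    "FixtureSpec",
    "make_noncommunicating_fixture",
    "make_indexical_fixture",
    "make_symbolic_series_fixture",
    "fixture_population",
    "random_genome",
    "random_bindings",
]

#: slope of the indexical broadcast: omega_out = 4.36 * y
INDEXICAL_SLOPE = 4.36
#: steering gain; keeps the heading in (-pi, pi) over the operational range
STEER_GAIN = 0.3


@dataclass
class FixtureSpec:
    name: str
    genome: Genome
    intended_label: str
    notes: str = ""


def _own_broadcast():
    return branch("*", const(INDEXICAL_SLOPE), var("y"))


def make_noncommunicating_fixture() -> FixtureSpec:
    """Constant output; heading a function of own position only."""
    genome = Genome(
        trees=[
            EquationTree(0, THETA, branch("+", var("x"), var("y"))),
            EquationTree(1, OMEGA, const(2.5)),
        ],
        v0={},
    )
    validate_genome(genome)
    return FixtureSpec(
        name="noncommunicating",
        genome=genome,
        intended_label="none",
        notes="omega_out constant, win appears nowhere; r is undefined.",
    )


def make_indexical_fixture() -> FixtureSpec:
    """Broadcast latitude, chase the difference between heard and own signal.

    theta = 0.3 (win - 4.36 y): positive (northward heading component)
    exactly when the neighbour's broadcast exceeds the agent's own, so two
    agents converge in latitude; with the channel muted the heard signal
    carries no neighbour information.
    """
    genome = Genome(
        trees=[
            EquationTree(0, THETA, branch("*", const(STEER_GAIN), branch("-", var("win"), _own_broadcast()))),
            EquationTree(1, OMEGA, _own_broadcast()),
        ],
        v0={},
    )
    validate_genome(genome)
    return FixtureSpec(
        name="indexical",
        genome=genome,
        intended_label="indexical",
        notes="omega_out = 4.36 y exactly; control-test |r_y| = 1.",
    )


def make_symbolic_series_fixture() -> tuple:
    """A synthetic era history driving the symbolic branch of the classifier.

    Returns ``(series, top_genomes, spec)``: forty eras in three phases --
    no advantage (eras 1-10), indexical plateau with |r_y| near 1 (11-30),
    then a rate jump above the plateau with collapsed correlation (31-40)
    while the top genome's output equation references ``win``.
    """
    indexical = make_indexical_fixture().genome
    noncomm = make_noncommunicating_fixture().genome
    # dialogue genome: the output is modified by the input signal
    dialogue = Genome(
        trees=[
            EquationTree(0, THETA, branch("*", const(STEER_GAIN), branch("-", var("win"), _own_broadcast()))),
            EquationTree(1, OMEGA, branch("+", branch("/", var("win"), const(2.0)), branch("-", var("x"), var("y")))),
        ],
        v0={},
    )
    validate_genome(dialogue)

    eras = list(range(1, 41))
    births_comm, births_nocomm, r_x, r_y = [], [], [], []
    top_genomes = {}
    for era in eras:
        if era <= 10:  # no communication: no advantage, r undefined
            births_comm.append(100)
            births_nocomm.append(100)
            r_x.append(None)
            r_y.append(None)
            top_genomes[era] = noncomm
        elif era <= 30:  # indexical plateau
            births_comm.append(300)
            births_nocomm.append(100)
            r_x.append(0.05)
            r_y.append(0.97)
            top_genomes[era] = indexical
        else:  # symbolic: rate jump, correlation collapse, dialogue genome
            births_comm.append(400)
            births_nocomm.append(100)
            r_x.append(0.30)
            r_y.append(0.20)
            top_genomes[era] = dialogue
    series = EraSeries(eras, births_comm, births_nocomm, r_x, r_y)
    spec = FixtureSpec(
        name="symbolic",
        genome=dialogue,
        intended_label="symbolic",
        notes="synthetic series: plateau 300 -> 400 jump with |r| <= 0.3.",
    )
    return series, top_genomes, spec


def fixture_population(spec: FixtureSpec, n: int, rng=None, a_mean=1.0, a_sigma=0.025):
    """``n`` copies of a fixture genome with motion gains drawn at birth,
    ready for :func:`noiseworld.control.run_control_test`."""
    if rng is None:
        rng = np.random.default_rng(0)
    return [(spec.genome, a_mean + a_sigma * rng.standard_normal()) for _ in range(n)]


def random_genome(rng, n_mutation_rounds: int = 3) -> Genome:
    """A diverse random genome: primordial plus a few mutation rounds.

    Handy for property checks and benchmarks that need genomes spanning
    tree shapes and evolved state variables without running evolution.
    """
    from .genetics import MutationConfig, add_new_equation, mutate_tree
    from .genome import TagAllocator, primordial_genome

    alloc = TagAllocator()
    g = primordial_genome(alloc, rng)
    cfg = MutationConfig()
    for _ in range(int(rng.integers(n_mutation_rounds + 1))):
        tree = g.trees[int(rng.integers(len(g.trees)))]
        if rng.random() < 0.3:
            add_new_equation(g, tree, rng, alloc)
        else:
            mutate_tree(tree, g.vocab, cfg, rng)
    validate_genome(g, node_limit=None)
    return g


def random_bindings(genome: Genome, rng) -> dict:
    """Uniform [-3, 3] bindings for every variable in a genome's scope."""
    return {v: float(rng.uniform(-3.0, 3.0)) for v in genome.vocab}
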