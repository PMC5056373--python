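"""Sexual reproduction of genomes: inheritance, mutation, splice, reduction.

There is no fitness function anywhere in this package.  Selection arises
solely from who manages to reproduce; the operators here only describe
what happens to a genome once two agents have met.

The per-tree mutation probability is ``p_m = 0.025 * beta / n`` where
``n`` is the offspring's tree count and ``beta = min(500/b, 100)`` is an
island-level multiplier recomputed every 10,000 timesteps from the birth
count ``b`` of the previous window.  ``beta`` keeps the number of
mutations per unit time roughly constant as reproduction rates change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome import (
    BASE_VARS,
    OPS,
    EquationTree,
    Genome,
    GenomeError,
    TagAllocator,
    const,
    copy_tree,
    delta_target,
    iter_nodes,
    ramped_half_and_half,
    reduce_equations,
    tree_variables,
    var,
)

__all__ = [
    "MutationConfig",
    "IslandGeneticsState",
    "OffspringResult",
    "compute_beta",
    "mutation_probability",
    "inherit_equations",
    "mutate_tree",
    "point_mutation",
    "subtree_mutation",
    "splice_from_parent",
    "mutate_initial_state",
    "add_new_equation",
    "make_offspring",
]


@dataclass
class MutationConfig:
    """All genetic-operator rates and ranges.

    Defaults are the standard simulation settings; every field can be
    overridden through the run configuration file.
    """

    base_rate: float = 0.025          # numerator coefficient of p_m
    sigma_perturb: float = 0.5        # Gaussian sigma for constant-leaf perturbation
    const_range: tuple = (-5.0, 5.0)  # range of freshly drawn constants k
    v0_perturb_sigma: float = 0.25
    v0_replace_range: tuple = (-1.0, 1.0)
    whole_tree_replace_prob: float = 0.05
    new_equation_factor: float = 0.5  # new-equation probability = factor * p_m
    reduction_prob: float = 0.1
    node_limit: int = 200
    beta_numerator: float = 500.0
    beta_cap: float = 100.0


@dataclass
class IslandGeneticsState:
    """Per-island mutation-rate bookkeeping (recomputed every sync window)."""

    births_window: int = 0
    beta: float = 100.0  # window 0 has no birth history: 500/0 saturates


def compute_beta(b: int, cfg: MutationConfig = MutationConfig()) -> float:
    """beta = min(500/b, 100); b = 0 saturates at the cap."""
    if b < 0:
        raise ValueError("birth count must be >= 0")
    if b == 0:
        return cfg.beta_cap
    return min(cfg.beta_numerator / b, cfg.beta_cap)


def mutation_probability(beta: float, n: int, cfg: MutationConfig = MutationConfig()) -> float:
    """p_m = 0.025 * beta / n, clamped to 1 so it remains a probability."""
    if n < 1:
        raise ValueError("tree count must be >= 1")
    return min(cfg.base_rate * beta / n, 1.0)


# --------------------------------------------------------------------------
# Inheritance
# --------------------------------------------------------------------------

def _closure(trees: list, v0: dict, parents: tuple, rng) -> None:
    """Pull in defining equations for referenced but undefined variables.

    If an inherited (or spliced-in) tree references a state variable whose
    delta equation was not inherited, the definition is copied from a
    parent, transitively.  When both parents carry distinct definitions of
    the same variable a fair coin picks the donor.
    """
    defined = {t.delta_var for t in trees if t.is_delta}
    base = set(BASE_VARS)
    while True:
        needed = set()
        for t in trees:
            needed |= tree_variables(t.root) - base - defined
        if not needed:
            return
        for v in sorted(needed):
            candidates = [p for p in parents if v in p.delta_trees]
            if not candidates:
                raise GenomeError(f"no parent defines state variable {v!r}")
            donor = candidates[0] if len(candidates) == 1 else candidates[int(rng.integers(2))]
            trees.append(donor.delta_trees[v].copy())
            v0[v] = donor.v0[v]
            defined.add(v)


def inherit_equations(parent1: Genome, parent2: Genome, rng, max_redraws: int = 1000) -> Genome:
    """Equation-level sexual inheritance with dependency closure.

    For every equation the parents have in common a fair coin picks which
    parent's version the offspring receives.  The theta and omega_out
    trees are keyed by role (the offspring must end with exactly one of
    each); state equations are keyed by lineage tag.  Equations unique to
    one parent are inherited only when an inherited tree references the
    variable they define (applied transitively).  The offspring must
    receive at least one equation from each parent; the coin flips are
    redrawn in full when that is violated.
    """
    d1, d2 = parent1.delta_trees, parent2.delta_trees
    tags1 = {t.tag: t for t in parent1.trees if t.is_delta}
    tags2 = {t.tag: t for t in parent2.trees if t.is_delta}
    common_tags = sorted(set(tags1) & set(tags2))

    for _ in range(max_redraws):
        origins = set()
        chosen = []  # (tree, parent_index)
        for role_pair in (
            (parent1.theta_tree, parent2.theta_tree),
            (parent1.omega_tree, parent2.omega_tree),
        ):
            k = int(rng.integers(2))
            chosen.append((role_pair[k], k))
            origins.add(k)
        for tag in common_tags:
            k = int(rng.integers(2))
            chosen.append(((tags1, tags2)[k][tag], k))
            origins.add(k)
        if origins == {0, 1}:
            break
    else:  # pragma: no cover - two role coins always admit a mixed draw
        raise GenomeError("could not satisfy one-equation-from-each-parent")

    trees = []
    v0 = {}
    for tree, k in chosen:
        trees.append(tree.copy())
        if tree.is_delta:
            v0[tree.delta_var] = (parent1, parent2)[k].v0[tree.delta_var]
    _closure(trees, v0, (parent1, parent2), rng)
    # Stable order: theta, omega_out, then state equations by tag.
    trees.sort(key=lambda t: (0 if t.target == "theta" else 1 if t.target == "omega_out" else 2, t.tag))
    return Genome(trees, v0)


# --------------------------------------------------------------------------
# Mutation operators
# --------------------------------------------------------------------------

def _node_index(root):
    """All (node, parent, child_slot) triples, root first."""
    out = [(root, None, 0)]
    stack = [root]
    while stack:
        node = stack.pop()
        if node.kind == "branch":
            for slot, child in enumerate(node.children):
                out.append((child, node, slot))
                stack.append(child)
    return out


def _replace_node(tree: EquationTree, entry, replacement) -> None:
    node, parent, slot = entry
    if parent is None:
        tree.root = replacement
    else:
        parent.children[slot] = replacement


def point_mutation(tree: EquationTree, vocab, cfg: MutationConfig, rng) -> None:
    """Perturb a constant leaf or mutate another node, with equal probability.

    Branch nodes are reassigned a different arithmetic operation; variable
    leaves become a different variable or a fresh constant in
    ``cfg.const_range``.  If the tree has no constant leaf (or consists of
    a single constant) the only feasible arm is taken.
    """
    entries = _node_index(tree.root)
    consts = [e for e in entries if e[0].kind == "const"]
    others = [e for e in entries if e[0].kind != "const"]
    use_const = bool(consts) and (not others or rng.random() < 0.5)
    if use_const:
        node = consts[int(rng.integers(len(consts)))][0]
        node.value += rng.normal(0.0, cfg.sigma_perturb)
        return
    entry = others[int(rng.integers(len(others)))]
    node = entry[0]
    if node.kind == "branch":
        alternatives = [op for op in OPS if op != node.op]
        node.op = alternatives[int(rng.integers(3))]
        return
    # variable leaf: another variable or a new constant, equally likely
    alternatives = [v for v in vocab if v != node.var_id]
    if alternatives and rng.random() < 0.5:
        node.var_id = alternatives[int(rng.integers(len(alternatives)))]
    else:
        lo, hi = cfg.const_range
        _replace_node(tree, entry, const(rng.uniform(lo, hi)))


def subtree_mutation(tree: EquationTree, vocab, cfg: MutationConfig, rng) -> bool:
    """Replace a random node with a fresh ramped half-and-half subtree.

    With probability ``cfg.whole_tree_replace_prob`` (default 5%) the new
    subtree instead replaces the entire tree and the original tree is
    spliced onto a random node of the replacement.  Returns True when the
    whole-tree arm was taken.
    """
    replacement = ramped_half_and_half(vocab, rng)
    if rng.random() < cfg.whole_tree_replace_prob:
        original = tree.root
        tree.root = replacement
        entries = _node_index(tree.root)
        _replace_node(tree, entries[int(rng.integers(len(entries)))], original)
        return True
    entries = _node_index(tree.root)
    _replace_node(tree, entries[int(rng.integers(len(entries)))], replacement)
    return False


def mutate_tree(tree: EquationTree, vocab, cfg: MutationConfig, rng) -> bool:
    """Point or subtree mutation with equal probability (in place).

    Returns True when a whole-tree replacement occurred.
    """
    if rng.random() < 0.5:
        point_mutation(tree, vocab, cfg, rng)
        return False
    return subtree_mutation(tree, vocab, cfg, rng)


def splice_from_parent(tree: EquationTree, parent: Genome, rng) -> None:
    """Replace a random node of ``tree`` with a copied random parent subtree.

    The donor genome is never modified.  Scope repair (a spliced subtree
    may reference a donor-only state variable) is the caller's job.
    """
    donor_tree = parent.trees[int(rng.integers(len(parent.trees)))]
    donor_entries = _node_index(donor_tree.root)
    subtree = copy_tree(donor_entries[int(rng.integers(len(donor_entries)))][0])
    entries = _node_index(tree.root)
    _replace_node(tree, entries[int(rng.integers(len(entries)))], subtree)


def mutate_initial_state(v0: dict, p_m: float, cfg: MutationConfig, rng) -> None:
    """Per entry at probability p_m: perturb by N(0, 0.25) or replace with
    a uniform draw from [-1, 1], with equal probability (in place)."""
    lo, hi = cfg.v0_replace_range
    for k in sorted(v0):
        if rng.random() < p_m:
            if rng.random() < 0.5:
                v0[k] += rng.normal(0.0, cfg.v0_perturb_sigma)
            else:
                v0[k] = rng.uniform(lo, hi)


def add_new_equation(genome: Genome, tree: EquationTree, rng, tag_alloc: TagAllocator) -> str:
    """Add a fresh state equation and wire a reference into ``tree``.

    A new state variable (named after its globally unique tag, so names
    can never collide across lineages) gets a ramped half-and-half delta
    tree and initial value 0; a variable-leaf reference to it replaces a
    uniformly chosen node of the triggering tree.  Returns the new name.
    """
    tag = tag_alloc.new_tag()
    name = f"s{tag}"
    vocab = genome.vocab + [name]  # the new equation may reference itself
    genome.trees.append(EquationTree(tag, delta_target(name), ramped_half_and_half(vocab, rng)))
    genome.v0[name] = 0.0
    entries = _node_index(tree.root)
    _replace_node(tree, entries[int(rng.integers(len(entries)))], var(name))
    return name


# --------------------------------------------------------------------------
# Full offspring pipeline
# --------------------------------------------------------------------------

@dataclass
class OffspringResult:
    """Outcome of one reproduction; ``genome`` is None for a node-cap death."""

    genome: Genome | None
    p_m: float
    tree_mutations: int = 0
    whole_tree_replacements: int = 0
    splices: int = 0
    v0_entries: int = 0
    new_equations: int = 0
    reduced: bool = False
    node_count: int = 0

    @property
    def died(self) -> bool:
        return self.genome is None


def make_offspring(
    parent1: Genome,
    parent2: Genome,
    genetics_state: IslandGeneticsState,
    cfg: MutationConfig,
    rng,
    tag_alloc: TagAllocator,
) -> OffspringResult:
    """Run the whole reproduction pipeline for one offspring.

    Pipeline: inheritance -> per-tree mutation at p_m -> per-tree splice
    at p_m -> per-v0-entry mutation at p_m -> per-tree new-equation at
    0.5*p_m -> 10%-lottery equation reduction -> node-cap check.  An
    offspring whose final genome exceeds ``cfg.node_limit`` nodes dies
    immediately (``genome`` is None).
    """
    g = inherit_equations(parent1, parent2, rng)
    n = len(g.trees)
    p_m = mutation_probability(genetics_state.beta, n, cfg)
    res = OffspringResult(genome=g, p_m=p_m)

    parents = (parent1, parent2)
    for tree in g.trees:
        if rng.random() < p_m:
            res.tree_mutations += 1
            if mutate_tree(tree, g.vocab, cfg, rng):
                res.whole_tree_replacements += 1
    for tree in g.trees:
        if rng.random() < p_m:
            res.splices += 1
            splice_from_parent(tree, parents[int(rng.integers(2))], rng)
    # Scope repair: splices (and variable point-mutations cannot, but
    # splices can) may have introduced donor-only state variables.
    _closure(g.trees, g.v0, parents, rng)

    res.v0_entries = len(g.v0)
    mutate_initial_state(g.v0, p_m, cfg, rng)

    p_new = cfg.new_equation_factor * p_m
    for tree in list(g.trees):
        if rng.random() < p_new:
            add_new_equation(g, tree, rng, tag_alloc)
            res.new_equations += 1

    if rng.random() < cfg.reduction_prob:
        g = reduce_equations(g)
        res.reduced = True

    res.node_count = g.node_count
    if res.node_count > cfg.node_limit:
        res.genome = None
    else:
        res.genome = g
    return res
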