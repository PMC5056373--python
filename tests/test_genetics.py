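"""Reproduction pipeline: rates, inheritance, mutation operators."""

import math

import numpy as np
import pytest

from noiseworld.genetics import (
    IslandGeneticsState,
    MutationConfig,
    add_new_equation,
    compute_beta,
    inherit_equations,
    make_offspring,
    mutate_initial_state,
    mutate_tree,
    mutation_probability,
    point_mutation,
    splice_from_parent,
    subtree_mutation,
)
from noiseworld.genome import (
    EquationTree,
    Genome,
    TagAllocator,
    branch,
    const,
    delta_target,
    generate_random_tree,
    serialize_genome,
    tree_node_count,
    tree_variables,
    validate_genome,
    var,
)
from .conftest import random_genome

CFG = MutationConfig()


def _simple_parents(c1=1.0, c2=2.0):
    """Two parents sharing theta (tag 0) and omega (tag 1), distinguishable
    by their constant leaves."""
    p1 = Genome([EquationTree(0, "theta", const(c1)),
                 EquationTree(1, "omega_out", const(c1))])
    p2 = Genome([EquationTree(0, "theta", const(c2)),
                 EquationTree(1, "omega_out", const(c2))])
    return p1, p2


class TestRateFormulas:
    @pytest.mark.parametrize("b,expected", [(500, 1.0), (4, 100.0), (1000, 0.5), (0, 100.0)])
    def test_beta_examples(self, b, expected):
        assert compute_beta(b) == expected

    @pytest.mark.parametrize("beta,n,expected", [(1, 5, 0.005), (100, 1, 1.0), (10, 10, 0.025)])
    def test_pm_examples(self, beta, n, expected):
        assert mutation_probability(beta, n) == pytest.approx(expected)

    def test_formulas_match_direct_oracle(self, rng):
        for _ in range(1000):
            b = int(rng.integers(0, 5000))
            n = int(rng.integers(1, 40))
            beta = compute_beta(b)
            assert beta == (100.0 if b == 0 else min(500.0 / b, 100.0))
            assert mutation_probability(beta, n) == min(0.025 * beta / n, 1.0)


class TestInheritance:
    def test_common_equation_coin_flip(self, rng):
        p1, p2 = _simple_parents()
        seen = set()
        for _ in range(200):
            child = inherit_equations(p1, p2, rng)
            seen.add((child.theta_tree.root.value, child.omega_tree.root.value))
        # offspring must mix parents, so the two all-one-parent patterns
        # (1,1) and (2,2) can never appear
        assert seen == {(1.0, 2.0), (2.0, 1.0)}

    def test_dependency_closure_pulls_defining_equation(self, rng):
        # p1's omega references s5, defined only by p1's tree 5
        p1 = Genome(
            [EquationTree(0, "theta", const(1.0)),
             EquationTree(1, "omega_out", var("s5")),
             EquationTree(5, delta_target("s5"), var("x"))],
            v0={"s5": 0.25},
        )
        p2 = Genome([EquationTree(0, "theta", const(2.0)),
                     EquationTree(1, "omega_out", const(2.0))])
        for _ in range(100):
            child = inherit_equations(p1, p2, rng)
            validate_genome(child, node_limit=None)
            if "s5" in tree_variables(child.omega_tree.root):
                assert "s5" in child.delta_trees
                assert child.v0["s5"] == 0.25

    def test_transitive_closure(self, rng):
        # s3's definition references s4, which must come along too
        p1 = Genome(
            [EquationTree(0, "theta", var("s3")),
             EquationTree(1, "omega_out", const(1.0)),
             EquationTree(3, delta_target("s3"), var("s4")),
             EquationTree(4, delta_target("s4"), const(0.5))],
            v0={"s3": 0.0, "s4": 0.1},
        )
        p2 = Genome([EquationTree(0, "theta", const(2.0)),
                     EquationTree(1, "omega_out", const(2.0))])
        for _ in range(100):
            child = inherit_equations(p1, p2, rng)
            validate_genome(child, node_limit=None)

    def test_role_uniqueness_with_mismatched_tags(self, rng):
        p1 = Genome([EquationTree(10, "theta", const(1.0)),
                     EquationTree(11, "omega_out", const(1.0))])
        p2 = Genome([EquationTree(20, "theta", const(2.0)),
                     EquationTree(21, "omega_out", const(2.0))])
        for _ in range(50):
            child = inherit_equations(p1, p2, rng)
            validate_genome(child, node_limit=None)
            assert len(child.trees) == 2


class TestMutationOperators:
    def test_constant_perturbation_distribution(self, rng):
        deltas = []
        for _ in range(4000):
            tree = EquationTree(0, "theta", const(2.0))
            point_mutation(tree, ["x"], CFG, rng)
            if tree.root.kind == "const":
                deltas.append(tree.root.value - 2.0)
        # single-constant tree: the perturb arm is the only feasible one
        assert len(deltas) == 4000
        assert abs(np.mean(deltas)) < 3 * 0.5 / math.sqrt(len(deltas))
        assert np.std(deltas) == pytest.approx(0.5, rel=0.1)

    def test_branch_op_mutates_to_different_op(self, rng):
        for _ in range(100):
            tree = EquationTree(0, "theta", branch("+", var("x"), var("y")))
            point_mutation(tree, ["x", "y"], CFG, rng)
            if tree.root.kind == "branch":
                assert tree.root.op in ("-", "*", "/") or (
                    # a constant-free tree may instead mutate a variable leaf
                    tree.root.op == "+"
                )

    def test_variable_leaf_becomes_other_variable_or_constant(self, rng):
        changed_var = changed_const = 0
        for _ in range(500):
            tree = EquationTree(0, "theta", var("x"))
            point_mutation(tree, ["x", "y", "win"], CFG, rng)
            if tree.root.kind == "var":
                assert tree.root.var_id != "x"
                changed_var += 1
            else:
                assert -5 <= tree.root.value <= 5
                changed_const += 1
        assert changed_var > 0 and changed_const > 0

    def test_whole_tree_replacement_splices_original(self, rng):
        hits = 0
        for _ in range(2000):
            original = branch("+", var("x"), var("y"))
            tree = EquationTree(0, "theta", original)
            if subtree_mutation(tree, ["x", "y"], CFG, rng):
                hits += 1
                assert any(
                    n is original
                    for n in _all_nodes(tree.root)
                ), "original tree must be spliced into the replacement"
        assert 0.03 < hits / 2000 < 0.07

    def test_splice_copies_and_donor_untouched(self, rng):
        donor = random_genome(rng)
        before = serialize_genome(donor)
        tree = EquationTree(0, "theta", var("x"))
        splice_from_parent(tree, donor, rng)
        assert serialize_genome(donor) == before
        # single-leaf tree: the replacement is the chosen donor subtree
        assert tree_node_count(tree.root) >= 1

    def test_v0_perturb_replace_split(self, rng):
        perturbs = replaces = 0
        for _ in range(4000):
            v0 = {"s1": 0.3}
            mutate_initial_state(v0, 1.0, CFG, rng)
            if abs(v0["s1"] - 0.3) < 1e-12:
                continue
            # replacement draws land in [-1, 1]; perturbations of 0.3 may
            # too, so classify by the union only where unambiguous
            if -1.0 <= v0["s1"] <= 1.0:
                replaces += 1
            else:
                perturbs += 1
        assert perturbs > 0 and replaces > 0

    def test_v0_replacement_bounded(self, rng):
        for _ in range(500):
            v0 = {"s1": 99.0}
            mutate_initial_state(v0, 1.0, CFG, rng)
            assert v0["s1"] <= 99.0 + 5 * 0.25  # perturb stays near, replace in [-1,1]

    def test_add_new_equation_grows_and_references(self, rng):
        alloc = TagAllocator(100)
        g = Genome([EquationTree(0, "theta", branch("+", var("x"), var("y"))),
                    EquationTree(1, "omega_out", const(1.0))])
        name = add_new_equation(g, g.trees[0], rng, alloc)
        assert len(g.trees) == 3
        assert name in tree_variables(g.theta_tree.root)
        assert g.v0[name] == 0.0
        tags = [t.tag for t in g.trees]
        assert len(set(tags)) == 3
        validate_genome(g, node_limit=None)


def _all_nodes(root):
    from noiseworld.genome import iter_nodes

    return list(iter_nodes(root))


class TestMakeOffspring:
    def test_offspring_mixes_parents_and_validates(self, rng):
        state = IslandGeneticsState(beta=1.0)
        alloc = TagAllocator(1000)
        for _ in range(300):
            p1 = random_genome(rng)
            p2 = random_genome(rng)
            res = make_offspring(p1, p2, state, CFG, rng, alloc)
            if res.genome is not None:
                validate_genome(res.genome, node_limit=CFG.node_limit)
                assert len(res.genome.trees) >= 2

    def test_node_cap_death(self, rng):
        state = IslandGeneticsState(beta=0.0)  # no mutations
        alloc = TagAllocator(0)
        big1 = generate_random_tree(8, "full", ["x"], rng)   # 255 nodes
        big2 = generate_random_tree(8, "full", ["y"], rng)
        p = Genome([EquationTree(0, "theta", big1), EquationTree(1, "omega_out", big2)])
        res = make_offspring(p, p, state, CFG, rng, alloc)
        assert res.genome is None and res.died
        assert res.node_count > 200

    def test_reduction_lottery_rate(self, rng):
        state = IslandGeneticsState(beta=1.0)
        alloc = TagAllocator(10_000)
        p1, p2 = _simple_parents()
        hits = sum(
            make_offspring(p1, p2, state, CFG, rng, alloc).reduced
            for _ in range(4000)
        )
        se = math.sqrt(0.1 * 0.9 / 4000)
        assert abs(hits / 4000 - 0.1) < 3 * se

    def test_tags_never_collide(self, rng):
        state = IslandGeneticsState(beta=100.0)  # p_m = 1: mutate everything
        alloc = TagAllocator(50)
        p1 = random_genome(rng)
        p2 = random_genome(rng)
        for _ in range(200):
            res = make_offspring(p1, p2, state, CFG, rng, alloc)
            if res.genome is not None:
                tags = [t.tag for t in res.genome.trees]
                assert len(tags) == len(set(tags))
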