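"""Shared fixtures: RNGs, random-genome factories, independent oracles."""

import math

import numpy as np
import pytest

from noiseworld.fixtures import random_bindings, random_genome

__all__ = ["oracle_eval", "random_genome", "random_bindings"]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def oracle_eval(root, bindings):
    """Independent tree evaluator: an explicit postorder stack machine.

    Written separately from the recursive evaluator it cross-checks;
    division follows IEEE-754 semantics (x/0 -> signed inf, 0/0 -> nan).
    """
    out = []
    stack = [(root, False)]
    while stack:
        node, expanded = stack.pop()
        if node.kind == "const":
            out.append(node.value)
        elif node.kind == "var":
            out.append(bindings[node.var_id])
        elif not expanded:
            stack.append((node, True))
            stack.append((node.children[1], False))
            stack.append((node.children[0], False))
        else:
            b = out.pop()
            a = out.pop()
            if node.op == "+":
                out.append(a + b)
            elif node.op == "-":
                out.append(a - b)
            elif node.op == "*":
                out.append(a * b)
            elif b != 0.0:
                out.append(a / b)
            elif a == 0.0 or a != a:
                out.append(math.nan)
            else:
                sign = 1.0 if math.copysign(1.0, a) == math.copysign(1.0, b) else -1.0
                out.append(sign * math.inf)
    assert len(out) == 1
    return out[0]


@pytest.fixture
def random_genome_factory():
    return random_genome


@pytest.fixture
def oracle():
    return oracle_eval
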