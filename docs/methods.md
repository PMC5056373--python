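# Methods

## The model

Agents are *evolvable mathematical models* (EMMs): systems of difference
equations encoded as arithmetic expression trees that serve as the agent's
genome. Per genome there is one tree for the heading `theta`, one for the
communication output `omega_out`, and one `delta` tree per evolved state
variable `s_k`; motion is governed by two immutable equations

    dx = a * dt * cos(theta)        dy = a * dt * sin(theta)

with the gain `a ~ N(1, 0.025)` drawn once at birth and `dt = 0.0005`.
Terminal nodes are variable leaves (`x`, `y`, `win`, `noise`, or an evolved
state variable) or numeric constants; branch nodes are `+ - * /`. Division
is plain IEEE-754 floating point: a division by zero yields a signed
infinity or NaN that propagates until the world's overflow rule catches it
(a non-finite output is replaced by a uniform draw from [-1, 1] and the
agent is marked to die at the next birth). There is no protected division;
overflow-death *is* the protection mechanism.

Agents hear, each timestep, the previous-step output of their current
nearest neighbour (recomputed from positions every step). Routing is
asymmetric: two agents sharing a nearest neighbour both hear it, but it
hears only the closer of the two. There is no fitness function. Two agents
within the reproduction distance `rho = 0.139` produce one offspring, and
every viable birth is matched by one random death, so island populations
are constant; selection is nothing but differential reproduction.

## Genetics

Offspring genomes pass through a fixed pipeline: equation-level
inheritance, per-tree mutation at `p_m`, per-tree splice at `p_m`, per-v0
mutation at `p_m`, new-equation addition at `0.5 p_m`, a 10% equation-
reduction lottery, and the 200-node cap (violators die immediately, with
no compensating death). The mutation probability is

    p_m = 0.025 * beta / n,     beta = min(500 / b, 100)

with `n` the offspring's tree count and `b` the island's births over the
previous 10,000 steps; `beta` is recomputed at each sync point and starts
at its saturation value 100 (the world begins with no birth history).
`p_m` is clamped to 1.

Inheritance keys state equations by their lineage tag (a fair coin picks
the parent version for each common tag) and the `theta`/`omega_out` trees
by role, so the offspring always has exactly one of each. Equations unique
to one parent are pulled in transitively whenever an inherited or
spliced-in tree references the state variable they define; the
one-equation-from-each-parent constraint is enforced by redrawing the coin
flips. New state variables are named after their globally unique tag,
which makes cross-lineage name collisions impossible by construction, may
reference themselves in their own delta tree, and start at `v0 = 0`.

Equation reduction applies five rewrite rules recursively to a fixed
point: constant folding, `T + T -> 2*T`, `T - T -> 0`, `T * 0 -> 0`, and
`0 / T -> 0` (T not the zero constant). On finite values reduction is
bit-exact (none of the rules reassociates floating-point operations), and
this is what the soundness suite measures; at non-finite points (bindings
that hit a division by zero) the rules can change the result, which
mirrors their printed definitions.

## The world

Islands form a toroidal grid (rows x cols chosen as the most nearly square
factorization of the island count); migration at birth (probability
`p_b = 0.001`) sends the offspring to one of the four border-sharing
neighbours — never diagonals — where it is delivered at the next
10,000-step sync point, placed like any newborn, and triggers one death at
that island's next timestep. If a sync point coincides with an era
boundary the owed death is settled before the snapshot is taken (no
dynamics occur in between), so conservation is exact at every era
boundary.

Per timestep and island, the order of operations is: owed migrant deaths;
signal routing from current positions; one shared noise draw per agent
(`N(0, sigma_noise)`, default 0.1, consumed only by genomes whose trees
reference `noise`); synchronous evaluation of all trees from time-t
values; state and motion update; overflow and edge checks (`|x|` or
`|y| > 20` marks the agent to die at the next birth); then a reproduction
scan on post-move positions. Pairs within `rho` are processed in ascending
distance, each agent in at most one event per step; marked agents never
parent and are preferentially selected as the death that accompanies each
birth. Newborns and relocated parents are placed uniformly in the
radius-1.13 disc about the origin with a minimum clearance of `rho`
(rejection sampling, 1000 attempts, then the largest-clearance candidate).

Determinism: each island owns a `numpy` RNG stream seeded from
`(seed, island_id)`, migrant delivery order uses a separate world-level
stream, and island iteration order is fixed, so identical `(config, seed)`
produce byte-identical snapshots and event logs. Islands could run
concurrently between sync points without changing results; this package
steps them sequentially (at the population sizes it targets, the
interpreter overhead dominates and process parallelism buys nothing).
Genomes are compiled once per birth into a single Python function; a
property test pins the compiled path to the recursive evaluator, which is
itself pinned to an independent stack-machine oracle in the test suite.

## Control tests and the correlation statistic

A control test replays a frozen snapshot population for a configurable
duration (default one era, 100,000 steps): meetings within `rho` are
counted, and both agents are relocated and reinitialized, but no offspring
genome is ever created; additionally every agent relocates with
probability 0.001 per step, emulating turnover. Every agent's series is
recorded — the top reproducer is unknowable in advance — and each sample
stores the *inputs* `(x, y)` together with the output they produced that
step, so an exactly linear broadcast like `omega = 4.36 y` yields
`|r_y| = 1` to machine precision. The Pearson coefficient is the standard
product-moment formula; it is undefined (returned as `None`) when the
output series is constant, and clamped to [-1, 1] against few-ulp
rounding excursions on perfectly linear series.

## Classification

Runs are labelled by the highest communication level attained:

* **none** — no era where the comm-enabled reproduction count reaches 1.5x
  the muted control;
* **indexical** — some era has that advantage together with
  `max(|r_x|, |r_y|) >= 0.9` for the top reproducer;
* **symbolic** — some later era beats the indexical plateau (the median
  comm-enabled count of the preceding 20 eras) by >= 1.15x while
  `max |r| <= 0.5` *and* the top reproducer's `omega_out` tree references
  `win` (a dialogue: output modified by input).

The underlying phenomena are regime changes, not sharp lines; the numeric
thresholds are this package's operational choices and all live on
`ClassifierConfig`. The dialogue condition is deliberately checked on the
output tree only — in the indexical regime the *steering* tree already
listens to the channel, and that must not count as symbolic. All
conditions are existential over eras, so extending a run's history can
upgrade but never downgrade its label.

## Fixtures

The handcrafted genomes mimic the three regimes without evolution. The
non-communicating fixture broadcasts a constant (its `r` is undefined by
construction). The indexical fixture broadcasts `omega = 4.36 y` and
steers with `theta = 0.3 (win - 4.36 y)`: the heading's sine has the sign
of the latitude gap to the heard neighbour, so pairs converge in `y`; the
gain 0.3 keeps the heading inside (-pi, pi) over the operational band
(|y| up to ~1.13, so |theta| <= 0.3 * 2 * 4.36 * 1.13 ~ 2.96). The
symbolic fixture pairs a synthetic 40-era series (no-advantage phase,
indexical plateau at 3x advantage with `r_y = 0.97`, then a 400-vs-300
rate jump with collapsed correlations) with a genome whose output equation
is `win/2 + (x - y)`. Fixtures are always simulated with
`sigma_noise = 0` so their contracts are exact.

What the fixtures do *not* show: they cannot demonstrate that evolution
discovers such schemes — only that every measurement stage (control test,
correlation, classifier, sonification) behaves correctly when fed each
regime. Emergence itself is a long-horizon stochastic outcome requiring
hundreds of eras on full-size islands; `run_world` supports such runs
(e.g. 4 islands x 50 agents x several hundred eras) but the test suite
does not gate on them.

## Problem sizes and numerical choices

The verification suites run at desk scale by design: reduction soundness
uses 1000 random genomes x 100 bindings (1e-9 relative tolerance,
division-by-zero bindings excluded); conservation uses a 2-island,
10-agent, 5-era world; determinism compares two full 1-era runs byte for
byte; operator-rate recovery uses 10,000 trials per operator against a
3-standard-error band; fixture control tests run 5,000-30,000 steps (the
indexical correlation contract is duration-independent, and 30,000 steps
give the comm-advantage comparison a comfortable margin: 10/10 seed-paired
wins). Ties in nearest-neighbour selection and in top-reproducer counts
break to the lowest index. Constants serialize via `repr`, the shortest
decimal string that round-trips the double bit-exactly.

## Known limitations

* Tree evaluation is interpreted Python (compiled per genome, but not
  vectorized); full-scale 100-island, multi-hundred-era histories are
  overnight jobs, not test-suite material.
* The classifier needs both comm-enabled and muted control counts per era;
  it cannot label a run from the evolving-world birth log alone.
* Snapshot reload covers populations, not mid-era world state; runs resume
  only at era granularity.
* Sonification produces a frequency table, not audio.
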