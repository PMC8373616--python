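# neuroblankets

Markov-blanket partitions of neural dynamical systems, across spatial
scales.

## The problem

Neuroscience routinely carves the brain into functional units — neurons,
cortical columns, regions, whole-brain networks — and then asks how those
units interact. What licenses a particular carving? One principled answer
is statistical: a set of *internal* states μ is a well-defined unit when a
*blanket* of states b renders it conditionally independent of everything
*external* η,

    μ ⊥ η | b   ⇔   p(μ, η | b) = p(μ | b) p(η | b).

In a directed (causal) graph, the minimal such blanket is the Markov
blanket of Pearl: the parents, the children, and the parents of the
children of μ. The blanket itself splits into *sensory* states s (which
affect, but are not affected by, the internal states) and *active* states
a (which affect, but are not affected by, the external states). For the
partition to hold in a dynamical setting, the flows must respect

    μ̇ = f_μ(μ, s, a)      ȧ = f_a(μ, s, a)
    η̇ = f_η(η, s, a)      ṡ = f_s(η, s, a)

i.e. exactly four dependency classes are forbidden: μ→s, μ→η, η→a, η→μ.
Losing a dependency preserves the blanket; gaining one generally destroys
it.

`neuroblankets` operationalises this formalism for the models neuroscience
actually uses. It provides:

- **Dependency graphs** over named states, Pearl blanket extraction,
  sensory/active classification, partition validation, and d-separation on
  the one-step unrolled (dynamic-Bayesian-network) view of cyclic flow
  graphs (`neuroblankets.graph`).
- **A model zoo** with declared dependency sparsity: a Hodgkin–Huxley
  variant with one gating state per channel, FitzHugh–Nagumo, Morris–Lecar,
  voltage/conductance neural-mass units coupled through sigmoid firing
  rates, and chains of four-population canonical-microcircuit (CMC)
  columns with laminar forward/backward connectivity
  (`neuroblankets.models`).
- **Simulation**: deterministic RK4 and stochastic Euler–Maruyama
  integration with bit-reproducible seeding, finite-difference
  linearization, and the Lyapunov stationary covariance
  (`neuroblankets.simulate`).
- **Statistical verification**: a nested-regression F-test of the one-step
  conditional independencies a partition claims, with mirror direction,
  stationary partial-correlation diagnostics and edge-gain negative
  controls (`neuroblankets.verify`).
- **Multiscale analysis**: coarse-graining of dependency graphs into macro
  units, recursive "blankets of blankets" ladders, and a soundness check
  that macro-scale validity implies micro-scale d-separation
  (`neuroblankets.multiscale`).
- **Synthetic fixtures**: random DAGs, random stable linear systems with
  exact four-role sparsity, single-edge perturbations, a Newtonian
  spring–mass chain exhibiting the same blanket template, and a static
  brain-wide network graph (`neuroblankets.fixtures`).
- **A CLI** (`neuroblankets build / verify / ladder`) that ties these into
  reproducible, fully seeded runs with DOT/GraphML/CSV/JSON artifacts.

## Worked example

The smallest interesting system is a pair of neural-mass units: each unit
has a membrane potential v and a conductance g; potentials depend only on
their own unit's conductance, while conductances collect the other unit's
potential through a sigmoid firing rate. From unit 1's perspective its
conductance is internal and unit 2's conductance is external:

```python
import numpy as np
import neuroblankets as nb

pair = nb.neural_mass_pair(A_mu=0.5, A_eta=0.5, noise=0.1)
partition = pair.partition()
print(partition.to_dict())
# {'internal': ['u1.g'], 'sensory': ['u2.v'], 'active': ['u1.v'], 'external': ['u2.g']}

print(nb.validate_partition(pair.declared_edges, partition))
# []            <- no forbidden dependency; the partition is structurally valid

traj = nb.integrate(pair, np.zeros(4), t_end=200.0, dt=0.01, seed=42)
res = nb.dynamic_ci_test(traj, partition, alpha=0.05)
print(f"F = {res.statistic:.3f}, p = {res.p_value:.3f}, verdict = {res.verdict}")
# F = 1.101, p = 0.294, verdict = accept
```

The test regresses the increment of the internal states on the current
internal + blanket states and asks whether adding the external states
reduces the residual sum of squares; here it does not (p = 0.29), as the
blanket structure predicts. Gaining a single forbidden edge destroys the
independence and the test detects it:

```python
from neuroblankets import fixtures
bad = fixtures.perturb_add_edge(pair, "external", "internal", weight=0.5, seed=0)
bad_traj = nb.integrate(bad, np.zeros(4), t_end=200.0, dt=0.01, seed=42)
print(nb.dynamic_ci_test(bad_traj, partition).p_value)
# 2.37e-05      -> verdict = reject
```

The same partition recurs at coarser scales. Grouping a four-column
canonical-microcircuit chain by column and choosing the leftmost column as
internal, the Markov blanket is the middle two columns — they insulate the
far ends from each other:

```python
m4 = nb.cmc_chain(4)
grouping = nb.CoarseGraining({n: n.split('.')[0] for n in m4.declared_edges.node_ids})
rung = nb.nested_blankets(m4.declared_edges, [grouping], [{"c1"}])[0]
print(rung["partition"].to_dict())
# {'internal': ['c1'], 'sensory': ['c3'], 'active': ['c2'], 'external': ['c4']}
print(nb.macro_ci_check(m4.declared_edges, grouping, rung["partition"]))
# True          <- macro validity is backed by micro-level d-separation
```

The same commands are available from the shell:

```sh
neuroblankets build --type cmc_chain --params '{"L": 2}' --out runs/cmc2
neuroblankets verify --model runs/cmc2/model.yaml --seed 1 --out runs/cmc2-verify
neuroblankets verify --model runs/cmc2/model.yaml --perturb external:active \
    --strict --out runs/cmc2-bad   # exits 2 and reports the violation
```

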