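# ccinfer

Graph-theoretic molecular descriptors and MILP-based inverse molecular
design, built around the **two-layered (2L) model** of chemical graphs and
the **cycle-configuration (CC)** descriptor family.

## The problem

QSAR/QSPR pipelines that work with interpretable, counting-style graph
descriptors face a representation gap: descriptors built from purely local
patterns cannot see *where* substituents sit around a ring.  The meta and
para isomers of dihydroxybenzene (resorcinol and hydroquinone) receive
identical 2L feature vectors, yet can have different measured activities.
This matters twice over — once for prediction accuracy, and once for
*inverse* design, where a mixed-integer linear program (MILP) searches for
a molecule whose feature vector satisfies a trained model: if the features
cannot express a motif, the MILP cannot control it.

`ccinfer` is for cheminformaticians who want an exact, solver-based
inverse-design loop over interpretable descriptors:

1. **Featurize** (2L + CC): a molecule `C = (H, α, β)` (explicit hydrogens,
   element labels α, bond multiplicities β ∈ {1,2,3}) is split by a branch
   parameter ρ (default 2) into an *interior* and *exterior*; every interior
   vertex `u` carries a *fringe tree* `C[u]`.  The 2L vector counts
   fringe-configurations (rooted-isomorphism classes of fringe trees),
   adjacency-configurations `(a, b, m)` and edge-configurations
   `(a d, b d′, m)` over interior edges, plus static descriptors.
   The CC vector adds, for each chordless cycle `C = (u₁ … u_ℓ)` with
   `ℓ ∈ [c_min, c_max]` (defaults 4–6), the canonical rank sequence
   `ξ(C) = min over 2ℓ rotations/reflections of (rank(μ₁), …, rank(μ_ℓ))`,
   where `μᵢ = mass*(C[uᵢ])` is the fringe-tree mass.  The full feature
   vector is the concatenation `f(C) = (f_2L(C), f_CC(C))`.
2. **Learn**: lasso linear regression (LLR), decision trees, random forests
   or small neural networks on `f(D)`, evaluated by the median R² / balanced
   accuracy over 10 repetitions of 5-fold cross-validation.  For LLR
   classification the threshold θ maximises a balanced-accuracy criterion
   over the training scores.
3. **Invert**: given a hyperplane `η(x) = w·x + b` and a *seed tree* —
   ring nodes expand to chordless cycles (ring edges force two cycles to
   share an edge), non-ring nodes/edges map to single vertices/edges — a
   MILP assigns one cycle-configuration per ring node, one fringe tree per
   interior vertex and one multiplicity per interior edge so that the
   decoded molecule is valence-correct, satisfies all availability sets and
   count bounds, and has `y* ≤ η(f(C†)) ≤ ȳ*` (or sits on the requested
   side of θ).  Solved with HiGHS via `scipy.optimize.milp`; every solution
   is decoded and re-featurized, and the round trip must agree exactly.

## Worked example

```python
from ccinfer.fixtures import reference_molecule
from ccinfer.featurize import build_vocabulary, featurize_dataset

mols = [reference_molecule(n) for n in ("catechol", "resorcinol", "hydroquinone")]
vocab = build_vocabulary(mols)
df = featurize_dataset(mols, vocab, "2L+CC",
                       ids=["catechol", "resorcinol", "hydroquinone"])
print("K_2L =", vocab.k_2l, " K_CC =", vocab.k_cc)
print(df[["n_heavy", "fc:C[-H]", "fc:C[-O[-H]]", "ec:C2-C3-2",
          "cc:1.1.1.1.2.2", "cc:1.1.1.2.1.2", "cc:1.1.2.1.1.2"]].to_string())
```

prints

```
K_2L = 23  K_CC = 3
              n_heavy  fc:C[-H]  fc:C[-O[-H]]  ec:C2-C3-2  cc:1.1.1.1.2.2  cc:1.1.1.2.1.2  cc:1.1.2.1.1.2
catechol          8.0       4.0           2.0         0.0             1.0             0.0             0.0
resorcinol        8.0       4.0           2.0         2.0             0.0             1.0             0.0
hydroquinone      8.0       4.0           2.0         2.0             0.0             0.0             1.0
```

Reading it: all three isomers share 8 heavy atoms, four CH fringe trees
(`C[-H]`, mass 13) and two phenolic fringe trees (`C[-O[-H]]`, mass 29).
Catechol (ortho) is already separated by its edge-configurations, but
resorcinol and hydroquinone agree on *every* 2L column — only the CC
columns differ: the meta ring canonicalises to `(1,1,1,2,1,2)` and the para
ring to `(1,1,2,1,1,2)`, where rank 1 is the lighter mass 13 and rank 2
the heavier 29.

Inverse design, in the same session:

```python
import numpy as np
from ccinfer.fixtures import reference_fringe
from ccinfer.learn import Hyperplane
from ccinfer.seedtree import SeedTree, Specification, InferenceTask
from ccinfer.milp import build_milp

cols = vocab.columns("2L+CC")
w = np.zeros(len(cols)); w[cols.index("n_heavy")] = 1.0
seed = SeedTree(nodes=["u1"], edges=[], ring_nodes={"u1"}, ring_edges=set())
spec = Specification(element_set=["C", "O"],
                     cc_sets={"u1": [(1, 1, 1, 2, 1, 2)]},
                     fringe_sets={"u1": [reference_fringe("psi1"), reference_fringe("psi2")]})
task = InferenceTask(model=Hyperplane(cols, w, 0.0), mode="regression",
                     y_lb=0, y_ub=99)
result = build_milp(seed, spec, task, vocab).solve()
print(result.status, result.predicted_value)       # optimal 8.0
print(result.graph.is_isomorphic_to(reference_molecule("resorcinol")))  # True
```

Forcing the meta cycle-configuration makes the solver reconstruct
resorcinol itself — the motif control that plain 2L descriptors cannot
express.

There is also a CLI (`ccinfer featurize / train / infer / make-fixtures`)
over SDF/SMILES inputs, CSV feature tables and JSON models; see
`ccinfer --help`.

## Limitations

See `docs/methods.md` for the model assumptions, parameter defaults,
numerical choices and known limitations (notably: kekulized input is
required, charges/stereochemistry are out of scope, and ring edges in seed
trees must form a matching).
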