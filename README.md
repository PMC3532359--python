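# threeprop

Node-label prediction on weighted undirected networks by **independently
weighted short random walks** (3Prop), together with the generic label
propagation (GLP) framework it generalizes.

## The problem

Given a network (protein interactions, genetic interactions, social ties)
and a set of nodes known to carry a label — a protein function, a political
affiliation, a demographic attribute — rank every other node by how likely
it is to carry the same label. Negative examples are usually unavailable,
so all non-positive nodes stand in for negatives.

Classical label propagation scores nodes by diffusing evidence from the
positives:

    f = Σ_{r≥0} λ^r M^r y,   0 < λ < 1,

where `y` is the 0/1 label vector and `M` is a degree-normalization of the
affinity matrix `A` — symmetric `S = D^{-1/2} A D^{-1/2}` (SLP) or
row-stochastic `P = D^{-1} A` (ALP). The term `(P^r y)_i` is the
probability that a length-`r` random walk from node `i` ends at a positive,
so propagation is a *positive, exponentially decaying* weighting of
short-walk probabilities. That hard-codes assortativity: direct neighbors
of positives always score high. On disassortative labelings (linked nodes
tend to differ) and shared-neighbor labelings (same-label nodes rarely
touch but share many neighbors — typical of genetic-interaction networks),
propagation can rank *worse than random* at every λ.

## The method

3Prop frees the first three walk lengths from the geometric ladder:

    f = w₁ M y + w₂ M² y + w₃ M³ y,

with real, possibly negative, weights fitted per task by linear
discriminant analysis:

    w = C⁻¹ (μ⁺ − μ⁻),

where μ⁺, μ⁻ are the class means of the per-node walk-feature rows
(x⁽¹⁾, x⁽²⁾, x⁽³⁾) and `C` the pooled within-class covariance. To keep a
node's own label out of its features, training positives are split: 2/3
drive the propagation, the held-out 1/3 (plus the non-positives) supply the
LDA statistics. Walks longer than three are left at zero weight: on
small-world networks the walk distribution is essentially stationary
(π_i = d_i/Σd) by r ≈ 10, so longer walks carry no label information —
the `diagnostics` module measures this directly.

## Worked example

```python
import numpy as np
from threeprop import (ThreeProp, GLP, auroc, default_spec, generate,
                       label_subsample)

# a 300-node network whose positives rarely touch but share hub neighbors
G, y = generate(default_spec("shared_neighbor", seed=0))

# train on half the positives, evaluate the held-out half vs all negatives
y_train = label_subsample(y, 0.5, seed=0)
held_out = (y == 1) & (y_train == 0)
eval_idx = np.flatnonzero(held_out | (y == 0))

tp = ThreeProp(random_state=0).fit(G.A, y_train)
glp = GLP(lam=0.5).fit(G.A, y_train)

print("3Prop weights:", tp.weights_.round(3))
print("held-out AUROC, 3Prop:", round(auroc(tp.scores_, y, eval_idx), 3))
print("held-out AUROC, GLP:  ", round(auroc(glp.scores_, y, eval_idx), 3))
```

Output:

```
3Prop weights: [ 0.054  0.809 -0.585]
held-out AUROC, 3Prop: 0.977
held-out AUROC, GLP:   0.183
```

The fitted weights put a large positive coefficient on length-2 walks
(shared neighbors), a negligible one on direct links and a negative one on
length-3 walks — a structure plain propagation cannot express: its fixed
positive, decaying weights rank the held-out positives far below random
(AUROC 0.18).

The same workflow is available from the shell:

```
threeprop simulate --pattern shared_neighbor --seed 0 --out-prefix net
threeprop cv --graph net.edges.tsv --labels net.labels.tsv --method nprop --out-prefix cv
threeprop diagnose --graph net.edges.tsv --out tv.tsv
```

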