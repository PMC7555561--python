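# rlca — regularized latent class analysis

`rlca` fits latent class models (LCMs) to dichotomous and polytomous
item-response data with *fused regularization*: penalties on pairwise
differences of item parameters that merge class-specific (and, for
polytomous items, category-specific) response probabilities into shared
values.  It is aimed at psychometricians and biostatisticians who want the
flexibility of exploratory LCMs without their notorious overparameterization
— e.g. for distractor analysis of multiple-choice tests, or typologies from
symptom checklists.

## Model

A latent class model with C classes represents I categorical items as
conditionally independent given class membership U:

    P(X = x) = Σ_c p_c Π_i P(X_i = x_i | U = c),

with item probabilities parameterized by multinomial logits γ_ikc
(reference category 0 fixed at zero) and class probabilities by logits δ_c.
The regularized LCM (RLCM) maximizes the penalized log-likelihood

    ℓ(γ, δ) − N Σ_i Pen(γ_i; λ),   e.g.  Pen(γ_i; λ) = Σ_{c<d} H_MCP(γ_ic − γ_id; λ)

by a penalized EM algorithm, where H is a LASSO, SCAD, or MCP penalty and
the pairwise differences may run over classes (λ1), categories (λ2), both,
or whole difference blocks (grouped fusion).  Parameters fused at the
optimum count once in AIC/BIC, and λ is chosen by grid search on BIC.  From
a fitted table of correct-response probabilities the package derives a
partial order of classes: class c lies below d when p_ic ≤ p_id for all
items (up to a tolerance of ι violating items).

See `docs/methods.md` for the estimation details, parameter defaults, and
limitations.

## Worked example

Simulate 1000 persons from the bundled 12-item, 4-class dichotomous design
(class probabilities 0.30/0.20/0.10/0.40, many item probabilities equal
across classes), fit the exploratory LCM and the MCP fused-class RLCM over a
λ grid, and inspect the selected model:

```python
import numpy as np
import rlca
from rlca.penalties import PenaltySpec

design = rlca.fixture_design("dichotomous_4class")
data, _ = rlca.simulate(design, 1000, seed=1)

base = rlca.fit(data, 4, spec=None, n_starts=10, seed=2)
print(f"exploratory LCM: loglik={base.loglik:.1f}  #np={base.n_params}  BIC={base.bic:.1f}")

spec = PenaltySpec("mcp", "fused_classes")
grid = [round(0.01 * j, 2) for j in range(1, 101)]
sel = rlca.grid_search(data, 4, spec, grid1=grid, seed=3, base_params=base.params)
best = sel.best_fit
print(f"RLCM (MCP, fused classes): best lambda={sel.best_lambda[0]:.2f}  "
      f"#np={best.n_params}  #nreg={best.n_regularized}  BIC={best.bic:.1f}")

matched = rlca.match_labels(best.params, design)
print("item 1 correct-response probabilities by class:",
      np.round(matched.item_probs(0)[1], 3))

table = np.vstack([matched.item_probs(i)[1] for i in range(12)])
order = rlca.partial_order(table, iota=0, tie_tol=1e-4)
print(rlca.order_report(order).to_string(index=False))
```

Output:

```
exploratory LCM: loglik=-6345.5  #np=51  BIC=13043.3
RLCM (MCP, fused classes): best lambda=0.12  #np=29  #nreg=22  BIC=12909.2
item 1 correct-response probabilities by class: [0.117 0.818 0.818 0.818]
from_class to_class  n_violations violating_items
        C1       C2             0
        C1       C3             0
        C2       C4             0
        C3       C4             0
```

The exploratory model needs all 51 parameters; the regularized fit fuses 22
item parameters away (the design contains exactly 22 redundancies), drops
BIC by ~134, and recovers item 1's generating structure (one low class,
three fused high classes).  The edge list is the Hasse diagram of the class
hierarchy: class 1 below 2 and 3 (which are incomparable), both below class
4 — exactly the generating partial order.

The same workflow is available from the shell:

```sh
rlca simulate --design dichotomous_4class --n 1000 --seed 1 --out sim.csv
rlca select --data sim.csv --classes 4 --family mcp --strategy fused_classes \
     --grid1 0.01:1.00:0.01 --criterion bic --out results/
rlca order --probs my_probs.csv --iota 2 --out edges.csv
rlca recode --data raw.csv --key key.csv --mode polytomous --out recoded.csv
```

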