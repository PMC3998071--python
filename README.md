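# sparsegrn

Sparse parameter estimation in nonlinear discrete-time state-space models by
a regularized expectation-maximization (rEM) algorithm, applied to
gene-regulatory-network (GRN) inference from expression time series.

## The problem

Expression levels of n genes observed at K time points are modeled as a
hidden-state dynamical system

```
x_k = A g(x_{k-1}) + u_k,      u_k ~ N(0, U)
y_k = x_k + v_k,               v_k ~ N(0, R)
```

where `g` is the element-wise logistic sigmoid and `A` is the n-by-n
regulatory-coefficient matrix: entry `a_ij` is the regulation of gene i by
gene j (positive activates, negative represses).  Real regulatory networks
are sparse — most entries of `A` are exactly zero — and the scientific goal
is to recover both the support and the magnitudes of `A` from short, noisy
series.

## The method

`A` receives a Laplace (l1) prior and is estimated by MAP-EM:

* **E-step** — a forward sigma-point (unscented) Gaussian filter and a
  backward Gaussian smoother produce the smoothed pairwise densities
  p(x_{k-1}, x_k | Y, A'), from which the expected complete-data objective
  `Q~(A)` — an exact quadratic in `A` for this model — is assembled by
  2n-dimensional sigma-point quadrature.
* **M-step** — `Q~(A) + 2 ||lam o A||_1` is minimized by iterative soft
  thresholding with Barzilai-Borwein step sizes, giving estimates with
  exact zeros.  The re-weighted variant (`rem_w`) alternates thresholding
  runs with rate updates `lam_i = 1 / (|a_i| + eps)`, removing the
  magnitude bias of the plain l1 penalty.

Setting `lam = 0` recovers conventional EM (no sparsity, closed-form
M-step).  Two literature baselines are included for comparison: direct
l1-penalized trajectory fitting and BPDN dynamic filtering on the
parameter-augmented state.

## Worked example

```python
import numpy as np
from sparsegrn import (SparseEMNetwork, fixture_A, simulate_grn,
                       rmse, matched_elements, sparsity_factor)

A = fixture_A("four_gene")                      # benchmark 4-gene network
data = simulate_grn(A, K=20, U=0.01, R=0.01, seed=7)

est = SparseEMNetwork(mode="rem_w", random_state=7).fit(data.Y)
print(np.round(est.coef_, 2))
print("RMSE            :", round(rmse(A, est.coef_), 3))
print("matched elements:", matched_elements(A, est.coef_), "/ 16")
print("sparsity factor :", sparsity_factor(A, est.coef_))
```

prints

```
[[ 2.91  0.    0.   -4.45]
 [-2.99  0.    4.93 -0.  ]
 [-6.09  4.02  0.    0.  ]
 [-0.   -5.62  3.19 -0.  ]]
RMSE            : 0.339
matched elements: 16 / 16
sparsity factor : 1.0
```

The estimate reproduces all 8 true edges with their signs, drives the 8
true zeros to exact zeros (matched elements 16/16; sparsity factor 1 is
ideal, above 1 means over-sparse), and the entry-wise RMSE is 0.34 against
coefficients of magnitude up to 6.

The same pipeline is available from the shell:

```
sparsegrn simulate --preset four_gene_lownoise --seed 7 -o sim
sparsegrn infer -i sim.csv --method rem_w --seed 7 -o fit
sparsegrn evaluate --estimate fit_A.csv --truth sim.json -o metrics.json
```

`infer` also accepts `em`, `rem` (fixed `--lam`), `l1` and `bpdn_df`, and
writes the fitted adjacency CSV plus a signed edge-list TSV.

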