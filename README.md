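# blockstab

Simulation and analytic prediction of the spectra — and hence the local
stability — of large block-structured random ecological community matrices.

## Scientific background

A classic result in theoretical ecology is that a large random community
matrix `M` (the Jacobian of an ecosystem near equilibrium) becomes unstable
once the community is too large, too connected, or too strongly interacting:
the rightmost eigenvalue of `M` crosses zero. Real ecological networks,
however, are far from unstructured. Two ubiquitous departures are

* **modularity** — interactions concentrate *within* groups (e.g. spatial or
  taxonomic compartments), and
* **bipartite / anti-modular structure** — interactions concentrate *between*
  two groups (e.g. plant–pollinator or host–parasitoid networks).

This package asks, and answers analytically: *does group structure stabilize
or destabilize a large community?* The answer is subtle. Modularity and
bipartiteness shift, reshape and split the bulk of the eigenvalue spectrum
and move the low-rank outlier eigenvalues, and whether the rightmost
eigenvalue moves left (stabilizing) or right (destabilizing) depends on the
mean, variance and reciprocal correlation of the interaction strengths.
For instance, with exploitative mean interactions (`mu < 0`) modularity is
typically mildly *stabilizing* while bipartite structure is strongly
*destabilizing* — driven by an outlier eigenvalue that detaches from the
bulk.

## Model

A community of `S` species is split into two groups of fractions `alpha` and
`1 - alpha` (`alpha <= 1/2`). A symmetric 0/1 adjacency matrix `K` (zero
diagonal) connects species pairs with probability `C_w` within groups and
`C_b` between groups; the overall connectance is `C`. The group structure is
summarized by the **modularity**

```
Q = L_w / L - beta,      beta = alpha^2 + (1 - alpha)^2
```

(`L_w` = fraction of links within groups; `beta` is the expectation for an
unstructured graph), so `Q > 0` is modular, `Q < 0` anti-modular, and the
attainable range given `(alpha, C)` is

```
Q_max = min(1 - beta, beta (1 - C) / C)
Q_min = max(-beta, -(1 - beta)(1 - C) / C)
```

Interaction strengths come in pairs: for each connected pair `(i, j)`,
`(W_ij, W_ji)` is drawn from a bivariate normal with mean `mu`, variance
`sigma2` and correlation `rho`. The community matrix is the elementwise
product `M = W ∘ K`. A **cascade** (food-web) variant orders species by a
random size trait and makes the larger partner's effect on the smaller
positive on average (`(1 + xi) mu`, with `mu < 0`, `xi > 1`) and the
reciprocal effect negative (`-(1 + xi) mu`), producing predator–prey sign
pairs.

The package provides:

* exact, seed-reproducible samplers for `K`, `W` (random and cascade) and `M`
  (`topology`, `interactions`);
* numerical spectra and a Monte-Carlo stability ratio
  `Gamma = Re lambda_1(structured) / Re lambda_1(unstructured)`
  (`spectra`);
* closed-form predictions of the spectral support (bulk ellipses or their
  bipartite square-root transform), the low-rank outliers with their
  finite-size correction, the rightmost eigenvalue and `Gamma`
  (`analytics`);
* file formats, JSON-configured runs, deterministic fixtures and a CLI
  (`matrix_io`, `config`, `fixtures`, `cli`).

## Worked example

Predict and simulate a modular community (`S = 1000`, `alpha = 1/2`,
`C = 0.2`, `Q = 0.4`, `mu = -1`, `sigma2 = 1`, `rho = 0`):

```python
import numpy as np
from blockstab import (BlockSpec, InteractionSpec, predict_rightmost,
                       predict_gamma, sample_community_matrix,
                       leading_eigenvalue, modularity_bounds)

print(modularity_bounds(0.5, 0.2))        # (-0.5, 0.5)

block = BlockSpec(S=1000, alpha=0.5, C=0.2, Q=0.4)
inter = InteractionSpec(mu=-1.0, sigma2=1.0, rho=0.0)
print(block.C_w, block.C_b)               # 0.36 0.04

sup = predict_rightmost(block, inter)
print(sup.case_label)                     # equal_blocks
print(round(sup.rightmost_bulk, 4))       # 25.9962
print([round(o, 4) for o in sup.outliers])  # [-200.312, -160.48]
print(round(sup.rightmost, 4))            # 25.9962  (bulk edge; outliers far left)

print(round(predict_gamma(block, inter), 4))  # 0.9417  -> modularity stabilizes

lam = np.mean([leading_eigenvalue(sample_community_matrix(block, inter, 100 + s))
               for s in range(5)])
print(round(lam, 4))                      # 25.7659  (simulation, 0.9% from prediction)
```

The same from the command line:

```
$ blockstab predict --S 1000 --alpha 0.5 --C 0.2 --Q 0.4 --mu -1 --reference --out support.json
wrote support.json (case=equal_blocks, rightmost=25.9962)

$ blockstab sweep --S 200 --alpha 0.5 --C 0.2 --mu -1 --steps 5 --reps 5 --seed 0 --out sweep.csv
wrote sweep.csv (5 grid points)
$ cat sweep.csv
Q,C_w,C_b,gamma,se_gamma,re_lambda1_structured,re_lambda1_reference,gamma_mean_of_ratios
-0.5,0,0.4,3.27222664235,0.066908409109,40.7377796893,12.449559319,3.27827222905
-0.25,0.1,0.3,1.79055332625,0.0462072621429,21.569034333,12.0460161765,1.79504711092
0,0.2,0.2,0.977554585245,0.0190790342873,12.4186804047,12.7038229805,0.977841203855
0.25,0.3,0.1,1.01008191085,0.0264834222921,12.40768144,12.2838368915,1.01091165257
0.5,0.4,0,0.919615180709,0.01625737964,11.2618428286,12.2462558957,0.920535963007
```

The sweep shows the qualitative picture directly: with `mu = -1`, bipartite
structure (`Q = -0.5`) inflates the rightmost eigenvalue more than threefold
(`Gamma ≈ 3.27`), while full modularity (`Q = 0.5`) is mildly stabilizing
(`Gamma ≈ 0.92`).

Other subcommands: `generate-adjacency`, `generate-matrix`, `spectrum`,
`fixtures`. Every command accepts `--config cfg.json` plus flag overrides
and a single `--seed`; see `blockstab --help`.

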