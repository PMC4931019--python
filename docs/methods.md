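# Methods

This note records the model definitions, the analytic derivations the
package implements, and the numerical choices made, in enough detail to
re-derive every formula in `blockstab.analytics`.

## 1. Generative model

Species `1..S` are split into group 1 (size `m = round(alpha S)`,
`alpha <= 1/2`) and group 2 (size `S - m`). The adjacency matrix `K` is
symmetric with zero diagonal; each unordered pair is linked independently
with probability `C_w` if both species share a group and `C_b` otherwise.

Modularity is defined relative to the binomial expectation:
`Q = L_w / L - beta` with `beta = alpha^2 + (1 - alpha)^2` (the expected
within-group fraction of links in an unstructured graph with the same
connectance). Fixing the overall connectance `C`, the block connectances
follow from `Q`:

```
C_w = C (Q + beta) / beta
C_b = C (1 - Q - beta) / (1 - beta)
```

Requiring `0 <= C_w, C_b <= 1` gives the attainable range
`Q_max = min(1 - beta, beta (1 - C)/C)`,
`Q_min = max(-beta, -(1 - beta)(1 - C)/C)`. `Q = Q_min` with
`C <= (1 - beta)` gives `C_w = 0`: a perfectly bipartite graph.

Interaction pairs `(W_ij, W_ji)` are bivariate normal
`(mu, mu, sigma2, sigma2, rho)`. The community matrix is `M = W ∘ K`
(Hadamard), so `M` has zero diagonal: all results concern the *shift* of
the rightmost eigenvalue; adding `-d I` for self-regulation `d` simply
translates the spectrum.

**Cascade variant.** Each species gets an i.i.d. `Uniform(0,1)` size trait.
For a linked pair, the effect of the larger on the smaller is drawn with
mean `(1 + xi) mu` and the reciprocal effect with mean `-(1 + xi) mu`
(common variance `sigma2`, pair correlation `rho` of the fluctuations).
With `mu < 0` and `xi > 1` this yields predator–prey sign pairs `(+, -)`
with the positive effect flowing up the size hierarchy, while the marginal
mean of all coefficients remains `mu`. Relative to the overall mean, the
cascade coefficients have marginal variance `sigma2 + xi^2 mu^2` and pair
covariance `rho sigma2 + (1 - xi^2) mu^2`: the random ±`xi mu` orientation
adds `xi^2 mu^2` to each variance and `-xi^2 mu^2` to the covariance
(verified by Monte Carlo).

## 2. Effective (connectance-absorbed) parameters

Conditioning on a link being present or absent, each entry of a block with
connectance `c` is a zero-inflated normal. Its moments are

```
mu_x        = c mu
sigma_x^2   = c (sigma2 + mu^2) - c^2 mu^2
rho_x sigma_x^2 = c (rho sigma2 + mu^2) - c^2 mu^2        x in {w, b}
```

These are exact (not large-`S` approximations) and are validated against
10^6-pair Monte Carlo in the test suite. Averages used below:
`sigma_bar^2 = (sigma_w^2 + sigma_b^2)/2` and
`rho_bar = (cov_w + cov_b) / (sigma_w^2 + sigma_b^2)` where
`cov_x = rho_x sigma_x^2`.

## 3. Low-rank / fluctuation split

Write `M = A + B` where `A` is the block-constant mean matrix
(`A_ij = mu_w` within, `mu_b` between, including the diagonal) and
`B = M - A` has zero-mean entries off the diagonal and `-mu_w` on it.

`A` has rank ≤ 2; its nonzero eigenvalues are those of the 2×2 matrix

```
S * [[alpha mu_w,     (1-alpha) mu_b],
     [alpha mu_b,     (1-alpha) mu_w]]
```

When `mu_w = mu_b = mu_eff != 0` (e.g. `Q = 0`) one eigenvalue is
`S mu_eff` and the other is 0, so there is exactly one outlier. The test
suite checks these against a direct eigensolve of the full `S x S`
block-constant matrix.

## 4. Bulk support of B

The bulk is governed by the elliptic-law universality class with
block-dependent variances. Implemented cases (dispatch order, tolerance
1e-12):

* **uniform** (`C_w = C_b`): ellipse centered at `(-mu_w, 0)` with
  semi-axes `sqrt(S sigma_eff^2) (1 ± rho_eff)` (horizontal `+`).
* **bipartite** (`sigma_w = 0`): see §5.
* **modular** (`sigma_b = 0`): the two blocks decouple; the support is the
  union of two ellipses with radii scaled by `sqrt(alpha S)` and
  `sqrt((1-alpha) S)` built from the within-block moments.
* **zero correlation** (`rho_w = rho_b = 0`, general `alpha`): a disc whose
  squared radius is `S` times the largest eigenvalue of
  `[[alpha sigma_w^2, (1-alpha) sigma_b^2], [alpha sigma_b^2, (1-alpha) sigma_w^2]]`.
* **equal blocks** (`alpha = 1/2`, any `rho`): an ellipse with the averaged
  moments `sigma_bar^2`, `rho_bar`, centered at `(-mu_w, 0)`.

Any other combination raises `UnsupportedCaseError` rather than returning a
wrong number. All supported cases are validated against simulated spectra
at `S = 1000` over a 54-point parameter grid (worst relative error of the
rightmost point ≈ 4%, a finite-size edge excess at small radius).

## 5. Bipartite case: square-root transform

With `C_w = 0`, `B` is block off-diagonal:
`B = [[0, X], [Y, 0]]` with `X` of shape `m × (S - m)`. Its nonzero
eigenvalues are the square roots (both branches) of the eigenvalues of
`X Y`. Writing the cavity/resolvent equations for the two block Green's
functions,

```
g1(z) = 1 / (z - S (1-alpha) c g2(z)),   g2(z) = 1 / (z - S alpha c g1(z)),
```

with `c = rho_b sigma_b^2` entering through the pair correlation, the
product `P = g1 g2` obeys a quadratic whose branch structure implies that
the spectrum of `X Y` fills an **ellipse** with

```
center  x_c = S rho_b sigma_b^2
r_x = S sigma_b^2 sqrt(alpha (1-alpha)) (1 + rho_b^2)
r_y = S sigma_b^2 sqrt(alpha (1-alpha)) (1 - rho_b^2)
```

The spectrum of `B` is the two-branch square-root image of that ellipse
plus the eigenvalue 0 (multiplicity `>= S - 2m`). The density on the
squared-spectrum ellipse is *not* uniform: its mean (trace identity
`tr(XY)/S = (1-alpha) S rho_b sigma_b^2` per eigenvalue of `XY`) differs
from the geometric center `x_c`. Both are exposed
(`spectral_mean` vs. the ellipse center) and both are verified against
simulation; conflating them is a documented pitfall.

The rightmost point of the square-root image maximizes
`a(x, y) = sqrt((x + sqrt(x^2 + y^2))/2)` over the ellipse. The default
implementation evaluates a dense parametric grid (20001 points) and
refines with bounded scalar minimization; a closed form from the
stationarity condition — the quadratic
`D(1-D) x^2 + B D x + (A - B^2/4) = 0` with `D = r_y^2/r_x^2`,
`B = 2 x_c r_y^2 / r_x^2`, `A = r_y^2 (1 - x_c^2/r_x^2)` — is available as
`method="closed_form"` and agrees with the grid to 1e-9; the grid is the
default because it is branch-safe for all parameter signs.

## 6. Outliers of M and finite-size correction

The outliers of `M` are the eigenvalues of `A` corrected for the
interaction with the bulk. To first order in `1/lambda`, an outlier
`lambda` of `A` moves to

```
lambda + N c / lambda - mu_w
```

where `N c` is the appropriate row-sum of pair covariances: for the
uniform/equal-blocks cases `N c = S rho_bar sigma_bar^2`; for the modular
case the eigenvector of `A` concentrates on one block of size
`N_b = (lambda / (S mu_w)) S` and `N c = N_b rho_w sigma_w^2`. For the
bipartite case no correction is applied (the raw eigenvalues of `A` are
used). An outlier is reported only if it lies outside the bulk's interval
on the real axis; otherwise it is swallowed by the bulk and invisible.

## 7. Stability ratio Gamma

`Gamma` is estimated as the ratio of the *mean* rightmost eigenvalue over
`n_reps` structured matrices to the mean over `n_reps` independent `Q = 0`
matrices with identical `(S, alpha, C, mu, sigma2, rho)`. The standard
error uses the delta method for a ratio of independent means; the mean of
per-pair ratios is also recorded (`gamma_mean_of_ratios`) for comparison.
Replicate streams derive from a single master seed via
`numpy.random.SeedSequence.spawn`, making every number in the package a
pure function of its seed.

The analytic `Gamma` (`predict_gamma`) is the ratio of the predicted
rightmost eigenvalues and matches the Monte-Carlo estimate within its
standard error at the problem sizes used in the tests.

## 8. Numerical choices

* Dense eigensolves use `numpy.linalg.eigvals`; a 1000×1000 solve costs
  ≈ 1 s single-threaded, which sets the test-suite and script budgets.
  Monte-Carlo checks use `S = 300`–`1000` and 5–50 replicates depending on
  the tolerance required.
* Adjacency sampling draws the upper triangle row-major from a
  `default_rng(seed)` stream, making matrices bit-reproducible across
  platforms.
* Ellipse/rightmost formulas are evaluated in closed form; the only
  iterative step is the one-dimensional refinement in §5.

## 9. Limitations

* Analytic bulk support is implemented for the five cases of §4; general
  `(alpha != 1/2, rho != 0, mixed blocks)` requires solving the full
  block cavity equations and is deliberately not approximated.
* Outlier corrections are first order in `1/lambda`; for outliers close to
  the bulk edge the correction degrades, and visibility is decided by the
  real-axis interval test rather than the exact two-dimensional support.
* The cascade variant's analytics are limited to its effective pair
  moments; its `Gamma` is estimated by simulation.
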