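"""Analytic spectra of block-structured random community matrices.

The community matrix is split as ``M = A + B``: a rank-<=2 block-constant
mean part ``A`` whose nonzero eigenvalues become the (up to two) real
outliers, and a fluctuation part ``B`` whose eigenvalues form the bulk.
After absorbing the connectances into effective moments, the bulk support
admits a closed form in four regimes:

* ``sigma_w = sigma_b``, ``rho_w = rho_b`` -- the elliptic law: an ellipse
  centred at ``(-mu_w, 0)`` with semi-axes ``sqrt(S sigma^2) (1 +/- rho)``.
* ``sigma_b = 0`` (perfectly modular) -- the union of two elliptic-law
  ellipses, one per independent block, with semi-axes scaled by
  ``sqrt(alpha S)`` and ``sqrt((1 - alpha) S)``.
* ``rho_w = rho_b = 0`` -- a circle of squared radius ``S`` times the
  leading eigenvalue of the 2x2 group-weighted variance matrix.
* ``alpha = 1/2`` -- an ellipse with variance the arithmetic mean of the
  within/between variances and correlation their variance-weighted mean.

The perfectly bipartite regime (``sigma_w = 0``) is handled through the
squared spectrum: the eigenvalues of the block product ``XY`` fill an
ellipse with centre ``S rho_b sigma_b^2`` and semi-axes
``S sigma_b^2 sqrt(alpha (1 - alpha)) (1 +/- rho_b^2)``; the support of B
is its square-root transform (plus the point 0 from the rank-deficient
factor).  The density inside that ellipse is not uniform: its mean is fixed
instead by the trace identity ``(1 - alpha) S rho_b sigma_b^2``.

Outliers inherit a low-rank-perturbation correction,
``lambda -> lambda + N c / lambda - mu_w`` with ``N c`` the ensemble-size x
pair-covariance of the relevant bulk; no such correction is available for
the bipartite case (where it is negligible once ``|mu|`` is appreciable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .interactions import InteractionSpec
from .topology import BlockSpec

__all__ = [
    "EffectiveParams",
    "SpectralSupport",
    "UnsupportedCaseError",
    "effective_parameters",
    "outliers_of_A",
    "bulk_support",
    "bipartite_support",
    "sqrt_ellipse_rightmost",
    "correct_outliers",
    "predict_rightmost",
    "predict_gamma",
]

_TOL = 1e-12


class UnsupportedCaseError(ValueError):
    """No closed form is available; fall back to numerical simulation."""


@dataclass
class EffectiveParams:
    """Connectance-absorbed moments of the two pair distributions.

    A pair that is present with probability ``C_x`` and, when present,
    drawn with moments (mu, sigma2, rho) has exact moments

        mu_x      = C_x mu
        sigma_x^2 = C_x (sigma^2 + mu^2) - C_x^2 mu^2
        rho_x sigma_x^2 = C_x (rho sigma^2 + mu^2) - C_x^2 mu^2.

    ``sigma2_bar`` and ``rho_bar`` are the equal-blocks (alpha = 1/2)
    summaries: arithmetic-mean variance and variance-weighted correlation.
    All second-moment fields depend on mu only through mu^2.
    """

    mu_w: float
    mu_b: float
    sigma2_w: float
    sigma2_b: float
    rho_w: float
    rho_b: float
    sigma2_bar: float = field(init=False)
    rho_bar: float = field(init=False)

    def __post_init__(self) -> None:
        self.sigma2_bar = 0.5 * (self.sigma2_w + self.sigma2_b)
        tot = self.sigma2_w + self.sigma2_b
        self.rho_bar = (self.cov_w + self.cov_b) / tot if tot > 0 else 0.0

    @property
    def cov_w(self) -> float:
        return self.rho_w * self.sigma2_w

    @property
    def cov_b(self) -> float:
        return self.rho_b * self.sigma2_b


@dataclass
class SpectralSupport:
    """Predicted bulk support plus predicted outliers.

    ``ellipses`` lists ``(center_x, r_x, r_y)``; when ``sqrt_transformed``
    is set they describe the support of the *squared* spectrum and the bulk
    of B is its square-root image.  ``outliers`` holds the (corrected,
    visible) real outlier eigenvalues; ``rightmost`` is the stability
    estimate ``max(rightmost_bulk, outliers)``.
    """

    case_label: str
    ellipses: list[tuple[float, float, float]]
    outliers: list[float] = field(default_factory=list)
    rightmost_bulk: float = 0.0
    rightmost: float = 0.0
    sqrt_transformed: bool = False
    spectral_mean: float | None = None

    def bulk_real_interval(self) -> tuple[float, float]:
        """Extent of the bulk support along the real axis."""
        if self.sqrt_transformed:
            return (-self.rightmost_bulk, self.rightmost_bulk)
        lo = min(c - rx for c, rx, _ in self.ellipses)
        hi = max(c + rx for c, rx, _ in self.ellipses)
        return (lo, hi)


def effective_parameters(inter: InteractionSpec, C_w: float, C_b: float) -> EffectiveParams:
    """Absorb the connectances into the moments of the diluted pair laws."""
    if not (0.0 <= C_w <= 1.0 and 0.0 <= C_b <= 1.0):
        raise ValueError("connectances must lie in [0, 1]")
    out = {}
    for tag, C_x in (("w", C_w), ("b", C_b)):
        mu_x = C_x * inter.mu
        s2 = C_x * (inter.sigma2 + inter.mu**2) - mu_x**2
        cov = C_x * (inter.rho * inter.sigma2 + inter.mu**2) - mu_x**2
        out["mu_" + tag] = mu_x
        out["sigma2_" + tag] = s2
        out["rho_" + tag] = cov / s2 if s2 > 0 else 0.0
    return EffectiveParams(**out)


def outliers_of_A(S: int, alpha: float, mu_w: float, mu_b: float) -> list[float]:
    """Nonzero eigenvalues of the block-constant mean matrix A.

    They equal the eigenvalues of the group-size-weighted 2x2 reduction
    ``S [[alpha mu_w, (1-alpha) mu_b], [alpha mu_b, (1-alpha) mu_w]]``,
    zeros dropped: none for mu_w = mu_b = 0, one for mu_w = mu_b != 0
    (the unstructured case), otherwise up to two.
    """
    red = S * np.array(
        [[alpha * mu_w, (1 - alpha) * mu_b], [alpha * mu_b, (1 - alpha) * mu_w]]
    )
    ev = np.linalg.eigvals(red)
    scale = max(abs(ev).max(), 1.0)
    keep = sorted(float(x.real) for x in ev if abs(x) > 1e-10 * scale)
    return keep


def _case_label(alpha: float, eff: EffectiveParams, tol: float = _TOL) -> str:
    if abs(eff.sigma2_w - eff.sigma2_b) < tol and abs(eff.cov_w - eff.cov_b) < tol:
        return "uniform"
    if eff.sigma2_w <= tol:
        return "bipartite"
    if eff.sigma2_b <= tol:
        return "modular"
    if abs(eff.rho_w) < tol and abs(eff.rho_b) < tol:
        return "zero_correlation"
    if abs(alpha - 0.5) < tol:
        return "equal_blocks"
    raise UnsupportedCaseError(
        "no closed-form spectrum for alpha != 1/2 with unequal blocks that are "
        "neither uncorrelated, perfectly modular nor perfectly bipartite; "
        "use numerical simulation (spectra.stability_ratio)"
    )


def bulk_support(S: int, alpha: float, eff: EffectiveParams) -> SpectralSupport:
    """Predicted support of the bulk (the eigenvalues of B).

    Dispatches on the tractable regimes described in the module docstring;
    raises :class:`UnsupportedCaseError` otherwise.
    """
    case = _case_label(alpha, eff)
    cx = -eff.mu_w
    if case == "bipartite":
        return bipartite_support(S, alpha, eff)
    if case == "uniform":
        h = np.sqrt(S * eff.sigma2_w) * (1 + eff.rho_w)
        v = np.sqrt(S * eff.sigma2_w) * (1 - eff.rho_w)
        ellipses = [(cx, float(h), float(v))]
    elif case == "modular":
        ellipses = []
        for n in (alpha, 1 - alpha):
            r = np.sqrt(n * S * eff.sigma2_w)
            ellipses.append((cx, float(r * (1 + eff.rho_w)), float(r * (1 - eff.rho_w))))
    elif case == "zero_correlation":
        V = np.array(
            [
                [alpha * eff.sigma2_w, (1 - alpha) * eff.sigma2_b],
                [alpha * eff.sigma2_b, (1 - alpha) * eff.sigma2_w],
            ]
        )
        r = float(np.sqrt(S * np.linalg.eigvals(V).real.max()))
        ellipses = [(cx, r, r)]
    else:  # equal_blocks
        h = np.sqrt(S * eff.sigma2_bar) * (1 + eff.rho_bar)
        v = np.sqrt(S * eff.sigma2_bar) * (1 - eff.rho_bar)
        ellipses = [(cx, float(h), float(v))]
    edge = max(c + rx for c, rx, _ in ellipses)
    return SpectralSupport(
        case_label=case, ellipses=ellipses, rightmost_bulk=edge, rightmost=edge
    )


def bipartite_support(S: int, alpha: float, eff: EffectiveParams) -> SpectralSupport:
    """Support of B when all interactions are between-subsystem (C_w = 0).

    Writing B in block off-diagonal form with factors X (alphaS x (1-alpha)S)
    and Y, the nonzero eigenvalues of ``B^2`` are those of ``XY``, which fill
    the ellipse

        centre  x_c = S rho_b sigma_b^2
        r_x         = S sigma_b^2 sqrt(alpha (1-alpha)) (1 + rho_b^2)
        r_y         = S sigma_b^2 sqrt(alpha (1-alpha)) (1 - rho_b^2).

    The support of B is the square-root transform of that ellipse together
    with the point 0 contributed by the larger, rank-deficient factor.  The
    (non-uniform) density has mean ``(1 - alpha) S rho_b sigma_b^2`` -- the
    exact expectation of the mean eigenvalue of XY.
    """
    if eff.sigma2_w > _TOL:
        raise ValueError("bipartite support requires sigma2_w = 0 (C_w = 0)")
    s2, rho = eff.sigma2_b, eff.rho_b
    x_c = S * rho * s2
    scale = S * s2 * np.sqrt(alpha * (1 - alpha))
    r_x = scale * (1 + rho**2)
    r_y = scale * (1 - rho**2)
    edge = sqrt_ellipse_rightmost(x_c, r_x, r_y)
    return SpectralSupport(
        case_label="bipartite",
        ellipses=[(float(x_c), float(r_x), float(r_y))],
        rightmost_bulk=float(edge),
        rightmost=float(edge),
        sqrt_transformed=True,
        spectral_mean=float((1 - alpha) * S * rho * s2),
    )


def _sqrt_real_part(x: np.ndarray, y2: np.ndarray) -> np.ndarray:
    """Real part a of sqrt(x + i y): a = sqrt((x + sqrt(x^2 + y^2)) / 2)."""
    return np.sqrt(np.maximum(x + np.sqrt(x**2 + y2), 0.0) / 2.0)


def sqrt_ellipse_rightmost(
    x_c: float, r_x: float, r_y: float, method: str = "grid"
) -> float:
    """Max real part of the square root over an axis-aligned ellipse.

    For ``z = x + i y`` on the ellipse boundary ``(x - x_c)^2 / r_x^2 +
    y^2 / r_y^2 = 1``, maximizes ``a(x) = sqrt((x + sqrt(x^2 + y^2(x))) / 2)``
    over ``x`` in ``[x_c - r_x, x_c + r_x]``.  The default is a dense grid
    search refined by bounded 1-D optimization; ``method='closed_form'``
    evaluates the stationary-point/vertex candidates of the quadratic
    stationarity condition instead (the classic two-case solution: interior
    tangency point or the right vertex).
    """
    if r_x < 0 or r_y < 0:
        raise ValueError("semi-axes must be non-negative")
    if r_x == 0:
        return float(_sqrt_real_part(np.array(x_c), np.array(r_y**2)))
    if r_y == 0:
        return float(np.sqrt(max(x_c + r_x, 0.0)))
    lo, hi = x_c - r_x, x_c + r_x

    def y2(x):
        return np.maximum(r_y**2 * (1.0 - ((x - x_c) / r_x) ** 2), 0.0)

    if method == "closed_form":
        # stationarity of f(x) = x + sqrt(x^2 + y^2(x)) with
        # y^2 = A + Bx - Dx^2 gives D(1-D)x^2 + BDx + (A - B^2/4) = 0,
        # valid where sqrt(x^2+y^2) = -(x(1-D) + B/2) >= 0.
        D = r_y**2 / r_x**2
        B = 2.0 * x_c * r_y**2 / r_x**2
        A = r_y**2 * (1.0 - x_c**2 / r_x**2)
        cands = [lo, hi]
        if abs(D - 1.0) < 1e-14:
            if abs(B) > 0:
                cands.append((B**2 / 4.0 - A) / B)
        else:
            disc = (B * D) ** 2 - 4.0 * D * (1.0 - D) * (A - B**2 / 4.0)
            if disc >= 0:
                rt = np.sqrt(disc)
                for sgn in (+1.0, -1.0):
                    cands.append((-B * D + sgn * rt) / (2.0 * D * (1.0 - D)))
        best = 0.0
        for x in cands:
            if not (lo - 1e-12 * (1 + abs(lo)) <= x <= hi + 1e-12 * (1 + abs(hi))):
                continue
            x = min(max(x, lo), hi)
            best = max(best, float(_sqrt_real_part(np.array(x), y2(x))))
        return best
    if method != "grid":
        raise ValueError(f"unknown method {method!r}")
    xs = np.linspace(lo, hi, 20001)
    a = _sqrt_real_part(xs, y2(xs))
    k = int(np.argmax(a))
    span = xs[1] - xs[0]
    blo, bhi = max(lo, xs[k] - 2 * span), min(hi, xs[k] + 2 * span)
    res = minimize_scalar(
        lambda x: -float(_sqrt_real_part(np.array(x), y2(x))),
        bounds=(blo, bhi),
        method="bounded",
        options={"xatol": 1e-14 * max(1.0, abs(hi))},
    )
    return max(float(a[k]), float(-res.fun))


def correct_outliers(
    raw: list[float],
    S: int,
    eff: EffectiveParams,
    case_label: str,
    alpha: float = 0.5,
) -> list[float]:
    """Low-rank-perturbation correction of the raw outlier locations.

    Each raw eigenvalue ``lambda`` of A is moved to
    ``lambda + N c / lambda - mu_w`` where ``N c`` is the ensemble-size x
    pair-covariance of the bulk seen by that outlier (``S rho_bar
    sigma_bar^2`` for the unstructured and equal-blocks cases, the block's
    own ``N_b cov_w`` for the perfectly modular case).  The ``-mu_w`` term
    restores the diagonal shift carried by B.  Not available for the
    bipartite case.
    """
    if case_label == "bipartite":
        raise UnsupportedCaseError(
            "no outlier correction for bipartite matrices; use the raw "
            "eigenvalues of A (the correction is negligible for large |mu|)"
        )
    corrected = []
    for lam in raw:
        if case_label == "modular":
            # attribute the outlier to its block: lambda = N_b mu_w
            n_b = lam / (S * eff.mu_w) if eff.mu_w != 0 else 1.0
            shift = n_b * S * eff.cov_w / lam
        else:
            shift = S * eff.rho_bar * eff.sigma2_bar / lam
        corrected.append(lam + shift - eff.mu_w)
    return corrected


def _visible(outliers: list[float], support: SpectralSupport) -> list[float]:
    lo, hi = support.bulk_real_interval()
    return [x for x in outliers if x < lo or x > hi]


def predict_rightmost(block: BlockSpec, inter: InteractionSpec) -> SpectralSupport:
    """Full analytic chain: effective moments -> A outliers -> bulk -> rightmost.

    Outliers are corrected where a formula exists (everywhere but the
    bipartite case) and reported only when they fall outside the bulk
    support along the real axis.
    """
    eff = effective_parameters(inter, block.C_w, block.C_b)
    support = bulk_support(block.S, block.alpha, eff)
    raw = outliers_of_A(block.S, block.alpha, eff.mu_w, eff.mu_b)
    if support.case_label == "bipartite":
        outliers = raw
    else:
        outliers = correct_outliers(raw, block.S, eff, support.case_label, block.alpha)
    support.outliers = _visible(outliers, support)
    support.rightmost = max([support.rightmost_bulk, *support.outliers])
    return support


def predict_gamma(block: BlockSpec, inter: InteractionSpec) -> float:
    """Analytic stability ratio: predicted rightmost at Q over that at Q = 0."""
    structured = predict_rightmost(block, inter)
    reference = predict_rightmost(block.with_modularity(0.0), inter)
    if reference.rightmost == 0:
        raise ZeroDivisionError("reference rightmost eigenvalue is zero")
    return structured.rightmost / reference.rightmost
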