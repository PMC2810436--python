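"""Equilibrium predictions of the spatial neutral community model.

The stationary state of the birth-death-dispersal-speciation process admits a
closed-form solution for the generating function of the number of individuals
inside a circular window of radius ``R``.  Writing ``alpha_h = (d/b)e^{-h}-1``
for the tilted demographic parameter, the h-derivative of the (cumulant)
generating function is assembled from a matched interior/exterior
modified-Helmholtz problem for the tilted mean density:

    dPhi/dh = pi R^2 theta_s / alpha_h + T(h, R)

    T = 2 pi R theta_s (1/alpha - 1/alpha_h) kappa
        / { kappa_h [ kappa_h K0(kappa R)/K1(kappa R)
                      + kappa I0(kappa_h R)/I1(kappa_h R) ] }

with ``kappa = sqrt(alpha)/sigma`` and ``kappa_h = sqrt(alpha_h)/sigma``.  The
expected species richness of the window follows by quadrature over
``h in (-inf, 0]`` (:func:`sar_exact`); expanding the interior Bessel ratio to
lowest order in ``alpha_h`` makes the h-integral elementary and yields the
closed form used everywhere else (:func:`sar_closed_form`):

    S(R) = (theta_s pi R^2 / alpha) (1 + alpha G) / (1 - G)
           * ln( (1 + G alpha) / (G (1 + alpha)) )

where :func:`g_function` is the Bessel-function combination

    G(R) = (R / (2 sigma^2 kappa)) K0(kappa R)/K1(kappa R) + R^2/(8 sigma^2).

All Bessel evaluations use exponentially scaled variants so products and
ratios remain finite across ten orders of magnitude of area.
"""
from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from scipy import integrate
from scipy import special as sp

from .containers import BetaDiversityCurve, PhaseReport, SARCurve
from .params import NeutralParams

__all__ = [
    "g_function",
    "sar_closed_form",
    "sar_exact",
    "dphi_dh",
    "local_slope",
    "power_law_exponent",
    "linear_phase_sar",
    "expected_density",
    "beta_diversity_F",
    "phase_report",
    "theta_s_from_density",
]


class QuadratureError(RuntimeError):
    """Numerical h-integration failed to converge; carries the worst radius."""


def _check_radii(R_values: Sequence[float]) -> np.ndarray:
    R = np.asarray(R_values, dtype=float)
    if np.any(R < 0):
        raise ValueError("radii must be nonnegative")
    if R.size > 1 and not np.all(np.diff(R) > 0):
        raise ValueError("radii must be sorted strictly increasing")
    return R


def _k_ratio(x: np.ndarray) -> np.ndarray:
    """K0(x)/K1(x), stable for all x > 0 (scaled Bessels; exponents cancel)."""
    return sp.kve(0, x) / sp.kve(1, x)


def _i_ratio(x: float) -> float:
    """I0(x)/I1(x), stable for all x > 0."""
    return sp.ive(0, x) / sp.ive(1, x)


def g_function(R, alpha: float, sigma: float):
    """The dimensionless Bessel combination G(R) entering the closed-form SAR.

    ``G(R) = (R/(2 sigma^2 kappa)) K0(kappa R)/K1(kappa R) + R^2/(8 sigma^2)``
    with ``kappa = sqrt(alpha)/sigma``.  G is finite for every ``R >= 0``
    (G(0) = 0; for large arguments the K-ratio tends to 1 so G grows like
    ``R/(2 sigma^2 kappa)``), and is evaluated with exponentially scaled
    Bessel functions so no overflow occurs even when ``R sqrt(alpha)/sigma``
    is in the hundreds.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("R must be nonnegative")
    kappa = math.sqrt(alpha) / sigma
    x = kappa * R
    out = np.where(
        x > 0,
        R * _k_ratio(np.where(x > 0, x, 1.0)) / (2.0 * sigma**2 * kappa),
        0.0,
    )
    out = out + R * R / (8.0 * sigma**2)
    return out if out.ndim else float(out)


def _log1p_over(t):
    """log1p(t)/t with the t -> 0 limit handled."""
    t = np.asarray(t, dtype=float)
    small = np.abs(t) < 1e-12
    safe = np.where(small, 1.0, t)
    return np.where(small, 1.0 - t / 2.0, np.log1p(safe) / safe)


def _closed_form_S(R: np.ndarray, alpha: float, sigma: float, theta_s: float) -> np.ndarray:
    G = np.asarray(g_function(R, alpha, sigma))
    # S = (theta pi R^2/alpha) (1+alpha G) * log1p(t)/t / (G (1+alpha)),
    # t = (1-G)/(G(1+alpha)); continuous through G = 1.
    out = np.zeros_like(np.asarray(R, dtype=float))
    pos = np.asarray(R) > 0
    Gp = G[pos]
    t = (1.0 - Gp) / (Gp * (1.0 + alpha))
    lf = _log1p_over(t)
    out[pos] = (
        theta_s * math.pi * np.asarray(R)[pos] ** 2 / alpha
        * (1.0 + alpha * Gp) * lf / (Gp * (1.0 + alpha))
    )
    return out


def sar_closed_form(params: NeutralParams, R_values: Sequence[float]) -> SARCurve:
    """Closed-form species-area curve over circular windows of the given radii.

    Exact in the lowest order of the ``alpha_h`` expansion of the equilibrium
    solution; S(0) = 0 and S is strictly increasing in R.
    """
    R = _check_radii(R_values)
    S = _closed_form_S(R, params.alpha, params.sigma, params.theta_s)
    return SARCurve(areas=math.pi * R**2, species=S, method="closed_form", params=params)


def dphi_dh(h: float, R: float, params: NeutralParams) -> float:
    """h-derivative of the window generating function (tilted mean count).

    At ``h = 0`` this equals the expected number of individuals in the window,
    ``pi R^2 theta_s/alpha``; as ``h -> -inf`` it decays like ``e^h`` and its
    integral over ``h in (-inf, 0]`` is the expected species richness.
    """
    alpha, sigma, theta = params.alpha, params.sigma, params.theta_s
    if h == 0.0:
        return math.pi * R * R * theta / alpha
    alpha_h = (1.0 + alpha) * math.expm1(-h) + alpha
    kappa = math.sqrt(alpha) / sigma
    kappa_h = math.sqrt(alpha_h) / sigma
    denom = kappa_h * (kappa_h * float(_k_ratio(kappa * R)) + kappa * _i_ratio(kappa_h * R))
    T = 2.0 * math.pi * R * theta * (1.0 / alpha - 1.0 / alpha_h) * kappa / denom
    return math.pi * R * R * theta / alpha_h + T


def sar_exact(
    params: NeutralParams,
    R_values: Sequence[float],
    epsrel: float = 1e-8,
    epsabs: float = 1e-12,
) -> SARCurve:
    """Species-area curve by numerical quadrature of the equilibrium solution.

    For each radius, integrates ``dPhi/dh`` over ``h in (-inf, 0]`` after the
    substitution ``u = e^h`` (mapping the domain to ``(0, 1]`` and removing the
    exponential endpoint); adaptive quadrature to the requested tolerance.
    """
    R = _check_radii(R_values)
    S = np.zeros_like(R)
    worst: Optional[tuple] = None
    for idx, r in enumerate(R):
        if r == 0.0:
            continue

        def integrand(u: float, r=r) -> float:
            return dphi_dh(math.log(u), r, params) / u

        with np.errstate(all="ignore"):
            val, err = integrate.quad(
                integrand, 0.0, 1.0, epsrel=epsrel, epsabs=epsabs, limit=500
            )
        if not math.isfinite(val) or (val > 0 and err / max(abs(val), epsabs) > 10 * epsrel):
            if worst is None or err > worst[1]:
                worst = (r, err, val)
            continue
        S[idx] = val
    if worst is not None:
        raise QuadratureError(
            f"h-integration failed to converge at R={worst[0]!r} "
            f"(estimate {worst[2]!r}, error {worst[1]!r})"
        )
    return SARCurve(areas=math.pi * R**2, species=S, method="quadrature", params=params)


def local_slope(params: NeutralParams, R: float, method: str = "closed_form") -> float:
    """Centered finite-difference d(log S)/d(log A) at area ``A = pi R^2``.

    Step 0.01 in log-area; the curvature of log S is mild everywhere so this
    step is well inside the linear-response regime.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    if method == "closed_form":
        evaluate = lambda rr: _closed_form_S(np.array([rr]), params.alpha, params.sigma, params.theta_s)[0]
    elif method == "quadrature":
        evaluate = lambda rr: sar_exact(params, [rr]).species[0]
    elif method == "linear_phase":
        return 1.0
    else:
        raise ValueError(f"unknown method {method!r}")
    dlog = 0.01
    logA = math.log(math.pi * R * R)
    r_hi = math.sqrt(math.exp(logA + dlog) / math.pi)
    r_lo = math.sqrt(math.exp(logA - dlog) / math.pi)
    return (math.log(evaluate(r_hi)) - math.log(evaluate(r_lo))) / (2.0 * dlog)


def power_law_exponent(alpha: float) -> float:
    """Exponent z of the approximate power-law phase of the species-area curve.

    Closed form: the analytic log-log derivative of the closed-form S(R) at
    the centre of the power-law window, ``log R = log sigma - (1/4) log alpha``
    (``R* = sigma alpha**-0.25``).  Independent of sigma and theta_s: only the
    demographic parameter alpha enters.  For the tropical-forest value
    ``alpha = 1e-7`` this evaluates to 0.21 (two decimals).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha!r}")
    sigma = 1.0  # z is sigma-free; any positive value gives the same result
    R = alpha ** -0.25 * sigma
    kappa = math.sqrt(alpha) / sigma
    x = kappa * R
    kr = float(_k_ratio(x))
    G = R * kr / (2.0 * sigma**2 * kappa) + R * R / (8.0 * sigma**2)
    # dG/dlogR: d(K0/K1)/dx = -1 + (K0/K1)^2 + (K0/K1)/x
    dkr_dx = -1.0 + kr * kr + kr / x
    dG = R * (kr + x * dkr_dx) / (2.0 * sigma**2 * kappa) + R * R / (4.0 * sigma**2)
    # z = (1/2) dlogS/dlogR with
    # dlogS/dlogR = 2 + dG * [alpha/(1+alpha G) - 1/(w G (1+G alpha)) + 1/(1-G)],
    # w = ln((1+G alpha)/(G(1+alpha))).  The last two terms cancel to O(1)
    # as G -> 1; switch to their joint expansion near the crossing.
    eps = 1.0 - G
    if abs(eps) > 1e-5:
        t = eps / (G * (1.0 + alpha))
        w = math.log1p(t)
        bracket = alpha / (1.0 + alpha * G) - 1.0 / (w * G * (1.0 + G * alpha)) + 1.0 / eps
    else:
        t = eps / (G * (1.0 + alpha))
        bracket = (
            alpha / (1.0 + alpha * G)
            - alpha / (1.0 + G * alpha)
            - 1.0 / (2.0 * G * (1.0 + G * alpha))
            + t / (12.0 * G * (1.0 + G * alpha))
        )
    return 0.5 * (2.0 + dG * bracket)


def linear_phase_sar(params: NeutralParams, R_values: Sequence[float]) -> SARCurve:
    """Large-area linear species-area law, ``S = theta_s A ln((1+alpha)/alpha)``.

    The asymptote of the closed form for ``A >> sigma^2/alpha``; the dispersal
    scale sigma drops out entirely.
    """
    R = _check_radii(R_values)
    A = math.pi * R**2
    S = params.theta_s * A * math.log((1.0 + params.alpha) / params.alpha)
    return SARCurve(areas=A, species=S, method="linear_phase", params=params)


def expected_density(params: NeutralParams) -> float:
    """Stationary expected individuals per unit area summed over species.

    ``<J> = theta_s / alpha``: lineages are founded at areal rate
    ``theta_s b`` and each contributes expected time-integrated abundance
    ``1/(alpha b)``.
    """
    return params.theta_s / params.alpha


def theta_s_from_density(density: float, alpha: float) -> float:
    """Invert the density relation: ``theta_s = alpha * <J>``."""
    if density <= 0 or alpha <= 0:
        raise ValueError("density and alpha must be positive")
    return alpha * density


def beta_diversity_F(params: NeutralParams, r_values: Sequence[float]) -> BetaDiversityCurve:
    """Distance decay of the conspecific probability:

    ``F(r) = K0(sqrt(alpha) r / sigma) * alpha / (2 pi sigma^2 theta_s)``.

    Valid for separations beyond the dispersal scale where F << 1; requires
    r > 0 because K0 diverges logarithmically at the origin.  If the requested
    separations put F above 1 the parameter regime is outside the solution's
    validity and an error is raised rather than clipping.
    """
    r = np.asarray(r_values, dtype=float)
    if np.any(r <= 0):
        raise ValueError("separations must be strictly positive (K0 diverges at r=0)")
    if r.size > 1 and not np.all(np.diff(r) > 0):
        raise ValueError("separations must be sorted strictly increasing")
    amplitude = params.alpha / (2.0 * math.pi * params.sigma**2 * params.theta_s)
    F = amplitude * sp.k0(math.sqrt(params.alpha) * r / params.sigma)
    if np.any(F > 1.0):
        bad = r[F > 1.0]
        raise ValueError(
            f"F(r) exceeds 1 at r={bad.min()!r}: parameter regime outside the "
            "validity of the distance-decay solution (F must be a probability)"
        )
    return BetaDiversityCurve(r=r, F=F, method="analytic", params=params)


def phase_report(params: NeutralParams) -> PhaseReport:
    """Phase boundaries and power-law exponent of the species-area curve."""
    return PhaseReport(
        A_small=params.sigma**2,
        A_large=params.sigma**2 / params.alpha,
        z=power_law_exponent(params.alpha),
        R_eval=params.sigma * params.alpha**-0.25,
    )
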