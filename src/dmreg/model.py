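"""The Downs-Mardia circular-circular regression model.

The model links a dependent angle ``v`` to an independent angle ``u``
through

    tan((v - beta)/2) = omega * tan((u - alpha)/2),

with angular locations ``alpha``, ``beta`` and a slope ``omega`` in
``[-1, 1]``.  For ``omega != 0`` this is a one-to-one map of the circle
onto itself; the conditional mean direction of ``v`` given ``u`` is

    mu(u) = beta + 2 * atan(omega * tan((u - alpha)/2)).

With von Mises errors VM(0, kappa), the log-likelihood is
``-n log I0(kappa) + kappa * n * rho_hat`` where ``rho_hat`` is the mean
cosine of the angular residuals.  Maximizing over kappa given
(alpha, beta, omega) is therefore equivalent to maximizing ``rho_hat``;
the concentration is recovered afterwards as the Bessel-ratio inverse
``kappa_hat = A1^{-1}(rho_hat)``.  Fitting proceeds by an exhaustive grid
search for initial values followed by a bounded derivative-free simplex
refinement (the conditional-mean map is non-smooth at the tangent branch
point, so gradient-free refinement is the robust choice).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .circular import (
    circular_distance,
    estimate_concentration,
    wrap_angle,
    wrap_signed,
)
from .exceptions import (
    FitFailedError,
    InvalidInputError,
    InvalidParameterError,
    SampleTooSmallError,
)

__all__ = [
    "DMParams",
    "AnglePairs",
    "DMFit",
    "predict",
    "rho_hat",
    "log_likelihood",
    "grid_initialize",
    "fit",
    "DEFAULT_ALPHA_STEP",
    "DEFAULT_OMEGA_STEP",
]

# Default lattice resolution for initial-value search: 3 degrees for the
# angular locations, 0.05 for the slope.
DEFAULT_ALPHA_STEP = np.pi / 60.0
DEFAULT_OMEGA_STEP = 0.05


@dataclass(frozen=True)
class DMParams:
    """Model parameters (alpha, beta, omega).

    ``alpha`` and ``beta`` are stored on the canonical branch ``(-pi, pi]``;
    ``omega`` must lie in ``[-1, 1]``.
    """

    alpha: float
    beta: float
    omega: float

    def __post_init__(self):
        for name in ("alpha", "beta"):
            val = getattr(self, name)
            if not np.isfinite(val):
                raise InvalidParameterError(f"{name} must be finite")
        if not np.isfinite(self.omega) or abs(self.omega) > 1.0 + 1e-12:
            raise InvalidParameterError(
                f"omega must lie in [-1, 1], got {self.omega}"
            )
        object.__setattr__(self, "alpha", wrap_signed(self.alpha))
        object.__setattr__(self, "beta", wrap_signed(self.beta))
        object.__setattr__(self, "omega", float(np.clip(self.omega, -1.0, 1.0)))


@dataclass(frozen=True)
class AnglePairs:
    """A paired circular sample (u_j, v_j), j = 1..n, in radians.

    Angles are wrapped to [0, 2*pi) on construction.  ``labels`` are
    optional row identifiers carried through to reports.
    """

    u: np.ndarray
    v: np.ndarray
    labels: tuple | None = None

    def __post_init__(self):
        u = np.atleast_1d(np.asarray(self.u, dtype=float))
        v = np.atleast_1d(np.asarray(self.v, dtype=float))
        if u.shape != v.shape or u.ndim != 1:
            raise InvalidInputError(
                f"u and v must be 1-d arrays of equal length, got {u.shape} and {v.shape}"
            )
        if u.size < 1:
            raise InvalidInputError("need at least one pair of angles")
        if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
            raise InvalidInputError("angles must be finite")
        if self.labels is not None and len(self.labels) != u.size:
            raise InvalidInputError("labels length must match the sample size")
        object.__setattr__(self, "u", wrap_angle(u))
        object.__setattr__(self, "v", wrap_angle(v))

    def __len__(self) -> int:
        return int(self.u.size)

    def drop(self, index: int) -> "AnglePairs":
        """A copy with the observation at 0-based ``index`` removed."""
        keep = np.arange(len(self)) != index
        labels = None
        if self.labels is not None:
            labels = tuple(l for i, l in enumerate(self.labels) if keep[i])
        return AnglePairs(self.u[keep], self.v[keep], labels)


@dataclass(frozen=True)
class DMFit:
    """A fitted Downs-Mardia regression.

    ``rho_hat`` is the mean cosine of the angular residuals at the
    estimates, ``kappa_hat`` its Bessel-ratio inverse, ``fitted`` the
    conditional mean directions, ``residuals`` the circular distances
    between observed and fitted values (each in [0, pi]).
    """

    params: DMParams
    rho_hat: float
    kappa_hat: float
    fitted: np.ndarray = field(repr=False)
    residuals: np.ndarray = field(repr=False)
    loglik: float
    n: int


def _mean_angle_terms(u, v, alpha, omega):
    """Means of cos and sin of (v - g(u)) where g(u) = 2 atan(omega tan((u-alpha)/2)).

    rho_hat(alpha, beta, omega) = A cos(beta) + B sin(beta), so the slope and
    location alpha determine the precision profile over beta in closed form.
    """
    half = 0.5 * wrap_signed(u - alpha)
    g = 2.0 * np.arctan(omega * np.tan(half))
    z = v - g
    return float(np.mean(np.cos(z))), float(np.mean(np.sin(z)))


def predict(u, params: DMParams):
    """Conditional mean direction of v given u (scalar or array), wrapped to [0, 2*pi).

    At the singular point ``u - alpha = pi (mod 2*pi)`` the map's limit is
    ``beta + pi`` for ``omega != 0`` and ``beta`` for ``omega = 0``.
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise InvalidInputError("u must be finite")
    half = 0.5 * wrap_signed(u - params.alpha)
    t = np.tan(half)
    with np.errstate(invalid="ignore"):
        shift = 2.0 * np.arctan(params.omega * t)
    # exact branch point: tan(pi/2) overflows only conceptually; numerically it
    # is a huge finite number, but guard the omega=0 indeterminate form 0*inf
    singular = ~np.isfinite(shift)
    if np.any(singular):
        limit = np.pi * np.sign(params.omega) if params.omega != 0 else 0.0
        shift = np.where(singular, limit, shift)
    out = wrap_angle(params.beta + shift)
    if np.ndim(u) == 0:
        return float(out)
    return out


def rho_hat(data: AnglePairs, params: DMParams) -> float:
    """Mean residual cosine (the precision estimate) at the given parameters.

    Equals 1 iff every v_j coincides with its conditional mean direction.
    """
    mu = predict(data.u, params)
    return float(np.mean(np.cos(data.v - mu)))


def log_likelihood(data: AnglePairs, params: DMParams, kappa: float) -> float:
    """Von Mises log-likelihood, up to an additive constant.

    ``-n log I0(kappa) + kappa * n * rho_hat``.  The profile over kappa is
    maximized at ``kappa = A1^{-1}(rho_hat)`` when the mean cosine is
    positive.
    """
    if not np.isfinite(kappa) or kappa < 0:
        raise InvalidParameterError(f"kappa must be non-negative, got {kappa}")
    n = len(data)
    # log I0(kappa) = kappa + log(i0e(kappa)), overflow-safe
    log_i0 = kappa + np.log(special.i0e(kappa))
    return float(-n * log_i0 + kappa * n * rho_hat(data, params))


def _grid_axes(alpha_step: float, omega_step: float):
    if alpha_step <= 0 or omega_step <= 0:
        raise InvalidParameterError("grid steps must be positive")
    alphas = np.arange(-np.pi, np.pi - 1e-12, alpha_step)
    omegas = np.arange(-1.0, 1.0 + 1e-12, omega_step)
    omegas = omegas[np.abs(omegas) > 1e-12]  # omega = 0 is degenerate
    if alphas.size == 0 or omegas.size == 0:
        raise InvalidParameterError("grid steps produce an empty lattice")
    return alphas, omegas


def grid_initialize(
    data: AnglePairs,
    alpha_step: float = DEFAULT_ALPHA_STEP,
    omega_step: float = DEFAULT_OMEGA_STEP,
) -> DMParams:
    """Exhaustive lattice search for initial values.

    Evaluates the precision ``rho_hat`` on the lattice
    ``alpha, beta in [-pi, pi)`` by ``alpha_step`` and
    ``omega in [-1, 1]`` by ``omega_step`` (excluding the degenerate
    ``omega = 0``) and returns the maximizing triple; ties are broken by
    lexicographic (alpha, beta, omega) order.
    """
    alphas, omegas = _grid_axes(alpha_step, omega_step)
    betas = alphas
    u, v = data.u, data.v
    # g has shape (n_alpha, n_omega, n): conditional means with beta = 0
    half = 0.5 * wrap_signed(u[None, :] - alphas[:, None])  # (Na, n)
    t = np.tan(half)
    g = 2.0 * np.arctan(omegas[None, :, None] * t[:, None, :])  # (Na, Nw, n)
    z = v[None, None, :] - g
    A = np.mean(np.cos(z), axis=-1)  # (Na, Nw)
    B = np.mean(np.sin(z), axis=-1)
    # rho(alpha, beta, omega) = A cos(beta) + B sin(beta); order axes
    # (alpha, beta, omega) so that argmax's first hit is the lexicographic
    # smallest triple
    rho = (
        A[:, None, :] * np.cos(betas)[None, :, None]
        + B[:, None, :] * np.sin(betas)[None, :, None]
    )
    ia, ib, iw = np.unravel_index(int(np.argmax(rho)), rho.shape)
    return DMParams(alpha=alphas[ia], beta=betas[ib], omega=omegas[iw])


def _profile_objective(u, v):
    """Negative beta-profiled precision as a function of (alpha, omega)."""

    def neg_profile_rho(x):
        alpha, omega = x
        omega = float(np.clip(omega, -1.0, 1.0))
        A, B = _mean_angle_terms(u, v, alpha, omega)
        return -float(np.hypot(A, B))

    return neg_profile_rho


def fit(
    data: AnglePairs,
    init: DMParams | None = None,
    seed=None,
    alpha_step: float = DEFAULT_ALPHA_STEP,
    omega_step: float = DEFAULT_OMEGA_STEP,
    xtol: float = 1e-6,
) -> DMFit:
    """Maximum-likelihood fit of the Downs-Mardia regression.

    Maximizes the precision ``rho_hat`` (equivalently the kappa-profiled
    log-likelihood) over (alpha, beta, omega) with ``omega`` bounded in
    [-1, 1].  The location ``beta`` is profiled out in closed form, so the
    simplex refinement runs over (alpha, omega) only, starting from ``init``
    or from the lattice maximizer.  ``seed`` drives optional randomized
    restarts when the refined optimum has non-positive precision.

    Raises
    ------
    SampleTooSmallError
        If n < 4 (three parameters plus one residual degree of freedom).
    FitFailedError
        If the optimal mean residual cosine is not positive (the model fits
        worse than orthogonal).
    """
    n = len(data)
    if n < 4:
        raise SampleTooSmallError(
            f"need at least 4 paired angles to fit 3 parameters, got {n}"
        )
    if init is None:
        init = grid_initialize(data, alpha_step=alpha_step, omega_step=omega_step)
    u, v = data.u, data.v
    objective = _profile_objective(u, v)

    def refine(x0):
        return optimize.minimize(
            objective,
            x0=np.asarray(x0, dtype=float),
            method="Nelder-Mead",
            bounds=[(x0[0] - np.pi, x0[0] + np.pi), (-1.0, 1.0)],
            options={"xatol": xtol, "fatol": 1e-12, "maxiter": 2000},
        )

    res = refine([init.alpha, init.omega])
    best = res
    if -best.fun <= 0.0:
        # randomized restarts before giving up on a positive precision
        rng = np.random.default_rng(seed)
        for _ in range(5):
            x0 = [rng.uniform(-np.pi, np.pi), rng.uniform(-1.0, 1.0)]
            cand = refine(x0)
            if cand.fun < best.fun:
                best = cand
            if -best.fun > 0.0:
                break
    alpha_hat = wrap_signed(float(best.x[0]))
    omega_hat = float(np.clip(best.x[1], -1.0, 1.0))
    A, B = _mean_angle_terms(u, v, alpha_hat, omega_hat)
    beta_hat = wrap_signed(float(np.arctan2(B, A)))
    params = DMParams(alpha=alpha_hat, beta=beta_hat, omega=omega_hat)
    rho = rho_hat(data, params)
    if rho <= 0.0:
        raise FitFailedError(
            f"mean residual cosine {rho:.4f} is not positive at the optimum; "
            "the model fits worse than orthogonal"
        )
    kappa = estimate_concentration(min(rho, 1.0 - 1e-15))
    fitted = predict(data.u, params)
    residuals = circular_distance(data.v, fitted)
    loglik = log_likelihood(data, params, kappa)
    return DMFit(
        params=params,
        rho_hat=rho,
        kappa_hat=kappa,
        fitted=fitted,
        residuals=residuals,
        loglik=loglik,
        n=n,
    )
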