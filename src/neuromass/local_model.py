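"""Reduced Hindmarsh–Rose (SJ3D-style) neural-mass model.

One brain region is modeled as coupled excitatory and inhibitory
populations of Hindmarsh–Rose neurons whose external input currents are
dispersed across the population.  A mode reduction collapses each
population to ``n_modes`` representatives: the input-current
distribution N(mu, sigma^2) is partitioned into ``n_modes`` equal-mass
quantile bins, neurons within a bin are summarized by one mean-field
state, and population averages couple the bins.  This yields six state
families — fast voltage-like variable ``xi``, recovery ``eta`` and slow
adaptation ``tau`` for the excitatory population, and counterparts
``alpha``, ``beta``, ``gamma`` for the inhibitory one — each of length
``n_modes`` (6 equations per mode).

Per mode m (mean fields X = sum_m w_m xi_m, A = sum_m w_m alpha_m over
bin masses w_m = 1/M):

    dxi_m    = eta_m - a xi_m^3 + b xi_m^2 - tau_m
               + K11 (X - xi_m) - K21 (A - xi_m) + I_E,m + w_m c_in
    deta_m   = c - d xi_m^2 - eta_m
    dtau_m   = r (s (xi_m - x0) - tau_m)
    dalpha_m = beta_m - a alpha_m^3 + b alpha_m^2 - gamma_m
               + K12 (X - alpha_m) + I_I,m
    dbeta_m  = c - d alpha_m^2 - beta_m
    dgamma_m = r (s (alpha_m - x0) - gamma_m)

K11 couples excitatory onto excitatory, K12 excitatory onto inhibitory,
K21 inhibitory onto excitatory (difference coupling; inhibition enters
with a negative sign).  The long-range network input ``c_in`` enters
additively on the fast excitatory variable of every mode, scaled by the
mode mass — the conventional injection point, chosen here as a model
convention.  With ``n_modes = 1`` and the inhibitory population silenced
the excitatory triplet is exactly the classical three-equation
Hindmarsh–Rose system with input current ``mu``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = ["SJ3DParams", "sj3d_derivative", "equilibrium_check", "initial_state"]


def _quantile_bin_means(mu: float, sigma: float, m: int) -> np.ndarray:
    """Mean input current of each of ``m`` equal-mass quantile bins of
    N(mu, sigma^2): mu + sigma (phi(z_{k-1}) - phi(z_k)) * m."""
    edges = norm.ppf(np.linspace(0.0, 1.0, m + 1))
    pdf = np.where(np.isfinite(edges), norm.pdf(edges), 0.0)
    return mu + sigma * (pdf[:-1] - pdf[1:]) * m


@dataclass
class SJ3DParams:
    """Parameters of the reduced Hindmarsh–Rose neural mass.

    ``K11``, ``K12``, ``K21`` are the excitatory/inhibitory coupling
    constants explored in [0, 1].  Intrinsic constants default to the
    classical Hindmarsh–Rose bursting regime (a=1, b=3, c=1, d=5,
    r=0.006, s=4, x0=-1.6) with dispersed input current
    N(mu=3.3, sigma=0.3) — the conventional defaults of the reduced
    model.  ``mode_weights`` are the bin probability masses (equal by
    construction).
    """

    K11: float = 0.5
    K12: float = 0.1
    K21: float = 0.15
    n_modes: int = 3
    a: float = 1.0
    b: float = 3.0
    c: float = 1.0
    d: float = 5.0
    r: float = 0.006
    s: float = 4.0
    x0: float = -1.6
    mu: float = 3.3
    sigma: float = 0.3

    def __post_init__(self) -> None:
        for name in ("K11", "K12", "K21"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside the exploration range [0, 1]")
        if self.n_modes < 1:
            raise ValueError("n_modes must be >= 1")

    @property
    def mode_weights(self) -> np.ndarray:
        return np.full(self.n_modes, 1.0 / self.n_modes)

    @property
    def ie(self) -> np.ndarray:
        """Per-mode excitatory input currents (quantile-bin means)."""
        return _quantile_bin_means(self.mu, self.sigma, self.n_modes)

    @property
    def ii(self) -> np.ndarray:
        """Per-mode inhibitory input currents (same dispersion model)."""
        return _quantile_bin_means(self.mu, self.sigma, self.n_modes)

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "K11", "K12", "K21", "n_modes",
                "a", "b", "c", "d", "r", "s", "x0", "mu", "sigma",
            )
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SJ3DParams":
        return cls(**d)

    def flat(self) -> np.ndarray:
        """Intrinsic constants as a flat array for the compiled integrator:
        [a, b, c, d, r, s, x0, K11, K12, K21]."""
        return np.array(
            [self.a, self.b, self.c, self.d, self.r, self.s, self.x0,
             self.K11, self.K12, self.K21],
            dtype=np.float64,
        )


def sj3d_derivative(
    state: np.ndarray, params: SJ3DParams, coupling_input: float
) -> np.ndarray:
    """Time derivative of one region's (6, n_modes) state.

    ``state`` rows are [xi, eta, tau, alpha, beta, gamma]; the returned
    array has the same shape.  Pure function of its arguments.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (6, params.n_modes):
        raise ValueError(f"state shape {state.shape} != (6, {params.n_modes})")
    if not (np.all(np.isfinite(state)) and np.isfinite(coupling_input)):
        raise FloatingPointError("non-finite state or coupling input")
    xi, eta, tau, alpha, beta, gamma = state
    w = params.mode_weights
    x_bar = float(w @ xi)
    a_bar = float(w @ alpha)
    p = params
    dxi = (
        eta - p.a * xi**3 + p.b * xi**2 - tau
        + p.K11 * (x_bar - xi) - p.K21 * (a_bar - xi)
        + p.ie + w * coupling_input
    )
    deta = p.c - p.d * xi**2 - eta
    dtau = p.r * (p.s * (xi - p.x0) - tau)
    dalpha = (
        beta - p.a * alpha**3 + p.b * alpha**2 - gamma
        + p.K12 * (x_bar - alpha) + p.ii
    )
    dbeta = p.c - p.d * alpha**2 - beta
    dgamma = p.r * (p.s * (alpha - p.x0) - gamma)
    return np.stack([dxi, deta, dtau, dalpha, dbeta, dgamma])


def equilibrium_check(params: SJ3DParams, state: np.ndarray, tol: float) -> bool:
    """True iff the uncoupled derivative's max-norm is below ``tol``."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    d = sj3d_derivative(state, params, 0.0)
    return bool(np.max(np.abs(d)) < tol)


def initial_state(params: SJ3DParams) -> np.ndarray:
    """Documented standard initial condition: fast variables at the
    Hindmarsh–Rose resting point x0, recovery variables at 1 - d x0^2,
    slow variables at 0."""
    m = params.n_modes
    s = np.zeros((6, m))
    s[0] = params.x0
    s[3] = params.x0
    s[1] = params.c - params.d * params.x0**2
    s[4] = params.c - params.d * params.x0**2
    return s
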