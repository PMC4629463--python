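"""Whole-brain simulation: delay-coupled neural masses and BOLD forward model.

One reduced Hindmarsh–Rose mass (:mod:`neuromass.local_model`) sits at
each connectome region.  Region ``j``'s fast excitatory mean field
``x_j`` propagates to region ``i`` through the structural pathway with
weight ``w_ij`` after a conduction delay ``L_ij / v``, entering node
``i`` as the long-range input

    c_i(t) = G * sum_j w_ij * x_j(t - L_ij / v)

The coupled stochastic system is integrated with the stochastic Heun
predictor–corrector scheme (additive white Gaussian noise, mean 0 and
SD 1 by default, amplitude ``sd * sqrt(dt)`` per step) at an integration
step of 0.0122 ms by default.  The fast excitatory mean field, decimated
to 1 ms, drives a balloon–windkessel hemodynamic model whose output is
sampled at TR = 2 s over 4 minutes after a transient discard — the
acquisition grid of the modeled resting-state protocol.

Conventions the implementation fixes (the coupled and observed variable,
the hemodynamic model, weight normalization, transient handling) are
documented in the package methods note; they are modeling choices, not
constraints of the underlying protocol.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .connectome import StructuralConnectome
from .local_model import SJ3DParams, initial_state

logger = logging.getLogger("neuromass")

__all__ = [
    "SimulationConfig",
    "BOLDSeries",
    "IntegrationDivergenceError",
    "compute_delay_steps",
    "coupling_term",
    "heun_stochastic_step",
    "sample_noise_stream",
    "simulate_neural",
    "bold_forward",
    "simulate_bold",
]

# ---------------------------------------------------------------------------
# configuration and containers

#: balloon–windkessel constants (canonical values; time constants in s)
BALLOON_CONSTANTS = {
    "kappa": 0.65,   # signal decay rate, 1/s
    "gamma": 0.41,   # flow-dependent elimination, 1/s
    "tau": 0.98,     # hemodynamic transit time, s
    "alpha": 0.32,   # Grubb's vessel stiffness exponent
    "E0": 0.34,      # resting oxygen extraction fraction
    "V0": 0.02,      # resting venous blood volume fraction
}

G_RANGE = (0.001, 0.1)
V_RANGE = (1.0, 100.0)


class IntegrationDivergenceError(RuntimeError):
    """State magnitude exceeded the divergence guard during integration."""


@dataclass
class SimulationConfig:
    """All biophysical and numerical parameters of one simulation.

    ``G`` is the long-range coupling (explored in [0.001, 0.1]) and ``v``
    the conduction velocity in mm/ms (numerically equal to m/s, explored
    in [1, 100]).  ``dt`` is the integration step in ms (default
    0.0122 ms); BOLD covers ``duration_s`` seconds at ``tr_s`` after the
    first ``transient_discard_s`` seconds of signal are dropped.
    ``weight_norm`` is ``'none'`` by default: coupling acts on the raw
    FA × streamline weights, whose scale is what makes the G range
    meaningful (``'max'`` divides by the maximum weight instead).
    Out-of-range G/v are rejected unless ``enforce_ranges=False``.
    """

    G: float = 0.05
    v: float = 20.0
    params: SJ3DParams = field(default_factory=SJ3DParams)
    dt: float = 0.0122
    noise_mean: float = 0.0
    noise_sd: float = 1.0
    duration_s: float = 240.0
    tr_s: float = 2.0
    transient_discard_s: float = 10.0
    seed: int = 0
    weight_norm: str = "none"
    hemodynamic_model: str = "balloon"  # or "gamma"
    bold_gain: float = 0.1
    decimate_ms: float = 1.0
    divergence_guard: float = 1e6
    noise_mask: tuple = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    init_perturbation: float = 0.05
    enforce_ranges: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration_s < self.tr_s:
            raise ValueError("duration_s must cover at least one TR")
        if self.v <= 0:
            raise ValueError("conduction velocity must be positive")
        if self.weight_norm not in ("max", "none"):
            raise ValueError("weight_norm must be 'max' or 'none'")
        if self.hemodynamic_model not in ("balloon", "gamma"):
            raise ValueError("hemodynamic_model must be 'balloon' or 'gamma'")
        if self.enforce_ranges:
            if not G_RANGE[0] <= self.G <= G_RANGE[1]:
                raise ValueError(
                    f"G={self.G} outside exploration range {G_RANGE}; "
                    "pass enforce_ranges=False to override"
                )
            if not V_RANGE[0] <= self.v <= V_RANGE[1]:
                raise ValueError(
                    f"v={self.v} outside exploration range {V_RANGE}; "
                    "pass enforce_ranges=False to override"
                )

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "G", "v", "dt", "noise_mean", "noise_sd", "duration_s", "tr_s",
            "transient_discard_s", "seed", "weight_norm", "hemodynamic_model",
            "bold_gain", "decimate_ms", "divergence_guard", "init_perturbation",
            "enforce_ranges",
        )}
        d["noise_mask"] = list(self.noise_mask)
        d["params"] = self.params.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        params = SJ3DParams.from_dict(d.pop("params", {}))
        if "noise_mask" in d:
            d["noise_mask"] = tuple(d["noise_mask"])
        return cls(params=params, **d)

    def config_hash(self) -> str:
        """Stable short hash of the full configuration, for provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def replace(self, **changes) -> "SimulationConfig":
        return replace(self, **changes)


@dataclass
class BOLDSeries:
    """Regions × time BOLD matrix sampled at ``tr_s`` seconds."""

    subject_id: str
    data: np.ndarray
    tr_s: float
    provenance: str = "simulated"  # simulated | empirical | surrogate

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("BOLD data must be regions x time")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data contains non-finite entries")
        if self.provenance not in ("simulated", "empirical", "surrogate"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# delays and coupling

def compute_delay_steps(lengths: np.ndarray, v: float, dt: float) -> np.ndarray:
    """Integer conduction delays in steps: round(L / v / dt), floor 1.

    Zero-length (absent) pathways are stored as 1 step by convention;
    their weight is zero so the value never enters the coupling sum.
    """
    if v <= 0:
        raise ValueError("conduction velocity must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    steps = np.round(np.asarray(lengths, dtype=float) / (v * dt))
    return np.maximum(steps, 1).astype(np.int64)


def coupling_term(
    history: np.ndarray,
    weights: np.ndarray,
    delays: np.ndarray,
    G: float,
    node: int,
    t: int,
) -> float:
    """Long-range input to ``node`` at step ``t``:
    ``G * sum_j weights[node, j] * history[t - delays[node, j], j]``.

    ``history`` holds one row per step of the per-node coupled signal.
    Raises if any required past value falls before the start of history.
    This is the plain-NumPy reference of the coupling used inside the
    compiled integration loop.
    """
    w = weights[node]
    idx = t - delays[node]
    needed = w != 0
    if np.any(idx[needed] < 0):
        raise RuntimeError(
            f"insufficient history at step {t} for node {node}: "
            f"need {int(-idx[needed].min())} more past steps"
        )
    js = np.nonzero(needed)[0]
    return G * float(sum(w[j] * history[idx[j], j] for j in js))


# ---------------------------------------------------------------------------
# stochastic Heun

def heun_stochastic_step(state, drift, dt, rng_draws=None, noise_sd=0.0,
                         guard=1e6):
    """One stochastic Heun predictor–corrector step with additive noise.

        noise  = noise_sd * sqrt(dt) * rng_draws
        pred   = x + dt * f(x) + noise
        x_next = x + dt/2 * (f(x) + f(pred)) + noise

    With ``noise_sd = 0`` this is exactly deterministic Heun.  The same
    Gaussian increment enters predictor and corrector, the standard
    additive-noise formulation of the scheme.
    """
    state = np.asarray(state, dtype=float)
    if rng_draws is None or noise_sd == 0.0:
        noise = 0.0
    else:
        noise = noise_sd * np.sqrt(dt) * np.asarray(rng_draws, dtype=float)
    f1 = np.asarray(drift(state))
    pred = state + dt * f1 + noise
    f2 = np.asarray(drift(pred))
    nxt = state + 0.5 * dt * (f1 + f2) + noise
    if not np.all(np.isfinite(nxt)) or np.max(np.abs(nxt)) > guard:
        raise IntegrationDivergenceError("state exceeded divergence guard")
    return nxt


@njit(cache=True)
def _noise_stream(n: int, seed: int):  # pragma: no cover - compiled
    np.random.seed(seed)
    out = np.empty(n)
    for i in range(n):
        out[i] = np.random.standard_normal()
    return out


def sample_noise_stream(n_draws: int, seed: int) -> np.ndarray:
    """Raw standard-normal draws from the integrator's noise generator.

    Exposes the exact RNG pathway the compiled network loop uses for its
    white Gaussian noise (mean 0, SD 1 before the ``sd * sqrt(dt)``
    scaling), so the noise contract can be checked directly.
    """
    return _noise_stream(int(n_draws), int(seed))


# ---------------------------------------------------------------------------
# compiled network integration

@njit(cache=True, fastmath=True)
def _rhs(state, coup, pc, ie, ii, wm, out):  # pragma: no cover - compiled
    n = state.shape[1]
    M = state.shape[2]
    a, b, c, d, r, s, x0 = pc[0], pc[1], pc[2], pc[3], pc[4], pc[5], pc[6]
    K11, K12, K21 = pc[7], pc[8], pc[9]
    for i in range(n):
        xbar = 0.0
        abar = 0.0
        for m in range(M):
            xbar += wm[m] * state[0, i, m]
            abar += wm[m] * state[3, i, m]
        for m in range(M):
            xi = state[0, i, m]
            eta = state[1, i, m]
            tau = state[2, i, m]
            al = state[3, i, m]
            be = state[4, i, m]
            ga = state[5, i, m]
            out[0, i, m] = (eta - a * xi**3 + b * xi**2 - tau
                            + K11 * (xbar - xi) - K21 * (abar - xi)
                            + ie[m] + wm[m] * coup[i])
            out[1, i, m] = c - d * xi**2 - eta
            out[2, i, m] = r * (s * (xi - x0) - tau)
            out[3, i, m] = (be - a * al**3 + b * al**2 - ga
                            + K12 * (xbar - al) + ii[m])
            out[4, i, m] = c - d * al**2 - be
            out[5, i, m] = r * (s * (al - x0) - ga)


@njit(cache=True)
def _integrate_network(W, delays, G, pc, ie, ii, wm, dt, n_steps, rec_every,
                       noise_mean, noise_sd, noise_mask, seed, state0,
                       guard):  # pragma: no cover - compiled
    n = W.shape[0]
    M = ie.shape[0]
    H = 1
    for i in range(n):
        for j in range(n):
            if delays[i, j] + 1 > H:
                H = delays[i, j] + 1
    hist = np.empty((H, n))
    state = state0.copy()
    for i in range(n):
        acc = 0.0
        for m in range(M):
            acc += wm[m] * state[0, i, m]
        for h in range(H):
            hist[h, i] = acc
    n_rec = n_steps // rec_every
    out = np.empty((n_rec, n))
    f1 = np.empty((6, n, M))
    f2 = np.empty((6, n, M))
    pred = np.empty((6, n, M))
    noise = np.empty((6, n, M))
    coup = np.empty(n)
    np.random.seed(seed)
    sq = np.sqrt(dt)
    noisy = noise_sd > 0.0 or noise_mean != 0.0
    rec_i = 0
    for t in range(n_steps):
        for i in range(n):
            acc = 0.0
            for j in range(n):
                wij = W[i, j]
                if wij != 0.0:
                    acc += wij * hist[(t - delays[i, j]) % H, j]
            coup[i] = G * acc
        for k in range(6):
            nm = noise_mask[k]
            for i in range(n):
                for m in range(M):
                    if noisy and nm != 0.0:
                        noise[k, i, m] = sq * nm * (
                            noise_mean + noise_sd * np.random.standard_normal()
                        )
                    else:
                        noise[k, i, m] = 0.0
        _rhs(state, coup, pc, ie, ii, wm, f1)
        for k in range(6):
            for i in range(n):
                for m in range(M):
                    pred[k, i, m] = state[k, i, m] + dt * f1[k, i, m] + noise[k, i, m]
        _rhs(pred, coup, pc, ie, ii, wm, f2)
        for k in range(6):
            for i in range(n):
                for m in range(M):
                    state[k, i, m] = (state[k, i, m]
                                      + 0.5 * dt * (f1[k, i, m] + f2[k, i, m])
                                      + noise[k, i, m])
        slot = (t + 1) % H
        for i in range(n):
            acc = 0.0
            for m in range(M):
                acc += wm[m] * state[0, i, m]
            hist[slot, i] = acc
        if (t + 1) % rec_every == 0:
            for i in range(n):
                out[rec_i, i] = hist[slot, i]
            rec_i += 1
            for i in range(n):
                xv = hist[slot, i]
                if not np.isfinite(xv) or abs(xv) > guard:
                    return out, state, t + 1
    return out, state, -1


def _normalized_weights(c: StructuralConnectome, mode: str) -> np.ndarray:
    w = c.weights.astype(np.float64)
    if mode == "max" and w.max() > 0:
        w = w / w.max()
    return w


def simulate_neural(
    c: StructuralConnectome,
    config: SimulationConfig,
    *,
    init_state: np.ndarray | None = None,
    return_final_state: bool = False,
):
    """Integrate the delay-coupled network and return the decimated fast
    excitatory mean field, shape ``(n_samples, n_regions)`` at
    ``config.decimate_ms`` resolution covering
    ``duration_s + transient_discard_s`` seconds.

    The initial state is the documented resting condition of the local
    model plus small uniform perturbations (scale
    ``config.init_perturbation``) drawn from ``config.seed``; the delay
    history is initialized by replicating the initial mean field.
    Raises :class:`IntegrationDivergenceError` naming the step if the
    state exceeds ``divergence_guard``.
    """
    n = c.n_regions
    p = config.params
    W = _normalized_weights(c, config.weight_norm)
    delays = compute_delay_steps(c.lengths, config.v, config.dt)
    total_ms = (config.duration_s + config.transient_discard_s) * 1000.0
    rec_every = max(1, int(round(config.decimate_ms / config.dt)))
    n_steps = int(round(total_ms / config.dt))
    n_steps -= n_steps % rec_every  # whole decimation blocks only
    if init_state is None:
        rng = np.random.default_rng(config.seed)
        init = initial_state(p)[:, None, :] + config.init_perturbation * rng.uniform(
            -1.0, 1.0, size=(6, n, p.n_modes)
        )
    else:
        init = np.asarray(init_state, dtype=float)
        if init.shape != (6, n, p.n_modes):
            raise ValueError(f"init_state shape {init.shape} != (6, {n}, {p.n_modes})")
    # numba's RNG is seeded separately; keep it in [0, 2^31)
    nb_seed = int(np.random.default_rng(config.seed).integers(0, 2**31 - 1))
    out, final, diverged = _integrate_network(
        np.ascontiguousarray(W),
        np.ascontiguousarray(delays),
        float(config.G),
        p.flat(),
        np.ascontiguousarray(p.ie),
        np.ascontiguousarray(p.ii),
        np.ascontiguousarray(p.mode_weights),
        float(config.dt),
        n_steps,
        rec_every,
        float(config.noise_mean),
        float(config.noise_sd),
        np.asarray(config.noise_mask, dtype=np.float64),
        nb_seed,
        np.ascontiguousarray(init),
        float(config.divergence_guard),
    )
    if diverged >= 0:
        raise IntegrationDivergenceError(
            f"integration diverged at step {diverged} "
            f"(t = {diverged * config.dt:.3f} ms)"
        )
    if return_final_state:
        return out, final
    return out


# ---------------------------------------------------------------------------
# hemodynamic forward model

@njit(cache=True, fastmath=True)
def _balloon(drive, dt_s, kappa, gamma, tau, alpha, E0, V0, k1, k2, k3):
    # pragma: no cover - compiled
    n, T = drive.shape
    y = np.empty((n, T))
    # positivity / range guards: physiological values sit in ~[0.5, 2];
    # the clamps only engage under extreme drive and keep the ODEs finite
    lo, hi = 0.01, 50.0
    for i in range(n):
        s = 0.0
        f = 1.0
        v = 1.0
        q = 1.0
        for t in range(T):
            E = 1.0 - (1.0 - E0) ** (1.0 / f)
            vexp = v ** (1.0 / alpha)
            ds = drive[i, t] - kappa * s - gamma * (f - 1.0)
            dv = (f - vexp) / tau
            dq = (f * E / E0 - vexp * q / v) / tau
            s += dt_s * ds
            f += dt_s * s
            v += dt_s * dv
            q += dt_s * dq
            if s < -100.0:
                s = -100.0
            elif s > 100.0:
                s = 100.0
            if f < lo:
                f = lo
            elif f > hi:
                f = hi
            if v < lo:
                v = lo
            elif v > hi:
                v = hi
            if q < 1e-4:
                q = 1e-4
            elif q > hi:
                q = hi
            y[i, t] = V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))
    return y


def _double_gamma_hrf(dt_s: float, length_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response (peak 6 s, undershoot
    16 s, ratio 1/6), unit sum."""
    from scipy.stats import gamma as gamma_dist

    t = np.arange(0.0, length_s, dt_s)
    h = gamma_dist.pdf(t, 6.0) - gamma_dist.pdf(t, 16.0) / 6.0
    return h / h.sum()


def bold_forward(
    neural: np.ndarray, config: SimulationConfig, subject_id: str = "sim"
) -> BOLDSeries:
    """Map a neural trajectory to BOLD sampled at TR.

    ``neural`` is ``(n_samples, n_regions)`` at ``config.decimate_ms``
    resolution and must cover ``transient_discard_s`` plus at least one
    TR.  The per-node drive is the demeaned mean field times
    ``bold_gain``; it passes through the balloon–windkessel ODEs
    (``hemodynamic_model='balloon'``, Euler at the decimated step) or a
    double-gamma convolution (``'gamma'``).  The first
    ``transient_discard_s`` seconds are discarded and the remainder
    sampled once per TR (end of each TR window).
    """
    neural = np.asarray(neural, dtype=float)
    dt_s = config.decimate_ms / 1000.0
    n_skip = int(round(config.transient_discard_s / dt_s))
    per = int(round(config.tr_s / dt_s))
    if neural.shape[0] < n_skip + per:
        raise ValueError(
            "neural signal shorter than transient_discard_s plus one TR"
        )
    drive = (neural - neural.mean(axis=0, keepdims=True)).T * config.bold_gain
    drive = np.ascontiguousarray(drive)
    if config.hemodynamic_model == "balloon":
        b = BALLOON_CONSTANTS
        k1 = 7.0 * b["E0"]
        k2 = 2.0
        k3 = 2.0 * b["E0"] - 0.2
        y = _balloon(drive, dt_s, b["kappa"], b["gamma"], b["tau"],
                     b["alpha"], b["E0"], b["V0"], k1, k2, k3)
    else:
        from scipy.signal import fftconvolve

        h = _double_gamma_hrf(dt_s)
        y = fftconvolve(drive, h[None, :], mode="full", axes=1)[:, : drive.shape[1]]
    n_t = (y.shape[1] - n_skip) // per
    idx = n_skip + per * np.arange(1, n_t + 1) - 1
    data = y[:, idx]
    return BOLDSeries(subject_id=subject_id, data=data, tr_s=config.tr_s,
                      provenance="simulated")


def simulate_bold(
    c: StructuralConnectome, config: SimulationConfig
) -> BOLDSeries:
    """Full forward pass: network integration then hemodynamic model."""
    neural = simulate_neural(c, config)
    return bold_forward(neural, config, subject_id=c.subject_id)
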