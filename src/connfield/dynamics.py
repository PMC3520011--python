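"""Stochastic neural-field dynamics on a connectivity matrix.

The model: node activity q (mean depolarisation) obeys the Langevin
equation

    dq = (−τ·q + Δ·κ·f̃(q)) dt + √ε dW,

where κ is the anatomical connectivity, Δ the spatial quadrature step,
f̃ the sigmoid firing rate centred so that f̃(u₀) = 0 at the fixed point,
and W a spatially uncorrelated Wiener process.  The connectivity is
scaled so that the slowest eigenvalue of the linearised drift approaches
zero from below (near-criticality), making resting fluctuations slow and
dominated by the leading anatomical eigenmode; functional connectivity is
the sample covariance of the simulated series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import linalg, optimize

from .fixtures import ConnectivityMatrix, InvalidParameterError

__all__ = [
    "FieldParams",
    "FixedPoint",
    "SimulationConfig",
    "SimulationResult",
    "firing_rate",
    "centred_firing_rate",
    "find_fixed_point",
    "linearize",
    "critical_scaling",
    "simulate",
    "functional_connectivity",
    "principal_functional_mode",
    "stationary_covariance",
]


class ConvergenceError(RuntimeError):
    """Fixed-point search failed to reach tolerance."""


class InstabilityError(RuntimeError):
    """Trajectory exceeded the divergence ceiling."""


class CannotScaleError(ValueError):
    """No positive connectivity eigenvalue: system unconditionally stable."""


class DegenerateInputError(ValueError):
    """Input carries no usable signal (e.g. a zero covariance matrix)."""


@dataclass(frozen=True)
class FieldParams:
    """Neural-field parameters.

    tau: activity decay rate (1/s).  gain_a: sigmoid slope.  theta:
    firing threshold (activity units).  epsilon: noise intensity (kept
    small so fluctuations stay in the linear regime).  spacing:
    quadrature step Δ of the kernel integral (1 for abstract graphs).
    centred: use f̃(q) = f(q) − f(u₀) so the fixed point is u₀ = 0.
    """

    tau: float = 1.0
    gain_a: float = 1.0
    theta: float = 0.0
    epsilon: float = 1e-3
    spacing: float = 1.0
    centred: bool = True

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.gain_a <= 0 or self.spacing <= 0:
            raise InvalidParameterError("tau, gain_a, spacing must be positive")
        if self.epsilon < 0:
            raise InvalidParameterError("epsilon must be nonnegative")


@dataclass(frozen=True)
class FixedPoint:
    """Steady state u₀ of the deterministic field, with the per-node
    linearised gain h = f′(u₀) and the residual of the defining equation."""

    u0: np.ndarray
    residual: float
    gain_h: np.ndarray


@dataclass(frozen=True)
class SimulationConfig:
    """Integration settings: Euler–Maruyama with step dt over n_samples
    time bins (defaults 0.01 s and 2001 samples); seeded; initial state at
    the fixed point or uniform-random around it."""

    dt: float = 0.01
    n_samples: int = 2001
    seed: int = 0
    initial_condition: Literal["fixed_point", "random_uniform"] = "fixed_point"
    random_amplitude: float = 0.1
    burn_in: int = 0
    divergence_ceiling: float = 1e6

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise InvalidParameterError("dt must be positive")
        if self.n_samples < 2:
            raise InvalidParameterError("n_samples must be at least 2")
        if not 0 <= self.burn_in < self.n_samples:
            raise InvalidParameterError("burn_in must be in [0, n_samples)")


@dataclass(frozen=True)
class SimulationResult:
    """Simulated resting-state series: times (s) × node activity, plus the
    configuration echo and the fingerprint of the matrix that produced it."""

    times: np.ndarray
    activity: np.ndarray  # shape (T, N)
    params: FieldParams
    config: SimulationConfig
    matrix_fingerprint: str


def firing_rate(q: np.ndarray | float, params: FieldParams) -> np.ndarray | float:
    """Sigmoid rate f(q) = 1/(1 + exp(−a(q − θ))), elementwise; saturates
    gracefully at extreme arguments."""
    x = params.gain_a * (np.asarray(q, dtype=float) - params.theta)
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if np.isscalar(q):
        return float(out)
    return out


def _rate_derivative(q: np.ndarray, params: FieldParams) -> np.ndarray:
    f = np.asarray(firing_rate(q, params))
    return params.gain_a * f * (1.0 - f)


def centred_firing_rate(
    q: np.ndarray | float, params: FieldParams, u0: np.ndarray | float = 0.0
) -> np.ndarray | float:
    """f̃(q) = f(q) − f(u₀): the rate used inside the dynamics so that the
    afferent drive vanishes at the fixed point (f̃(u₀) = 0)."""
    return firing_rate(q, params) - firing_rate(u0, params)


def find_fixed_point(
    matrix: ConnectivityMatrix,
    params: FieldParams,
    init: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> FixedPoint:
    """Solve −τ·u + Δ·κ·f(u) = 0 (f̃ if centred) for the steady state.

    With the centred rate the solution is u₀ = 0 exactly.  Otherwise a
    damped fixed-point iteration u ← (1−α)u + α·Δ·κ·f(u)/τ is tried and a
    Newton (hybrid Powell) fallback takes over on stagnation.
    """
    n = matrix.n_nodes
    kernel = params.spacing * matrix.weights

    if params.centred:
        u0 = np.zeros(n)
        return FixedPoint(u0=u0, residual=0.0, gain_h=_rate_derivative(u0, params))

    def defect(u: np.ndarray) -> np.ndarray:
        return -params.tau * u + kernel @ np.asarray(firing_rate(u, params))

    u = np.zeros(n) if init is None else np.asarray(init, dtype=float).copy()
    alpha = 0.5
    for _ in range(max_iter):
        res = defect(u)
        if np.max(np.abs(res)) <= tol:
            return FixedPoint(
                u0=u, residual=float(np.max(np.abs(res))),
                gain_h=_rate_derivative(u, params),
            )
        u = u + alpha * res / params.tau

    sol = optimize.root(defect, u, method="hybr", tol=tol * 1e-2)
    res = defect(sol.x)
    rmax = float(np.max(np.abs(res)))
    if rmax > tol:
        raise ConvergenceError(f"fixed point not found; last residual {rmax:.3e}")
    return FixedPoint(u0=sol.x, residual=rmax, gain_h=_rate_derivative(sol.x, params))


def linearize(
    matrix: ConnectivityMatrix,
    params: FieldParams,
    fixed_point: FixedPoint | None = None,
) -> np.ndarray:
    """Jacobian of the drift at the fixed point: J = Δ·κ·diag(h) − τ·I with
    h = f′(u₀) per node.  Its eigenvalues are the dynamical rates λ_l."""
    if fixed_point is None:
        fixed_point = find_fixed_point(matrix, params)
    h = np.asarray(fixed_point.gain_h, dtype=float)
    n = matrix.n_nodes
    return params.spacing * matrix.weights * h[None, :] - params.tau * np.eye(n)


def critical_scaling(
    matrix: ConnectivityMatrix,
    params: FieldParams,
    delta: float | None = None,
) -> tuple[ConnectivityMatrix, float]:
    """Scale κ so the slowest dynamical eigenvalue sits at −delta.

    Returns (s·κ, s) with s = (τ − delta)/(h·Δ·max Re L(κ)); after scaling
    max Re λ(J) = −delta and every other Re λ ≤ −delta.  delta defaults to
    0.01·τ, the operationalisation of "approaching" criticality.
    """
    if delta is None:
        delta = 0.01 * params.tau
    if not 0 < delta <= params.tau:
        raise InvalidParameterError("delta must lie in (0, tau]")
    fp = find_fixed_point(matrix, params)
    h = float(np.mean(fp.gain_h))  # uniform at a uniform fixed point
    lmax = float(np.max(np.linalg.eigvals(matrix.weights).real))
    if h * params.spacing * lmax <= 0:
        raise CannotScaleError(
            "connectivity has no positive eigenvalue; already unconditionally stable"
        )
    s = (params.tau - delta) / (h * params.spacing * lmax)
    return matrix.with_weights(s * matrix.weights), float(s)


def simulate(
    matrix: ConnectivityMatrix,
    params: FieldParams,
    config: SimulationConfig | None = None,
    *,
    allow_unstable: bool = False,
) -> SimulationResult:
    """Integrate the Langevin field with the Euler–Maruyama scheme.

    Update per 0.01-s-style time bin:
    q ← q + dt·(−τq + Δ·κ·f̃(q)) + √(ε·dt)·η, η i.i.d. standard normal per
    node and step.  Identical seeds give bit-identical trajectories.  The
    kernel is applied as a plain matrix product with no wraparound, which
    realises the zero-flux (truncation) boundary setting.
    """
    config = config or SimulationConfig()
    fp = find_fixed_point(matrix, params)
    if not allow_unstable:
        lam = np.linalg.eigvals(linearize(matrix, params, fp))
        if np.max(lam.real) >= 0:
            raise InstabilityError(
                f"max Re lambda = {np.max(lam.real):.3e} >= 0; scale the matrix "
                "first (critical_scaling) or pass allow_unstable=True"
            )
    n = matrix.n_nodes
    rng = np.random.default_rng(config.seed)
    if config.initial_condition == "fixed_point":
        q = fp.u0.copy()
    else:
        q = fp.u0 + rng.uniform(
            -config.random_amplitude, config.random_amplitude, size=n
        )
    kernel = params.spacing * matrix.weights
    f0 = np.asarray(firing_rate(fp.u0, params))
    dt = config.dt
    noise_scale = np.sqrt(params.epsilon * dt)
    T = config.n_samples
    traj = np.empty((T, n))
    traj[0] = q
    for t in range(1, T):
        rate = np.asarray(firing_rate(q, params)) - f0 if params.centred else np.asarray(
            firing_rate(q, params)
        )
        drift = -params.tau * q + kernel @ rate
        q = q + dt * drift
        if noise_scale > 0:
            q = q + noise_scale * rng.standard_normal(n)
        if np.max(np.abs(q)) > config.divergence_ceiling:
            raise InstabilityError(f"trajectory diverged at step {t}")
        traj[t] = q
    keep = slice(config.burn_in, None)
    times = np.arange(T)[keep] * dt
    return SimulationResult(
        times=times,
        activity=traj[keep],
        params=params,
        config=config,
        matrix_fingerprint=matrix.fingerprint(),
    )


def functional_connectivity(
    result: SimulationResult, drop_burn_in: bool = True
) -> np.ndarray:
    """Sample covariance of node activity over time — the functional
    connectivity matrix.  Constant series yield the zero matrix."""
    x = result.activity
    if x.shape[0] < 2:
        raise InvalidParameterError("need at least 2 samples")
    fc = np.cov(x, rowvar=False, ddof=1)
    return np.atleast_2d(fc)


def principal_functional_mode(fc: np.ndarray) -> np.ndarray:
    """Unit-norm leading eigenvector of a covariance matrix, sign fixed so
    its largest-magnitude entry is positive."""
    fc = np.asarray(fc, dtype=float)
    if not np.allclose(fc, fc.T, atol=1e-10):
        raise InvalidParameterError("covariance matrix must be symmetric")
    if np.allclose(fc, 0.0):
        raise DegenerateInputError("zero covariance matrix has no principal mode")
    vals, vecs = np.linalg.eigh((fc + fc.T) / 2.0)
    v = vecs[:, -1]
    pivot = int(np.argmax(np.abs(v)))
    if v[pivot] < 0:
        v = -v
    return v


def stationary_covariance(jacobian: np.ndarray, epsilon: float) -> np.ndarray:
    """Stationary covariance Σ of the linear (Ornstein–Uhlenbeck) limit,
    solving the Lyapunov equation JΣ + ΣJᵀ + εI = 0.  Independent analytic
    benchmark for the simulated functional connectivity."""
    j = np.asarray(jacobian, dtype=float)
    if np.max(np.linalg.eigvals(j).real) >= 0:
        raise InstabilityError("Lyapunov solution requires a stable Jacobian")
    return linalg.solve_continuous_lyapunov(j, -epsilon * np.eye(j.shape[0]))
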