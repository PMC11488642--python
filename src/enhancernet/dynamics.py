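"""Time integration of the identity dynamics.

Deterministic paths use adaptive Runge-Kutta (rtol 1e-8 / atol 1e-10);
stochastic paths use fixed-step Euler-Maruyama with additive white noise
of amplitude sigma per component and dt = 0.01 tau, clipping the state at
zero after each step (expression cannot be negative; the deterministic
dynamics preserve nonnegativity on their own since dx/dt >= -x/tau).

The inverse temperature may vary in time (annealing) via ``beta_schedule``,
any callable t -> beta; a constant production term ``forcing`` implements
constitutive TF overexpression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from .network import RegulatoryNetwork, enhancer_activities

__all__ = ["NoiseSpec", "Trajectory", "simulate"]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
DEFAULT_EM_DT_FACTOR = 0.01  # Euler-Maruyama step, in units of tau


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white noise: amplitude sigma (expression units / sqrt(time)).

    A seed is mandatory; there is no implicit global random state.
    """

    sigma: float
    seed: int

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.seed is None:
            raise ValueError("an explicit seed is required")


@dataclass
class Trajectory:
    """Sampled path: times, beta(t), states x(t) and activities p(t)."""

    times: np.ndarray        # (n,)
    beta_values: np.ndarray  # (n,)
    states: np.ndarray       # (n, T)
    activities: np.ndarray   # (n, E)

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.beta_values) == len(self.states)
                == len(self.activities) == n):
            raise ValueError("trajectory fields must have equal lengths")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.beta_values < 0):
            raise ValueError("beta must be >= 0 along the trajectory")

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def concatenate(self, other: "Trajectory") -> "Trajectory":
        """Join a continuation run (its t=0 aligned to our final time)."""
        shift = self.times[-1]
        keep = other.times > 0
        return Trajectory(
            times=np.concatenate([self.times, other.times[keep] + shift]),
            beta_values=np.concatenate([self.beta_values,
                                        other.beta_values[keep]]),
            states=np.vstack([self.states, other.states[keep]]),
            activities=np.vstack([self.activities, other.activities[keep]]),
        )


def _as_beta_fn(net: RegulatoryNetwork, beta_schedule
                ) -> Callable[[float], float]:
    if beta_schedule is None:
        b = float(net.beta)
        return lambda t: b
    if callable(beta_schedule):
        return beta_schedule
    b = float(beta_schedule)
    return lambda t: b


def simulate(net: RegulatoryNetwork, x0, t_span, beta_schedule=None,
             noise: NoiseSpec | None = None, recipe_forcing=None,
             sample_dt: float | None = None, rtol: float = DEFAULT_RTOL,
             atol: float = DEFAULT_ATOL) -> Trajectory:
    """Integrate the dynamics from ``x0`` over ``t_span`` = (t0, t1).

    Deterministic (noise None or sigma=0) integration uses RK45; with noise,
    fixed-step Euler-Maruyama at dt = 0.01 tau with per-component additive
    noise sigma dW and clipping at zero.  ``recipe_forcing`` is a length-T
    delta vector adding delta_j / tau to the production of TF j throughout
    the run.  Raises on non-finite states, naming the time of failure.
    """
    x0 = np.asarray(x0, dtype=float).ravel()
    if x0.shape != (net.n_tfs,):
        raise ValueError(f"x0 has length {x0.size}, expected {net.n_tfs}")
    if np.any(x0 < -1e-9):
        raise ValueError("x0 must be nonnegative")
    x0 = np.clip(x0, 0.0, None)
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not (np.isfinite(t0) and np.isfinite(t1) and t1 > t0):
        raise ValueError("t_span must be finite with t1 > t0")
    beta_fn = _as_beta_fn(net, beta_schedule)
    forcing = None
    if recipe_forcing is not None:
        forcing = np.asarray(recipe_forcing, dtype=float).ravel()
        if forcing.shape != (net.n_tfs,):
            raise ValueError("recipe_forcing must have length T")

    if sample_dt is None:
        sample_dt = max((t1 - t0) / 500.0, DEFAULT_EM_DT_FACTOR * net.tau)

    if noise is not None and noise.sigma > 0:
        times, states = _euler_maruyama(net, x0, t0, t1, beta_fn, noise,
                                        forcing, sample_dt)
    else:
        times, states = _adaptive(net, x0, t0, t1, beta_fn, forcing,
                                  sample_dt, rtol, atol)

    betas = np.array([beta_fn(t) for t in times])
    acts = np.array([enhancer_activities(net, x, beta=b)
                     for x, b in zip(states, betas)])
    return Trajectory(times=times, beta_values=betas, states=states,
                      activities=acts)


def _rhs(net, beta_fn, forcing):
    Q_T = net.coupling.T
    eff = net.binding_eff
    w = net.weights
    tau = net.tau

    def f(t, x):
        s = beta_fn(t) * (eff @ x) + w
        s = s - s.max()
        e = np.exp(s)
        p = e / e.sum()
        v = Q_T @ p - x
        if forcing is not None:
            v = v + forcing
        return v / tau

    return f


def _adaptive(net, x0, t0, t1, beta_fn, forcing, sample_dt, rtol, atol):
    t_eval = np.arange(t0, t1, sample_dt)
    if t_eval[-1] < t1:
        t_eval = np.append(t_eval, t1)
    sol = solve_ivp(_rhs(net, beta_fn, forcing), (t0, t1), x0,
                    method="RK45", t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"integration failed at t={sol.t[-1]:g}: "
                           f"{sol.message}")
    if not np.all(np.isfinite(sol.y)):
        bad = np.where(~np.isfinite(sol.y).all(axis=0))[0][0]
        raise FloatingPointError(
            f"non-finite state at t={sol.t[bad]:g}")
    return sol.t, sol.y.T.copy()


def _euler_maruyama(net, x0, t0, t1, beta_fn, noise, forcing, sample_dt):
    dt = DEFAULT_EM_DT_FACTOR * net.tau
    n_steps = int(np.ceil((t1 - t0) / dt))
    rng = np.random.default_rng(noise.seed)
    f = _rhs(net, beta_fn, forcing)
    sqrt_dt = np.sqrt(dt)
    every = max(1, int(round(sample_dt / dt)))

    x = x0.copy()
    times = [t0]
    states = [x.copy()]
    t = t0
    for k in range(n_steps):
        step = min(dt, t1 - t)
        x = x + step * f(t, x) + noise.sigma * sqrt_dt * rng.standard_normal(
            net.n_tfs)
        np.clip(x, 0.0, None, out=x)
        t = t0 + (k + 1) * dt if k < n_steps - 1 else t1
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(f"non-finite state at t={t:g}")
        if (k + 1) % every == 0 or k == n_steps - 1:
            times.append(t)
            states.append(x.copy())
    return np.array(times), np.array(states)
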