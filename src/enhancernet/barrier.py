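"""Chromatin barrier to reprogramming: a bistable repressive modification.

Each enhancer carries a slow repressive modification level u_i that is
autocatalytic (Hill production of order n >> 1) and inhibited by enhancer
activity: the production drive f(p_i) is a decreasing function of the
initiation probability p_i.  While an enhancer is active (p_i above a
critical threshold) the low branch u_i ~ 0 is maintained; when its
activity drops below p_crit the low branch disappears through a
saddle-node and u_i jumps to a high branch, adding an energy penalty
``-lambda u_i`` to the enhancer weight and so locking the cell out of the
corresponding identity.  Depending on the Hill threshold rho the switch is
bistable (the high branch persists when activity recovers -- hysteresis)
or reversible.

The precise kinetic closure is a design choice of this package: production
``f(p) * (baseline + u^n / (rho^n + u^n))`` with linear degradation, and a
smoothly decreasing ``f`` crossing the saddle-node boundary at p_crit.
Only the qualitative contract (stable low branch above p_crit, jump and
hysteresis below) should be relied upon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .network import RegulatoryNetwork

__all__ = ["BarrierParams", "chromatin_barrier_step", "hysteresis_sweep"]


def _default_f_factory(p_crit: float, f_low: float = 2.0, f_high: float = 9.0,
                       width: float = 0.02) -> Callable:
    def f(p):
        return f_low + (f_high - f_low) / (
            1.0 + np.exp((np.asarray(p, float) - p_crit) / width))
    return f


@dataclass
class BarrierParams:
    """Parameters of the repressive-modification switch.

    lambda_penalty: energy penalty scale applied to weights as -lambda*u.
    rho: Hill half-point of the autocatalysis (sets bistability regime).
    hill_n: Hill order (>= 2; sharp switch for n >> 1).
    p_crit: enhancer activity below which the low branch disappears.
    f_shape: decreasing map p -> production drive; defaults to a sigmoid
        stepping from ~9 (silent enhancer) to ~2 (active enhancer).
    baseline: basal production fraction (keeps the low branch at
        u ~ f(p)*baseline instead of exactly zero, so the saddle-node can
        actually be crossed).
    u: current modification levels (length E).
    """

    lambda_penalty: float = 1.0
    rho: float = 1.0
    hill_n: int = 8
    p_crit: float = 0.05
    baseline: float = 0.1
    degradation: float = 1.0
    f_shape: Callable | None = None
    u: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.hill_n < 2:
            raise ValueError("hill_n must be >= 2")
        if not (0.0 < self.p_crit < 1.0):
            raise ValueError("p_crit must lie in (0, 1)")
        if self.rho <= 0 or self.degradation <= 0 or self.baseline < 0:
            raise ValueError("rho, degradation > 0 and baseline >= 0")
        if self.f_shape is None:
            self.f_shape = _default_f_factory(self.p_crit)
        grid = np.linspace(0.0, 1.0, 101)
        vals = np.asarray(self.f_shape(grid), dtype=float)
        if np.any(np.diff(vals) > 1e-12):
            raise ValueError("f_shape must be monotone decreasing in p")
        if self.u is not None:
            self.u = np.asarray(self.u, dtype=float)
            if np.any(self.u < 0):
                raise ValueError("u must be >= 0")

    def init_u(self, n_enhancers: int) -> np.ndarray:
        if self.u is None:
            self.u = np.zeros(n_enhancers)
        return self.u


def barrier_rate(params: BarrierParams, p, u) -> np.ndarray:
    """du/dt for modification levels u at enhancer activities p."""
    u = np.asarray(u, dtype=float)
    hill = u ** params.hill_n / (params.rho ** params.hill_n
                                 + u ** params.hill_n)
    drive = np.asarray(params.f_shape(p), dtype=float)
    return drive * (params.baseline + hill) - params.degradation * u


def chromatin_barrier_step(net: RegulatoryNetwork, params: BarrierParams,
                           x, dt: float, n_substeps: int = 10):
    """Advance u by dt at the current state and return (u, effective w).

    The modification integrates explicitly (sub-stepped for stiffness);
    the returned weights are ``w - lambda * u``: transcription from a
    marked enhancer is suppressed as u grows.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    u = params.init_u(net.n_enhancers)
    p = net.activities(x)
    h = dt / n_substeps
    for _ in range(n_substeps):
        u = np.clip(u + h * barrier_rate(params, p, u), 0.0, None)
    params.u = u
    effective_weights = net.weights - params.lambda_penalty * u
    return u, effective_weights


def hysteresis_sweep(params: BarrierParams, p_values, u0: float = 0.0,
                     t_per_step: float = 40.0, dt: float = 0.02) -> np.ndarray:
    """Quasi-static sweep of a single enhancer's activity.

    Holds each activity value for ``t_per_step`` while integrating u, and
    records the settled u; sweeping p down past p_crit and back up exposes
    the hysteresis loop when rho places the switch in the bistable regime.
    """
    u = float(u0)
    out = []
    for p in p_values:
        steps = int(t_per_step / dt)
        for _ in range(steps):
            u = max(u + dt * float(barrier_rate(params, np.array([p]),
                                                np.array([u]))[0]), 0.0)
        out.append(u)
    return np.array(out)
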