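"""Network data model and core dynamics of TF-enhancer feedback.

The state of a cell is a nonnegative vector ``x`` of transcription-factor
(TF) expression levels.  Enhancers (or enhancer *types*: equivalence classes
of physical enhancers with identical binding profiles) compete for a shared
pool of transcription-initiation machinery.  The probability that
transcription initiates at enhancer ``i`` follows a Boltzmann distribution
over the enhancer activation energies, which are set by TF binding::

    s_i = beta * zeta_i * (xi_i . x) + w_i          (enhancer score)
    p   = softmax(s)                                (initiation probabilities)
    dx/dt = (Q^T p - x) / tau                       (expression turnover)

``Xi`` (binding) holds the affinities of each enhancer for each TF, ``Q``
(coupling) the transcription rates each enhancer drives, ``w`` a baseline
log-activity (signalling input), ``beta`` the inverse temperature set by
chromatin-modification turnover, and ``zeta`` an optional per-enhancer gain
(pioneer-factor accessibility).

When ``Q`` is proportional to the (gain-scaled) binding matrix -- the
autoregulatory/reciprocal case ubiquitous in developmental networks -- the
dynamics are a gradient flow on the potential::

    V(x) = 0.5 ||x||^2 - (nu / beta) * logsumexp(beta * Xi x + w)

whose minima are the cell types encoded by the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import logsumexp, softmax

__all__ = [
    "RegulatoryNetwork",
    "ReciprocityReport",
    "enhancer_scores",
    "enhancer_activities",
    "drift",
    "potential",
    "jacobian",
    "check_reciprocity",
    "reduce_to_types",
]

#: tolerance for declaring Q proportional to the gain-scaled binding matrix
_SYMMETRY_ATOL = 1e-9


def _fit_nu(binding_eff: np.ndarray, coupling: np.ndarray) -> float:
    """Least-squares scalar nu minimising ||Q - nu * Xi_zeta||_F."""
    denom = float(np.sum(binding_eff * binding_eff))
    if denom == 0.0:
        return 0.0
    return float(np.sum(coupling * binding_eff) / denom)


@dataclass(frozen=True)
class RegulatoryNetwork:
    """Parameterization (Xi, Q, w, beta, tau, zeta) of the identity network.

    The single source of truth for all dynamics.  Instances are immutable;
    use :meth:`with_beta` / :meth:`with_weights` to derive variants.
    """

    tf_names: tuple
    enhancer_names: tuple
    binding: np.ndarray       # Xi, E x T, >= 0
    coupling: np.ndarray      # Q, E x T, >= 0
    weights: np.ndarray       # w, length E
    beta: float = 1.0
    tau: float = 1.0
    gain: np.ndarray | None = None  # zeta, length E, >= 0; default all ones
    symmetric: bool = field(init=False, default=False)
    nu: float = field(init=False, default=1.0)

    def __post_init__(self) -> None:
        binding = np.asarray(self.binding, dtype=float)
        coupling = np.asarray(self.coupling, dtype=float)
        weights = np.asarray(self.weights, dtype=float).ravel()
        gain = (np.ones(binding.shape[0]) if self.gain is None
                else np.asarray(self.gain, dtype=float).ravel())
        object.__setattr__(self, "tf_names", tuple(self.tf_names))
        object.__setattr__(self, "enhancer_names", tuple(self.enhancer_names))
        object.__setattr__(self, "binding", binding)
        object.__setattr__(self, "coupling", coupling)
        object.__setattr__(self, "weights", weights)
        object.__setattr__(self, "gain", gain)

        E, T = binding.shape
        if len(self.enhancer_names) != E or len(self.tf_names) != T:
            raise ValueError(
                f"name/shape mismatch: binding is {E}x{T} but got "
                f"{len(self.enhancer_names)} enhancer names and "
                f"{len(self.tf_names)} TF names")
        if len(set(self.tf_names)) != T:
            raise ValueError("TF names must be unique")
        if len(set(self.enhancer_names)) != E:
            raise ValueError("enhancer names must be unique")
        if coupling.shape != (E, T):
            raise ValueError(
                f"coupling shape {coupling.shape} != binding shape {(E, T)}")
        if weights.shape != (E,):
            raise ValueError(f"weights must have length {E}, got {weights.shape}")
        if gain.shape != (E,):
            raise ValueError(f"gain must have length {E}, got {gain.shape}")
        if np.any(binding < 0) or np.any(coupling < 0) or np.any(gain < 0):
            raise ValueError("binding, coupling and gain must be nonnegative")
        if not (self.beta >= 0):
            raise ValueError("beta must be >= 0")
        if not (self.tau > 0):
            raise ValueError("tau must be > 0")

        # reciprocity flag is recomputed, never user-asserted
        eff = gain[:, None] * binding
        nu = _fit_nu(eff, coupling)
        sym = bool(np.max(np.abs(coupling - nu * eff), initial=0.0)
                   <= _SYMMETRY_ATOL)
        object.__setattr__(self, "nu", nu if sym else 1.0)
        object.__setattr__(self, "symmetric", sym)

    # -- derived views ----------------------------------------------------
    @property
    def n_tfs(self) -> int:
        return self.binding.shape[1]

    @property
    def n_enhancers(self) -> int:
        return self.binding.shape[0]

    @property
    def binding_eff(self) -> np.ndarray:
        """Gain-scaled binding matrix (rows zeta_i * xi_i)."""
        return self.gain[:, None] * self.binding

    @property
    def patterns(self) -> np.ndarray:
        """Candidate cell-type expression patterns: the rows of Q."""
        return self.coupling

    def with_beta(self, beta: float) -> "RegulatoryNetwork":
        return replace(self, beta=float(beta))

    def with_weights(self, weights: Sequence[float]) -> "RegulatoryNetwork":
        return replace(self, weights=np.asarray(weights, dtype=float))

    # -- convenience method surface ---------------------------------------
    def scores(self, x, beta=None):
        return enhancer_scores(self, x, beta=beta)

    def activities(self, x, beta=None):
        return enhancer_activities(self, x, beta=beta)

    def drift(self, x, beta=None, forcing=None):
        return drift(self, x, beta=beta, forcing=forcing)

    def potential(self, x, beta=None):
        return potential(self, x, beta=beta)

    def jacobian(self, x, beta=None):
        return jacobian(self, x, beta=beta)


def _check_state(net: RegulatoryNetwork, x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.shape != (net.n_tfs,):
        raise ValueError(
            f"state has length {x.shape[0]} along the TF axis, "
            f"expected {net.n_tfs}")
    return x


def enhancer_scores(net: RegulatoryNetwork, x, beta: float | None = None
                    ) -> np.ndarray:
    """Log-Boltzmann score of each enhancer at expression state ``x``.

    ``s_i = beta * zeta_i * (xi_i . x) + w_i``.  The baseline weights enter
    un-scaled by beta, so signalling biases persist in the beta -> 0 limit.
    """
    x = _check_state(net, x)
    b = net.beta if beta is None else beta
    return b * (net.binding_eff @ x) + net.weights


def enhancer_activities(net: RegulatoryNetwork, x, beta: float | None = None
                        ) -> np.ndarray:
    """Transcription-initiation probabilities p = softmax(scores)."""
    s = enhancer_scores(net, x, beta=beta)
    if not np.all(np.isfinite(s)):
        raise FloatingPointError("non-finite enhancer scores")
    return softmax(s)


def drift(net: RegulatoryNetwork, x, beta: float | None = None,
          forcing: np.ndarray | None = None) -> np.ndarray:
    """Deterministic velocity dx/dt = (Q^T p(x) - x + delta) / tau.

    ``forcing`` is an optional length-T constitutive production vector
    (TF overexpression, delta of the reprogramming dynamics).
    """
    x = _check_state(net, x)
    p = enhancer_activities(net, x, beta=beta)
    v = net.coupling.T @ p - x
    if forcing is not None:
        v = v + np.asarray(forcing, dtype=float)
    return v / net.tau


def potential(net: RegulatoryNetwork, x, beta: float | None = None) -> float:
    """Scalar potential V(x); defined only for reciprocal (symmetric) nets.

    ``V(x) = 0.5 ||x||^2 - (nu/beta) logsumexp(beta Xi_zeta x + w)``, so that
    drift = -grad V / tau.  At beta = 0 the analytic limit is used (the
    logsumexp term reduces to the softmax(w)-weighted mean-field term; the
    state-independent constant logsumexp(w)/beta is dropped).
    """
    if not net.symmetric:
        raise ValueError("potential undefined for asymmetric networks")
    x = _check_state(net, x)
    b = net.beta if beta is None else beta
    quad = 0.5 * float(x @ x)
    if b == 0.0:
        p0 = softmax(net.weights)
        return quad - net.nu * float(p0 @ (net.binding_eff @ x))
    s = b * (net.binding_eff @ x) + net.weights
    return quad - net.nu / b * float(logsumexp(s))


def jacobian(net: RegulatoryNetwork, x, beta: float | None = None
             ) -> np.ndarray:
    """Analytic T x T Jacobian of the drift.

    ``J = (beta Q^T (diag(p) - p p^T) Xi_zeta - I) / tau``; symmetric exactly
    when Q is proportional to the gain-scaled binding matrix (reciprocity).
    """
    x = _check_state(net, x)
    b = net.beta if beta is None else beta
    p = enhancer_activities(net, x, beta=beta)
    eff = net.binding_eff
    qp = net.coupling.T * p  # T x E, columns q_i p_i
    core = qp @ eff - np.outer(net.coupling.T @ p, p @ eff)
    return (b * core - np.eye(net.n_tfs)) / net.tau


@dataclass(frozen=True)
class ReciprocityReport:
    is_reciprocal: bool
    max_asymmetry: float
    nu: float


def check_reciprocity(net: RegulatoryNetwork, n_probe_points: int = 20,
                      seed: int = 0) -> ReciprocityReport:
    """Probe Jacobian symmetry at random states.

    Reciprocal TF-TF interactions (symmetric Jacobian everywhere) are
    equivalent to autoregulation, Q = nu * Xi_zeta; the report's flag agrees
    with ``net.symmetric`` by construction of the dynamics.
    """
    rng = np.random.default_rng(seed)
    scale = float(np.max(net.coupling, initial=1.0)) or 1.0
    worst = 0.0
    for _ in range(n_probe_points):
        x = rng.uniform(0.0, scale, size=net.n_tfs)
        J = jacobian(net, x)
        worst = max(worst, float(np.max(np.abs(J - J.T))))
    nu = _fit_nu(net.binding_eff, net.coupling)
    return ReciprocityReport(is_reciprocal=worst < 1e-6,
                             max_asymmetry=worst, nu=nu)


def reduce_to_types(net: RegulatoryNetwork, tol: float = 1e-9
                    ) -> RegulatoryNetwork:
    """Collapse physical enhancers with identical binding into enhancer types.

    Enhancers whose gain-scaled binding rows agree elementwise within ``tol``
    form one type.  Because the softmax is additive over equal scores, the
    merged weight is ``w* = log sum_i exp(w_i)`` and the merged coupling row
    the softmax(w)-weighted mean of the members' rows, which leaves the
    dynamics exactly invariant.  Idempotent.
    """
    eff = net.binding_eff
    groups: list[list[int]] = []
    for i in range(net.n_enhancers):
        for g in groups:
            if np.max(np.abs(eff[i] - eff[g[0]])) <= tol:
                g.append(i)
                break
        else:
            groups.append([i])
    if all(len(g) == 1 for g in groups):
        return net

    rows_b, rows_q, ws, names = [], [], [], []
    for g in groups:
        idx = np.array(g)
        rows_b.append(eff[idx[0]])
        w_star = float(logsumexp(net.weights[idx]))
        shares = softmax(net.weights[idx])
        rows_q.append(shares @ net.coupling[idx])
        ws.append(w_star)
        names.append("+".join(net.enhancer_names[i] for i in g))
    return RegulatoryNetwork(
        tf_names=net.tf_names,
        enhancer_names=tuple(names),
        binding=np.array(rows_b),
        coupling=np.array(rows_q),
        weights=np.array(ws),
        beta=net.beta,
        tau=net.tau,
    )
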