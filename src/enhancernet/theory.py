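"""Closed-form theory of pattern families and temperature transitions.

A *pattern family* models a set of closely related cell types (e.g. neuron
classes sharing most of their TF code): K related patterns share N' always-
active TFs and differ over N variable TFs, of which a fraction eta is active
in each pattern (drawn at random); N'' TFs are always inactive, and K'
unrelated patterns draw their active set uniformly.  All patterns are unit
norm with active level a = 1/sqrt(n_active).

Similarity statistics of the family:

    A = (eta^2 N + N') / (eta N + N')        within-family inner product
    B = (eta N + N') / (N + N' + N'')        cross-family inner product
    C = 1 - 1/(eta N + N')                   pattern vs its two-bit variant

With unit-norm patterns, equal weights and internal similarity A, the
potential of the average of a subset of size n is::

    V(n) = s/2 - (1/beta) ln(n e^{beta s} + (K - n) e^{beta B}),
    s = (1 + (n-1) A) / n

Comparing V across subset sizes gives the temperature thresholds of
hierarchical differentiation: the global family average yields to smaller
subsets around beta_1 = 2 ln K / (1 - A), and a bipotent pair of similarity
c yields to its terminals around beta = 4 ln 2 / (1 - c) (potential
crossing) -- while the *local* (pitchfork) loss of stability of the pair
average happens exactly at beta = 2 / (1 - c).  The specification gain

    chi = 2 ln 2 * N eta (1 - eta) / ln K

is the ratio of the beta needed to individuate a newly evolved two-bit
variant pair to the beta that first destabilizes the family progenitor; it
depends only on the variable TFs and scales with the Bernoulli variance
eta(1 - eta) of the active code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attractors import cosine_distance, refine_fixed_point
from .network import RegulatoryNetwork

__all__ = [
    "PatternFamilyParams",
    "SimilaritySummary",
    "sample_pattern_family",
    "add_two_bit_variant",
    "similarity_stats",
    "empirical_similarity_stats",
    "averaged_pattern_energy",
    "critical_beta_bipotent",
    "specification_gain_chi",
    "two_threshold_scan",
    "family_network",
]


@dataclass(frozen=True)
class PatternFamilyParams:
    """Ensemble parameters (K, K', N, N', N'', eta) of a pattern family."""

    K: int                 # related patterns
    N: int                 # variable TF positions
    eta: float             # active fraction among variable positions
    K_prime: int = 0       # unrelated patterns
    N_prime: int = 0       # always-active positions (shared block)
    N_doubleprime: int = 0  # always-inactive positions
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1 or self.K_prime < 0:
            raise ValueError("need K >= 1 and K' >= 0")
        if min(self.N, self.N_prime, self.N_doubleprime) < 0:
            raise ValueError("position counts must be >= 0")
        if not (0 < self.eta <= 1):
            raise ValueError("eta must be in (0, 1]")
        if self.K >= 2 and round(self.eta * self.N) < 1:
            raise ValueError("eta*N must be >= 1 when K >= 2, otherwise "
                             "related patterns cannot be distinct")

    @property
    def n_active_variable(self) -> int:
        """Active bits among the variable positions (eta N, rounded)."""
        return int(round(self.eta * self.N))

    @property
    def n_tfs(self) -> int:
        return self.N + self.N_prime + self.N_doubleprime

    @property
    def active_level(self) -> float:
        """a = 1/sqrt(n_active): unit-norm rows."""
        return 1.0 / np.sqrt(self.n_active_variable + self.N_prime)


@dataclass(frozen=True)
class SimilaritySummary:
    A: float  # mean within-family inner product
    B: float  # mean cross-family inner product
    C: float | None  # pattern vs two-bit variant (None if not measurable)

    def __post_init__(self) -> None:
        if self.B is not None and self.A is not None:
            if not (-1 - 1e-9 <= self.B <= self.A + 1e-9 <= 1 + 1e-9):
                raise ValueError("require -1 <= B <= A <= 1")


def sample_pattern_family(params: PatternFamilyParams, seed=None,
                          max_retries: int = 100):
    """Draw the family's pattern matrix (rows unit norm) and labels.

    Related rows share the N' active block and draw their eta*N active
    variable positions uniformly; unrelated rows draw their full active set
    uniformly over all positions.  Duplicate rows are redrawn (bounded
    retries); an infeasible request raises.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n_act = params.n_active_variable
    a = params.active_level
    T = params.n_tfs
    from math import comb
    if params.K > comb(params.N, n_act):
        raise ValueError(
            f"cannot draw {params.K} distinct related patterns: only "
            f"{comb(params.N, n_act)} distinct active sets exist")

    rows, labels = [], []
    seen: set = set()
    for k in range(params.K):
        for _ in range(max_retries):
            pos = tuple(sorted(rng.choice(params.N, size=n_act,
                                          replace=False)))
            if pos not in seen:
                seen.add(pos)
                break
        else:
            raise RuntimeError("failed to draw a distinct related pattern")
        row = np.zeros(T)
        row[list(pos)] = a
        row[params.N:params.N + params.N_prime] = a
        rows.append(row)
        labels.append(f"related:{k}")
    n_act_unrel = n_act + params.N_prime
    seen_u: set = set()
    for k in range(params.K_prime):
        for _ in range(max_retries):
            pos = tuple(sorted(rng.choice(T, size=n_act_unrel,
                                          replace=False)))
            if pos not in seen_u:
                seen_u.add(pos)
                break
        else:
            raise RuntimeError("failed to draw a distinct unrelated pattern")
        row = np.zeros(T)
        row[list(pos)] = a
        rows.append(row)
        labels.append(f"unrelated:{k}")
    return np.array(rows), labels


def add_two_bit_variant(xi: np.ndarray, row_index: int, seed: int = 0):
    """Append an evolved sister pattern differing from ``xi[row_index]`` by
    two bits (one active position moved), modelling genetic individuation.

    Returns (augmented matrix, index of the new row)."""
    rng = np.random.default_rng(seed)
    row = xi[row_index].copy()
    active = np.flatnonzero(row > 0)
    inactive = np.flatnonzero(row == 0)
    if active.size == 0 or inactive.size == 0:
        raise ValueError("row must have both active and inactive positions")
    off = rng.choice(active)
    on = rng.choice(inactive)
    row[off] = 0.0
    row[on] = xi[row_index][off]
    return np.vstack([xi, row]), xi.shape[0]


def similarity_stats(params: PatternFamilyParams) -> SimilaritySummary:
    """Analytic (A, B, C) for the ensemble."""
    num = params.eta ** 2 * params.N + params.N_prime
    den = params.eta * params.N + params.N_prime
    A = num / den
    B = den / params.n_tfs if params.n_tfs > 0 else 0.0
    C = 1.0 - 1.0 / den
    return SimilaritySummary(A=A, B=B, C=C)


def empirical_similarity_stats(xi: np.ndarray, labels) -> SimilaritySummary:
    """Measured (A, B, C) from a sampled family.

    C is the inner product between a row labelled ``variant:<k>`` (or the
    last row, if a variant was appended without labels) and its source; it
    is None when no variant pair is identifiable."""
    labels = list(labels)
    rel = [i for i, l in enumerate(labels) if l.startswith("related")]
    unrel = [i for i, l in enumerate(labels) if l.startswith("unrelated")]
    G = xi @ xi.T
    A_vals = ([G[rel[i], rel[j]]
               for i, j in zip(*np.triu_indices(len(rel), k=1))]
              if len(rel) > 1 else [])
    B_vals = [G[i, j] for i in rel for j in unrel]
    C = None
    var = [(i, l) for i, l in enumerate(labels) if l.startswith("variant:")]
    if var:
        i, l = var[0]
        src = int(l.split(":", 1)[1])
        C = float(G[src, i])
    A = float(np.mean(A_vals)) if A_vals else 1.0
    B = float(np.mean(B_vals)) if B_vals else 0.0
    return SimilaritySummary(A=A, B=min(B, A), C=C)


def averaged_pattern_energy(A: float, B: float, subset_size: int,
                            beta: float, K: int) -> float:
    """Potential of the average of ``subset_size`` unit-norm patterns with
    internal similarity A, similarity B to the other K - n patterns.

    ``V = s/2 - (1/beta) ln(n e^{beta s} + (K-n) e^{beta B})`` with
    ``s = (1 + (n-1)A)/n``; reduces to the single-pattern energy at n = 1.
    Log-sum-exp is evaluated stably for large beta."""
    n = int(subset_size)
    if n < 1 or n > K:
        raise ValueError("need 1 <= subset_size <= K")
    if abs(A) > 1 or abs(B) > 1:
        raise ValueError("similarities must lie in [-1, 1]")
    if beta <= 0:
        raise ValueError("beta must be > 0")
    s = (1.0 + (n - 1) * A) / n
    terms = np.array([beta * s + np.log(n)]
                     + ([beta * B + np.log(K - n)] if K > n else []))
    m = terms.max()
    lse = m + np.log(np.sum(np.exp(terms - m)))
    return 0.5 * s - lse / beta


def critical_beta_bipotent(pair_cosine: float,
                           criterion: str = "pitchfork") -> float:
    """Critical beta at which a bipotent progenitor yields to its terminals.

    For two unit-norm patterns of cosine similarity c, the pair average
    loses *local* stability at exactly ``beta = 2/(1 - c)`` (a pitchfork
    along the difference direction; ``criterion="pitchfork"``, the value the
    numerical bifurcation scan measures).  The rough potential-crossing
    estimate, where the terminal pattern's energy first drops below the
    average's, is ``beta = 4 ln 2 / (1 - c)`` (``criterion="potential"``;
    this is the form entering the specification-gain ratio).  Diverges for
    an identical pair (c -> 1)."""
    if not (-1.0 <= pair_cosine <= 1.0):
        raise ValueError("cosine similarity must lie in [-1, 1]")
    if pair_cosine >= 1.0:
        return np.inf
    if criterion == "pitchfork":
        return 2.0 / (1.0 - pair_cosine)
    if criterion == "potential":
        return 4.0 * np.log(2.0) / (1.0 - pair_cosine)
    raise ValueError(f"unknown criterion {criterion!r}")


def specification_gain_chi(params: PatternFamilyParams) -> float:
    """Relative increase in beta needed to evolve a new cell type.

    ``chi = 2 ln 2 * N eta (1 - eta) / ln K``: the ratio between the beta
    that individuates a two-bit variant pair (4 ln 2/(1 - C)) and the beta
    that first destabilizes the family progenitor (2 ln K/(1 - A)).  The
    shared block N' cancels: chi depends only on the variable TFs, through
    the variance eta(1 - eta) of the active code."""
    if params.K < 2:
        raise ValueError("chi requires at least two related patterns")
    return (2.0 * np.log(2.0) * params.N * params.eta * (1.0 - params.eta)
            / np.log(params.K))


# ---------------------------------------------------------------------------
# numerical two-threshold measurement


def family_network(xi: np.ndarray, beta: float = 1.0) -> RegulatoryNetwork:
    """Symmetric network whose enhancer types are the family patterns."""
    E, T = xi.shape
    return RegulatoryNetwork(
        tf_names=tuple(f"TF{j}" for j in range(T)),
        enhancer_names=tuple(f"P{i}" for i in range(E)),
        binding=xi, coupling=xi, weights=np.zeros(E), beta=beta)


def _candidate_states(xi: np.ndarray):
    """Progenitor candidates: all pair averages plus dendrogram-cut cluster
    averages (progenitors arise only for high-internal-similarity subsets,
    so the 2^K subset lattice is never enumerated)."""
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import pdist

    K = xi.shape[0]
    states = []
    ii, jj = np.triu_indices(K, k=1)
    states.append(0.5 * (xi[ii] + xi[jj]))          # all pair averages
    if K > 3:
        Z = linkage(pdist(xi, metric="cosine"), method="average")
        clusters = []
        for k in range(2, min(K, 40)):
            labels = fcluster(Z, k, criterion="maxclust")
            for c in np.unique(labels):
                members = np.flatnonzero(labels == c)
                if 2 < len(members) < K:
                    clusters.append(xi[members].mean(axis=0))
        if clusters:
            states.append(np.array(clusters))
    return np.vstack(states)


def _potentials(xi: np.ndarray, states: np.ndarray, beta: float
                ) -> np.ndarray:
    """V(x) = ||x||^2/2 - logsumexp(beta Xi x)/beta for each row of states."""
    s = beta * (states @ xi.T)
    m = s.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(s - m).sum(axis=1))
    return 0.5 * np.einsum("ij,ij->i", states, states) - lse / beta


def _average_is_ground_state(xi, x_avg, candidates, beta) -> bool:
    v_avg = _potentials(xi, x_avg[None, :], beta)[0]
    v_single = _potentials(xi, xi, beta).min()
    v_sub = _potentials(xi, candidates, beta).min()
    return bool(v_avg <= min(v_single, v_sub) + 1e-12)


def _all_patterns_specified(net, xi, beta, match_cos=0.05):
    """Every pattern is a distinct stable fixed point *and* energetically
    individuated: its potential lies below that of every containing pair
    average (so committed states, not pair progenitors, are favoured)."""
    K = xi.shape[0]
    v_single = _potentials(xi, xi, beta)
    ii, jj = np.triu_indices(K, k=1)
    v_pairs = _potentials(xi, 0.5 * (xi[ii] + xi[jj]), beta)
    worst = np.full(K, -np.inf)
    for i, j, v in zip(ii, jj, v_pairs):
        worst[i] = max(worst[i], -v)
        worst[j] = max(worst[j], -v)
    if np.any(v_single >= -worst):       # some pair average still beats a pattern
        return False
    points = []
    for row in xi:
        fp = refine_fixed_point(net, row, beta=beta, label_tol=np.inf)
        if not (fp.converged and fp.stable):
            return False
        if cosine_distance(fp.x, row) > match_cos:
            return False
        points.append(fp.x)
    pts = np.array(points)
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return bool(d.min() > 1e-3)


def two_threshold_scan(xi: np.ndarray, beta_grid, match_cos: float = 0.05,
                       rel_precision: float = 5e-3) -> dict:
    """Measure the two temperature thresholds of a pattern family.

    ``beta_destabilize``: smallest beta at which the global family average
    stops being the potential minimum among the candidate states (patterns,
    pair averages, dendrogram cluster averages) -- the point where slow
    annealing first leaves the multipotent progenitor.  The average can
    remain *locally* stable well beyond this beta (metastability), so local
    eigenvalue tests are deliberately not used here.

    ``beta_full_specification``: smallest beta at which every pattern is a
    distinct stable fixed point and is energetically favoured over every
    containing pair average -- i.e. even the most similar sister pair is
    individuated.  Both thresholds are refined by bisection on the grid.
    """
    beta_grid = np.sort(np.asarray(beta_grid, dtype=float))
    net = family_network(xi)
    x_avg = xi.mean(axis=0)
    candidates = _candidate_states(xi)

    def ground(b):
        return _average_is_ground_state(xi, x_avg, candidates, b)

    if not ground(beta_grid[0]):
        raise RuntimeError("global average is not the ground state at the "
                           "bottom of the beta grid; extend it downward")
    flags = [ground(b) for b in beta_grid]
    if all(flags):
        raise RuntimeError("global average still the ground state at the "
                           "top of the beta grid; extend it upward")
    k = int(np.argmin(flags))  # first False
    lo, hi = beta_grid[k - 1], beta_grid[k]
    while (hi - lo) > rel_precision * hi:
        mid = 0.5 * (lo + hi)
        if ground(mid):
            lo = mid
        else:
            hi = mid
    beta_destab = 0.5 * (lo + hi)

    def spec(b):
        return _all_patterns_specified(net, xi, b, match_cos)

    lo, hi = beta_destab, None
    for b in beta_grid:
        if b <= beta_destab:
            continue
        if spec(b):
            hi = b
            break
        lo = b
    if hi is None:
        raise RuntimeError("patterns never fully specified on the beta grid;"
                           " extend the grid upward")
    while (hi - lo) > rel_precision * hi:
        mid = 0.5 * (lo + hi)
        if spec(mid):
            hi = mid
        else:
            lo = mid
    beta_full = max(0.5 * (lo + hi), beta_destab)
    return {"beta_destabilize": float(beta_destab),
            "beta_full_specification": float(beta_full),
            "ratio": float(beta_full / beta_destab)}
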