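"""Fixed points of the identity dynamics and their beta-dependence.

Cell types are stable fixed points.  At high beta these sit at the rows of
the coupling matrix (terminal identities); at low and intermediate beta,
averages of high-similarity subsets of rows are (meta)stable and play the
role of multipotent/bipotent progenitors.  This module finds fixed points
(Newton polish of candidates, restart sweeps), classifies their stability
from the analytic Jacobian, labels them against patterns and subset
averages, and scans stability intervals along a beta grid.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import root
from scipy.spatial.distance import pdist

from .dynamics import simulate
from .network import RegulatoryNetwork, drift, jacobian

__all__ = [
    "FixedPoint",
    "AttractorSet",
    "refine_fixed_point",
    "enumerate_attractors",
    "pattern_stability_report",
    "subset_average_stability",
    "bifurcation_scan_beta",
    "candidate_subsets",
    "label_state",
    "cosine_distance",
]

STABILITY_EIG_TOL = 1e-8     # strict margin on the leading real part
DEDUP_DISTANCE = 1e-3        # Euclidean, expression space
LABEL_COSINE_TOL = 1e-3      # scale-free identity matching


def cosine_distance(a, b) -> float:
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 1.0
    return float(1.0 - a @ b / (na * nb))


@dataclass(frozen=True)
class FixedPoint:
    x: np.ndarray
    residual: float                     # ||drift||
    leading_eigenvalue_real_part: float
    stability: str                      # "stable" | "unstable" | "marginal"
    label: str
    converged: bool = True

    @property
    def stable(self) -> bool:
        return self.stability == "stable"


@dataclass
class AttractorSet:
    points: list
    beta: float
    dedup_tolerance: float = DEDUP_DISTANCE

    def __iter__(self):
        return iter(self.points)

    def __len__(self):
        return len(self.points)

    @property
    def labels(self):
        return [fp.label for fp in self.points]


def candidate_subsets(net: RegulatoryNetwork, max_pair_size: int = 2):
    """Subsets whose row averages are plausible progenitors.

    All singletons and pairs, the full set, plus the subsets produced by
    cutting the cosine-similarity dendrogram of the patterns at every merge
    height -- progenitors are predicted only for high-internal-similarity
    subsets, so the exponential set of all subsets is never enumerated.
    """
    E = net.n_enhancers
    subsets = [frozenset([i]) for i in range(E)]
    subsets += [frozenset(c) for c in itertools.combinations(range(E), 2)]
    subsets.append(frozenset(range(E)))
    if E > 2:
        pats = net.patterns
        norms = np.linalg.norm(pats, axis=1)
        ok = norms > 0
        if ok.sum() > 2:
            d = pdist(pats[ok], metric="cosine")
            Z = linkage(d, method="average")
            for k in range(2, ok.sum()):
                labels = fcluster(Z, k, criterion="maxclust")
                for c in np.unique(labels):
                    members = frozenset(np.where(ok)[0][labels == c])
                    if len(members) > 1:
                        subsets.append(members)
    return sorted(set(subsets), key=lambda s: (len(s), sorted(s)))


def subset_average_state(net: RegulatoryNetwork, subset) -> np.ndarray:
    idx = sorted(subset)
    return net.patterns[idx].mean(axis=0)


def label_state(net: RegulatoryNetwork, x, tol: float = LABEL_COSINE_TOL,
                subsets=None) -> tuple[str, float]:
    """Identity label of a state: nearest pattern or subset average.

    Returns ``("pattern:<name>", d)`` / ``("average:<names>", d)`` within
    cosine distance ``tol``, else ``("other", d_best)``.
    """
    best_label, best_d = "other", np.inf
    for k, row in enumerate(net.patterns):
        d = cosine_distance(x, row)
        if d < best_d:
            best_label, best_d = f"pattern:{net.enhancer_names[k]}", d
    if subsets is None:
        subsets = [s for s in candidate_subsets(net) if len(s) > 1]
    for s in subsets:
        if len(s) < 2:
            continue
        d = cosine_distance(x, subset_average_state(net, s))
        if d < best_d - 1e-12:  # exact pattern matches take precedence
            names = ",".join(sorted(net.enhancer_names[i] for i in s))
            best_label, best_d = f"average:{names}", d
    if best_d <= tol:
        return best_label, best_d
    return "other", best_d


def refine_fixed_point(net: RegulatoryNetwork, x0, beta: float | None = None,
                       tol: float = 1e-12, label_tol: float = LABEL_COSINE_TOL,
                       subsets=None) -> FixedPoint:
    """Newton polish of a candidate fixed point, with stability from the
    analytic Jacobian.  Non-convergence is flagged, never silent."""
    x0 = np.asarray(x0, dtype=float).ravel()
    if np.any(x0 < -1e-8):
        raise ValueError("x0 must be nonnegative")
    x0 = np.clip(x0, 0.0, None)
    b = net.beta if beta is None else float(beta)
    tau = net.tau

    def F(x):
        return drift(net, x, beta=b) * tau

    def J(x):
        return jacobian(net, x, beta=b) * tau

    sol = root(F, x0, jac=J, method="hybr", tol=tol)
    x = sol.x
    res = float(np.linalg.norm(drift(net, x, beta=b)))
    # the residual is the criterion: hybr can report failure on flat
    # landscapes even when the root is found to machine precision
    converged = res < 1e-10 and bool(np.all(x > -1e-9))
    x = np.clip(x, 0.0, None)
    lead = float(np.max(np.real(np.linalg.eigvals(jacobian(net, x, beta=b)))))
    if lead < -STABILITY_EIG_TOL:
        stability = "stable"
    elif lead > STABILITY_EIG_TOL:
        stability = "unstable"
    else:
        stability = "marginal"
    label, _ = label_state(net, x, tol=label_tol, subsets=subsets)
    return FixedPoint(x=x, residual=res,
                      leading_eigenvalue_real_part=lead,
                      stability=stability, label=label, converged=converged)


def _converge(net, x0, beta, t_max=200.0, settle_tol=1e-9):
    """Integrate towards an attractor, in chunks, until the flow settles."""
    x = np.asarray(x0, float)
    t_chunk = 25.0 * net.tau
    total = 0.0
    while total < t_max:
        traj = simulate(net.with_beta(beta), x, (0.0, t_chunk),
                        sample_dt=t_chunk)
        x = traj.final_state
        total += t_chunk
        if np.linalg.norm(drift(net, x, beta=beta)) < settle_tol:
            break
    return x


def enumerate_attractors(net: RegulatoryNetwork, n_random_restarts: int = 20,
                         perturbation_scale: float = 0.25, seed: int = 0,
                         beta: float | None = None,
                         n_noisy_per_pattern: int = 2) -> AttractorSet:
    """Sweep initial conditions and collect the distinct stable attractors.

    Seeds: every pattern row, rows under multiplicative noise of the stated
    scale (default 25%), and uniform random states.  Each seed is integrated
    to convergence, Newton-polished, classified, and deduplicated by
    Euclidean distance.
    """
    b = net.beta if beta is None else float(beta)
    rng = np.random.default_rng(seed)
    pats = net.patterns
    scale = float(np.max(pats, initial=1.0)) or 1.0
    seeds = [row.copy() for row in pats]
    for row in pats:
        for _ in range(n_noisy_per_pattern):
            seeds.append(np.clip(
                row * (1 + perturbation_scale * rng.standard_normal(row.size)),
                0.0, None))
    for _ in range(n_random_restarts):
        seeds.append(rng.uniform(0.0, scale, size=net.n_tfs))

    subsets = [s for s in candidate_subsets(net) if len(s) > 1]
    found: list[FixedPoint] = []
    for x0 in seeds:
        x = _converge(net, x0, b)
        fp = refine_fixed_point(net, x, beta=b, subsets=subsets)
        if not fp.converged or not fp.stable:
            continue
        if any(np.linalg.norm(fp.x - g.x) < DEDUP_DISTANCE for g in found):
            continue
        found.append(fp)
    return AttractorSet(points=found, beta=b)


@dataclass(frozen=True)
class PatternReport:
    enhancer_name: str
    is_fixed_point: bool
    is_stable: bool
    cosine_condition_ok: bool
    residual: float


def pattern_stability_report(net: RegulatoryNetwork,
                             beta: float | None = None) -> list:
    """Per-pattern check: is each coupling row a stable fixed point, and does
    its binding profile win its own softmax competition?

    The alignment condition generalises the symmetric case: at state q_k the
    gain-scaled binding score must be maximal for enhancer k itself; a
    pattern dominated by a similar competitor with larger overall binding
    affinity stays unstable at every beta.
    """
    b = net.beta if beta is None else float(beta)
    reports = []
    eff = net.binding_eff
    for k, row in enumerate(net.patterns):
        scores = eff @ row
        cond = bool(np.argmax(scores) == k
                    and scores[k] > np.max(np.delete(scores, k), initial=-np.inf))
        fp = refine_fixed_point(net, row, beta=b)
        # magnitude-aware: a weak twin refining onto its stronger copy's
        # state has zero cosine distance but is not a fixed point at x=q_k
        near = (np.linalg.norm(fp.x - row)
                <= 0.05 * max(np.linalg.norm(row), 1e-12))
        reports.append(PatternReport(
            enhancer_name=net.enhancer_names[k],
            is_fixed_point=bool(fp.converged and near),
            is_stable=bool(fp.converged and near and fp.stable),
            cosine_condition_ok=cond,
            residual=fp.residual))
    return reports


def subset_average_stability(net: RegulatoryNetwork, subset, beta,
                             match_tol: float = LABEL_COSINE_TOL) -> dict:
    """Test the average of a subset's rows as a fixed point at ``beta``.

    ``is_fixed_point`` requires Newton convergence *near* the candidate
    (within cosine distance ``match_tol``) -- a refinement that jumps to a
    different state does not count.
    """
    subset = frozenset(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    x0 = subset_average_state(net, subset)
    fp = refine_fixed_point(net, x0, beta=beta)
    d = cosine_distance(fp.x, x0)
    is_fp = bool(fp.converged and d <= match_tol)
    return {"is_fixed_point": is_fp,
            "is_stable": bool(is_fp and fp.stable),
            "fixed_point": fp,
            "cosine_distance": d}


def _stable_at(net, subset, beta, match_tol):
    r = subset_average_stability(net, subset, beta, match_tol=match_tol)
    return r["is_stable"]


def bifurcation_scan_beta(net: RegulatoryNetwork, candidates, beta_grid,
                          match_tol: float = 1e-2,
                          rel_precision: float = 1e-3) -> list:
    """Stability interval in beta for each candidate subset average.

    ``candidates``: iterable of index subsets (singletons are patterns).
    For each, the grid is scanned and interval endpoints are refined by
    bisection to the requested relative precision.  Returns a list of
    ``{"label", "subset", "beta_stable_from", "beta_stable_to"}`` records
    (NaN endpoints when never stable on the grid).
    """
    beta_grid = np.asarray(beta_grid, dtype=float)
    if np.any(np.diff(beta_grid) <= 0):
        raise ValueError("beta_grid must be increasing")
    out = []
    for subset in candidates:
        subset = frozenset(subset)
        names = ",".join(sorted(net.enhancer_names[i] for i in subset))
        kind = "pattern" if len(subset) == 1 else "average"
        flags = np.array([_stable_at(net, subset, b, match_tol)
                          for b in beta_grid])
        if not flags.any():
            out.append({"label": f"{kind}:{names}", "subset": subset,
                        "beta_stable_from": np.nan,
                        "beta_stable_to": np.nan})
            continue
        i0 = int(np.argmax(flags))
        i1 = len(flags) - 1 - int(np.argmax(flags[::-1]))
        lo = beta_grid[i0]
        if i0 > 0:
            lo = _bisect_edge(net, subset, beta_grid[i0 - 1], beta_grid[i0],
                              match_tol, rel_precision, rising=True)
        hi = beta_grid[i1]
        if i1 < len(flags) - 1:
            hi = _bisect_edge(net, subset, beta_grid[i1], beta_grid[i1 + 1],
                              match_tol, rel_precision, rising=False)
        out.append({"label": f"{kind}:{names}", "subset": subset,
                    "beta_stable_from": float(lo),
                    "beta_stable_to": float(hi)})
    return out


def _bisect_edge(net, subset, b_lo, b_hi, match_tol, rel_precision, rising):
    # rising: unstable at b_lo, stable at b_hi (onset); else offset
    while (b_hi - b_lo) > rel_precision * max(abs(b_hi), 1e-12):
        mid = 0.5 * (b_lo + b_hi)
        s = _stable_at(net, subset, mid, match_tol)
        if s == rising:
            b_hi = mid
        else:
            b_lo = mid
    return 0.5 * (b_lo + b_hi) if rising else 0.5 * (b_lo + b_hi)
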