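"""Hierarchical differentiation by annealing of the inverse temperature.

Annealing transiently lowers beta (destabilising terminal identities in
favour of the global progenitor) and then raises it slowly; on the way up
the state passes through a Waddingtonian cascade of metastable progenitors
-- averages of ever smaller, internally similar subsets of terminal
patterns -- before committing to one terminal identity.  Signalling (the
weight vector w) biases which identity wins; a negative-feedback update of
w across repeated annealing runs produces balanced production of all
lineages, mimicking in vivo feedback on differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist

from .attractors import candidate_subsets, cosine_distance, label_state
from .dynamics import NoiseSpec, Trajectory, simulate
from .network import RegulatoryNetwork, drift

__all__ = [
    "AnnealingSchedule",
    "PlateauEvent",
    "LineageTree",
    "anneal",
    "detect_plateaus",
    "assign_identity",
    "balanced_differentiation",
    "BalancedDifferentiationResult",
    "lineage_tree",
    "tree_to_newick",
]


@dataclass(frozen=True)
class AnnealingSchedule:
    """beta(t): an optional hold at beta_start (pre-drop) followed either by
    a linear ramp from beta_start to beta_end over ``duration`` time units,
    or -- when ``levels`` is given -- by a staircase that holds each level
    for duration/len(levels).

    The staircase is the quasi-adiabatic schedule: at each hold the state
    relaxes onto the current attractor (progenitor), so plateau dwell
    speeds drop to integration accuracy instead of being limited by the
    ramp rate.
    """

    beta_start: float = 0.0
    beta_end: float = 50.0
    duration: float = 50.0
    pre_drop: float = 0.0   # hold time at beta_start before the ramp
    levels: tuple | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.beta_start < 0 or self.beta_end < 0 or self.pre_drop < 0:
            raise ValueError("beta values and pre_drop must be >= 0")
        if self.levels is not None:
            levels = tuple(float(b) for b in self.levels)
            if not levels or any(b < 0 for b in levels):
                raise ValueError("levels must be non-empty and >= 0")
            object.__setattr__(self, "levels", levels)
            object.__setattr__(self, "beta_end", levels[-1])

    @property
    def total_time(self) -> float:
        return self.pre_drop + self.duration

    def __call__(self, t: float) -> float:
        if t <= self.pre_drop:
            return (self.beta_start if self.levels is None
                    else self.levels[0])
        u = min(max((t - self.pre_drop) / self.duration, 0.0), 1.0)
        if self.levels is None:
            return self.beta_start + u * (self.beta_end - self.beta_start)
        k = min(int(u * len(self.levels)), len(self.levels) - 1)
        return self.levels[k]


@dataclass(frozen=True)
class PlateauEvent:
    t_start: float
    t_end: float
    state: np.ndarray
    label: str
    cosine_distance: float

    @property
    def dwell(self) -> float:
        return self.t_end - self.t_start


def anneal(net: RegulatoryNetwork, x0, schedule: AnnealingSchedule,
           noise: NoiseSpec | None = None, relax_time: float = 20.0,
           sample_dt: float = 0.05) -> Trajectory:
    """Simulate an annealing run, then relax deterministically at beta_end.

    The ramp phase carries the noise (lineage choice is noise-driven); the
    terminal relaxation (default 20 tau) runs without noise so the final
    state settles onto the committed attractor.
    """
    ramp = simulate(net, x0, (0.0, schedule.total_time),
                    beta_schedule=schedule, noise=noise, sample_dt=sample_dt)
    relax = simulate(net, ramp.final_state, (0.0, relax_time),
                     beta_schedule=lambda t: schedule.beta_end,
                     sample_dt=sample_dt)
    return ramp.concatenate(relax)


def detect_plateaus(traj: Trajectory, net: RegulatoryNetwork,
                    min_dwell: float | None = None,
                    speed_threshold: float | None = None) -> list:
    """Progenitor plateaus: maximal intervals of slow flow, excluding the
    terminal interval, labelled by the nearest pattern or subset average.

    Speed is ``||dx/dt||`` evaluated with the instantaneous beta.  Defaults:
    speed_threshold = 1e-3 * (mean pattern norm)/tau, min_dwell = 2 tau.
    """
    if len(traj.times) == 0:
        raise ValueError("empty trajectory")
    if min_dwell is None:
        min_dwell = 2.0 * net.tau
    if speed_threshold is None:
        typ = float(np.mean(np.linalg.norm(net.patterns, axis=1)))
        speed_threshold = 1e-3 * typ / net.tau

    speeds = np.array([np.linalg.norm(drift(net, x, beta=b))
                       for x, b in zip(traj.states, traj.beta_values)])
    slow = speeds < speed_threshold

    subsets = [s for s in candidate_subsets(net) if len(s) > 1]
    raw = []
    i, n = 0, len(slow)
    while i < n:
        if not slow[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and slow[j + 1]:
            j += 1
        mid = (i + j) // 2
        x = traj.states[mid]
        label, d = label_state(net, x, tol=np.inf, subsets=subsets)
        raw.append(PlateauEvent(t_start=float(traj.times[i]),
                                t_end=float(traj.times[j]),
                                state=x.copy(), label=label,
                                cosine_distance=float(d)))
        i = j + 1

    # consecutive slow intervals at the same identity are one plateau
    # (a staircase schedule produces a brief speed blip at every level)
    merged: list[PlateauEvent] = []
    for ev in raw:
        if merged and merged[-1].label == ev.label:
            prev = merged[-1]
            keep = prev if prev.dwell >= ev.dwell else ev
            merged[-1] = PlateauEvent(t_start=prev.t_start, t_end=ev.t_end,
                                      state=keep.state, label=keep.label,
                                      cosine_distance=keep.cosine_distance)
        else:
            merged.append(ev)
    # the interval holding the final state is terminal, not a progenitor
    if merged and merged[-1].t_end >= traj.times[-1] - 1e-9:
        merged.pop()
    return [ev for ev in merged if ev.dwell >= min_dwell]


def assign_identity(net: RegulatoryNetwork, x) -> tuple[str, float, bool]:
    """Nearest pattern by cosine distance: (name, distance, tie_flag).

    Ties (within 1e-12) break to the lowest row index and are flagged."""
    x = np.asarray(x, dtype=float)
    d = np.array([cosine_distance(x, row) for row in net.patterns])
    k = int(np.argmin(d))
    tie = bool(np.sum(d <= d[k] + 1e-12) > 1)
    return net.enhancer_names[k], float(d[k]), tie


@dataclass
class BalancedDifferentiationResult:
    counts: dict
    final_weights: np.ndarray
    uncommitted: int
    trajectories: list = field(default_factory=list)


def balanced_differentiation(net: RegulatoryNetwork, k_max: int,
                             schedule: AnnealingSchedule | None = None,
                             sigma: float = 0.01, seed: int = 0,
                             commit_tol: float = 0.1,
                             keep_trajectories: bool = False
                             ) -> BalancedDifferentiationResult:
    """Repeated annealing with negative feedback on the signalling weights.

    Starting from w = 0 and the average of all terminal states, run k_max
    annealing differentiations; after run k ending in lineage i, update
    ``w_i <- w_i - 0.5 (1 - k/k_max)`` and re-centre w to mean zero.  Only
    w changes across runs -- signalling controls production without
    touching the identities (Xi, Q).  Runs that fail to commit to any
    pattern (cosine distance > commit_tol) count as "uncommitted".
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if schedule is None:
        schedule = AnnealingSchedule(beta_start=0.0, beta_end=50.0,
                                     duration=50.0)
    rng = np.random.default_rng(seed)
    w = np.zeros(net.n_enhancers)
    counts = {name: 0 for name in net.enhancer_names}
    uncommitted = 0
    trajs = []
    x0 = net.patterns.mean(axis=0)
    for k in range(k_max):
        run_net = net.with_weights(w)
        noise = (NoiseSpec(sigma=sigma, seed=int(rng.integers(2 ** 31)))
                 if sigma > 0 else None)
        traj = anneal(run_net, x0, schedule, noise=noise, sample_dt=0.25)
        if keep_trajectories:
            trajs.append(traj)
        name, d, _ = assign_identity(run_net, traj.final_state)
        if d > commit_tol:
            uncommitted += 1
            continue
        counts[name] += 1
        i = net.enhancer_names.index(name)
        w[i] -= 0.5 * (1.0 - k / k_max)
        w = w - w.mean()
    return BalancedDifferentiationResult(counts=counts, final_weights=w,
                                         uncommitted=uncommitted,
                                         trajectories=trajs)


# ---------------------------------------------------------------------------
# lineage trees from terminal profiles


@dataclass
class LineageTree:
    """Binary merge tree over terminal cell types (cosine-distance heights).

    Thin wrapper over a scipy linkage matrix with the leaf labels attached.
    """

    labels: list
    linkage_matrix: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def lineage_tree(profiles: dict, method: str = "average") -> LineageTree:
    """Agglomerative clustering of terminal expression profiles by cosine
    distance (average linkage by default; "complete" also supported).

    Deterministic given the profiles: labels are sorted before clustering.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    if method not in ("average", "complete"):
        raise ValueError("method must be 'average' or 'complete'")
    labels = sorted(profiles)
    X = np.array([np.asarray(profiles[l], dtype=float) for l in labels])
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        bad = labels[int(np.argmax(norms == 0))]
        raise ValueError(f"zero-norm profile: {bad!r}")
    d = np.clip(pdist(X, metric="cosine"), 0.0, None)
    Z = linkage(d, method=method)
    return LineageTree(labels=labels, linkage_matrix=Z)


def tree_to_newick(tree: LineageTree) -> str:
    """Newick text with merge heights as branch lengths."""
    root = to_tree(tree.linkage_matrix)

    def walk(node, parent_height):
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{tree.labels[node.id]}:{length:.10g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    body = f"({walk(root.left, root.dist)},{walk(root.right, root.dist)})"
    return body + ";"
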