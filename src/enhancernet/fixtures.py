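"""Seeded generators for the toy networks and synthetic datasets.

Everything here is reproducible bit-for-bit from its arguments; no file is
read.  The synthetic expression matrices emulate cell-type-averaged count
data (sparse cell-type-specific TF blocks, shared housekeeping genes,
lognormal measurement noise) at desk scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .network import RegulatoryNetwork
from .theory import PatternFamilyParams

__all__ = [
    "chained_pairs_network",
    "chained_pairs_annealing_schedule",
    "shadow_enhancer_network",
    "individuation_initial_states",
    "individuation_attractor_census",
    "fixture_celegans_family",
    "orthogonal_pattern_network",
    "synthetic_expression_matrix",
    "nested_block_profiles",
]

#: which TFs each enhancer type of the chained toy network binds
#: (pairs (EN1,EN2), (EN3,EN4), (EN5,EN6) overlap by exactly one TF)
CHAINED_PAIRS_LAYOUT = {
    "EN1": ("TF1", "TF2"),
    "EN2": ("TF2", "TF3"),
    "EN3": ("TF4", "TF5"),
    "EN4": ("TF5", "TF6"),
    "EN5": ("TF7", "TF8"),
    "EN6": ("TF8", "TF9"),
}


def chained_pairs_network(induced_weight: float = 0.05, beta: float = 50.0):
    """Chained 9-TF / 6-enhancer-type toy network for annealing demos.

    Each enhancer binds exactly two TFs; the pairs (1,2), (3,4), (5,6)
    overlap by a single TF, so each pair forms a family with internal
    cosine similarity 1/2 and zero similarity across families.  EN5
    carries a slight positive weight (signalling induction of that fate).
    Returns (network, metadata)."""
    tf_names = tuple(f"TF{i}" for i in range(1, 10))
    enh_names = tuple(CHAINED_PAIRS_LAYOUT)
    binding = np.zeros((6, 9))
    for i, en in enumerate(enh_names):
        for tf in CHAINED_PAIRS_LAYOUT[en]:
            binding[i, tf_names.index(tf)] = 1.0
    binding /= np.linalg.norm(binding, axis=1, keepdims=True)
    w = np.zeros(6)
    w[enh_names.index("EN5")] = induced_weight
    net = RegulatoryNetwork(tf_names=tf_names, enhancer_names=enh_names,
                            binding=binding, coupling=binding.copy(),
                            weights=w, beta=beta)
    meta = {"layout": {k: list(v) for k, v in CHAINED_PAIRS_LAYOUT.items()},
            "induced_enhancer": "EN5", "induced_weight": induced_weight}
    return net, meta


#: staircase levels for quasi-adiabatic annealing of the chained toy
#: network; the pair-progenitor stability window for cosine-1/2 pairs is
#: beta in about (4.0, 4.35), hence the finer steps around beta = 4
CHAINED_PAIRS_ANNEAL_LEVELS = (0.0, 1.0, 2.0, 3.0, 3.6, 4.2, 4.8, 5.6, 7.0, 9.0,
                       12.0, 17.0, 24.0, 30.0)


def chained_pairs_annealing_schedule(hold_time: float = 60.0):
    """Quasi-adiabatic staircase schedule for the chained toy network.

    At each hold the state relaxes fully onto the current progenitor, so
    the two-progenitor cascade (global average, then the induced pair
    average) is resolved independently of plateau-detection thresholds."""
    from .differentiation import AnnealingSchedule
    return AnnealingSchedule(levels=CHAINED_PAIRS_ANNEAL_LEVELS,
                             duration=hold_time * len(CHAINED_PAIRS_ANNEAL_LEVELS))


# ---------------------------------------------------------------------------
# evolution of a new cell type through shadow enhancers (physical Q != Xi)

_INDIVIDUATION_STAGES = ("ancestral", "mutated", "destabilized")


def shadow_enhancer_network(stage: str, include_background: bool = True,
                 scale: float = 1.0, beta: float = 32.0,
                 self_affinity: float = 2.0) -> RegulatoryNetwork:
    """Physical-enhancer network for the genetic-individuation scenario.

    An ancestral identity expresses TF1-4 through copies of one enhancer
    type placed near each of the four TFs (each copy drives only its
    adjacent TF), with extra shadow copies near TF1 and TF2.  Stages:

    - "ancestral":   every copy binds TF1-4 equally (one enhancer type);
      the only family attractor is the ancestral state.
    - "mutated":     the TF3-adjacent copy evolves into a variant type
      binding TF1,2,3 (losing TF4) and the TF4-adjacent copy into one
      binding TF1,2,4; the ancestral state and the two sister states
      coexist as attractors.
    - "destabilized": the copies near TF1 and TF2 also split into the two
      variant types, so no copy binds all four TFs; the ancestral state is
      destabilised and only the sisters remain.

    The variant types bind their newly individuated TF with a higher
    affinity (``self_affinity``, default 2) than the shared TF1/TF2.  This
    asymmetry is what makes the intermediate stage genuinely tristable:
    with uniform binary binding the ancestral state sheds the sisters
    through a supercritical pitchfork (they appear exactly when it
    destabilises, so the three states never coexist), whereas the
    strongly self-binding variant supports its sister state through a
    fold well below the ancestral state's instability.

    A background block of two disjoint identities on TFs 5-8 (also built
    from physical copies) stays stable through every stage.  Binding rows
    are unit-normalised then multiplied by ``scale`` (the family
    phenomenology is robust to +-50%); ``beta`` is the fixed operating
    temperature.  All couplings are unit rate to the adjacent gene, so
    Q != Xi and the full asymmetric dynamics are exercised.
    """
    if stage not in _INDIVIDUATION_STAGES:
        raise ValueError(f"stage must be one of {_INDIVIDUATION_STAGES}")
    a = float(self_affinity)
    anc = {"TF1": 1.0, "TF2": 1.0, "TF3": 1.0, "TF4": 1.0}
    varA = {"TF1": 1.0, "TF2": 1.0, "TF3": a}     # lost TF4
    varB = {"TF1": 1.0, "TF2": 1.0, "TF4": a}     # lost TF3
    if stage == "ancestral":
        fam = [("E1", anc, "TF1"), ("S1", anc, "TF1"),
               ("E2", anc, "TF2"), ("S2", anc, "TF2"),
               ("E3", anc, "TF3"), ("E4", anc, "TF4")]
    elif stage == "mutated":
        fam = [("E1", anc, "TF1"), ("S1", anc, "TF1"),
               ("E2", anc, "TF2"), ("S2", anc, "TF2"),
               ("E3", varA, "TF3"), ("E4", varB, "TF4")]
    else:
        fam = [("E1", varA, "TF1"), ("S1", varB, "TF1"),
               ("E2", varA, "TF2"), ("S2", varB, "TF2"),
               ("E3", varA, "TF3"), ("E4", varB, "TF4")]
    entries = list(fam)
    tf_names = ["TF1", "TF2", "TF3", "TF4"]
    if include_background:
        tf_names += ["TF5", "TF6", "TF7", "TF8"]
        bg1 = {"TF5": 1.0, "TF6": 1.0}
        bg2 = {"TF7": 1.0, "TF8": 1.0}
        entries += [("B1", bg1, "TF5"), ("B2", bg1, "TF6"),
                    ("B3", bg2, "TF7"), ("B4", bg2, "TF8")]
    T = len(tf_names)
    names, binding, coupling = [], [], []
    for name, binds, drives in entries:
        row = np.zeros(T)
        for tf, aff in binds.items():
            row[tf_names.index(tf)] = aff
        row *= scale / np.linalg.norm(row)
        q = np.zeros(T)
        q[tf_names.index(drives)] = 1.0
        names.append(name)
        binding.append(row)
        coupling.append(q)
    return RegulatoryNetwork(tf_names=tuple(tf_names),
                             enhancer_names=tuple(names),
                             binding=np.array(binding),
                             coupling=np.array(coupling),
                             weights=np.zeros(len(names)), beta=beta)


def individuation_initial_states(net: RegulatoryNetwork, tilt: float = 0.02) -> dict:
    """Named starting profiles for the individuation scenario.

    The ancestral start is duplicated with a small tilt towards TF3 or TF4
    so that, when the ancestral identity has been destabilised, the
    deterministic flow can leave the (unstable) symmetric manifold."""
    def state(active, bump=None):
        x = np.zeros(net.n_tfs)
        for tf in active:
            x[net.tf_names.index(tf)] = 0.5
        if bump:
            x[net.tf_names.index(bump)] += tilt
        return x

    out = {
        "ancestral+3": state(("TF1", "TF2", "TF3", "TF4"), "TF3"),
        "ancestral+4": state(("TF1", "TF2", "TF3", "TF4"), "TF4"),
        "sisterA": state(("TF1", "TF2", "TF3")),
        "sisterB": state(("TF1", "TF2", "TF4")),
    }
    if "TF5" in net.tf_names:
        out["background1"] = state(("TF5", "TF6"))
        out["background2"] = state(("TF7", "TF8"))
    return out


def individuation_attractor_census(net: RegulatoryNetwork, t_converge: float = 400.0,
                          dedup: float = 1e-3) -> dict:
    """Distinct stable states reached from the named starting profiles.

    Returns family and background attractor counts plus the states; the
    family count is the figure-of-merit of the individuation scenario
    (1 ancestral -> 3 mutated -> 2 destabilized)."""
    from .attractors import _converge, refine_fixed_point

    starts = individuation_initial_states(net)
    family, background = [], []
    fam_idx = [net.tf_names.index(t) for t in ("TF1", "TF2", "TF3", "TF4")]
    for name, x0 in starts.items():
        x = _converge(net, x0, net.beta, t_max=t_converge)
        fp = refine_fixed_point(net, x, label_tol=np.inf)
        if not (fp.converged and fp.stable):
            continue
        bucket = family if name.startswith(("ancestral", "sister")) \
            else background
        if any(np.linalg.norm(fp.x - y) < dedup for y in bucket):
            continue
        # a family start must land on a family state (and vice versa)
        mass = fp.x[fam_idx].sum() / max(fp.x.sum(), 1e-300)
        if bucket is family and mass < 0.5:
            continue
        bucket.append(fp.x)
    return {"family_count": len(family),
            "background_count": len(background),
            "family_states": family,
            "background_states": background}


def fixture_celegans_family(N_prime: int = 0, seed: int = 0
                            ) -> PatternFamilyParams:
    """Neuron-class-like pattern family: K=118 classes over N=68 variable
    TFs with a sparse active fraction eta=0.1."""
    return PatternFamilyParams(K=118, N=68, eta=0.1, N_prime=N_prime,
                               seed=seed)


def orthogonal_pattern_network(n_patterns: int, beta: float = 50.0,
                               n_tfs: int | None = None) -> RegulatoryNetwork:
    """Mutually orthogonal unit patterns (one private TF each by default)."""
    T = n_tfs or n_patterns
    if T < n_patterns:
        raise ValueError("need at least one TF per pattern")
    xi = np.zeros((n_patterns, T))
    for i in range(n_patterns):
        xi[i, i] = 1.0
    return RegulatoryNetwork(
        tf_names=tuple(f"TF{j+1}" for j in range(T)),
        enhancer_names=tuple(f"EN{i+1}" for i in range(n_patterns)),
        binding=xi, coupling=xi.copy(), weights=np.zeros(n_patterns),
        beta=beta)


# ---------------------------------------------------------------------------
# synthetic expression matrices


def nested_block_profiles(depth: int = 3, tfs_per_block: int = 3,
                          leaf_level: float = 6.0, decay: float = 0.5):
    """Noise-free nested-block profiles for 2**depth terminal cell types.

    Each internal node of a complete binary tree contributes a TF block
    shared by the leaves below it, with magnitude shrinking towards the
    root (``leaf_level * decay**distance_from_leaf``); cosine similarity is
    therefore strictly ordered by tree distance and average-linkage
    clustering on cosine distance recovers the generating topology.
    Returns (profiles dict, newick string of the generating tree)."""
    n_leaves = 2 ** depth
    labels = [f"L{i+1}" for i in range(n_leaves)]
    # nodes: tuples (level, index); level 0 = leaves
    blocks = []
    for level in range(depth + 1):
        for idx in range(2 ** (depth - level)):
            blocks.append((level, idx))
    col = {b: i for i, b in enumerate(blocks)}
    X = np.zeros((n_leaves, len(blocks) * tfs_per_block))
    for leaf in range(n_leaves):
        for level in range(depth + 1):
            b = (level, leaf >> level)
            j = col[b] * tfs_per_block
            X[leaf, j:j + tfs_per_block] = leaf_level * decay ** level

    def nwk(level, idx):
        if level == 0:
            return labels[idx]
        return f"({nwk(level-1, 2*idx)},{nwk(level-1, 2*idx+1)})"

    profiles = {lab: X[i] for i, lab in enumerate(labels)}
    return profiles, nwk(depth, 0) + ";"


def synthetic_expression_matrix(n_celltypes: int = 8, tfs_per_block: int = 3,
                                n_housekeeping: int = 10,
                                noise_sd: float = 0.1, seed: int = 0,
                                mean_count: float = 400.0,
                                basal_count: float = 3.0
                                ) -> ExpressionMatrix:
    """Cell-type-averaged count matrix with a known lineage hierarchy.

    Identity TFs follow the nested-block construction (counts of order
    ``mean_count`` in the types that express them) on top of a leaky basal
    level everywhere, with lognormal measurement noise; the basal leak is
    what lets sparsely expressed lineage markers clear a mean-expression
    filter, as real cell-type-averaged counts do.  Housekeeping genes are
    expressed near-uniformly everywhere, so a variability filter removes
    them.  n_celltypes must be a power of two."""
    depth = int(np.log2(n_celltypes))
    if 2 ** depth != n_celltypes:
        raise ValueError("n_celltypes must be a power of two")
    rng = np.random.default_rng(seed)
    profiles, _ = nested_block_profiles(depth=depth,
                                        tfs_per_block=tfs_per_block)
    labels = sorted(profiles)
    X = np.array([profiles[l] for l in labels])  # cell types x TFs
    counts = (basal_count
              + np.where(X > 0, mean_count * (X / X.max()), 0.0)
              ) * rng.lognormal(0.0, noise_sd, X.shape)
    genes = [f"IdTF{j+1}" for j in range(X.shape[1])]
    hk = mean_count * rng.lognormal(0.0, 0.02,
                                    (n_housekeeping, n_celltypes))
    hk_genes = [f"HK{j+1}" for j in range(n_housekeeping)]
    df = pd.DataFrame(np.vstack([counts.T, hk]),
                      index=genes + hk_genes, columns=labels)
    return ExpressionMatrix(data=df)
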