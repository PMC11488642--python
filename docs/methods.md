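# Methods

## The model

The package simulates the feedback between transcription factors (TFs)
and the enhancers that drive their expression.  The state is a
nonnegative vector `x` of TF expression levels.  Enhancers (or *enhancer
types* — equivalence classes of physical enhancers with identical binding
profiles) compete for a shared pool of transcription-initiation
machinery; on cell-identity timescales the probability that transcription
initiates at enhancer `i` is Boltzmann-distributed over the enhancer
activation energies, which are set by TF binding through chromatin
modification:

```
s_i   = β ζ_i (ξ_i · x) + w_i
p     = softmax(s)
dx/dt = (Qᵀ p − x) / τ
```

- `Ξ` (E×T, ≥0): binding affinities of each enhancer for each TF.
- `Q` (E×T, ≥0): transcription rates each enhancer drives.
- `w` (length E): baseline log-activity; the signalling input.
- `β ≥ 0`: inverse temperature — the sharpness of the softmax
  competition, biologically tied to the turnover of activating chromatin
  modifications (e.g. histone acetylation).  Low β: promiscuous
  activation; high β: cell-type-specific enhancer selection.
- `ζ` (length E, ≥0, default 1): per-enhancer gain (pioneer-factor
  accessibility).
- `τ > 0` (default 1): expression turnover timescale; all times are in
  units of τ.

The weights enter the score *un-scaled* by β.  This is the convention
under which weights still discriminate between enhancers in the β→0
limit and under which balanced differentiation can apply fixed additive
decrements to `w` across an annealing sweep; the two conventions only
differ by a reparameterization `w → βw` at fixed β.

**Reciprocity.** When `Q = ν Ξ_ζ` for a scalar ν (autoregulation: identity
TFs bind the enhancers that drive their own expression), the Jacobian is
symmetric everywhere — reciprocal TF–TF interactions — and the dynamics
are a gradient flow on

```
V(x) = ½‖x‖² − (ν/β) logsumexp(β Ξ_ζ x + w)
```

whose minima are the encoded cell types.  The flag is recomputed from the
matrices (least-squares ν, elementwise tolerance 1e−9), never asserted by
the caller.  At β=0 the analytic limit `V = ½‖x‖² − ν softmax(w)·(Ξ_ζ x)`
is used (the state-independent `logsumexp(w)/β` constant is dropped).

**Fixed-point structure.** With unit-norm, pairwise-distinct binding rows
the rows of `Q` are stable fixed points at high β (cell types); the
average of a subset of rows is a fixed point when the subset's internal
cosine similarity is high and its external similarity low (progenitors
with multilineage priming); at β=0 the softmax(w)-weighted average of the
rows is the unique global attractor (the multipotent state).

## Numerics

- Deterministic integration: `scipy.integrate.solve_ivp` RK45 with
  rtol 1e−8 / atol 1e−10.
- Stochastic integration: fixed-step Euler–Maruyama, dt = 0.01 τ, additive
  white noise of amplitude σ per component, state clipped at zero after
  each step (deterministic dynamics preserve nonnegativity on their own
  since dx/dt ≥ −x/τ).  Every noisy run requires an explicit seed.
- Fixed-point polish: `scipy.optimize.root` (Powell hybrid) with the
  analytic Jacobian `J = (β Qᵀ(diag p − ppᵀ)Ξ_ζ − I)/τ`.  Convergence is
  judged by the residual ‖dx/dt‖ < 1e−10 (the solver's own success flag
  is unreliable on nearly flat landscapes).  Stability: leading eigenvalue
  real part < −1e−8 is stable, > +1e−8 unstable, otherwise "marginal" —
  never silently stable.
- Attractor enumeration seeds from every pattern row, rows with 25%
  multiplicative noise, and uniform random restarts; states are integrated
  to convergence, polished, deduplicated at Euclidean distance 1e−3, and
  labelled by the nearest pattern or subset average at cosine distance
  1e−3 (labels use cosine distance because identity is a TF *pattern*,
  not a magnitude; pattern-ness of a single row additionally checks the
  magnitude, so a weak duplicate of a stronger row is not misreported as
  its own fixed point).
- Candidate progenitor subsets are singletons, pairs, the full set, and
  the subsets produced by cutting the cosine-distance dendrogram of the
  patterns — never the 2^E lattice, since progenitors arise only for
  high-internal-similarity subsets.

## Annealing and plateau detection

Annealing transiently lowers β and then raises it; on the way up the
state passes through a Waddington-like cascade of progenitors.  Two
schedule shapes are provided: a linear ramp, and a quasi-adiabatic
*staircase* that holds a sequence of β levels.  The staircase is what the
plateau detector is designed around: at each hold the state relaxes onto
the current progenitor and the measured speed drops to integration
accuracy, so plateau detection (speed < 1e−3·‖pattern‖/τ for ≥ 2τ,
terminal interval excluded, per-hold segments merged by identity label)
is insensitive to order-of-magnitude changes of the speed threshold.
Under a finite-rate linear ramp the plateau speed is instead limited by
the quasi-static drift `|dx*/dβ|·dβ/dt`, which ties threshold robustness
to the ramp rate; this is why the bundled chained-toy-network demo uses a
staircase.  The min-dwell parameter stays at 2τ: dwell times at
marginally unstable progenitors are set by saddle escape times (~5–10τ
under finite-rate schedules), so it is the speed threshold, not the
dwell, that carries the order-of-magnitude robustness.

For the chained toy network (six enhancers binding overlapping TF pairs,
within-pair cosine ½, a 0.05 weight on the induced fate) the pair
progenitor is stable only for β between ≈4.0 (global-average pitchfork)
and ≈4.35 (pair pitchfork, 2/(1−½) with softmax-tail corrections), so the
staircase levels step finely through that window.  The cascade is then:
global average of all six rows → induced pair average → induced pattern.

Balanced differentiation repeats annealing runs from the average of all
terminal states with σ=0.01 noise; after a run commits to lineage `i`,
`w_i ← w_i − 0.5(1 − k/k_max)` and `w` is re-centred to mean zero.  Only
`w` changes — signalling controls production without touching identities.
Runs not within cosine distance 0.1 of any pattern count as uncommitted.

## Reprogramming

Constitutive overexpression of TF j at degree δ_j adds δ_j/τ to its
production (additive forcing, not clamping — the perturbation modifies
production dynamics and leaves the unforced attractor coordinates
untouched).  To first order it deepens the potential at pattern `i` by
`Σ_j δ_j ξ_{i,j}`, so recipes are scored by that sum and ranked by the
margin over the best off-target pattern; greedy forward selection with
deterministic name-ordered tie-breaks builds multi-factor recipes.
Defaults: δ=1 per factor, 20τ forced expression, 20τ relaxation.  A
positive margin is necessary for selective reprogramming at small δ;
success requires the withdrawn state to commit (cosine distance < 0.05)
to a pattern different from the source.

## Chromatin barrier

A slow repressive modification `u_i` per enhancer is autocatalytic and
inhibited by enhancer activity.  The exact published kinetics are not
recoverable from the source text, so the package fixes a closure with the
required qualitative contract: production `f(p)·(c₀ + uⁿ/(ρⁿ+uⁿ))` with
linear degradation, `f` smoothly decreasing and crossing the saddle-node
boundary at `p_crit` (defaults: n=8, ρ=1, c₀=0.1, f stepping ≈9→≈2 around
p_crit=0.05).  Above p_crit the low branch `u ≈ f·c₀` is stable; below it
the low branch disappears and `u` jumps to a high branch, adding an energy
penalty `−λu` to the enhancer weight.  For small ρ the switch is bistable
(hysteresis: the high branch survives when activity recovers); for large
ρ it is reversible.  Only this qualitative contract should be relied on.

## Pattern-family theory

A family of K related cell types shares N′ always-active TFs and differs
over N variable TFs with active fraction η (the sampled count of active
variable bits is round(ηN); the active level is 1/√n_active so rows are
exactly unit norm).  Closed forms, each cross-validated in the tests
against oracles built only from the dynamics modules:

- within-family inner product A = (η²N + N′)/(ηN + N′),
- cross-family inner product B = (ηN + N′)/(N + N′ + N″),
- pattern vs two-bit variant C = 1 − 1/(ηN + N′),
- subset-average potential V(n) = s/2 − (1/β)ln(n e^{βs} + (K−n)e^{βB}),
  s = (1+(n−1)A)/n,
- progenitor potential-crossing threshold β₁ ≈ 2 ln K/(1−A),
- bipotent pair: *pitchfork* (local stability loss of the pair average)
  at exactly 2/(1−c); *potential crossing* (the terminal pattern's energy
  drops below the pair average's) at 4 ln 2/(1−c),
- specification gain χ = 2 ln 2 · Nη(1−η)/ln K, the ratio of the
  pair-individuation threshold to the progenitor-destabilization
  threshold.  The shared block cancels: χ depends only on the variable
  TFs, through the Bernoulli variance η(1−η) of the active code.  At
  K=118, N=68, η=0.1 (the sparse homeobox code of the mature nematode
  nervous system), χ = 1.78 — an ≈80% further increase in β.

`critical_beta_bipotent` defaults to the pitchfork criterion because that
is what a numerical stability scan measures; the potential criterion is
the annealing-relevant (global) one and is what enters χ.  The two differ
by the factor 2 ln 2 ≈ 1.39: between them the pair average is locally
stable but no longer the ground state (metastability).

`two_threshold_scan` measures both thresholds on an explicit sampled
family by *potential comparison*, not local eigenvalues:
`beta_destabilize` is the smallest β at which the global family average
stops being the potential minimum among candidate states (patterns, pair
averages, dendrogram cluster averages), and `beta_full_specification` the
smallest β at which every pattern is a distinct stable fixed point *and*
energetically favoured over every containing pair average.  Local
eigenvalue criteria are deliberately not used for the first threshold:
because of subcritical coexistence the average stays locally stable far
beyond the β at which slow annealing abandons it, which would make the
measured ratio meaningless (≈1).  On K=118/N=68/η=0.1 families carrying
an evolved two-bit variant pair the measured ratio is ≈1.7–1.8,
consistent with χ.

## The shadow-enhancer individuation fixture

The new-cell-type evolution scenario uses physical enhancers (Q ≠ Ξ):
copies of one enhancer type sit near each of TF1–4 (each driving only its
adjacent gene at unit rate), with extra shadow copies near TF1 and TF2,
plus a background block of two disjoint identities on TFs 5–8.  Stages:
ancestral (all copies bind TF1–4), intermediate (the TF3- and
TF4-adjacent copies evolve into variants binding {1,2,3} and {1,2,4}),
destabilized (the copies near TF1/TF2 split into the two variants, no
copy binds all four).

The variant types bind their newly individuated TF with affinity 2
versus 1 for the shared TFs.  This is a deliberate design choice: with
uniform binary binding the sister states are born exactly at the
supercritical pitchfork that destabilizes the ancestral state (verified
numerically across normalization, shadow multiplicity and coupling
variants), so the three states of the intermediate stage could never
coexist.  A strongly self-binding variant supports its sister state
through a fold well below the ancestral instability, producing genuine
tristability for β ≳ 16 at unit scale.  The default operating point
β=32 keeps the attractor counts 1 → 3 → 2 (with both background types
stable throughout) under ±50% uniform scaling of the binding magnitudes.
At this operating point the sister attractors are strongly concentrated
on the individuated TF (TF1/TF2 reduced); nearer the tristability onset
they are balanced mixtures.

## Expression-matrix pipeline

Cell-type-averaged counts (genes × cell types, CSV/TSV) are log(1+x)
transformed and filtered for genes whose mean AND population standard
deviation (ddof=0, configurable) across cell types strictly exceed
log 4.  The surviving profiles, unit-normalised, are the rows of Ξ = Q;
w = 0; the terminal β is calibrated as the smallest grid value at which
every cell type is a stable fixed point.  Lineage trees are
average-linkage (optionally complete-linkage) agglomerative clusterings
of the pairwise cosine distances between terminal profiles, exported as
Newick with merge heights as branch lengths.

## Synthetic data

The synthetic expression generator emulates cell-type-averaged count
matrices: a complete binary lineage hierarchy of depth 3 (8 terminal
types) in which each tree node contributes a TF block (3 TFs) expressed
by the leaves below it with magnitude halving towards the root
(≈400 counts at leaf blocks), a leaky basal level of ≈3 counts for all
identity TFs (without which single-type markers cannot clear a mean
filter — as in real averaged data, where leaky transcription keeps
sparse markers nonzero), ≈10 housekeeping genes expressed near-uniformly,
and lognormal measurement noise (sd 0.1 of log counts).  It does *not*
emulate dropout, batch structure, unbalanced lineage sizes, or
non-tree-like similarity, so passing the recovery tests shows that the
pipeline recovers a clean nested similarity structure, not that it is
robust to the full messiness of real atlases.  Pattern families for the
theory module are generated by the documented ensemble and are
combinatorial codes, not calibrated to any measured expression levels.

## Problem sizes used by the test suite

Simulation-based checks run at desk scale: networks of 2–8 enhancer
types over 4–12 TFs; pattern families at the published K=118, N=68
(theory scans, ~seconds per seed via Newton continuation and vectorised
potential sweeps); 100 gradient-flow trajectories of 8τ; 300 balanced
differentiation runs; 10-seed suites elsewhere.  These sizes were chosen
so each property is measured with comfortable statistical margin while
the whole suite stays fast.

## Known limitations

- No explicit chromatin-state variable is simulated; β and w absorb the
  fast modification kinetics (quasi-steady state).
- The potential is defined only for reciprocal networks; asymmetric
  networks raise rather than return an approximate Lyapunov value.
- Attractor enumeration is restart-based; it carries no global
  completeness guarantee in high dimension.
- The two-threshold scan's candidate set (pairs + dendrogram clusters)
  can in principle miss an exotic progenitor subset; the theory predicts
  progenitors only for internally similar subsets, which these cover.
- Real-data adapters (cell atlases, haematopoietic compendia) are out of
  scope; the expression pipeline is exercised on synthetic matrices only.
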