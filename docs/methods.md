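# Methods

## Model

The simulator couples a Greenberg–Hastings excitable network to a point
agent in a rectangular arena. Nodes occupy one of three states — excited
(E), refractory (R), quiescent (Q) — and update synchronously from the
previous epoch's states only: E → R and R → Q with probability 1; Q → E
with spontaneous probability `p_spont` (default 0.1) or deterministically
when the summed input g · Σ_j Ĉ_ij b_j strictly exceeds the node's
threshold T_i, where Ĉ is the connectivity matrix divided by its global
maximum and b_j is binarized activity (1 iff excited). Max-normalisation
makes the (coupling, threshold) axes dimensionless and comparable across
connectomes; raw weights are stored untouched by the connectome module.

Exogenous forcing (sensory input, task-negative balancing) overwrites the
computed state for that epoch only; a node forced excited on consecutive
epochs stays excited — its E → R rule is suppressed while clamped.

Per-epoch order of the closed loop: (1) sensory forcing from the previous
pose and collision flags, (2) task-negative balancing, (3) the synchronous
network update, (4) local threshold plasticity, (5) motor decoding and
movement. The run is a pure function of (connectome, roles, config,
arena); one master seed feeds a single random stream, and every stochastic
operation draws from it in a fixed order (the per-node spontaneous draw is
consumed every epoch regardless of parameter values, so records are
reproducible across parameter changes).

## Homeostatic mechanisms

**Local** (variants `local`, `combined`): T_i ← T_i + α (b_i − ρ).
Thresholds are not clamped; under prolonged silence they go negative,
which is the rule's true fixed point (any positive input then fires the
node). The update is skipped, by default, for nodes whose state was
exogenously clamped that epoch (`homeostasis_scope="unforced"`). Rationale:
a clamped node's activity is not produced by its own dynamics, and a
task-negative node forced excited nearly every epoch would otherwise
accumulate threshold drift of α(1 − ρ) per epoch without bound, making the
combined model's thresholds *more* variable than the local model's — the
opposite of the stabilisation the balancing mechanism produces for the
rest of the network. `homeostasis_scope="all"` (the literal per-node rule
with no exclusions) and `"exclude_roles"` (sensory/motor/task-negative
nodes never update) are available for comparison.

**Macroscopic** (variants `macro`, `combined`): with B = 4 task-negative
nodes and k = min(|forced sensory nodes|, B), the first B − k
task-negative nodes in a fixed priority order (alternating left/right
across the two bilateral pairs) are forced excited, the remaining k forced
quiescent, so min(|TP forced|, 4) + |TN forced E| = 4 at every epoch. The
clamped-complement rule is the minimal mapping from the 0–6 possible
sensory loads onto the 4 available task-negative nodes that preserves
count constancy on its feasible range.

## Structural fixed points of the dynamics

Two closed-form bounds shape everything downstream:

- **Spontaneous floor.** With spontaneous rate p, an unforced node's
  stationary excited fraction cannot fall below p/(1 + 2p); at p = 0.1
  this is 1/12 ≈ 0.083. No threshold setting reduces it, so homeostatic
  targets ρ < 1/12 are unattainable: thresholds grow without bound (the
  homeostasis sweep flags this as divergence) and activity pins at the
  floor. Targets ρ ≥ 1/12 are attained to within a few 10⁻⁴ in 5000-epoch
  runs.
- **Refractory ceiling.** The E → R → Q cycle takes at least three epochs,
  capping unforced mean activity at 1/3. The phase transition of the
  static model therefore runs from ≈ 0.083–0.11 (floor plus sensory load)
  to ≈ 0.36 (ceiling plus clamped sensory nodes), not from 0 to 1.

A corollary concerns avalanche analysis: cascades are delimited by
whole-network silent bins, whose probability at the floor is
(1 − 1/12)⁶⁶ ≈ 0.003 for 66 nodes. In the converged regimes of this model
the raster is effectively never silent, one giant cascade spans the
record, and the power-law fit is undefined. The avalanche machinery is
therefore validated against oracle draws from the reference K^(−3/2) law
(where the least-squares exponent, NLL, and kappa all calibrate as they
should) rather than against the simulator's own converged output.

## Embodiment conventions

- Arena 20 × 20 world units; the 10-unit far-vision range covers half the
  arena. The agent is a point; initial pose is the arena centre with a
  heading drawn uniformly from the run's stream.
- Rays at heading ± 10° (left ray +10°); exact ray–segment intersection
  with the four bounding walls.
- Near vision < 2 units, far vision 2–10 units (near and far mutually
  exclusive per side); somatosensory forcing holds for every epoch in
  which wall contact holds.
- Turn = exactly ±30° (π/6); left rotate node turns counterclockwise.
  Only the move command is smoothed (v = 7/8 raw + 1/8 previous); turn
  smoothing is available behind `smooth_turn`.
- Collisions clip the position 10⁻³ units inside the wall (never exactly
  on the boundary, avoiding degenerate ray casts). The hit is attributed
  to the agent's left or right by the signed angle from its heading to the
  wall's *outward* normal (positive → left); |angle| < 1° counts as
  head-on and flags both sides. The outward-normal convention is the one
  under which a head-on hit has angle 0 and a wall struck at 45° on the
  agent's left is attributed left.

## Analysis conventions

- **Avalanches:** epochs grouped into bins of Δt (trailing partial bin
  dropped); cascades are maximal runs of bins with ≥ 1 excitation event;
  boundary-touching cascades are kept. Least-squares fit: OLS of log₁₀
  P(K) on log₁₀ K over observed sizes, no logarithmic binning. Reference
  law normalised on the observed [min K, max K] (a 66-node system
  truncates the law). Kappa uses m = 10 logarithmically spaced evaluation
  points.
- **Movement entropy:** Shannon entropy (base 2) of the joint (v, h)
  histogram, 16 equal-width bins per axis over each series' observed
  range; a constant axis collapses to one bin. The joint form captures
  motor-signal dependence; marginals can be recovered by passing one
  constant series.
- **Fractal dimension:** Bresenham-rasterized trajectory on a 1024²
  grid covering the arena; box sizes resolution/2^k for k = 1 ..
  log₂(res) − 2; the two coarsest sizes are excluded from the fit
  (they saturate for any non-trivial path). Calibrates to 1.00 ± 0.05 on
  a straight line and 2.00 ± 0.05 on a space-filling sweep.
- **Coupling correlations:** raw Pearson correlations over epochs, no
  detrending or smoothing; constant series are reported as r = 0 with a
  warning.
- **Group contrasts:** pooled-variance two-sample t (df = n_a + n_b − 2;
  58 for 30 vs 30); per-run correlations are compared to zero via Fisher's
  z and a one-sample t with df = n − 1.
- **Activity variability:** reported both as the across-node SD per epoch
  averaged over epochs (`activity_node_sd`) and as the SD over time of the
  network mean (`activity_temporal_sd`); threshold variability as the SD
  and CV over time of the network-mean threshold.

## Operating point and study sizes

The default configuration places the static model at the phase transition
found by the phase sweep on the default synthetic connectome: coupling
g = 1, initial threshold 0.2, midway between the floor (≈ 0.11 embodied)
and ceiling (≈ 0.36) regimes. Local homeostasis defaults to the
low-target/high-learning-rate regime (ρ = 0.1, α = 0.1), where the
attained rate matches the target and thresholds converge within a few
hundred epochs.

Desk-scale study sizes: sweeps default to 5000 epochs per cell; the
variant comparison uses 2000-epoch runs, with 10 repeats per variant in
the bundled reproduction script (the full design of 30 repeats runs in a
few minutes via `embodied-gh variants`). Convergence measurements discard
the first half of each run as adaptation transient. Per-cell and
per-repeat seeds are derived from the master seed and the grid position,
so results are independent of evaluation order.

## Synthetic connectome

The generator emulates the gross statistics of a streamline-count
structural matrix: 66 regions in two mirrored hemispheres, 4 modules per
hemisphere, intra-module connection probability 0.3 versus 0.05 between
modules, log-normal (heavy-tailed) positive weights, homologous pairs
always connected, symmetric with zero diagonal. It does **not** emulate
anatomical topology (hub placement, spatial embedding, realistic
inter-hemispheric density), so results that depend on where sensory and
motor roles fall relative to connectivity hubs — in particular the
strength of sensory→motor propagation that can trap a non-homeostatic
agent against a wall — need not transfer from this stand-in to an
empirical connectome. A user-supplied CSV matrix is accepted anywhere the
synthetic one is used.

## Known limitations

- Behavioral contrasts between variants are muted relative to what a
  strongly trapped static agent would show: at `p_spont` = 0.1 motor nodes
  fire spontaneously about once per 12 epochs, so every variant roams the
  20 × 20 arena and behavioral richness largely tracks overall drive. The
  robust variant signatures here are the wall–activity decoupling and the
  threshold-stability gain of the combined model, not the entropy/fractal
  orderings.
- Avalanche statistics require a sparsely active raster; see the silence
  argument above.
- No synaptic (weight) plasticity, conduction delays, interior obstacles,
  multi-agent arenas, or continuous-time dynamics.
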