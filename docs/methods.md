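# Methods

`switchpath` implements a complete desk-scale pipeline for the rational
acceleration of protein conformational switches built on mutually
exclusive folding: native-centric residue-level models of alternate-frame
-folding (AFF) constructs, weighted-ensemble (WE) path sampling of the
switching process under Brownian dynamics, rate/stability/transition-path
analysis, and a contact-score screen that proposes rate-enhancing
mutations.  This note records the model, the estimators, the synthetic
systems the tests run on, and the design choices made where more than one
reasonable option existed.

## The energy model

Proteins are represented by one bead per residue at the Cα position.  The
potential is a standard structure-based ("Gō-type") form in which only
native interactions are attractive:

* **Bonds** — harmonic, `k_b (r − r0)²`, `k_b = 100 ε Å⁻²`, `r0` from the
  reference structure.
* **Angles** — harmonic in the cosine, `k_a (cos θ − cos θ0)²`,
  `k_a = 20 ε rad⁻²`-equivalent.  The cosine form has a regular gradient
  at θ = π; acos-based angles diverge there and destabilize overdamped
  integration of partially unfolded chains.
* **Dihedrals** — `k1 (1 − cos(φ − φ0)) + k3 (1 − cos 3(φ − φ0))`,
  `k1 = 1 ε`, `k3 = 0.5 ε`.  Torsions are skipped while a bond triple is
  within ~6° of collinear, where φ is undefined; the angle term makes
  such geometries rare.
* **Native contacts** — 12-10 wells `ε (5 (r0/r)¹² − 6 (r0/r)¹⁰)` with the
  minimum at the native pair distance and uniform depth ε (the single
  calibration scalar).  Native pairs are those with sequence separation
  ≥ 3 and Cα–Cα distance ≤ 8 Å in the reference structure; both values
  are configurable.
* **Excluded volume** — `ε_ev (σ/r)¹²` with σ = 4 Å between all pairs
  separated by more than three bonds that are not attractive native
  contacts, truncated and shifted to zero at 2σ (the residual force there
  is ~10⁻⁴ ε/Å, far below thermal forces).  A pair whose native well has
  been deleted by an in-silico mutation reverts to this term, so mutated
  residues keep their steric body.

All bonded constants scale with ε so a single parameter sets the energy
scale, the usual convention for this model class.

### AFF constructs

An AFF construct is assembled as *duplicated C-terminal segment + linker +
full wild-type sequence*.  The N frame (wild-type fold) keeps the
wild-type contact map on the original copy; the N′ frame (circular-permutant
fold) is produced by index remapping — contacts involving the duplicated
range move to the N-terminal copy.  Contacts entirely inside the shared
segment are stored once, tagged `shared`, with identical parameters in both
frames, so the two frame maps are (r0, ε)-identical multisets by
construction.  The linker contributes bonded terms only.  No term couples
or penalizes the frames directly: mutual exclusivity emerges because the
two copies of the duplicated segment compete sterically for the same
interface on the shared segment.

Bonded native values are measured on a hybrid reference: terms lying
entirely within the duplicate+linker+shared region take the
circular-permutant (N′-folded) geometry, all others the N-folded geometry;
the two agree on the shared segment.

### Mutations and ligand binding

An underpacking substitution (e.g. Phe → Ala) is modeled as the idealized
maximum-underpacking limit: every attractive native interaction of the
parent residue is deleted (ε → 0) while bonded terms and excluded volume
are untouched.  Ligand (Ca²⁺) binding is a uniform multiplicative deepening
(scale ≥ 1) of the binding-competent frame's contacts that involve a
user-supplied binding-loop residue set; scale 1 reproduces the apo model
exactly, and the binding-dead frame keeps scale 1.

## Dynamics

Overdamped (inertialess) Euler–Maruyama Brownian dynamics:
`x ← x + (D Δt / k_BT) F + ξ`, `ξ ~ N(0, 2 D Δt)` per coordinate, with a
single per-bead diffusion coefficient (no hydrodynamics).  Real-unit runs
default to 20 °C (k_BT with R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹), τ = 100 ps
segments, conformations stored every 50 ps, D = 0.02 Å² ps⁻¹; reduced-unit
fixtures set k_BT = 1, D = 1.  Numerical stability is guarded by a per-step
displacement bound (default 2 Å per bead) that raises an error rather than
silently clipping; the bead-fixture timestep (1.25×10⁻³ reduced time) was
chosen so the bound is never reached in ordinary sampling.

Trajectories are bitwise reproducible: all noise is drawn from a single
seeded NumPy generator in a fixed order.

## Weighted-ensemble sampling

The WE engine maintains weighted walkers that are split and merged per
progress-coordinate bin every τ so each occupied bin holds
`walkers_per_bin` walkers (default 4).  Splitting divides weight equally
among clones; merging repeatedly combines the two lowest-weight walkers,
the survivor chosen with probability proportional to weight and absorbing
both weights.  These rules conserve total probability exactly (checked to
10⁻¹² every iteration) and preserve the expectation of every weight-linear
observable, so binning only redistributes computational effort and never
biases the sampled dynamics.

Bins are half-open `[low, high)` rectilinear cells whose outermost cells
absorb under/overflow, so every finite coordinate maps to exactly one bin.
A `BinMapper` may carry its own coordinate function; the AFF fixtures bin
on the (rmsd_N, rmsd_N′) progress pair with fine cells near the folded
basins.

*Steady-state mode* recycles walkers that reach the target state:
terminated and restarted from the initial-state sampler with unchanged
weight; the recycled weight per unit time is the flux f_ij.  *Equilibrium
mode* never recycles.  Each walker carries a history label — the state it
visited most recently, inherited through splits, merges (survivor's
label) and iterations — evaluated at segment ends (τ resolution).

## Estimators

* **Rate constants** — `k_ij = f_ij / p_i`, with f_ij the mean recycled
  flux per unit time after burn-in (default: the first 10% of iterations
  are discarded; AFF fixtures discard 30% because their bin occupation
  builds up slowly) and p_i the time-averaged weight fraction carrying
  label i.  Walkers that have not yet touched either state are excluded
  from numerator and denominator; their weight fraction is reported so
  its decay can be verified.  With several independent runs the s.e.m. of
  k across runs is attached.  Zero post-burn-in flux yields a warning and
  an upper bound of one event per run length.
* **States** — from an equilibrium histogram along the progress
  coordinate: each state boundary sits at its basin's mode (the position
  of the probability-distribution maximum), the boundary bin belonging to
  the state and the barrier region open between the modes.  Two separated
  modes are required; unimodal or flat histograms are rejected.
* **Stabilities** — `ΔG_fold = −k_BT ln(P_folded/P_unfolded)` from
  equilibrium archives, or from opposing steady-state runs combined
  through their labeled-ensemble rate balance, which for a two-state
  system reduces to `−k_BT ln(k_fold/k_unfold)`.  The latter converges on
  the barrier-relaxation timescale rather than the (possibly enormous)
  unfolding timescale and is the default protocol for mutant ΔΔG tables.
* **Barrier changes** — `ΔΔG‡ = RT ln(k_mut/k_WT)`, reported to one
  decimal in summaries.
* **MFPT** — 1/k with first-order error propagation.
* **Efficiency** — `S = (MFPT × n_events) / (aggregate WE time)`: the
  expected brute-force cost of harvesting the same number of switching
  events divided by what the WE run actually cost.  Recycling events are
  counted as events; correlated arrivals make this an optimistic count,
  which does not affect the monotone growth of S with barrier height that
  the efficiency suite checks.
* **Free-energy surfaces** — walker weights accumulated on a progress
  grid, `G = −k_BT ln P`; multiple runs pooled by averaging normalized
  fields.  Transition-path-ensemble fields spread each path's weight
  uniformly over its frames.
* **Transition path ensemble** — for every recycling event the lineage is
  walked backward to the last stored frame inside the initial state; the
  segment from the first frame after it through the first frame inside
  the target is the transition path, carrying the recycled weight.
  Unproductive excursions are excluded by construction.  Frames exist at
  the sampling interval, so path end-points are resolved to that
  granularity.
* **Contact scores** — a contact is formed when its pair distance is
  ≤ 1.2 × r0 (configurable; the choice only needs to separate docked from
  undocked unambiguously).  A residue's score in an ensemble is the
  weighted mean number of formed native contacts; cross-run s.e.m. comes
  from per-run means.
* **Candidate ranking** — mutation sites are ordered by the sum of the
  two direction-normalized ground-minus-TPE score differences; in a
  dual-frame construct a site aggregates a residue and its duplicate-copy
  twin, mirroring the practice of mutating both copies at once.  Sites in
  or adjacent (±1) to the binding-site list, or whose mutant ΔG_fold is
  above the stability floor (~−2 kcal mol⁻¹ for the real system), are
  flagged and excluded.  The negative control is the buried interface
  site (contact degree ≥ median over the interface set) with the smallest
  combined change; ties break toward the lower residue index.

## Synthetic systems

All tests and the acceptance script run on generated fixtures; nothing is
downloaded.

* **1-D double/triple well** — `V(x) = h((x/a)² − 1)²` with an optional
  Gaussian dimple at the origin as a metastable intermediate.  Rates are
  known independently from a long-trajectory, history-labeled passage-time
  kernel that shares no code with the WE engine, and from the closed-form
  double-integral MFPT.  This system stands in for switching processes of
  tunable barrier height.
* **Hairpin** — a 16-bead two-strand antiparallel zigzag; the minimal
  cooperative two-state folder, used for stability calibration.
* **Two-hand toy AFF** — the 20-residue wild-type fold consists of two
  5+5-strand "hands" (A: residues 1–10, B: 11–20) stacked at an interface
  of 9 contacts; hand B is duplicated through a 2-residue linker
  (construct length 32), so the two copies of B compete for hand A.
  Intra-hand contacts are deepened (factor 2 by default) relative to the
  interface, keeping the hands internally folded — including the orphan
  copy — while switching crosses only the soft docking interface.  The
  interface depth default (ε = 1.25 k_BT) puts each docked state a few
  k_BT below undocked and the switching barrier high enough that no
  switch occurs in ordinary brute-force runs, i.e. genuinely rare-event
  territory at fixture scale.

### What the fixtures do and do not show

The toy systems reproduce the *structure* of the problem — two mutually
exclusive folds sharing a segment, an interface whose residues lose
contacts in the transition-path ensemble, orphan segments with retained
internal structure, rare switching accelerated by interface mutations —
at barriers of order 10 k_BT rather than the tens of k_BT of a real
protein switch.  Passing tests therefore validate the estimators, the
weight bookkeeping and the screen logic, not the quantitative kinetics of
any real protein.  Real-protein features deliberately absent: sequence-
specific contact energies, non-native attraction (which real switching
intermediates may require for quantitative kinetics), side-chain
packing, solvent and hydrodynamic effects.

## Problem sizes

The shipped test-and-acceptance configuration uses: double-well runs of
400–1500 iterations at τ = 0.5 with 16 interior bins; toy-AFF runs of
350–400 iterations at τ = 0.2 with a 9×9-edge RMSD grid (a few hundred
walkers); hairpin stability runs of 300–450 iterations with eight walkers
per bin on a fine RMSD ladder; brute-force oracles of 200–400 events; two
to five independent WE runs wherever an s.e.m. is quoted.  These sizes
were chosen as the smallest at which the oracle comparisons are stable;
each can be raised through the corresponding configuration objects
without code changes.

## Known limitations

* Rate estimates on the toy AFF carry run-to-run scatter of roughly a
  factor of two to three at the shipped run lengths (larger in the
  forward, docking-limited direction); comparisons are made against
  3×-s.e.m. bands across independent runs, and single-contact mutation
  effects (~1 k_BT of barrier) sit below that resolution.
* Stabilities deeper than roughly −7 k_BT hinge on unfolding fluxes of
  order e⁻¹³, whose desk-scale estimator scatter is ±1–2 k_BT even with
  fine bins and extra walkers per bin; reproducing such a ΔG_fold to
  ±0.3 kcal mol⁻¹ needs cluster-scale sampling.
* Recycling and history labels are evaluated at τ resolution, the
  standard WE convention; sub-τ excursions through a state are invisible.
* Equilibrium-mode convergence is limited by the slowest physical
  relaxation; the bidirectional steady-state combination is preferred for
  deep two-state systems.
* The efficiency metric counts recycling events, an upper bound on
  independent events.
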