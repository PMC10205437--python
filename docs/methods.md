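# Methods

## Overview

`dais` post-processes pairs of sampled protein conformational ensembles
(Case vs. Control) to locate mutation-attributable structural change and
the hydrogen-bond rearrangements around it.  The method assumes the two
ensembles describe the same polymer (mutations change residue identity,
not numbering), start from near-identical conformations at the first
frame, and have already been stripped of solvent and ions.  All
coordinates are in Å; all persistence values are sphere radii in Å.

## Persistent homology backend

The point cloud per frame is a fixed subset of alpha-carbons, drawn once
per Case/Control pair (without replacement, by residue key, default
`n_cas = 500`) and shared by both conditions and all frames — feature
correspondence by generator overlap is meaningless otherwise.

The default filtration is the **alpha complex**: the Delaunay
triangulation (scipy/Qhull) with each simplex entering at its smallest
empty circumscribing radius (its circumradius if the simplex is Gabriel,
else the smallest filtration value among its cofaces).  Gabriel tests
are made against the full point set, vectorized.  A **Vietoris–Rips**
mode (all subsets, half the maximum pairwise distance) is retained for
small clouds and cross-checks; it is exponential in cloud size and
refuses complexes beyond 2×10⁶ simplices.

Persistence is computed by the standard Z/2 column reduction of the
boundary matrix in filtration order, maintaining the reduction matrix V
(R = DV).  For a feature born at simplex σ, the stored **generator set**
is the vertex set of the cycle V[σ] — the cycle that exists at birth
time.  On a loop of CAs this is the full ring of residues, which is what
overlap matching needs; the alternative (the reduced column of the death
simplex) localizes near the simplex that fills the hole and makes
frame-to-frame overlap unstable.  Dimension-0 classes are computed
(the essential class is kept with death = ∞) but excluded from tracking
by default; only loops and voids are tracked.

Numerical choices:

- Simplex order ties are broken by (filtration value, dimension, vertex
  tuple), so faces always precede cofaces.
- Coincident duplicate points are deduplicated with a warning; clouds
  with fewer than 2 points (or fewer than 4 in alpha mode) are rejected.
- Exactly degenerate clouds (e.g. cospherical subsets of symmetric test
  geometries) fail the exact Delaunay build; the backend then retries
  with joggled input (Qhull `QJ`, perturbation ~1e-10 of the coordinate
  range — far below every tolerance used downstream, and deterministic).
- Features with persistence < 0.05 Å are treated as numerical noise and
  dropped before tracking (configurable).

Validation: the Rips mode is compared against an independent
full-complex boundary-matrix reduction (bit-integer columns) on random
clouds — identical (dimension, birth, death) multisets to 1e-9; the
alpha mode is compared against a brute-force Čech filtration (minimum
enclosing ball radii), which has identical persistence for clouds in
general position.

## Feature tracking and pairing

Two features correspond when their generator overlap
|G_p ∩ G_q| / max(|G_p|, |G_q|) **strictly exceeds** δ = 0.75; equality
at the threshold is a non-match.  Within a condition, matching is
restricted to adjacent frames (t → t+1): greedy one-to-one assignment in
descending similarity, ties by smaller |ΔBirth| + |ΔDeath|, then lower
feature id — deterministic by construction.  Unmatched features close
their track (disappearance) or open a new one (creation).  Across
conditions, tracks are paired greedily by the similarity of their
first-frame generator sets, the frame at which Case and Control are
constructed to coincide.  Tracks shorter than 10 % of the frame count
are dropped before pairing as noise.  Gap-tolerant tracking (a feature
vanishing for a few frames and resuming) is not implemented; such a
feature yields two tracks.

## Change scoring

Each diagram point (Birth, Death) is re-plotted as (Birth, Death−Birth)
and the polar distance r = √(Birth² + (Death−Birth)²) is followed along
a track, divided by its initial value, and smoothed with a centered
moving average (default window 11 frames, shrinking at the edges;
window 1 is the identity).  The smoother is deliberately parameter-light;
the window is clamped to the next lower odd value for tracks shorter
than the configured window, so short-but-valid tracks remain scoreable.
The polar angle is computed and stored but plays no role in scoring.

The ID score of a pair is |Σ_t Δr_t| with
Δr_t = r̄_case(t) − r̄_control(t) over the frames where both tracks
exist.  The plain absolute sum allows sign cancellation (a drift up then
down scores 0); a `sum_abs` flag switches to Σ|Δr_t| for users who want
total excursion, but the default follows the plain formula.

The percentile filter uses the linear-interpolation percentile rank
((rank − 1)/(n − 1) × 100, average ranks for ties): scores at or below
the 1st or at or above the 99th percentile are excluded as outliers,
the closed 5th–95th band is excluded as small, and only the open bands
(1, 5) and (95, 99) are retained.  With fewer than 20 scores the filter
is skipped (percentiles are meaningless) and everything is retained with
a warning.

Secondary-structure gating consumes a DSSP output file computed on the
first Control frame (class assignments are unstable frame-to-frame at
simulation temperatures).  "Lacking a specific secondary structure" is
defined as DSSP classes {T, S, −}; a retained score survives iff at
least half (closed bound, configurable) of its generator residues carry
a class in {H, G, I, E, B}.  The filter only ever demotes.

## Hydrogen-bond analysis

Candidate atoms are all atoms of every residue whose CA lies within
10 Å (closed bound) of any generator CA of the features of interest.
A bond D–H···A is present in a frame when:

- H lies within 1.2 Å of its nearest N/O, which is taken as the
  covalent donor D (per frame; unassignable hydrogens are skipped),
- A is an N/O of a *different* residue,
- 1.5 ≤ R(H···A) ≤ 2.2 Å (closed bounds),
- the D–H–A angle measured at the hydrogen strictly exceeds 160°
  (180° = linear).

Boundary comparisons carry a 1e-9 guard so geometries constructed
exactly on a bound land on the intended side.  The formation rate is the
mean of the per-frame presence vector; bonds are matched across
conditions by (chain, residue number, atom name) — never residue name,
so mutated residues compare — with rate 0 where absent, ranked by
|Δrate|, reported top-20 and flagged at |Δrate| ≥ 0.3 by default.  Only
hydrogen bonds are analyzed; van der Waals, salt-bridge and π-stacking
interactions are out of scope.

## Variant diversity profiling

For many Case variants against one Control, cell (v, res) of the
change-count matrix is the number of retained change features of
variant v whose generator set contains residue res — raw counts, no
normalization (a row-normalization flag is not applied by default).
UMAP (n_neighbors 15, min_dist 0.1, Euclidean, fixed seed) embeds the
rows for visualization.  NMF (scikit-learn, random init) is consensus-
clustered over restarts: each restart labels variants by their dominant
coefficient component; the mean connectivity matrix is hierarchically
clustered (average linkage) and its cophenetic correlation computed per
candidate rank.  The selected rank is the largest before the first drop
of the cophenetic coefficient exceeding 0.05; if the curve never drops
that much, the largest rank attaining the maximum (the end of the
stable plateau) is chosen — under-ranked consensus is often perfectly
stable, so the smallest such rank would systematically under-fit.
Factors come from the best-reconstruction restart at the selected rank.

## Synthetic fixtures

The fixture generator emulates thermodynamic-sampling output
geometrically: a ring of CAs (radius 10 Å) with isotropic Gaussian
thermal jitter per frame (default sd 0.05 Å, chosen well inside the
regime where the ring's loop persists; the guarantee holds to 0.5 Å), a
small out-of-plane sine modulation (0.5 Å) keeping the cloud in general
position for the 3D alpha complex even at zero jitter, optional
N/H/O atoms per residue with glycine naming for H-bond tests, and an
optional injected change in the Case copy.  Both conditions share the
jitter stream, so the pair is bit-identical without an injection and
coincides exactly at frame 0 with one.

`ring_opening` places the injected residues on their own small ring
(≥ 2.5 Å radius, ~3 Å spacing) far outside the H-bond neighborhood of
the main ring and grows its radius linearly by `magnitude` after the
onset frame — a localized change whose feature generators are exactly
the injected residues.  `hinge` dilates the injected residues radially
about the centroid (a global opening mode; the main loop's death radius
grows strictly at zero jitter).  The H-bond system realizes requested
per-frame H···A distances and D–H–A angles exactly in a two-residue
donor/acceptor geometry.

What the fixtures do **not** model: force-field energetics, correlated
or anisotropic fluctuations, solvent effects, realistic backbone
geometry or side chains.  Passing tests therefore demonstrate the
correctness of the computational pipeline on clouds with known topology
and controlled perturbations — not the biological sensitivity or
specificity of the method on real trajectories.

## Problem sizes

The test and validation runs use deliberately desk-scale inputs: rings
of 12–50 residues over 20–100 frames, brute-force persistence oracles on
clouds of ≤ 12 points, 24-variant planted count matrices.  These sizes
exercise every code path (the alpha backend itself handles 500-point
clouds in well under a second per frame) while keeping the full suite
fast and deterministic.

## Known limitations

- Generator sets depend on the representative cycle the reduction
  happens to produce; they are canonical only up to homology.  Different
  but homologous representatives would change overlap similarities.
- Adjacent-frame matching cannot follow a feature through a frame where
  it momentarily dips below the persistence cutoff.
- The ID score's sign cancellation (above) is faithful to the plain
  formula but can hide oscillating changes; use `sum_abs` if that
  matters.
- Alpha-complex values on joggled (degenerate) inputs are exact only up
  to the joggle magnitude (~1e-10).
- DSSP output is consumed, not computed; an installed `mkdssp` can be
  invoked through a convenience wrapper but is not required.
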