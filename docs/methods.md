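# Methods

## Labelled point patterns

All statistics operate on 2D point clouds on a bounded rectangle, each
point carrying a categorical label `q_i ∈ {B, M, S, T, N}` (blood vessel,
macrophage, stromal, tumour, necrotic) and, where meaningful, a continuous
mark `p_i ∈ [0, 1]`. Coordinates are in units of one cell diameter. Marks
on non-mark-carrying points are *missing* (NaN), never 0, because a mark
of 0 is a meaningful M1 phenotype. The CSV dialect is comma-separated with
a mandatory header (`x, y, category, mark`), '.' decimal separator, and
empty cells for missing marks; a JSON sidecar records the domain bounds,
boundary mode and snapshot time.

## Pair correlation statistics

The cross-PCF bins source–target pairs into annuli `[r_k, r_k + dr)`,
`r_k = k·dr`, centred on source points, and normalises the per-annulus
target count by the density expected under complete spatial randomness
(CSR). Two boundary conventions are supported:

* **clipped** (default): distances are Euclidean and each annulus is
  intersected with the domain rectangle. The intersection area is computed
  analytically as the difference of two circle–rectangle overlaps, each
  decomposed into four signed corner integrals of
  `∫ min(b, sqrt(R² − x²)) dx`; a rejection-sampling Monte-Carlo estimate
  is used in tests as the independent oracle. Because annulus areas differ
  between centres, the clipped cross-PCF is not symmetric in its
  arguments.
* **periodic**: the rectangle is a torus; distances wrap and every annulus
  has the full area `π (2 r_k + dr) dr`. On a torus the statistic is
  exactly symmetric. Radii beyond half the shorter side are not
  meaningful on a torus and the full-ring area is used regardless.

Self-pairs are excluded when source and target coincide. Empty
populations yield an all-NaN result flagged undefined rather than an
exception, because snapshots with no tumour cells are an expected outcome
of the simulation, not an error. Undefined values are always NaN plus an
explicit mask, never silently 0 or 1. Bins are half-open, so a pair at
exactly the outer edge belongs to the next annulus.

The wPCF replaces the source indicator by a weighting kernel. The default
is triangular with half-width ΔP = 0.2, which trades phenotype resolution
against estimator variance; a Gaussian kernel (unbounded support) and an
exact-match indicator (the ΔP → 0 limit, under which each row reduces to
the cross-PCF of the exactly matching sub-population) are provided as
alternatives. Rows of the (P, r) surface whose total weight `W_P`
vanishes are undefined. A two-mark variant weights both the annulus
centres (by closeness to P1) and the counted points (by closeness to P2),
normalised by `W_P1 W_P2 / A`; it is symmetric under swapping the two
populations on a periodic domain.

The default radial binning (dr = 0.1, 191 bins, r ∈ [0, 19.1)) and mark
grid (0, 0.01, …, 1) cover the 0–20 cell-diameter range over which
tumour-scale structure (perivascular niches, exclusion zones) is
expressed, and fix the flattened signature length at
191 × (2·101 + 1) = 38,773. All statistics are scale invariant: scaling
coordinates, domain and dr together leaves every value unchanged.

## Agent-based model

The simulation couples off-lattice cell mechanics to five explicit-grid
reaction–diffusion fields on a 40 × 40 cell-diameter tissue with no-flux
boundaries. Time is in hours; with drag ν = 1 a force of magnitude f
moves a free cell at f diameters per hour.

**Mechanics.** Cells interact through linear springs within
R_int = 1.5 diameters: repulsion with stiffness 4 inside the rest length
(sum of radii), adhesion with stiffness 1 beyond it. Repulsion-dominant
stiffnesses are used because, in a close-packed aggregate, far more
neighbour pairs sit in the attractive band than in contact; equal
stiffnesses make dense tissue collapse. Spring strength scales with the
pair's combined radius, so shrinking necrotic cells exert progressively
weaker forces. Positions advance by forward Euler with dt = 0.05 h. Two
numerical safeguards apply: a per-step displacement cap of 0.5 diameters,
which only engages in transiently jammed clusters where the elastic
forces are largest and least physical (ordinary displacements are below
0.25), and a hard error if any displacement would exceed one diameter.

**Active forces and crowding.** Macrophages receive an isotropic random
force (magnitude 1.0, redrawn each step) plus the phenotype-weighted
chemotactic forces `χ_c (1−p) ∇c/|∇c| + χ_ξ p ∇ξ/|∇ξ|`; a vanishing
gradient contributes nothing (the 0/0 convention). Tumour cells climb EGF
gradients with a response that saturates in gradient magnitude
(half-saturation 0.02), so shallow far-field gradients do not drag them
at full strength. All active forces meet a resistance proportional to the
cell's summed contact overlap (2 units of force per unit overlap), a
yield-stress picture of migration through packed tissue: weakly driven
cells cannot invade a dense mass at all, strongly driven ones can, which
is what converts chemotactic strength into infiltration depth — the
mechanism behind the regime structure below. Macrophages are smaller
(radius 0.4 vs 0.5) and their resistance counts only overlap with
non-macrophage cells, reflecting amoeboid migration.

**Fields.** Oxygen is sourced at vessels and consumed by stromal and
tumour cells; CSF-1 and TGF-β are produced by tumour cells; CXCL12 at
vessels; EGF by macrophages at rate κ_ε p. Each field advances by
explicit 5-point finite differences with sub-stepping inside the
diffusive stability bound, and decay is applied as an exact exponential
factor (operator splitting), so a uniform field decays as `e^(−λt)` to
machine precision. Point sources deposit on the nearest node as rate/h².
Concentrations are clamped non-negative, which bounds point consumption
by availability. TGF-β is deliberately short-ranged
(decay length ~1.8 diameters) so that it reports *depth inside the tumour
mass* rather than tumour size; the conversion threshold g_crit = 0.8 is
reached only at depth ≳ 1.5 diameters (the boundary value is ≈ 0.5
independent of tumour size in the relevant range).

**Cell behaviour.** Stromal and tumour cells progress through an
oxygen-gated cycle (mean 16 h, per-cell jitter ±25%; stroma cycles 10×
slower, making it near-quiescent filler tissue). Below the type's hypoxic
threshold the clock pauses reversibly; below the necrosis threshold the
cell dies irreversibly, then shrinks linearly over 30 h and is removed.
Compression pauses the cycle (contact inhibition) when the effective area
— from the nearest-neighbour distance — falls below 85% (stroma) or 45%
(tumour) of the rest area. Macrophages extravasate from vessels at
`P* c/(c + c_1/2)` per hour with phenotype 0 and an expired kill
cooldown; their phenotype ratchets up at Δp = 0.12 per hour wherever
TGF-β exceeds g_crit and never decreases; they kill one random tumour
cell within R_int per event with probability per hour
`P*_φ (1 − p¹⁰/(p¹⁰ + 0.5¹⁰))` (zero during the 10 h cooldown), turning
it necrotic.

**Initial condition.** A ~30-cell tumour disc at the centre, a jittered
stromal lattice (spacing 1.8) elsewhere, and 20 vessels placed uniformly
with minimum pairwise separation 4 and at least 12 diameters from the
centre, so that tumour cells reach the vasculature only by directed
migration, not by initial adjacency. Oxygen is pre-relaxed to its
vessel-supplied steady profile so cells do not start in spurious anoxia;
the other fields start at zero. Event probabilities are rate·dt, guarded
by the requirement rate·dt ≤ 1.

**Regime structure.** The defaults were chosen so that the three
qualitative immunoediting outcomes appear at the intended corners of the
(χ_c, c_1/2) plane by 150 h: at χ_c = 1 macrophage drive cannot beat the
tissue's yield resistance, so macrophages stay in the stroma and at the
rim, the tumour is contained by oxygen limitation and rim killing
(Equilibrium); at χ_c = 1.5 with c_1/2 = 0.3 the extravasation rate
roughly doubles and the larger M1 population at the rim — which never
sees supra-threshold TGF-β and so keeps killing — clears the tumour
(Elimination); at χ_c = 3.5 macrophages punch into the core, convert
before killing much, exit towards vessels up CXCL12 (χ_ξ = 6 exceeds the
yield resistance of the tumour ring) and lay EGF trails that tumour cells
follow to the vasculature (Escape). These parameter values are the
package's own calibration of rate constants the model family does not pin
down; they were tuned only against these qualitative regimes, never
against classification accuracy. Tumour cells that reach a vessel remain
in the domain — intravasation is not modelled — so an Escape-state tumour
can still be eliminated later, which is exactly the transition the
trajectory analysis exhibits.

**Reduced scale.** Simulations run to t = 150 h on a 40 × 40 domain with
~500–1500 agents (a few tens of seconds each), rather than the long
horizons and HPC ensembles a full study would use; the tests therefore
check regime identity, calibration and separability, not any published
percentage. The reduced-scale classification uses correspondingly
coarsened signature grids (dr = 0.5 with 38 bins, 51 mark values):
at ~150 macrophages per snapshot, 0.1-diameter annuli at small r hold so
few weighted pairs that their values are noise-dominated spikes which
PCA would latch onto. Determinism: one `numpy` Generator drives all stochastic
events, so identical (parameters, seed) give identical trajectories.

## Signature pipeline

A snapshot's PCF signature is `{wPCF(r,p,B), wPCF(r,p,T), g_BT(r)}`
computed on shared grids. Vectorisation concatenates the blocks in fixed
order (wPCF_B row-major with P outer, then wPCF_T, then g_BT) and imputes
undefined entries with 1 — the CSR no-correlation baseline, consistent
with tumour-free snapshots whose vessel–tumour statistic is trivially
uninformative; imputing 0 would inject a strong spurious "exclusion"
signal. The imputation mask is retained so the choice is auditable.

Auto-labelling applies, in order: Elimination if at most 5 tumour cells
remain; Escape if any tumour cell lies within 1 diameter of a vessel;
else Equilibrium. Both thresholds are configuration, since in real
applications such labels are assigned by inspection.

PCA is fitted on mean-centred training vectors; the component count is
truncated to what the sample supports (at most n_samples). The classifier
is an RBF-kernel SVM with scikit-learn's default regularisation and
kernel-width conventions over the leading principal components.
Train/test splits follow replicate index (early replicates train, the
last tests). Class centroids can be truncated to k components and mapped
back through the PCA basis into the three-block signature layout for
plotting. Projecting a time series of signatures gives a trajectory in
the reduced space; a single simulation can visit Equilibrium-, Escape-
and Elimination-like states at different times.

## Synthetic validation patterns

The line-of-crosses construction (200 crosses equally spaced on y = 1 of
a 2×2 square at midpoint positions, avoiding corner double-counting; 1000
uniform circles with mark |1−y| or |1−y|²) has a known wPCF ridge
(P = r, P = r²) and is the primary end-to-end check of the surface.
Circles are given category M so marks flow through the same code path as
macrophage phenotypes. CSR generators provide the calibration null
(every defined statistic has expectation 1); the banded generator
generalises the construction to arbitrary declared distance-to-mark laws
with bounded noise for ridge-recovery and robustness tests. The
generators emulate geometry and labelling only — none of the segmentation
noise, intensity variation or irregular tissue boundaries of real
multiplex data — so passing tests demonstrate correctness of the
estimators and pipeline, not robustness to imaging artefacts.

## Known limitations

* The mechanics are a minimal spring model; the displacement cap alters
  dynamics inside transiently jammed clusters, where the linear force law
  is least trustworthy anyway.
* The ABM calibration targets qualitative regime identity at reduced
  scale; rate constants are not fitted to biological measurements.
* The cross-PCF border correction assumes a rectangular window.
* Undefined-row imputation with the CSR baseline is one defensible
  choice; alternatives (masking, model-based imputation) would change the
  PCA geometry.
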