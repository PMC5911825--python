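# Methods

This note documents the models implemented in `covfes`, the numerical
choices behind them, and what the synthetic generators do and do not
emulate.

## Units and constants

Energies are kcal/mol, distances Å, angles degrees (radians internally),
temperatures K. k_B = 0.0019872041 kcal mol⁻¹ K⁻¹; the default temperature
is 300 K (k_BT ≈ 0.596 kcal/mol).

## Analytic reaction surfaces

The synthetic landscape standing in for a QM/MM reaction surface is

U(x, y) = k_c[(x−x_m)² + (y−y_m)²] − D_R G_R(x, y) − D_P G_P(x, y),

a quadratic confinement (k_c = 1 kcal mol⁻¹ Å⁻², centered midway between
the wells) minus two negative Gaussians at the reactant-like
(x ≈ 3.4, y ≈ 2.0) and product-like (x ≈ 1.9, y ≈ −1.5) positions. Any
two-basin family reproducing the diagonal reactant→product topology would
do; Gaussians-plus-confinement was chosen because calibration and
quadrature are cheap and closed-form-exact ground truth is available:

- **ΔA (reaction free energy)** = −k_BT ln(Z_P/Z_R) with each Z computed by
  2D trapezoid quadrature of exp(−U/k_BT) over a rectangular basin region
  (401 × 401 points per region by default).
- **Barrier** = the lowest level at which the two basin minima become
  connected in the sublevel set {U ≤ L} on a dense grid (binary search with
  connected-component labelling) minus the reactant minimum. This equals
  the maximum along the dense-grid minimax path, obtained far faster.

**Equal-curvature wells.** The two wells share the curvature of the
reactant well (Gaussian width ∝ √depth). With equal curvatures the
harmonic entropies of the basins cancel, so the region-quadrature ΔA
coincides with the difference of the well minima to within anharmonic
terms (< 0.05 kcal/mol at 300 K for the default geometry). This matters
because the pipeline's ΔA_reac is a difference of surface *minima*: with
unequal curvatures the two definitions would disagree by an entropic term
of several tenths of a kcal/mol and "recovering the calibrated truth"
would be ill-posed.

**Calibration** is nested 1D root finding (Brent): for each candidate
reactant depth, the product depth is solved so the quadrature ΔA matches
the request; the reactant depth is then solved so the flooding barrier
matches. The calibrated surface is verified to hit both targets within
0.05 kcal/mol, else a calibration error naming the offending parameter is
raised. A 1D double-well analogue (same construction one dimension down)
serves the proton-transfer profile.

## Umbrella windows and the Metropolis sampler

The restraint convention is **U_bias = k(ξ−ξ₀)² without the ½ factor**,
matching how spring constants like k = 100 kcal mol⁻¹ Å⁻² are quoted for
the engine that produced the original window data; a `half_convention`
flag switches to ½k(ξ−ξ₀)². Canonical ladders are provided as constants:
x from 3.6 to 1.8 Å in 0.1 Å steps (19 windows), y over 26 windows of
0.2 Å from 2.8 Å (2.8 → −2.2 Å; the printed −2.0 endpoint and the printed
26-window count disagree by one step, and the count — corroborated by the
494-window total and the 24.7 ns aggregate — is taken as authoritative),
and r from 1 to −1 Å in 0.1 Å steps (21 windows).

Window sampling targets exp(−[U+U_bias]/k_BT) by alternating two
Metropolis kernels, each in detailed balance with the target:

1. a Gaussian random walk whose step is tuned to 30–60% acceptance during
   burn-in (default 10% of the requested samples) and then frozen;
2. an independence proposal from the bias Gaussian N(ξ₀, k_BT/2k), whose
   Hastings ratio reduces to exp(−ΔU/k_BT) in the bare potential; each
   accepted move fully decorrelates the chain.

A pure random walk leaves an integrated autocorrelation time of ~20 steps
under a k = 100 restraint, which makes the window-offset network too noisy
to resolve 0.1–0.2 kcal/mol differences at 2 × 10³ samples/window; the
alternating kernel brings the autocorrelation down to a few steps at the
same sample count. Windows with k = 0 on any axis use the random walk
throughout. Per-window seeds are `SeedSequence(master, spawn_key=(index,))`
and are recorded in the window metadata, so any window regenerated alone
is bit-identical to its batch-generated counterpart.

## WHAM

One solver covers 1D and 2D. Window samples are histogrammed on a shared
left-closed/right-open grid; the self-consistent equations

p_j ∝ M_j / Σ_i N_i exp[(f_i − c_ij)/k_BT],
exp(−f_i/k_BT) = Σ_j p_j exp(−c_ij/k_BT)

are solved by first minimizing the equivalent convex objective
(Zhu & Hummer, J. Comput. Chem. 33 (2012) 453) with L-BFGS and then
polishing with the fixed-point iteration until the maximum offset change
is ≤ 10⁻⁷ kcal/mol (default; max 10⁵ iterations, unconverged runs are
flagged, never silent). A = −k_BT ln p referenced to its minimum; empty
bins are masked rather than padded — pseudo-counts would bias exactly the
high-energy regions a barrier estimate depends on.

**Binning.** The default histogram refines the window ladder 3× per axis.
The bias energy enters at bin centers, which is accurate only while the
bias varies ≪ k_BT across a bin; at k = 100 and 2× refinement the
variation reaches ~0.4 k_BT per half-bin and produces a measured
systematic error of 0.2–0.3 kcal/mol in the reactant↔product offset,
which 3× refinement removes. Replacing center evaluation by a
uniform-within-bin average of exp(−βU_bias) was tested and rejected: the
biased density is concentrated, not uniform, within a bin, and the convex
average grossly overweights bins near window centers (errors > 1
kcal/mol).

**Uncertainty** is available two ways: Bayesian bootstrap (Dirichlet
weights over each window's samples, 50 resamples, per-bin SD) and the
time-block convention (re-running WHAM on windows truncated at increasing
end-points and reporting mean ± SD of a scalar extractor), the latter
matching how convergence is conventionally quoted for this protocol.

Diagnostics: pairwise histogram-overlap coefficients (Σ min of normalized
counts) with nearest-neighbour pairs flagged below threshold, and
Shapiro–Wilk normality per biased coordinate per window (the method is a
choice; series longer than 4096 points are thinned evenly because the W
statistic degenerates at very large n).

## Basins, paths, barriers

Local minima are found under 8-connectivity; every unmasked cell is
assigned by steepest descent with (value, cell-index) lexicographic
tie-breaking, which merges plateaus deterministically; an all-flat surface
yields one basin flagged degenerate. The minimum free-energy path is the
**minimax** (lowest-saddle) path: phase 1 computes the bottleneck level by
Dijkstra, phase 2 picks, inside the sublevel set, the path of minimal
total energy with deterministic tie-breaking (cells settle in (distance,
index) order and are never re-parented). The transition state is the
path's arg-max; ΔA_act = A(TS) − A(start) ≥ 0 and
ΔA_reac = A(end) − A(start). Minimax was chosen over steepest-descent or
string constructions because it is grid-native, deterministic, and
reproduces exactly the saddle energy that ΔA_act needs; "minimal total
energy" (rather than minimal mean) is used among tied paths because the
sum is prefix-monotone and hence Dijkstra-compatible.

## Boltzmann inversion and conformational statistics

The conformational surface is A = −k_BT ln P on a (distance, dihedral)
histogram: distance 2.5–9.5 Å in 0.1 Å classes; dihedral classes are 15°
wide. The nominal −160°…+160° span is not a multiple of 15°, so the
default keeps the class width exact — 21 classes centered on multiples of
15°, spanning [−157.5°, +157.5°) — and tallies everything else as
out-of-range (an exact-span mode with ~15.24° classes is available). The
reactive-conformation criterion is **strictly** d < 3.9 Å (a van-der-Waals
contact distance taken as a configuration constant, not re-derived from
force-field radii); H-bond occupancy uses d ≤ cutoff (3.5 Å heavy-atom
default). Both conventions are configurable.

State definitions are (label, dihedral interval, optional distance
interval); assignment takes the first matching definition, with
non-overlap enforced. The default states follow the observed basin
geometry (a: dihedral −55° ± 20°, distance 2.5–4.5 Å; b: +90°…+130°,
4.5–7.5 Å). Note that interval-style definitions truncate emission tails,
so occupancy *ratios* from them carry a small capture bias; for
free-energy-gap recovery the tests use a full midpoint partition of the
dihedral axis instead. The basin gap is ΔA(a→b) = −k_BT ln(P_b/P_a)
(negative ⇒ b more stable). Distance–dihedral coupling is quantified by
the point-biserial correlation of the distance against the
**dihedral-only** state label (distance constraints are stripped from the
definitions there, since they would correlate with the distance
mechanically), with a 1000-shuffle permutation p-value and the fraction of
state switches at which the distance crosses a 4.5 Å midline within ±5
snapshots.

## Two-state trajectory generator

A first-order hidden Markov chain with per-state Gaussian emissions for
the S–Cβ distance, the C1–C2–N1–C3 dihedral (wrapped into (−180°, 180°])
and an H-bond distance. Defaults are 4 replicas × 30 000 snapshots
(10 ps/frame, i.e. 300 ns per replica — the pooled 120 000 snapshots
mirror the study conditions). Two presets encode the two systems: a
gatekeeper-mutant-like model with equally populated states (a: 3.5 ± 0.4 Å,
−55° ± 15°; b: 5.5 ± 0.6 Å, +110° ± 10°) and a P-loop-mutant-like model
whose unreactive state b is stabilized by 1 kcal/mol (switch-probability
ratio exp(1/k_BT)) with state a shifted to 4.5 Å, b at 6.2 ± 0.45 Å, and a
short (2.9 ± 0.3 Å) H-bond emitted in b. Switch probabilities (0.01–0.02
per frame) give a handful of state visits per replica, resembling the
slow conformational exchange seen in such trajectories.

What the generator does **not** emulate: non-Gaussian and skewed
distance distributions, intra-state dynamics and autocorrelation beyond
the two-state switching, replica-to-replica drift, and any coupling of
the H-bond distance to the switching kinetics beyond state membership.
Passing recovery tests therefore demonstrates estimator correctness on
well-specified input, not robustness to real-trajectory pathologies; in
particular the preset reactive fractions are properties of the Gaussian
emissions, not predictions for any real system.

## Thermodynamic integration and replicate statistics

TI uses per-λ gradient series over a strictly increasing schedule in
(0, 1) (the 16-point water-swap schedule ships as a constant); the first
third of each series is discarded by default (matching a 10M-of-30M-move
burn-in convention) and the trapezoid is taken over the sampled range
only — no extrapolation to λ = 0/1 unless explicitly enabled (constant
extension). Replicate aggregation reports mean, SD (n−1) and SEM = SD/√n;
n = 1 yields zero spread and a `single` flag. ΔpKa lists aggregate the
same way.

## Pipeline determinism

`run_pipeline` drives simulate → wham → analyze → conffes → ti → report
from one YAML config with defaults echoed back and errors aggregated by
field name. Every stochastic stage receives
`SeedSequence(master, spawn_key=(stage,))`; identical config + seed
reproduces every artifact byte for byte (verified in the tests). Reports
are JSON; tables TSV; window files plain text with a YAML manifest.

## Problem sizes

Defaults were chosen so the full validation cycle runs on one CPU in a few
minutes: recovery studies use 2 × 10³ samples per window over the 494
windows (five seeds), 1D oracle checks use 5 × 10⁴ samples per window over
21 windows, and conformational recovery uses the pooled 1.2 × 10⁵
snapshots. At these sizes the recovered barrier and reaction free energy
carry a per-seed SD of ~0.1–0.15 kcal/mol, comfortably inside the 0.2
kcal/mol recovery contract.

## Known limitations

- The minimax path is grid-resolution-limited; saddle energies inherit
  the histogram discretization (measured ≈ −0.07 kcal/mol on the barrier
  at the default binning against a noise-free binned oracle).
- WHAM bias energies at bin centers assume fine bins; very stiff biases
  (k ≫ 100) need a larger `refine`.
- The independence kernel assumes the harmonic-bias Gaussian overlaps the
  within-window target; for potentials with gradients ≫ 2kσ it degrades
  toward pure random walk (it never biases the target, only the mixing).
- `profile_delta` compares basin minima, not basin integrals; for strongly
  anharmonic or unequal-curvature basins these differ.
- PDB support is deliberately minimal: fixed-column ATOM/HETATM records,
  first model only, no bond perception or trajectory formats.
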