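# Methods

This note records the models, numerical choices and limitations behind
`spherogen`, in the spirit of a methods appendix. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Cellular Potts simulation

**Model.** Each site of a 3D lattice carries a cell id (0 = medium).
The energy is the standard constrained-Potts form: quadratic penalties
λ_V (V_i − V_i^t)² and λ_A (A_i − A_i^t)² per cell plus contact energies
J^(c-c) and J^(c-m) per unlike neighbour pair. Dynamics are Metropolis:
a uniformly chosen site attempts to copy the label of a uniformly chosen
neighbour; ΔH ≤ 0 is always accepted, ΔH > 0 with probability
exp(−ΔH/T). One MCS = N attempts, N = lattice size. Equal-label
proposals are null attempts that still consume one of the N tries, so
the MCS time unit is configuration independent.

**Discrete geometry.** Neighbour shells follow the squared-Euclidean-
distance convention used by mainstream CPM software: order k collects
offsets with ‖δ‖² ∈ {1..k}, giving 6/18/26/32 neighbours for orders
1–4. Defaults: copy-source (Potts) order 3, contact order 4. The
surface area A_i entering the area constraint is counted with the
*contact-order* neighbourhood so the constraint and the contact terms
see a single geometry. Boundaries are fixed walls: sites outside the
box count as medium both as contact partners and as copy sources, which
is the physically right picture for a spheroid surrounded by medium
(periodic boundaries would wrap cells onto themselves).

**Targets.** `assign_targets` draws a uniform derangement of the cells
and gives cell i the initial actual (V, A) of cell P(i). Every cell is
therefore frustrated (its targets differ from its own start) while the
multiset of targets equals the multiset of actuals, preserving the
ensemble's size distribution. Cells may shrink to zero volume; a
vanished cell keeps its (unreachable) targets so that the energy stays
exactly consistent with incremental bookkeeping — its constant penalty
term cancels in every ΔH.

**Incremental bookkeeping.** The simulator caches per-cell V and A and
two global doubled contact-pair tallies; a single flip touches at most
2 + 32 cells, and the ΔH is assembled from those caches in O(neighbour
count). The test suite verifies, on thousands of random proposals, that
the incremental ΔH equals a from-scratch Hamiltonian recomputation to
1e-9 and that all caches equal brute-force recounts after long runs.

**Equilibrium validation.** The copy-from-neighbour kernel is the
biologically meaningful dynamics, but on tiny lattices it is not
reversible: a label with zero voxels can never be proposed again, and
the all-medium state is absorbing, so no literal-kernel chain can match
a Boltzmann distribution on a 2-site toy. `propose_and_apply` therefore
also offers a symmetric uniform-label proposal (the standard
modified-Metropolis variant used for ergodicity checks). With it, the
acceptance rule and ΔH machinery — the parts shared with the production
kernel — are validated against exp(−H/T)/Z on an exactly enumerable
2-site system, with recorded samples thinned (every 4th MCS) so the
3σ multinomial bound applies to approximately independent draws.

**Temperature.** T = 30 is the calibrated value alongside the Table of
defaults; it is exposed unchanged and not auto-scaled for other lattice
sizes, since the energy scale depends on cell volumes through the
quadratic constraints.

## Parameter scan and metric m

The scan simulates every (λ_V, λ_A, J^(c-c), J^(c-m)) combination of a
Cartesian grid (defaults: {0.001, 2, 4, 6, 8, 10}² × {0.0001, 2, 4, 6,
8, 10} × {10, 55, 100}; 648 combinations) from one cleaned start volume
and ranks ascending by m = mean_W · mean_IoU. Feature distributions are
compared in raw units via the 1-D Wasserstein distance (quantile-
function integral, `scipy.stats.wasserstein_distance`); IoU is per start
cell, with vanished cells contributing 0 and dropping out of the end
feature distribution. Each combination gets a seed derived from the
parameter values themselves, so duplicated combinations give identical
records and any execution schedule yields the same table.

Taken literally, the product form scores a completely frozen run
(all W_k = 0, IoU = 1) as m = 0 even though freezing defeats the
purpose of the simulation; mean_W and mean_IoU are therefore always
reported separately so frozen runs are visible. The implementation
keeps the literal product.

## Label cleaning and morphometrics

Cleaning removes labels with < 5 voxels or spanning < 4 z-planes
(near-certain stitching errors at typical acquisition settings), then
applies a per-label 3×3×3 closing and one dilation, both writing into
background only with lower labels winning conflicts, so labels never
merge. The removal + closing steps are idempotent; the dilation, by
definition, grows one voxel into the remaining medium on each
application, so the full operation is not (a second pass adds another
boundary shell where medium remains). z-up-sampling replicates planes
by nearest neighbour to the in-plane pixel size.

The seven features use: voxel-count volume; exposed-face (6-neighbour)
surface area — deliberately the same discrete definition as the CPM's
area, accepting the staircase bias in exchange for cross-module
consistency (a marching-cubes estimator would be smoother but
inconsistent with the simulation's energy); V/A ratio; axis lengths as
4·sqrt(λ) of the coordinate-covariance eigenvalues (ellipsoid
convention); sphericity π^(1/3)(6V)^(2/3)/A; and meridional
eccentricity sqrt(1 − λ_min/λ_max). Features are computed after
isotropic up-sampling. Single-voxel labels get zero axes and
eccentricity with a warning.

## Phantom data

All stages are testable without external recordings via phantoms. The
spheroid phantom samples n seed points uniformly in a ball and labels
each in-ball voxel by its nearest seed. Three Lloyd-relaxation rounds
(seeds moved to cell centroids) turn the raw Poisson-Voronoi mosaic
into a near-centroidal tessellation; this choice is deliberate: raw
Poisson-Voronoi cells are substantially more eccentric than cells in a
dense spheroid interior, whereas centroidal Voronoi tessellations are
the standard geometric model of packed tissue. Defaults (64³ box,
radius 28, 50 cells) give a mean cell diameter of ~15 voxels, i.e. a
realistic nucleus-to-cell size relation at the working resolution while
staying desk-scale. Prototypes are solid axis-aligned ellipsoids
(semi-axes uniform in [3, 6] voxels) textured with Gaussian-smoothed
white noise rescaled to [0.3, 1.0] — placement and imaging need
plausible non-constant texture, not a chromatin model.

What the phantoms do *not* emulate: intensity inhomogeneity across
cells, necrotic cores, proliferation gradients, touching-nuclei
ambiguity, or anisotropic raw voxels. Passing tests on phantoms
validates the machinery (energies, placement rules, metric
definitions), not biological fidelity of any particular dataset.

## Nucleus placement

Per cell (ascending label order): draw a prototype uniformly; rotate it
by the minimal-angle rotation taking its major principal axis onto the
cell's (skipped for near-spherical cells, axis ratio within 5%); scale
isotropically so the voxelised mask volume is within 5% of
volume_ratio · V_cell (a single centre-based affine resampling per
candidate scale, refined a few iterations — naive `zoom` endpoint
mapping distorts small arrays); then try up to 10 positions drawn from
an isotropic Gaussian at the cell centroid (σ = sigma_frac · r_eq,
rejected until inside the cell's bounding box), accepting the first
whose overlap with *unoccupied* cell voxels reaches overlap_threshold.
After 5 prototypes without success the cell is skipped. Accepted
nuclei write max-blended intensity over the full mask (soft boundary)
but label only mask ∩ cell voxels, with the label equal to the parent
cell id so borders, membranes and nuclei stay joinable — which also
makes nuclei pairwise disjoint by construction.

Defaults volume_ratio = 0.35, overlap_threshold = 0.8,
sigma_frac = 0.15: the mechanisms are fixed but the values are free
parameters of the method; σ = 0.15·r_eq keeps nuclei near-central,
consistent with the placement contract that at ratio 0.3 the vast
majority of placed nuclei occupy 0.25–0.35 of their cell once boundary
clipping is accounted for (larger spreads push a noticeable fraction of
nuclei below that band through clipping at the cell surface).

## Imaging simulation

Applied in acquisition order: (1) exponential depth attenuation
exp(−z·Δz/attenuation_depth) from the first plane (decay length in um;
∞ disables); (2) normalised anisotropic Gaussian PSF truncated at 4σ
(σ in um, converted with the voxel spacing; constant images are fixed
points, interior signal mass is conserved to 1e-6); (3) integer block-
average downsampling with trailing remainders cropped and spacing
rescaled — instance labels are downsampled alongside by majority vote
with ties to the lowest label; (4) Poisson shot noise at a photon gain
plus additive Gaussian read-out noise, clipped at zero. A neutral
configuration is the exact identity.

## GAN objectives and instance labels

The generator contract is a two-channel output: nuclei signal ŷ and a
soft binary label channel v̂ sharing the decoder features. Objectives
are implemented in their literal log forms — conditional:
L_cGAN + L_sGAN + λ_L1·L_L1 with L_cGAN = E[log D(y,x)] +
E[log(1−D(ŷ,x))], L_sGAN the same for the unconditional label
discriminator D_Seg (which may be fed unpaired label pools), and L_L1
the mean absolute error; cycle-consistent: L_GAN_A + L_GAN_B + L_GAN_S
+ λ_cyc(E|x−x̃| + E|y−ỹ|). Discriminator outputs are ε-clamped
(default 1e-7) before logs. λ_L1 = 100 and λ_cyc = 10 follow the
conventional pix2pix/CycleGAN settings; practical trainers often swap
the log terms for least-squares surrogates, which is out of scope —
the log form is the specified contract. The soft v̂ (not a thresholded
copy) is what D_Seg sees.

Instance labels are recovered from v̂ by thresholding (default 0.5),
subtracting the binary membrane (splitting nuclei that touch across a
cell boundary), a binary opening with a radius-1 ball against
speckle, and assigning every remaining foreground voxel the simulated
cell label underneath — foreground over medium is removed by that
assignment. Threshold and radius are exposed; the defaults are the
smallest values that suppress single-voxel artifacts without eroding
plausible nuclei.

The smoke training harness exists to show the objectives are
optimisable and finite end to end. Its built-in backend is a tiny numpy
model family (per-voxel logistic generators, pooled-statistic logistic
discriminators) updated by simultaneous-perturbation gradient estimates
of the minimax objective on ≤16³ volumes for ≤200 iterations. It is a
contract check, not a trainer; any framework-backed (G, D) pair obeying
the same I/O contract can be plugged in.

## Quality measures

**KID.** Unbiased squared MMD with kernel k(a,b) = (a·b/d + 1)³.
Volumes are scored slice-wise and averaged over the three plane
families; per direction, MMD² is averaged over 20 random subsets of 50
slices (reduced with a warning on thin stacks), following the usual KID
subset protocol. For equal sample sizes the equal-size U-statistic
(cross diagonal excluded) is used so that element-wise identical sets
score exactly 0; for unequal sizes the standard unbiased estimator with
the full cross term is used. The two conventions cannot be unified: the
exact-zero property requires the pairing-dependent form, single-sample
permutation invariance the other; the package prioritises exact zero
and documents that at equal sizes only joint permutations leave the
value unchanged. Kernel products use fixed-order per-element reductions
(einsum) so the cancellation is bitwise exact. The default feature
extractor is a fixed random orthogonal projection of 32×32-resized
slices to d = 64 — deterministic and dependency-free; an InceptionV3
adapter can be substituted where pretrained weights exist, in which
case resizing/normalisation choices follow that model's preprocessing.

**SEG/DET.** A ground-truth object matches the predicted label covering
a strict majority (> 0.5) of its voxels; at most one such label exists.
SEG is the mean Jaccard over GT objects (unmatched → 0). DET is
1 − min(AOGM-D, AOGM-D0)/AOGM-D0 with AOGM-D = 5·NS + 10·FN + 1·FP
(splits, false negatives, false positives) and AOGM-D0 = 10·|GT| — the
weights are the external Cell Tracking Challenge convention, not
quantities derived here. The crop protocol scores a whole-image
prediction cropped to the ground-truth patch, so border objects are
segmented in full context and objects outside the crop never count as
false positives.

## Problem sizes and determinism

Default working scales are deliberately desk-size: 16³–64³ lattices,
20–50 cells, 20–1000 MCS; the acceptance script runs the full pipeline
(two independent replicates, 1000 MCS each at 64³) in a few minutes on
one CPU thanks to the compiled Metropolis kernel. All randomness flows
from one top-level seed through named substreams (stage name → seed),
so adding a stage never perturbs another stage's draws and every run is
bit-reproducible; per-MCS kernel streams are derived from the run seed
and the MCS index.

## Known limitations

- Absolute CPM parameter values transfer from other implementations
  only approximately: internal area tracking conventions differ between
  codebases, and the face-pair definition here is one specific choice.
- No cell division, death, chemotaxis, type-dependent contact matrices,
  or connectivity constraints; cells can fragment or vanish at hot
  parameter settings (vanishing is logged).
- The membrane "appearance" path stops at binary membranes; turning
  them into realistic membrane textures is a learned transformation
  outside this package's scope.
- The default KID extractor is *not* InceptionV3; absolute KID values
  are not comparable to published numbers, only relative comparisons
  within one extractor are meaningful.
- Placement guarantees no minimum nucleus spacing beyond cell
  containment, and prototype diversity is bounded by the prototype
  database.
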