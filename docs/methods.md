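# Methods

This note documents the models, estimators and conventions implemented in
`sweetmsm`, the choices made where the design was genuinely open, and the
limits of what the synthetic validation shows.

## The toy transporter

**Potential.** The generator defines an analytic potential over the
collective variables (CVs) of an alternate-access transporter: the
extracellular gating distance `d_ec` (Å), the intracellular gating distance
`d_ic` (Å), the ligand channel coordinate `z_lig` (Å, positive toward the
extracellular side) and the ligand facial angle `theta_face` (degrees,
periodic with period 360°). The potential is a sum of inverted anisotropic
Gaussian basins plus a quadratic wall outside the declared per-dimension
bounds. This form was chosen over, e.g., polynomial double wells because it
is smooth, has a closed-form gradient, and basin depths/positions/widths
are individually tunable.

The default configuration places four basins emulating the conformational
cycle of a sugar transporter:

| basin | d_ec (Å) | d_ic (Å) | z_lig (Å) | θ_face (°) | depth (kcal/mol) |
|-------|---------|---------|----------|-----------|------------------|
| IF    | 4       | 13      | −15      | 135       | 4.0 |
| OC    | 5       | 5       | 0        | 180       | 2.5 |
| HG    | 9       | 9       | 5        | 225       | 3.0 |
| OF    | 13      | 4       | 15       | 270       | 2.8 |

IF is deepest (the resting state of a concentration-gradient-driven
uniporter), the HG basin sits at an ~9 Å aperture on both gates, the ligand
z centers span 30 Å so trajectories traverse ~40 Å of channel, and each
basin carries a distinct facial angle. Basin widths are (2.5, 2.5, 6, 50)
in the four dimensions — wide enough that a desk-scale Langevin campaign
can connect the basins; depth differences of 0.2–1.5 kcal/mol set the
population ordering. Units are Å, degrees and kcal/mol throughout, with
kT = 0.5961 kcal/mol at 300 K. A two-basin variant over (d_ec, d_ic)
(`double_well_config`, depths 2.6/1.6 kcal/mol, saddle ≈ 1.9 kcal/mol above
the deep well) is the workhorse for quantitative landscape checks.

**Integrator.** Overdamped Euler–Maruyama,
`x' = x − (dt/γ)∇U + sqrt(2 kT dt/γ) ξ`, with fixed dt (default 0.02 in toy
time units) and friction γ = 1. The scheme's stationary bias is O(dt) and
negligible at the tolerances tested (the 1-D harmonic stationary variance
test passes at 5% with dt = 0.01). The facial angle is propagated on the
circle and wrapped at 360°. Leaving the bounded domain by more than its
span raises an integration-instability error naming the step. All
randomness flows through `numpy.random.default_rng(seed)`; identical seeds
give bit-identical trajectories.

**Embedding.** Latent frames are realized as 3-D bead coordinates: twelve
channel residues on two hexagonal rings (z = ±6 Å) whose radii breathe with
the gating distances, four single-bead gating residues placed exactly
`d_ec`/`d_ic` apart on the x (extracellular, z = +10) and y (intracellular,
z = −10) axes, one aromatic ring, and 6-bead ligand copies. The transported
copy's reference atom sits at `z_lig` above the protein center of mass and
the copy's COM is displaced from it by 1.5 Å along (0, cos θ, sin θ), so
the yz-plane facial angle equals `theta_face` exactly; decoy copies sit
30 Å from the channel axis. Because the embedding computes the protein COM
per frame and places the ligand relative to it, measurement∘embedding is
the identity on (d_ec, d_ic, z_lig, θ_face) to machine precision — the
basis of all geometric round-trip tests.

**What the toy does not emulate.** No atomistic force field, solvent,
membrane or thermostat artifacts; no rugged local minima within basins; no
coupling between protein fluctuations and ligand orientation beyond the
constructed one; feature noise is purely geometric. Passing tests therefore
demonstrate the correctness of the analysis machinery, not the adequacy of
any specific MSM hyperparameters for real MD data.

## Adaptive sampling

Least-counts seeding: per round, the accumulated frames (configurable to
per-round scope) are clustered by k-means on the active metric; clusters
are ranked by ascending population with ties to the lower cluster index;
seeds are drawn round-robin along that ranking, each pick taking the
not-yet-chosen frame nearest the cluster center. The metric schedule is a
list of stages (gating distances → ligand z → both), each with a trigger —
round count, bound-state reached, or landscape stall (convergence check
true for n consecutive rounds). The stall tolerance has no
literature-derived default; it is a config value (default 0.25 kcal/mol
mean absolute change with <1% finite-bin growth). Campaign transcripts
(clusters, populations, seeds, trajectories) are pure functions of
(config, master seed).

## MSM construction and validation

**tICA.** Mean-free data; instantaneous covariance symmetrized over both
time ends; time-lagged covariance symmetrized as (C(τ)+C(τ)ᵀ)/2; ridge ε on
C(0) (default 1e−10) guards singularity. The generalized symmetric
eigenproblem is solved with `scipy.linalg.eigh`; components are ordered by
descending eigenvalue and normalized to unit variance under C(0). Tests
compare eigenpairs against an independent dense non-symmetric solve of
C(0)⁻¹C(τ) to 1e−8.

**Microstates.** Seeded `sklearn` k-means. The spec-level operations
(`cluster_microstates`, least-counts clustering, CK macrostate lumping) use
scikit-learn behind the module surface; everything statistical about the
MSM itself is implemented here.

**Reversible estimation.** Sliding-window counts at lag τ; trajectories
shorter than τ+1 are excluded (a model should only use trajectories at
least as long as its lag); the largest strongly connected component of the
count graph is retained. The reversible maximum-likelihood transition
matrix comes from the standard fixed-point iteration on the symmetric flux
matrix X (X_ij ∝ π_i T_ij): `X_ij ← (C_ij + C_ji)/(c_i/x_i + c_j/x_j)`,
tolerance 1e−10 on the X increment, at most 1e5 sweeps. Detailed balance
holds by construction; π is read off the flux row sums. Frame weights are
π_i/N_i for frames in active microstate i and 0 outside; they sum to 1.

**Implied timescales.** t_k(τ) = −τ/ln λ_{k+1}(τ). Eigenvalues ≤ 0 are
flagged and reported as NaN. The convergence verdict — relative spread
below 10% across the upper half of the lag ladder — is a numeric stand-in
for the visual inspection practitioners use; the threshold is ours.

**VAMP-2.** For indicator functions on microstates the covariances are
diagonal, so the whitened operator is
K = diag(c₀)^{−1/2} C₀₁ diag(c₁)^{−1/2}; the score is the sum of squared
singular values truncated at the requested rank, constant singular function
included (score = 1 for a single state; 1 + Σλ² for an exact reversible T).
VAMP-2 without cross-validation is the default; shuffle-split scoring was
considered and left out as the grid-search ranking on toy data did not
require it.

**Reweighting validation.** Raw microstate populations versus π, with a
Theil–Sen slope and the worst |log₁₀(π/f)|; the pass thresholds (slope
within 0.25 of 1, max log-ratio ≤ 0.5) are configurable. Equilibrium data
lands on x = y; deliberately biased campaigns do not, while their
reweighted landscapes recover the analytic reference — the package's
core bias-removal check.

**Chapman–Kolmogorov.** Macrostates by k-means on the top
(m−1) non-trivial right eigenvectors of T (a light-weight metastable
lumping; full PCCA+ memberships are out of scope; user-supplied sets are
accepted). For each factor k, set-to-set probabilities predicted by T(τ)^k
are compared with those re-estimated at lag kτ; confidence bands are
percentile bootstrap over trajectories (default 95%); the test passes when
at least 95% of finite comparison points fall inside the bands. Factors
whose lag exceeds every trajectory are skipped with a warning.

## Landscapes

ΔG_bin = −kT ln(p_bin/p_max) from the weighted 2-D histogram; the global
minimum is 0 by construction and empty bins are masked (NaN — serialized as
empty fields, never 0 or +inf). Default binning is 60×60 over the observed
range padded 2%; validation scenarios bin over the potential's declared CV
domain instead, since least-counts campaigns push excursions into the
confining wall where the landscape is an artifact of the confinement.
When two landscapes are compared they are each anchored at their global
minimum over the evaluated bins — the "ΔG = 0 at the lowest state"
convention. The analytic reference for a binned landscape integrates the
Boltzmann weight over each bin (midpoint quadrature, 4 sub-points per
axis), which is the quantity a histogram estimates; comparing against
bin-center energies instead would conflate discretization with estimator
error.

Barriers: strict 8-neighborhood minima over finite bins; the barrier from
state a to b is the minimax path height over 8-connected finite bins minus
ΔG(a) (Dijkstra with max-along-path cost). Requested states snap to the
nearest minimum. A fully flat landscape has no strict minima but returns a
trivial barrier of 0. Whether published barrier readings follow
minimum-energy paths or bin differences is generally unstated; the minimax
path is this package's convention and matches how landscapes are read
visually.

Bootstrap errors: subsets of trajectories drawn without replacement
(default 200 subsets of 80%, trajectory granularity), MSM re-estimated per
subset against the fixed cluster assignments, landscape rebuilt on fixed
bins; the per-bin standard deviation across subsets is the error surface,
defined where at least two subsets have a finite value. Subsets whose
connected set is empty are dropped and counted.

## Ligand geometry

θ_xy is measured from the +X axis, counterclockwise, in [0, 360); θ_xz and
θ_yz take the first named axis as zero. Only relative sectors and the 180°
facial boundary carry meaning, so the zero direction is a convention —
fixed here and documented. The transported copy is the one whose COM lies
in the channel cylinder (protein-COM-centered, default radius 6 Å), ties
resolved toward the axis then the lower copy index. The protein COM is
computed over protein heavy beads with unit masses — appropriate for the
toy bead model, and the single convention used throughout; +z is
extracellular by declaration, never inferred.

Per-residue RMSD compares every frame pair between two state ensembles
after least-squares superposition on the alignment selection
(`scipy.spatial.transform.Rotation.align_vectors`); tables carry
mean ± SD and n = |A|·|B| pairs, and significance uses Welch's two-sided
t-test from the summary statistics at α = 0.05 and 0.01.

Contact classification applies, per ligand-atom/protein-atom pair, the
precedence hydrogen bond > CH···π > van der Waals with one class per pair:
vdW within r_i + r_j + 0.5 Å; hydrogen bond at donor–acceptor ≤ 3.5 Å with
a D–H···A angle ≥ 110° when a hydrogen position is supplied (bead
topologies carry none, so the distance criterion alone applies);
CH···π for a carbon within 4.5 Å of an aromatic ring centroid with the
centroid direction within 60° of the ring normal. These are conventional
contact-analysis defaults, all overridable. Residue frequency tables drop
residues contacting the ligand in under 1% of frames.

LIE energies are explicit Lennard-Jones pair sums with Lorentz–Berthelot
combining and a 12 Å default cutoff; the summary drops frames outside
1.5×IQR of the per-frame energy distribution ("outliers removed" is
otherwise underspecified) and reports mean ± SD of the rest.

## Descriptor selection

From metastable states harvested at landscape minima (strict 8-neighbor
minima; frames within 1 bin by default), filtered to k-medoids centers
(from-scratch PAM, 100 seeded restarts, ties to the lowest frame index —
scikit-learn has no k-medoids), the candidate features are inverse pairwise
Cβ distances (Cα for glycines) over the configurable channel-residue set.
The dispersion statistic is the standard deviation of each pair's inverse
distance across states; dispersions are z-scored across pairs and pairs
with z > 3 are selected. Whether the z-scoring in the published procedure
runs over mean distances or dispersions is ambiguous; dispersion directly
encodes "extent of change in the measured distance" and is used here, with
the threshold configurable. Zero variance across all pairs yields an empty
selection with a warning rather than an error.

## Pipeline

Stages run in order sample → embed → featurize → msm → landscape → ligand;
a stage failure is recorded and downstream stages are skipped while earlier
artifacts persist. Per-stage seeds are the first four bytes of
SHA-256("master:stage") reduced mod 2³¹ — independent streams without
config bloat. Array archives are written with fixed zip timestamps so
identical (config, seed) runs are byte-identical; every artifact is
checksummed into the run report. Default pipeline hyperparameters (8
rounds × 5 seeds × 800 frames; tICA lag 10, 3 tICs, 40 clusters, MSM lag
40, ITS ladder 10–80, CK factors 2 and 3) were chosen so the default toy
run completes in well under a minute on one CPU and the three validation
verdicts pass on the default configuration; they are starting points, not
recommendations for real data.

## Validation scenarios and problem sizes

The `benchmarks` module fixes the study conditions used by the test suite
and `scripts/acceptance.py`: equilibrium Boltzmann recovery uses a 400k-step
double-well run, 50 microstates, lag 25, 20×20 domain bins, and requires
RMSE < 0.3 kT over bins with ≥ 100 effective (Kish) samples; the
bias-removal scenario runs a 16-round × 10-seed × 2500-frame least-counts
campaign (60 within-round clusters keep the seeding aggressive) and
requires the raw histogram to err by > 1 kT somewhere well-sampled while
the MSM-reweighted landscape meets the equilibrium criterion; CK
discrimination uses 15 × 4000-step chains, passing on Markovian data and
failing on a 2-state lumping of a 3-state chain with a slow internal
transition; bootstrap sanity uses 50 subsets at 80% (a scaled-down version
of the 200-subset procedure) and checks zero error for duplicated data and
a shrinking median when the dataset is quadrupled. Oracle checks (tICA
eigenpairs, VAMP-2 closed form, LIE brute force) run at 1e−8/1e−10
absolute tolerances on well-conditioned fixtures.

## Known limitations

- The reversible MLE is dense; state spaces beyond a few thousand
  microstates would need the sparse formulation.
- CK macrostating by eigenvector k-means can split genuinely metastable
  sets on noisy spectra; supply explicit sets when that matters.
- The landscape-stall trigger compares landscapes on the binning of the
  first round it sees, so late excursions outside that range do not count
  toward "growth".
- No kinetics beyond implied timescales (no MFPT/TPT), no hidden Markov
  models, no electrostatic LIE term, no pore-radius profiles.
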