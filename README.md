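# sweetmsm

Markov-state-model analysis of transporter–substrate selectivity, exercised
end-to-end on a synthetic toy transporter.

Membrane transporters such as the *Arabidopsis* sugar transporter AtSWEET13
move substrates by alternate access: the channel opens alternately to the
intracellular and extracellular side, passing through occluded and
hourglass-like intermediates. Characterizing how such a protein
discriminates between substrates (glucose versus sucrose, say) from
molecular-dynamics data requires a long analysis chain: adaptive sampling to
cover the conformational cycle, agnostic feature selection, time-lagged
independent component analysis (tICA), Markov state model (MSM) estimation
and validation, MSM-reweighted free-energy landscapes with bootstrap errors,
and ligand-centric geometric analyses of facial and positional selectivity.
Every link in that chain can silently go wrong, and on real MD data there is
no ground truth to catch it.

`sweetmsm` re-implements that chain as a tested, reusable library, and pairs
it with a synthetic data generator — an analytic multi-basin potential over
transporter collective variables, sampled by Langevin dynamics and embedded
as 3-D bead coordinates — so that every operation can be validated against
exact ground truth. It is aimed at computational biophysicists who build
MSM pipelines and want their machinery verified before pointing it at real
trajectories.

## The model

The toy potential lives on the collective variables
(d_EC, d_IC, z_lig, θ_face): the extracellular and intracellular gating
distances (Å), the ligand position along the channel axis (Å), and the
ligand facial angle (degrees, periodic). It is a sum of inverted
anisotropic Gaussian basins plus a quadratic confining wall,

    U(x) = − Σ_b D_b exp(−½ Σ_d (x_d − c_bd)² / w_bd²) + wall(x),

with four basins by default — inward-facing (IF, deepest), occluded (OC),
hourglass (HG, ~9 Å aperture on both gates), and outward-facing (OF) —
sampled by overdamped Euler–Maruyama Langevin dynamics at kT = 0.5961
kcal/mol (300 K). The embedding places gate beads exactly d_EC and d_IC
apart and realizes z_lig and θ_face exactly, so measurement is the exact
inverse of generation.

On top of this the package implements, from scratch:

- **least-counts adaptive sampling** with a staged metric schedule
  (gating → ligand z → combined) and a landscape-stall convergence rule;
- **tICA** as the symmetrized generalized eigenproblem C(τ)v = λC(0)v;
- **reversible MSM estimation** by detailed-balance-constrained maximum
  likelihood, implied timescales t_k(τ) = −τ/ln λ_{k+1}(τ), VAMP-2 scored
  hyperparameter grid search, raw-versus-reweighted count validation, and
  the Chapman–Kolmogorov test with bootstrap confidence bands;
- **MSM-weighted free-energy landscapes** ΔG = −kT ln(p/p_max) with
  minimax-path barriers and the 200-subset / 80% bootstrap error procedure;
- **ligand selectivity analyses**: transported-copy selection among
  interchangeable ligand copies, θ_xy spinning and θ_xz/θ_yz flipping
  angles, atom z position, per-residue RMSD state comparisons with Welch
  t-tests, contact classification (vdW / hydrogen bond / CH···π), and
  Lennard-Jones linear interaction energies.

## Worked example

Estimate a reversible MSM from an equilibrium run on the built-in
double-well potential and read a barrier off the reweighted landscape:

```python
import numpy as np
from sweetmsm import toysim, msm, landscapes

pot = toysim.make_transporter_potential(toysim.double_well_config())
traj = toysim.simulate_langevin(pot, pot.centers[0], n_steps=200_000,
                                dt=0.05, seed=7)

dtrajs, _ = msm.cluster_microstates([traj.cvs], k=50, seed=0)
model = msm.estimate_msm(dtrajs, lag=25)
weights = np.concatenate(msm.frame_weights(model, dtrajs))
grid = landscapes.free_energy_landscape(
    traj.cvs[:, 0], traj.cvs[:, 1], weights,
    edges=(np.linspace(1, 15, 21), np.linspace(1, 15, 21)),
    kT=pot.kT, x_name="d_ec", y_name="d_ic")

minima, barrier = landscapes.find_minima_and_barrier(grid, (5, 14), (14, 5))
t2 = -model.lag / np.log(model.eigenvalues(2)[1])
print(f"local minima found: {len(minima)}")
print(f"barrier deep->shallow: {barrier:.2f} kcal/mol ({barrier/pot.kT:.1f} kT)")
print(f"slowest implied timescale: {t2:.0f} frames at lag {model.lag}")
```

This prints:

```
local minima found: 11
barrier deep->shallow: 1.95 kcal/mol (3.3 kT)
slowest implied timescale: 810 frames at lag 25
```

The barrier matches the analytic saddle of the configured potential
(1.94 kcal/mol) to within one bin's discretization error. The minima list
contains the two configured wells plus shallow noise minima from finite
sampling; `find_minima_and_barrier` snaps the requested states to the
nearest genuine minima, and the slowest implied timescale (~810 frames)
reflects the inter-well exchange.

The full pipeline — campaign, featurization, MSM with validation verdicts,
landscapes, θ/z series — runs from the command line:

```sh
sweetmsm run-all --seed 1 --out my_run
```

and exits 0 only when the implied-timescale, reweighting and CK validations
all pass.

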