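"""End-to-end validation scenarios on the toy transporter.

Each function runs one self-contained study: it generates its own data with
the package's generators, runs the analysis under test, and returns the
measured quantities together with the problem size.  These scenarios back
both the acceptance test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

from . import features, landscapes, ligandgeom, msm, sampling, toysim

# ---------------------------------------------------------------------------
# Boltzmann recovery and bias removal
# ---------------------------------------------------------------------------


def _domain_edges(potential, bins=20):
    return (np.linspace(*potential.bounds[0], bins + 1),
            np.linspace(*potential.bounds[1], bins + 1))


def _anchored_deviation_kT(potential, G, ok, ref):
    """Deviation between two landscapes, each anchored at its global minimum
    over the evaluated bins (the ``dG = 0 at the lowest state`` convention)."""
    dev = (G - G[ok].min()) - (ref - ref[ok].min())
    return (float(np.sqrt(np.mean(dev[ok] ** 2)) / potential.kT),
            float(np.abs(dev[ok]).max() / potential.kT))


def _landscape_rmse_kT(potential, xs, ys, weights, bins=20, ess_min=100,
                       edges=None):
    if edges is None:
        edges = _domain_edges(potential, bins)
    grid = landscapes.free_energy_landscape(xs, ys, weights, kT=potential.kT,
                                            edges=edges)
    ref = toysim.binned_reference_free_energy(potential, grid.x_edges,
                                              grid.y_edges)
    ok = np.isfinite(grid.free_energy) & (grid.effective_samples >= ess_min)
    rmse, mx = _anchored_deviation_kT(potential, grid.free_energy, ok, ref)
    return rmse, mx, int(ok.sum()), grid


def boltzmann_recovery(seed: int = 1, n_steps: int = 400_000) -> dict:
    """MSM-weighted free-energy landscape of an equilibrium double-well
    Langevin run versus the analytic potential (RMSE in kT over bins with at
    least 100 effective samples)."""
    pot = toysim.make_transporter_potential(toysim.double_well_config())
    lat = toysim.simulate_langevin(pot, pot.centers[0], n_steps=n_steps,
                                   dt=0.05, seed=seed)
    dtrajs, _ = msm.cluster_microstates([lat.cvs], k=50, seed=seed)
    model = msm.estimate_msm(dtrajs, lag=25)
    w = np.concatenate(msm.frame_weights(model, dtrajs))
    rmse, _, n_bins, _ = _landscape_rmse_kT(pot, lat.cvs[:, 0], lat.cvs[:, 1], w)
    return {"rmse_kT": rmse, "n": n_steps, "n_bins": n_bins}


def bias_removal(seed: int = 1, n_rounds: int = 16, n_seeds: int = 10,
                 traj_len: int = 2500) -> dict:
    """Least-counts adaptive campaign on the double well: the raw histogram
    deviates from the analytic landscape while the MSM-reweighted landscape
    recovers it.

    Fine within-round clustering (60 clusters) keeps the least-counts
    seeding aggressive -- rare frontier regions are heavily oversampled --
    while 2500-frame trajectories leave enough transitions at the MSM lag
    for a well-conditioned reversible estimate.
    """
    pot = toysim.make_transporter_potential(toysim.double_well_config())
    sched = sampling.MetricSchedule([sampling.Stage("gating")])
    camp = sampling.run_campaign(pot, pot.centers[0], sched,
                                 n_rounds=n_rounds, n_seeds=n_seeds,
                                 traj_len=traj_len, k_clusters=60, dt=0.04,
                                 seed=seed)
    cvs = camp.all_cvs()
    dtrajs, _ = msm.cluster_microstates([t.cvs for t in camp.trajectories],
                                        k=75, seed=seed)
    model = msm.estimate_msm(dtrajs, lag=40)
    w = np.concatenate(msm.frame_weights(model, dtrajs))
    msm_rmse, _, n_bins, grid = _landscape_rmse_kT(pot, cvs[:, 0], cvs[:, 1], w)
    # raw histogram on the same bins, raw counts as the sampling criterion
    raw_grid = landscapes.free_energy_landscape(
        cvs[:, 0], cvs[:, 1], kT=pot.kT, edges=(grid.x_edges, grid.y_edges))
    ref = toysim.binned_reference_free_energy(pot, grid.x_edges, grid.y_edges)
    ok = np.isfinite(raw_grid.free_energy) & (raw_grid.counts >= 100)
    _, raw_max = _anchored_deviation_kT(pot, raw_grid.free_energy, ok, ref)
    return {"raw_max_dev_kT": raw_max, "msm_rmse_kT": msm_rmse,
            "n": int(cvs.shape[0]), "n_bins": n_bins}


# ---------------------------------------------------------------------------
# closed forms and oracles
# ---------------------------------------------------------------------------


def its_closed_form(seed: int = 1, n_steps: int = 100_000) -> dict:
    """Implied timescale of a 2-state chain: exact from the eigenvalue, and
    estimated from a finite simulation."""
    T = np.array([[0.95, 0.05], [0.10, 0.90]])
    lam2 = float(np.sort(np.linalg.eigvals(T))[0].real)
    t2_exact = -1.0 / np.log(lam2)
    model = msm.MSMModel(lag=1, active_set=np.arange(2), T=T,
                         pi=msm.stationary_distribution(T), reversible=False)
    t2_model = -1.0 / np.log(model.eigenvalues(2)[1])
    d = msm.simulate_chain(T, n_steps, seed=seed)
    its = msm.implied_timescales([d], lags=[1], n_timescales=1,
                                 reversible=True)
    t2_est = float(its.timescales[0, 0])
    return {
        "exact_abs_err": abs(t2_model - t2_exact),
        "estimated_rel_err": abs(t2_est - t2_exact) / t2_exact,
        "t2_exact": t2_exact, "n": n_steps,
    }


def tica_oracle_deviation(seed: int = 1, n_frames: int = 400,
                          n_features: int = 6) -> dict:
    """Worst deviation between the package tICA eigenpairs and a dense
    generalized eigensolver over random instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(5):
        X = rng.normal(size=(n_frames, n_features)).cumsum(axis=0) * 0.01
        X = X + rng.normal(size=X.shape)
        model = msm.tica_fit(X, lag=3, regularization=0.0)
        _, c0, ct = msm._tica_covariances([X], 3)
        evals = np.sort(np.real(scipy.linalg.eig(np.linalg.solve(c0, ct))[0]))[::-1]
        worst = max(worst, float(np.abs(model.eigenvalues - evals).max()))
        for k in range(n_features):
            v = model.components[:, k]
            resid = ct @ v - model.eigenvalues[k] * (c0 @ v)
            worst = max(worst, float(np.abs(resid).max()))
    return {"max_abs_deviation": worst, "n": 5 * n_frames}


def vamp2_closed_form_deviation(seed: int = 1, n_states: int = 6) -> dict:
    """VAMP-2 of exact reversible transition matrices versus
    ``1 + sum lambda_k^2``."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(5):
        C = rng.uniform(0.1, 2.0, size=(n_states, n_states))
        C = C + C.T
        T = C / C.sum(axis=1, keepdims=True)
        lam = np.sort(np.real(scipy.linalg.eigvals(T)))[::-1]
        expect = 1.0 + float(np.sum(lam[1:] ** 2))
        worst = max(worst, abs(msm.vamp2_from_transition_matrix(T) - expect))
    return {"max_abs_deviation": worst, "n": 5 * n_states}


def lie_oracle_deviation(seed: int = 1, n_frames: int = 5) -> dict:
    """LIE pair sums versus an explicit brute-force double loop."""
    rng = np.random.default_rng(seed)
    n_l, n_r = 5, 8
    # two spatially separated groups keep every pair distance >= ~4 A, so
    # the energies stay at physical magnitudes and absolute agreement with
    # the double loop is meaningful
    coords = rng.uniform(0, 5, size=(n_frames, n_l + n_r, 3))
    coords[:, n_l:, 0] += 9.0
    eps = rng.uniform(0.05, 0.3, n_l + n_r)
    sig = rng.uniform(2.5, 3.8, n_l + n_r)
    res = ligandgeom.lie_vdw(coords, range(n_l), range(n_l, n_l + n_r),
                             eps, sig, cutoff=1e6)
    worst = 0.0
    for f in range(n_frames):
        expect = 0.0
        for i in range(n_l):
            for j in range(n_l, n_l + n_r):
                r = np.linalg.norm(coords[f, i] - coords[f, j])
                e = np.sqrt(eps[i] * eps[j])
                s = 0.5 * (sig[i] + sig[j])
                expect += 4 * e * ((s / r) ** 12 - (s / r) ** 6)
        worst = max(worst, abs(res.energies[f] - expect))
    return {"max_abs_deviation": worst, "n": n_frames * n_l * n_r}


# ---------------------------------------------------------------------------
# Chapman-Kolmogorov behavior
# ---------------------------------------------------------------------------


def ck_behavior(seed: int = 1, n_traj: int = 15, traj_len: int = 4000) -> dict:
    """CK test outcome on Markov-simulated data and on a constructed
    non-Markovian lumping of a 3-state chain."""
    T = np.array([[0.95, 0.05, 0.0],
                  [0.05, 0.90, 0.05],
                  [0.0, 0.10, 0.90]])
    dtrajs = [msm.simulate_chain(T, traj_len, seed=seed * 1000 + i)
              for i in range(n_traj)]
    model = msm.estimate_msm(dtrajs, lag=1)
    good = msm.ck_test(dtrajs, model, n_macrostates=2, factors=(2, 3, 5),
                       n_bootstrap=30, seed=seed)
    Tn = np.array([[0.98, 0.02, 0.0],
                   [0.05, 0.93, 0.02],
                   [0.0, 0.02, 0.98]])
    lump = np.array([0, 1, 1])
    bad_d = [lump[msm.simulate_chain(Tn, traj_len, seed=seed * 2000 + i)]
             for i in range(n_traj)]
    bad_model = msm.estimate_msm(bad_d, lag=1)
    bad = msm.ck_test(bad_d, bad_model, n_macrostates=2, factors=(5, 10, 25),
                      n_bootstrap=30, seed=seed)
    return {
        "markov_fraction_within": good.fraction_within,
        "markov_passed": good.passed,
        "nonmarkov_fraction_within": bad.fraction_within,
        "nonmarkov_passed": bad.passed,
        "n": n_traj * traj_len,
    }


# ---------------------------------------------------------------------------
# geometry and descriptors
# ---------------------------------------------------------------------------


def geometric_exactness() -> dict:
    """Unit-case theta angles plus embed->measure round trips."""
    worst = 0.0
    cases = [((1.0, 0.0), 0.0), ((0.0, 1.0), 90.0), ((-1.0, -1.0), 225.0)]
    for (dx, dy), expect in cases:
        ts = ligandgeom.theta_xy(np.array([[dx, dy, 2.0]]), np.zeros((1, 3)))
        worst = max(worst, abs(ts.theta[0] - expect))
    for (dy, dz), expect in [((1.0, 0.0), 0.0), ((0.0, 1.0), 90.0)]:
        ts = ligandgeom.theta_face(np.array([[0.0, dy, dz]]),
                                   np.zeros((1, 3)), plane="yz")
        worst = max(worst, abs(ts.theta[0] - expect))
    thetas = np.array([170.0, 179.5, 180.5, 225.0])
    cvs = np.column_stack([np.full(4, 8.7), np.full(4, 12.3),
                           np.full(4, 5.0), thetas])
    lat = toysim.LatentTrajectory(cvs=cvs, times=np.arange(4), seed=0,
                                  dim_names=toysim.TRANSPORTER_DIMS)
    top = toysim.make_toy_topology()
    traj = toysim.embed_coordinates(lat, top)
    gs = features.gating_distances(traj)
    worst = max(worst, float(np.abs(gs.d_ec - 8.7).max()),
                float(np.abs(gs.d_ic - 12.3).max()))
    com = traj.protein_com()
    atoms = top.ligand_copies[0]
    z = ligandgeom.atom_z_position(traj.coords[:, atoms[0]], com)
    worst = max(worst, float(np.abs(z - 5.0).max()))
    lig_com = traj.coords[:, atoms].mean(axis=1)
    ts = ligandgeom.theta_face(traj.coords[:, atoms[0]], lig_com, plane="yz")
    worst = max(worst, float(np.abs(ts.theta - thetas).max()))
    return {"max_abs_error_deg_or_A": worst, "n": len(cases) + 2 + 4}


def planted_descriptor_recovery(seed: int = 1, n_decoys: int = 50,
                                factor: float = 10.0) -> dict:
    """Agnostic z-score selection must recover exactly the planted
    high-dynamic-range pair among the decoys."""
    rng = np.random.default_rng(seed)
    n_states, sigma0 = 12, 0.02
    base = 8.0 + rng.uniform(-1, 1, size=n_decoys + 1)
    dists = base + rng.normal(0, sigma0 * base**2,
                              size=(n_states, n_decoys + 1))
    planted = n_decoys // 2
    dists[:, planted] = base[planted] + rng.normal(
        0, factor * sigma0 * base[planted] ** 2, size=n_states)
    names = [f"pair{i}" for i in range(n_decoys + 1)]
    sel = features.select_agnostic_descriptors(dists, names, threshold=3.0)
    return {
        "exact_recovery": sel.selected == [names[planted]],
        "planted_z": float(sel.z_scores[planted]),
        "n_selected": len(sel.selected),
        "n": n_decoys + 1,
    }


# ---------------------------------------------------------------------------
# bootstrap error sanity
# ---------------------------------------------------------------------------


def bootstrap_sanity(seed: int = 1, n_subsets: int = 50,
                     traj_len: int = 1500) -> dict:
    """Bootstrap error landscape: zero for duplicated data, shrinking when
    the dataset is quadrupled."""
    pot = toysim.make_transporter_potential(toysim.double_well_config())

    def dataset(n_traj, seed0):
        lats = [toysim.simulate_langevin(pot, pot.centers[i % 2],
                                         n_steps=traj_len - 1, dt=0.05,
                                         seed=seed0 + i)
                for i in range(n_traj)]
        dtrajs, _ = msm.cluster_microstates([t.cvs for t in lats], k=25,
                                            seed=seed)
        obs = [(t.cvs[:, 0], t.cvs[:, 1]) for t in lats]
        return obs, dtrajs

    obs, dtrajs = dataset(4, seed * 100)
    err_dup = landscapes.bootstrap_error_landscape(
        obs * 4, dtrajs * 4, msm_lag=10, bins_or_edges=10, n_subsets=2,
        frac=0.999, seed=seed)
    dup_max = float(np.nanmax(err_dup.error))
    medians = []
    for n_traj in (6, 24):
        obs, dtrajs = dataset(n_traj, seed * 200)
        err = landscapes.bootstrap_error_landscape(
            obs, dtrajs, msm_lag=10, bins_or_edges=10, n_subsets=n_subsets,
            frac=0.8, seed=seed)
        medians.append(float(np.nanmedian(err.error)))
    return {
        "duplicated_max_sd": dup_max,
        "median_sd_small": medians[0],
        "median_sd_quadrupled": medians[1],
        "shrinks": medians[1] < medians[0],
        "n": n_subsets,
    }


# ---------------------------------------------------------------------------
# analytic reference quantity
# ---------------------------------------------------------------------------

#: Printed axis lengths (A) of the all-atom simulation box the toy system
#: stands in for: 80 x 80 x 101.
BOX_AXES = (80.0, 80.0, 101.0)


def simulation_box_volume() -> dict:
    """Rectangular box volume from the printed axis lengths."""
    return {"volume_A3": toysim.box_volume(BOX_AXES), "n": 3}
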