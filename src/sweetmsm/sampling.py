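"""Adaptive-sampling campaign driver: least-counts seeding, a staged metric
schedule, and a landscape-convergence stopping rule.

Each round, the accumulated latent frames are clustered by k-means on the
active sampling metric; clusters are ranked by ascending population and new
trajectories are seeded round-robin from the least-populated clusters (the
frame nearest each cluster center is the restart state).  This deliberately
oversamples rare regions -- the bias an MSM later removes.  The metric
schedule mirrors a staged campaign: gating distances first, ligand channel
position once a substrate is bound, then both combined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from . import landscapes as _landscapes
from .errors import InvalidConfigError, InvalidParameterError
from .toysim import LatentTrajectory, ToyPotential, simulate_langevin

# named metrics: which latent CV columns drive the clustering
METRIC_COLUMNS = {
    "gating": ("d_ec", "d_ic"),
    "ligand_z": ("z_lig",),
    "combined": ("d_ec", "d_ic", "z_lig"),
}


def metric_values(trajectories: list[LatentTrajectory], metric: str) -> np.ndarray:
    """Stacked (n_frames_total, m) metric matrix over all trajectories."""
    if metric not in METRIC_COLUMNS:
        raise InvalidConfigError(f"unknown metric {metric!r}")
    cols = METRIC_COLUMNS[metric]
    present = trajectories[0].dim_names
    use = [c for c in cols if c in present]
    if not use:
        # toy potentials without a ligand dimension fall back to all CVs
        use = list(present)
    return np.vstack([np.column_stack([t.column(c) for c in use]) for t in trajectories])


# ---------------------------------------------------------------------------
# least-counts seed selection
# ---------------------------------------------------------------------------


@dataclass
class SeedSet:
    frame_indices: np.ndarray  # global frame indices into the stacked metric
    cluster_labels: np.ndarray  # cluster of each seed
    populations: np.ndarray  # per-cluster populations


def least_counts_seeds(metric_vals: np.ndarray, k_clusters: int, n_seeds: int,
                       seed: int = 0) -> SeedSet:
    """Seed states from the least-populated k-means clusters.

    Clusters are ranked by ascending population (ties toward the lower
    cluster index); seeds are drawn round-robin over that ranking, taking
    per pick the not-yet-chosen frame nearest the cluster center.
    """
    X = np.atleast_2d(np.asarray(metric_vals, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and metric_vals.ndim == 1:
        X = X.T
    n = X.shape[0]
    if n_seeds < 1:
        raise InvalidParameterError("n_seeds must be >= 1")
    if n_seeds > n:
        raise InvalidParameterError(f"n_seeds={n_seeds} exceeds {n} frames")
    k_clusters = min(k_clusters, n)
    km = KMeans(n_clusters=k_clusters, random_state=seed, n_init=5).fit(X)
    labels, centers = km.labels_, km.cluster_centers_
    pops = np.bincount(labels, minlength=k_clusters)
    order = np.lexsort((np.arange(k_clusters), pops))  # ascending pop, low index first
    # frames of each cluster sorted by distance to center (stable: low index first)
    per_cluster = []
    for c in order:
        members = np.nonzero(labels == c)[0]
        d = np.linalg.norm(X[members] - centers[c], axis=1)
        per_cluster.append(members[np.argsort(d, kind="stable")])
    chosen, chosen_labels = [], []
    ptr = [0] * len(per_cluster)
    while len(chosen) < n_seeds:
        progressed = False
        for ci, frames in enumerate(per_cluster):
            if len(chosen) >= n_seeds:
                break
            while ptr[ci] < len(frames) and frames[ptr[ci]] in chosen:
                ptr[ci] += 1
            if ptr[ci] < len(frames):
                chosen.append(int(frames[ptr[ci]]))
                chosen_labels.append(int(order[ci]))
                ptr[ci] += 1
                progressed = True
        if not progressed:
            break
    return SeedSet(frame_indices=np.array(chosen, dtype=int),
                   cluster_labels=np.array(chosen_labels, dtype=int),
                   populations=pops)


# ---------------------------------------------------------------------------
# metric schedule
# ---------------------------------------------------------------------------


@dataclass
class Stage:
    """One stage of the sampling-metric schedule.

    ``trigger`` advances past this stage once fired:
      - ("round_count", n): after n completed rounds
      - ("bound_state", dim, lo, hi): once any frame has dim inside [lo, hi]
      - ("landscape_stall", n_rounds, tol): landscape convergence check true
        for n_rounds consecutive rounds
    """

    metric: str
    trigger: tuple | None = None


@dataclass
class MetricSchedule:
    stages: list[Stage]

    def __post_init__(self):
        if not self.stages:
            raise InvalidConfigError("schedule needs at least one stage")
        for st in self.stages:
            if st.metric not in METRIC_COLUMNS:
                raise InvalidConfigError(f"unknown metric {st.metric!r}")


def default_schedule(stall_rounds: int = 3, stall_tol: float = 0.25) -> MetricSchedule:
    """Gating distances, then ligand z once binding stalls the landscape,
    then both combined."""
    return MetricSchedule(stages=[
        Stage("gating", trigger=("landscape_stall", stall_rounds, stall_tol)),
        Stage("ligand_z", trigger=("bound_state", "z_lig", -5.0, 10.0)),
        Stage("combined", trigger=None),
    ])


@dataclass
class CampaignState:
    """Pure record of a campaign's progress used for trigger evaluation."""

    round_index: int = 0
    trajectories: list = field(default_factory=list)
    stall_streaks: dict = field(default_factory=dict)  # stage index -> streak


def _trigger_fired(stage_i: int, stage: Stage, state: CampaignState) -> bool:
    trig = stage.trigger
    if trig is None:
        return False
    kind = trig[0]
    if kind == "round_count":
        return state.round_index >= trig[1]
    if kind == "bound_state":
        dim, lo, hi = trig[1], trig[2], trig[3]
        for t in state.trajectories:
            if dim in t.dim_names:
                z = t.column(dim)
                if np.any((z >= lo) & (z <= hi)):
                    return True
        return False
    if kind == "landscape_stall":
        return state.stall_streaks.get(stage_i, 0) >= trig[1]
    raise InvalidConfigError(f"unknown trigger kind {kind!r}")


def metric_schedule_step(state: CampaignState, schedule: MetricSchedule) -> str:
    """Active metric: the first stage whose trigger has not fired; the last
    stage persists indefinitely.  Evaluation is pure."""
    for i, stage in enumerate(schedule.stages):
        if not _trigger_fired(i, stage, state):
            return stage.metric
    return schedule.stages[-1].metric


# ---------------------------------------------------------------------------
# convergence rule
# ---------------------------------------------------------------------------


def convergence_check(landscape_t, landscape_prev, tol: float = 0.25) -> bool:
    """True iff the mean |dG| change over mutually finite bins is below
    ``tol`` and the finite-bin set grew by less than 1%."""
    mean_dev, growth = _landscapes.landscape_difference(landscape_prev, landscape_t)
    return bool(mean_dev < tol and growth < 0.01)


# ---------------------------------------------------------------------------
# campaign driver
# ---------------------------------------------------------------------------


@dataclass
class RoundRecord:
    round_index: int
    metric: str
    populations: list
    seeds: list  # (trajectory index, frame index) pairs
    n_new_trajectories: int


@dataclass
class Campaign:
    trajectories: list[LatentTrajectory]
    rounds: list[RoundRecord]
    seed: int

    def all_cvs(self) -> np.ndarray:
        return np.vstack([t.cvs for t in self.trajectories])


def _global_to_local(trajectories, global_idx: int):
    pos = 0
    for ti, t in enumerate(trajectories):
        if global_idx < pos + len(t):
            return ti, global_idx - pos
        pos += len(t)
    raise InvalidParameterError("seed frame outside accumulated dataset")


def run_campaign(
    potential: ToyPotential,
    x0,
    schedule: MetricSchedule,
    n_rounds: int,
    n_seeds: int = 5,
    traj_len: int = 200,
    k_clusters: int = 20,
    dt: float = 0.02,
    friction: float = 1.0,
    seed: int = 0,
    kT: float | None = None,
    scope: str = "all",  # cluster "all" recorded rounds or "round" only
) -> Campaign:
    """Run an adaptive-sampling campaign with the toy Langevin propagator.

    Round r: stack the in-scope frames, evaluate the schedule, cluster on the
    active metric, pick least-counts seeds, and propagate ``n_seeds`` new
    trajectories of ``traj_len`` frames from the seed states.  The whole
    transcript is a pure function of ``(config, seed)``.
    """
    if scope not in ("all", "round"):
        raise InvalidConfigError("scope must be 'all' or 'round'")
    ss = np.random.SeedSequence(seed)
    init_seed = int(ss.generate_state(1)[0] % (2**31))
    first = simulate_langevin(potential, x0, n_steps=traj_len - 1, dt=dt,
                              friction=friction, seed=init_seed, kT=kT)
    trajectories = [first]
    last_round = [first]
    rounds: list[RoundRecord] = []
    state = CampaignState(round_index=0, trajectories=trajectories)
    prev_landscape = None
    for r in range(n_rounds):
        pool = trajectories if scope == "all" else last_round
        metric = metric_schedule_step(state, schedule)
        vals = metric_values(pool, metric)
        round_seed = int(np.random.SeedSequence((seed, r, 1)).generate_state(1)[0] % (2**31))
        seeds = least_counts_seeds(vals, k_clusters=k_clusters,
                                   n_seeds=n_seeds, seed=round_seed)
        offset = 0 if scope == "all" else sum(len(t) for t in trajectories[: -len(last_round)])
        seed_pairs = []
        new_trajs = []
        for si, gidx in enumerate(seeds.frame_indices):
            ti, fi = _global_to_local(pool, int(gidx))
            if scope == "round":
                ti = len(trajectories) - len(last_round) + ti
            seed_pairs.append((int(ti), int(fi)))
            x_start = trajectories[ti].cvs[fi]
            prop_seed = int(
                np.random.SeedSequence((seed, r, 2, si)).generate_state(1)[0] % (2**31)
            )
            new_trajs.append(
                simulate_langevin(potential, x_start, n_steps=traj_len - 1, dt=dt,
                                  friction=friction, seed=prop_seed, kT=kT)
            )
        trajectories.extend(new_trajs)
        last_round = new_trajs
        rounds.append(RoundRecord(round_index=r, metric=metric,
                                  populations=[int(p) for p in seeds.populations],
                                  seeds=seed_pairs,
                                  n_new_trajectories=len(new_trajs)))
        state = CampaignState(round_index=r + 1, trajectories=trajectories,
                              stall_streaks=dict(state.stall_streaks))
        # update landscape-stall streaks on the active stage's metric dims
        vals_now = metric_values(trajectories, metric)
        if vals_now.shape[1] >= 2:
            xs, ys = vals_now[:, 0], vals_now[:, 1]
        else:
            xs, ys = vals_now[:, 0], vals_now[:, 0]
        edges = None
        if prev_landscape is not None:
            edges = (prev_landscape.x_edges, prev_landscape.y_edges)
        try:
            grid = _landscapes.free_energy_landscape(
                xs, ys, bins=24, kT=potential.kT,
                edges=edges if edges is not None else None,
            )
        except Exception:  # pragma: no cover - degenerate tiny campaigns
            grid = None
        for i, stg in enumerate(schedule.stages):
            if stg.trigger and stg.trigger[0] == "landscape_stall":
                tol = stg.trigger[2]
                if grid is not None and prev_landscape is not None and convergence_check(
                    grid, prev_landscape, tol
                ):
                    state.stall_streaks[i] = state.stall_streaks.get(i, 0) + 1
                else:
                    state.stall_streaks[i] = 0
        if grid is not None:
            prev_landscape = grid
    return Campaign(trajectories=trajectories, rounds=rounds, seed=int(seed))


def export_restart_pdbs(campaign: Campaign, topology, outdir) -> list:
    """Write each round's seed states as single-model PDB restart files.

    Returns the list of written paths, one per (round, seed) pair.
    """
    from pathlib import Path

    from . import io as _io
    from .toysim import LatentTrajectory, embed_coordinates

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for rec in campaign.rounds:
        for si, (ti, fi) in enumerate(rec.seeds):
            lat = campaign.trajectories[ti]
            frame = np.vstack([lat.cvs[fi], lat.cvs[fi]])  # 2-frame minimum
            single = LatentTrajectory(cvs=frame, times=np.arange(2),
                                      seed=lat.seed, dim_names=lat.dim_names)
            traj = embed_coordinates(single, topology)
            path = outdir / f"round{rec.round_index:03d}_seed{si:03d}.pdb"
            _io.write_pdb_multiframe(topology, traj.coords[:1], path)
            written.append(path)
    return written


def campaign_transcript(campaign: Campaign) -> dict:
    """JSON-serializable transcript of rounds, metrics and seeds."""
    return {
        "schema": "sweetmsm/campaign-v1",
        "seed": campaign.seed,
        "n_trajectories": len(campaign.trajectories),
        "rounds": [
            {
                "round": r.round_index,
                "metric": r.metric,
                "populations": r.populations,
                "seeds": [list(s) for s in r.seeds],
                "n_new_trajectories": r.n_new_trajectories,
            }
            for r in campaign.rounds
        ],
    }
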