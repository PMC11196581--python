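"""End-to-end pipeline orchestration.

Wires the stages together -- generate/sample -> embed -> featurize -> MSM
construction and validation -> MSM-weighted landscapes with bootstrap errors
-> ligand selectivity analyses -> report -- with per-stage seeds derived
from a master seed and an artifact manifest with checksums, so a run is a
pure function of (config, master seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import features as _features
from . import io as _io
from . import landscapes as _landscapes
from . import ligandgeom as _ligandgeom
from . import msm as _msm
from . import sampling as _sampling
from . import toysim as _toysim
from .errors import InvalidConfigError

SCHEMA_TAG = "sweetmsm/pipeline-v1"


def default_config() -> dict:
    return {
        "schema": SCHEMA_TAG,
        "seed": 1,
        "outdir": "sweetmsm_run",
        "toysim": {"potential": "default", "n_ligand_copies": 3},
        "sampling": {
            "n_rounds": 8, "n_seeds": 5, "traj_len": 800, "k_clusters": 15,
            "dt": 0.02, "friction": 1.0, "scope": "all",
            "stall_rounds": 3, "stall_tol": 0.25,
        },
        "msm": {
            "tica_lag": 10, "n_tics": 3, "k_clusters": 40, "lag": 40,
            "its_lags": [10, 20, 30, 40, 60, 80], "n_timescales": 2,
            "ck_factors": [2, 3], "ck_macrostates": 2, "ck_bootstrap": 20,
            "regularization": 1e-8,
        },
        "landscapes": {"bins": 32, "bootstrap": {"n_subsets": 20, "frac": 0.8}},
        "ligandgeom": {"atom": "C1", "theta_modes": ["xy", "yz"]},
        "units": {"length": "angstrom", "angle": "degree", "energy": "kcal/mol"},
    }


def stage_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed derived by hashing (master seed, stage name)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def load_config(path: str | Path) -> dict:
    path = Path(path)
    try:
        with open(path) as fh:
            if path.suffix in (".yaml", ".yml"):
                cfg = yaml.safe_load(fh)
            else:
                cfg = json.load(fh)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise InvalidConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise InvalidConfigError(f"{path} does not contain a mapping")
    merged = default_config()
    for k, v in cfg.items():
        if isinstance(v, dict) and isinstance(merged.get(k), dict):
            merged[k].update(v)
        else:
            merged[k] = v
    return merged


def validate_config(config: dict) -> list[str]:
    """Structural and semantic checks; an empty list means valid."""
    issues: list[str] = []
    if "seed" not in config or not isinstance(config["seed"], int):
        issues.append("seed: missing or not an integer")
    smp = config.get("sampling", {})
    msm_cfg = config.get("msm", {})
    lnd = config.get("landscapes", {})
    for key in ("tica_lag", "lag"):
        if msm_cfg.get(key, 1) < 1:
            issues.append(f"msm.{key}: must be >= 1")
    frac = lnd.get("bootstrap", {}).get("frac", 0.8)
    if not (0 < frac < 1):
        issues.append("landscapes.bootstrap.frac: must be in (0, 1)")
    traj_len = smp.get("traj_len", 0)
    if traj_len and msm_cfg.get("lag", 1) >= traj_len:
        issues.append(
            "msm.lag: trajectories must be at least as long as the MSM lag time "
            f"(traj_len={traj_len} <= lag={msm_cfg.get('lag')})"
        )
    n_frames = (smp.get("n_rounds", 0) * smp.get("n_seeds", 0) + 1) * traj_len
    if n_frames and msm_cfg.get("k_clusters", 1) > n_frames:
        issues.append("msm.k_clusters: exceeds the expected number of frames")
    if smp.get("n_seeds", 1) < 1:
        issues.append("sampling.n_seeds: must be >= 1")
    return issues


@dataclass
class RunReport:
    stages: dict = field(default_factory=dict)  # name -> "ok" | "failed: ..." | "skipped"
    validations: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)  # path -> sha256
    seed: int = 0

    @property
    def all_validations_passed(self) -> bool:
        return all(bool(v) for v in self.validations.values())

    def to_dict(self) -> dict:
        return {
            "schema": SCHEMA_TAG,
            "seed": self.seed,
            "stages": self.stages,
            "validations": {k: bool(v) for k, v in self.validations.items()},
            "artifacts": self.artifacts,
        }


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict | None = None) -> RunReport:
    """Execute all stages in order; a failed stage is recorded and the
    downstream stages are skipped, but prior artifacts are preserved."""
    cfg = config if config is not None else default_config()
    issues = validate_config(cfg)
    if issues:
        raise InvalidConfigError("; ".join(issues))
    master = int(cfg["seed"])
    outdir = Path(cfg.get("outdir", "sweetmsm_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=master)
    artifacts: list[Path] = []
    state: dict = {}

    def record(path: Path):
        artifacts.append(path)

    stages = [
        ("sample", _stage_sample),
        ("embed", _stage_embed),
        ("featurize", _stage_featurize),
        ("msm", _stage_msm),
        ("landscape", _stage_landscape),
        ("ligand", _stage_ligand),
    ]
    failed = False
    for name, fn in stages:
        if failed:
            report.stages[name] = "skipped"
            continue
        try:
            fn(cfg, master, outdir, state, report, record)
            report.stages[name] = "ok"
        except Exception as exc:  # noqa: BLE001 - report and stop
            report.stages[name] = f"failed: {exc}"
            failed = True
    for p in artifacts:
        if p.exists():
            report.artifacts[str(p.relative_to(outdir))] = _checksum(p)
    _io.save_json(outdir / "report.json", report.to_dict())
    return report


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _get_potential(cfg):
    pot_cfg = cfg["toysim"].get("potential", "default")
    if pot_cfg == "default":
        pot_cfg = _toysim.default_transporter_config()
    return _toysim.make_transporter_potential(pot_cfg)


def _stage_sample(cfg, master, outdir, state, report, record):
    smp = cfg["sampling"]
    potential = _get_potential(cfg)
    if smp.get("schedule", "staged") == "gating":
        schedule = _sampling.MetricSchedule([_sampling.Stage("gating")])
    else:
        schedule = _sampling.default_schedule(
            stall_rounds=smp.get("stall_rounds", 3),
            stall_tol=smp.get("stall_tol", 0.25))
    x0 = potential.centers[int(np.argmax(potential.depths))]
    campaign = _sampling.run_campaign(
        potential, x0, schedule,
        n_rounds=smp["n_rounds"], n_seeds=smp["n_seeds"],
        traj_len=smp["traj_len"], k_clusters=smp["k_clusters"],
        dt=smp["dt"], friction=smp["friction"],
        seed=stage_seed(master, "sample"), scope=smp.get("scope", "all"),
    )
    state["potential"] = potential
    state["campaign"] = campaign
    path = outdir / "campaign.json"
    _io.save_json(path, _sampling.campaign_transcript(campaign))
    record(path)


def _stage_embed(cfg, master, outdir, state, report, record):
    topology = _toysim.make_toy_topology(
        n_ligand_copies=cfg["toysim"].get("n_ligand_copies", 3)
    )
    state["topology"] = topology
    state["trajs"] = [_toysim.embed_coordinates(lat, topology)
                      for lat in state["campaign"].trajectories]


def _stage_featurize(cfg, master, outdir, state, report, record):
    gs = [_features.gating_distances(t) for t in state["trajs"]]
    fm = [_features.inverse_pairwise_cbeta_distances(t) for t in state["trajs"]]
    state["gating"] = gs
    state["features"] = fm
    path = outdir / "features.npz"
    _io.save_arrays(path, **{f"traj_{i:03d}": f.values for i, f in enumerate(fm)})
    record(path)
    manifest = outdir / "feature_names.csv"
    manifest.write_text("\n".join(fm[0].names) + "\n")
    record(manifest)


def _stage_msm(cfg, master, outdir, state, report, record):
    mc = cfg["msm"]
    feats = [f.values for f in state["features"]]
    tica = _msm.tica_fit(feats, lag=mc["tica_lag"], n_components=mc["n_tics"],
                         regularization=mc.get("regularization", 1e-8))
    proj = tica.transform(feats)
    dtrajs, cluster_model = _msm.cluster_microstates(
        proj, k=mc["k_clusters"], seed=stage_seed(master, "msm")
    )
    model = _msm.estimate_msm(dtrajs, lag=mc["lag"], reversible=True)
    its = _msm.implied_timescales(dtrajs, mc["its_lags"],
                                  n_timescales=mc["n_timescales"])
    reweight = _msm.reweighting_validation(dtrajs, model)
    ck = _msm.ck_test(dtrajs, model, n_macrostates=mc["ck_macrostates"],
                      factors=tuple(mc["ck_factors"]),
                      n_bootstrap=mc["ck_bootstrap"],
                      seed=stage_seed(master, "ck"))
    state.update(tica=tica, dtrajs=dtrajs, cluster_model=cluster_model,
                 model=model)
    report.validations["its_converged"] = bool(np.all(its.converged))
    report.validations["reweighting_x_eq_y"] = bool(reweight.passed)
    report.validations["ck_passed"] = bool(ck.passed)
    path = outdir / "msm.npz"
    _io.save_arrays(path, T=model.T, pi=model.pi,
                    active_set=model.active_set,
                    centers=cluster_model.centers,
                    its_lags=its.lags, its_timescales=its.timescales)
    record(path)
    meta = outdir / "msm.json"
    _io.save_json(meta, {
        "schema": SCHEMA_TAG, "lag": model.lag,
        "n_active": int(model.active_set.size),
        "its_converged": [bool(c) for c in its.converged],
        "reweight_slope": reweight.slope,
        "reweight_max_log10_ratio": reweight.max_log10_ratio,
        "ck_fraction_within": ck.fraction_within,
    })
    record(meta)


def _stage_landscape(cfg, master, outdir, state, report, record):
    lc = cfg["landscapes"]
    weights = _msm.frame_weights(state["model"], state["dtrajs"])
    xs = np.concatenate([g.d_ec for g in state["gating"]])
    ys = np.concatenate([g.d_ic for g in state["gating"]])
    grid = _landscapes.free_energy_landscape(
        xs, ys, np.concatenate(weights), bins=lc["bins"],
        kT=state["potential"].kT, x_name="d_ec", y_name="d_ic",
    )
    state["landscape"] = grid
    boot_cfg = lc.get("bootstrap", {})
    observables = [(g.d_ec, g.d_ic) for g in state["gating"]]
    boot = _landscapes.bootstrap_error_landscape(
        observables, state["dtrajs"], msm_lag=state["model"].lag,
        bins_or_edges=(grid.x_edges, grid.y_edges),
        n_subsets=boot_cfg.get("n_subsets", 20),
        frac=boot_cfg.get("frac", 0.8),
        seed=stage_seed(master, "bootstrap"), kT=state["potential"].kT,
    )
    path = outdir / "landscape.csv"
    _landscapes.landscape_to_long_dataframe(grid).to_csv(path, index=False)
    record(path)
    apath = outdir / "landscape.npz"
    _io.save_arrays(apath, free_energy=grid.free_energy, x_edges=grid.x_edges,
                    y_edges=grid.y_edges, bootstrap_error=boot.error)
    record(apath)


def _stage_ligand(cfg, master, outdir, state, report, record):
    lg = cfg["ligandgeom"]
    traj = state["trajs"][0]
    top = traj.topology
    copy_idx = _ligandgeom.select_transported_ligand(traj)
    atoms = top.ligand_copies[0]
    names = [top.atom_name[i] for i in atoms]
    ai = atoms[names.index(lg.get("atom", "C1"))]
    com = traj.protein_com()
    zs = _ligandgeom.atom_z_position(traj.coords[:, ai], com)
    lig_com = traj.coords[:, atoms].mean(axis=1)
    cols = {"frame": np.arange(traj.n_frames), "transported_copy": copy_idx, "z": zs}
    for mode in lg.get("theta_modes", ["xy", "yz"]):
        if mode == "xy":
            ts = _ligandgeom.theta_xy(traj.coords[:, ai], com, z=zs)
        else:
            ts = _ligandgeom.theta_face(traj.coords[:, ai], lig_com, plane=mode, z=zs)
        cols[f"theta_{mode}"] = ts.theta
    import pandas as pd

    path = outdir / "theta_series.csv"
    pd.DataFrame(cols).to_csv(path, index=False)
    record(path)
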