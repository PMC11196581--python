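"""Synthetic toy-transporter data generator.

Defines an analytic multi-basin potential over transporter collective
variables (extracellular gating distance ``d_ec``, intracellular gating
distance ``d_ic``, ligand channel position ``z_lig`` and ligand facial angle
``theta_face``), samples it with overdamped Langevin dynamics, and embeds the
latent states as 3-D bead coordinates.  Because the embedding is constructed
so that measurement is its exact inverse on the latent variables, every
downstream geometric operation can be tested against analytic ground truth.

The default potential emulates the alternate-access cycle of a sugar
transporter: four metastable conformational basins (inward-facing IF -- the
deepest, occluded OC, hourglass HG, outward-facing OF) over the two gating
distances, a ligand that traverses ~40 A of channel z, and a distinct facial
angle per basin.  Units are A, degrees and kcal/mol throughout; kT at 300 K
is 0.5961 kcal/mol.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as _io
from .errors import (
    EmbeddingError,
    IntegrationUnstableError,
    InvalidConfigError,
    InvalidParameterError,
)

#: Boltzmann constant times 300 K in kcal/mol.
KT_300K = 0.5961

THETA_PERIOD = 360.0


# ---------------------------------------------------------------------------
# potential
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyPotential:
    """Sum of inverted anisotropic Gaussian basins plus a confining
    quadratic wall outside the stated bounds.

    ``U(x) = -sum_b depth_b * exp(-0.5 * sum_d ((x_d - c_bd)/w_bd)^2) + wall``

    Periodic dimensions (the facial angle) wrap displacements at the period
    and carry no wall.
    """

    dim_names: tuple[str, ...]
    basin_names: tuple[str, ...]
    centers: np.ndarray  # (B, D)
    depths: np.ndarray  # (B,)
    widths: np.ndarray  # (B, D)
    periodic: np.ndarray  # (D,) bool
    bounds: np.ndarray  # (D, 2); ignored on periodic dims
    wall_k: float = 1.0  # kcal/mol/A^2
    kT: float = KT_300K

    def __post_init__(self):
        if self.centers.shape[0] < 1:
            raise InvalidConfigError("potential needs at least one basin")
        if np.any(self.widths <= 0):
            raise InvalidConfigError("basin widths must be positive")
        if np.any(self.depths < 0):
            raise InvalidConfigError("basin depths must be non-negative")

    @property
    def ndim(self) -> int:
        return self.centers.shape[1]

    def _delta(self, x: np.ndarray) -> np.ndarray:
        """Displacements x - center, wrapped on periodic dims; (..., B, D)."""
        d = x[..., None, :] - self.centers
        per = self.periodic
        if per.any():
            d = np.where(per, (d + THETA_PERIOD / 2) % THETA_PERIOD - THETA_PERIOD / 2, d)
        return d

    def _wall_excess(self, x: np.ndarray) -> np.ndarray:
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        exc = np.clip(x - hi, 0, None) + np.clip(x - lo, None, 0)
        return np.where(self.periodic, 0.0, exc)

    def energy(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        d = self._delta(x)
        g = np.exp(-0.5 * np.sum((d / self.widths) ** 2, axis=-1))  # (..., B)
        exc = self._wall_excess(x)
        return -np.sum(self.depths * g, axis=-1) + self.wall_k * np.sum(exc**2, axis=-1)

    def gradient(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        d = self._delta(x)
        g = np.exp(-0.5 * np.sum((d / self.widths) ** 2, axis=-1))
        basin = np.sum((self.depths[:, None] * g[..., None]) * d / self.widths**2, axis=-2)
        return basin + 2.0 * self.wall_k * self._wall_excess(x)


TRANSPORTER_DIMS = ("d_ec", "d_ic", "z_lig", "theta_face")


def default_transporter_config() -> dict:
    """Four-basin alternate-access cycle over (d_ec, d_ic, z_lig, theta_face).

    IF is the deepest basin; HG sits at an ~9 A aperture on both gates; the
    ligand z centers span ~30 A between IF and OF so sampled trajectories
    traverse ~40 A of channel.
    """
    return {
        "dims": list(TRANSPORTER_DIMS),
        "periodic": [False, False, False, True],
        "bounds": [[2.0, 16.0], [2.0, 16.0], [-22.0, 22.0], [0.0, 360.0]],
        "wall_k": 2.0,
        "kT": KT_300K,
        "basins": {
            "IF": {"center": [4.0, 13.0, -15.0, 135.0], "depth": 4.0,
                   "width": [2.5, 2.5, 6.0, 50.0]},
            "OC": {"center": [5.0, 5.0, 0.0, 180.0], "depth": 2.5,
                   "width": [2.5, 2.5, 6.0, 50.0]},
            "HG": {"center": [9.0, 9.0, 5.0, 225.0], "depth": 3.0,
                   "width": [2.5, 2.5, 6.0, 50.0]},
            "OF": {"center": [13.0, 4.0, 15.0, 270.0], "depth": 2.8,
                   "width": [2.5, 2.5, 6.0, 50.0]},
        },
    }


def double_well_config() -> dict:
    """2-D double well over the two gating distances; the deep well stands in
    for the IF basin, the shallow one for OF."""
    return {
        "dims": ["d_ec", "d_ic"],
        "periodic": [False, False],
        "bounds": [[1.0, 15.0], [1.0, 15.0]],
        "wall_k": 1.0,
        "kT": KT_300K,
        "basins": {
            "deep": {"center": [5.0, 11.0], "depth": 2.6, "width": [2.2, 2.2]},
            "shallow": {"center": [11.0, 5.0], "depth": 1.6, "width": [2.2, 2.2]},
        },
    }


def make_transporter_potential(config: dict | None = None) -> ToyPotential:
    """Build a :class:`ToyPotential` from a basin-spec dictionary."""
    cfg = config if config is not None else default_transporter_config()
    basins = cfg.get("basins", {})
    if not basins:
        raise InvalidConfigError("config must name at least one basin")
    names = tuple(basins)
    ndim = len(cfg["dims"])
    centers, depths, widths = [], [], []
    for name in names:
        b = basins[name]
        c, w = list(b["center"]), list(b["width"])
        if len(c) != ndim or len(w) != ndim:
            raise InvalidConfigError(f"basin {name!r}: center/width length != {ndim}")
        if any(wi <= 0 for wi in w):
            raise InvalidConfigError(f"basin {name!r}: non-positive width")
        centers.append(c)
        depths.append(float(b["depth"]))
        widths.append(w)
    return ToyPotential(
        dim_names=tuple(cfg["dims"]),
        basin_names=names,
        centers=np.array(centers, dtype=float),
        depths=np.array(depths, dtype=float),
        widths=np.array(widths, dtype=float),
        periodic=np.array(cfg.get("periodic", [False] * ndim), dtype=bool),
        bounds=np.array(cfg.get("bounds", [[-50.0, 50.0]] * ndim), dtype=float),
        wall_k=float(cfg.get("wall_k", 1.0)),
        kT=float(cfg.get("kT", KT_300K)),
    )


# ---------------------------------------------------------------------------
# Langevin propagation
# ---------------------------------------------------------------------------


@dataclass
class LatentTrajectory:
    """Time series of collective variables with ground-truth potential."""

    cvs: np.ndarray  # (F, D)
    times: np.ndarray  # (F,) frame indices
    seed: int
    dim_names: tuple[str, ...]
    potential: ToyPotential | None = None

    def __post_init__(self):
        if self.cvs.shape[0] < 2:
            raise InvalidParameterError("a trajectory needs at least 2 frames")
        if not np.all(np.isfinite(self.cvs)):
            raise InvalidParameterError("trajectory contains non-finite CVs")

    def __len__(self) -> int:
        return self.cvs.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.cvs[:, self.dim_names.index(name)]


def simulate_langevin(
    potential: ToyPotential,
    x0,
    n_steps: int,
    dt: float = 0.02,
    kT: float | None = None,
    friction: float = 1.0,
    seed: int = 0,
    guard_factor: float = 1.0,
) -> LatentTrajectory:
    """Overdamped Euler--Maruyama propagation of the toy potential.

    ``x_{n+1} = x_n - dt/gamma * grad U(x_n) + sqrt(2 kT dt / gamma) * xi``

    Identical seeds give bit-identical trajectories; ``kT = 0`` degenerates
    to deterministic gradient descent.  Leaving the bounded domain by more
    than ``guard_factor`` times its span raises
    :class:`IntegrationUnstableError` naming the offending step.
    """
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    if n_steps < 1:
        raise InvalidParameterError("n_steps must be >= 1")
    if kT is None:
        kT = potential.kT
    x = np.array(x0, dtype=float)
    if x.shape != (potential.ndim,):
        raise InvalidParameterError(f"x0 must have shape ({potential.ndim},)")

    rng = np.random.default_rng(seed)
    mob = dt / friction
    sigma = np.sqrt(2.0 * kT * dt / friction)
    per = potential.periodic
    lo, hi = potential.bounds[:, 0].copy(), potential.bounds[:, 1].copy()
    span = np.maximum(hi - lo, 10.0)  # keep a usable guard on narrow domains
    glo, ghi = lo - guard_factor * span, hi + guard_factor * span

    out = np.empty((n_steps + 1, potential.ndim))
    out[0] = x
    # one draw per step keeps the stream independent of chunking
    noise = rng.standard_normal((n_steps, potential.ndim)) if kT > 0 else None
    for n in range(n_steps):
        x = x - mob * potential.gradient(x)
        if noise is not None:
            x = x + sigma * noise[n]
        if per.any():
            x[per] = np.mod(x[per], THETA_PERIOD)
        if np.any((~per) & ((x < glo) | (x > ghi))):
            raise IntegrationUnstableError(n + 1)
        out[n + 1] = x
    return LatentTrajectory(
        cvs=out,
        times=np.arange(n_steps + 1),
        seed=int(seed),
        dim_names=potential.dim_names,
        potential=potential,
    )


# ---------------------------------------------------------------------------
# topology and embedding
# ---------------------------------------------------------------------------


@dataclass
class ToyTopology:
    """Bead-model topology: labeled protein beads, gating pairs, aromatic
    ring definitions and interchangeable ligand copies."""

    resid: np.ndarray  # (A,) int
    resname: list[str]
    atom_name: list[str]
    backbone: np.ndarray  # (A,) bool
    vdw_radius: np.ndarray  # (A,) A
    lj_epsilon: np.ndarray  # (A,) kcal/mol
    lj_sigma: np.ndarray  # (A,) A
    donor: np.ndarray  # (A,) bool
    acceptor: np.ndarray  # (A,) bool
    rings: list[list[int]]
    ligand_copies: list[np.ndarray]
    channel_residues: np.ndarray  # resids
    gating_pairs: dict  # {"extracellular": (resid, resid), "intracellular": ...}
    layout: dict = field(default_factory=dict)

    def __post_init__(self):
        resids = set(int(r) for r in self.resid)
        for side, (a, b) in self.gating_pairs.items():
            if a not in resids or b not in resids:
                raise InvalidConfigError(f"gating pair {side} references missing residue")
        for copy_idx in self.ligand_copies:
            if len(copy_idx) < 1:
                raise InvalidConfigError("ligand copy with no atoms")
        for ring in self.rings:
            if len(ring) < 5:
                raise InvalidConfigError("ring definition with fewer than 5 atoms")
        if np.any(self.lj_epsilon < 0) or np.any(self.lj_sigma <= 0):
            raise InvalidConfigError("invalid Lennard-Jones parameters")

    @property
    def n_atoms(self) -> int:
        return len(self.resid)

    @property
    def ligand_atoms(self) -> np.ndarray:
        if not self.ligand_copies:
            return np.array([], dtype=int)
        return np.concatenate(self.ligand_copies)

    @property
    def protein_atoms(self) -> np.ndarray:
        mask = np.ones(self.n_atoms, dtype=bool)
        mask[self.ligand_atoms] = False
        return np.nonzero(mask)[0]

    def atoms_of_residue(self, resid: int) -> np.ndarray:
        idx = np.nonzero(self.resid == resid)[0]
        if idx.size == 0:
            raise InvalidConfigError(f"residue {resid} not in topology")
        return idx


# the toy re-uses the gating residue numbering of the AtSWEET13 system:
# Lys65-Asp189 extracellular, Phe43-Phe164 intracellular
GATE_EC = (65, 189)
GATE_IC = (43, 164)

_CHANNEL_RESNAMES = ["ALA", "VAL", "SER", "GLY", "PHE", "THR"]


def make_toy_topology(n_ligand_copies: int = 3, ligand_resname: str = "GLC") -> ToyTopology:
    """Construct the canonical toy transporter topology.

    Twelve channel residues sit on two hexagonal rings (z = +-6 A) whose radii
    breathe with the gating distances; four single-bead gating residues move
    on the x (extracellular) and y (intracellular) axes; one channel PHE
    carries a 6-membered aromatic ring.  Ligand copies have 6 beads each; copy
    0 is embedded in the channel, the others are bulk decoys.
    """
    resid: list[int] = []
    resname: list[str] = []
    atom_name: list[str] = []
    backbone: list[bool] = []
    donor: list[bool] = []
    acceptor: list[bool] = []

    def add(rid, rn, an, bb, dn=False, ac=False):
        resid.append(rid)
        resname.append(rn)
        atom_name.append(an)
        backbone.append(bb)
        donor.append(dn)
        acceptor.append(ac)
        return len(resid) - 1

    channel_resids = []
    ring_atoms: list[int] = []
    ca_idx: dict[int, int] = {}
    cb_idx: dict[int, int] = {}
    rid = 100
    for ring_i in range(2):  # upper (EC side), lower (IC side)
        for j in range(6):
            rn = _CHANNEL_RESNAMES[j]
            channel_resids.append(rid)
            ca_idx[rid] = add(rid, rn, "CA", True,
                              dn=(rn == "SER"), ac=(rn in ("SER", "THR")))
            if rn != "GLY":
                cb_idx[rid] = add(rid, rn, "CB", False)
            if rn == "PHE" and ring_i == 0:
                ring = [add(rid, rn, f"CR{k}", False) for k in range(6)]
                ring_atoms = ring
            rid += 1

    gate_idx = {}
    for grid, rn in [(GATE_EC[0], "LYS"), (GATE_EC[1], "ASP"),
                     (GATE_IC[0], "PHE"), (GATE_IC[1], "PHE")]:
        gate_idx[grid] = add(grid, rn, "CA", True,
                             dn=(rn == "LYS"), ac=(rn == "ASP"))

    ligand_copies = []
    for c in range(n_ligand_copies):
        lrid = 500 + c
        atoms = [add(lrid, ligand_resname, "C1", False)]
        for k in range(4):
            atoms.append(add(lrid, ligand_resname, f"C{k + 2}", False))
        atoms.append(add(lrid, ligand_resname, "O1", False, dn=True, ac=True))
        ligand_copies.append(np.array(atoms, dtype=int))

    n = len(resid)
    resid_arr = np.array(resid, dtype=int)
    name_arr = atom_name
    radius = np.where([a.startswith("O") for a in name_arr], 1.52, 1.70)
    eps = np.where([a.startswith("O") for a in name_arr], 0.21, 0.11)
    sig = np.where([a.startswith("O") for a in name_arr], 3.00, 3.40)

    return ToyTopology(
        resid=resid_arr,
        resname=resname,
        atom_name=name_arr,
        backbone=np.array(backbone, dtype=bool),
        vdw_radius=radius.astype(float),
        lj_epsilon=eps.astype(float),
        lj_sigma=sig.astype(float),
        donor=np.array(donor, dtype=bool),
        acceptor=np.array(acceptor, dtype=bool),
        rings=[ring_atoms] if ring_atoms else [],
        ligand_copies=ligand_copies,
        channel_residues=np.array(channel_resids, dtype=int),
        gating_pairs={"extracellular": GATE_EC, "intracellular": GATE_IC},
        layout={
            "ring_z": 6.0,
            "ring_radius": 8.0,
            "ring_coupling": 0.25,
            "gate_z": 10.0,
            "gate_ref": (8.5, 8.5),
            "ligand_arm": 1.5,
            "ligand_ring_radius": 0.8,
            "ref_atom_offset_x": 1.0,
            "decoy_radius": 30.0,
            "channel_radius": 6.0,
            "channel_z_extent": 25.0,
            "ca_idx": {str(k): v for k, v in ca_idx.items()},
            "cb_idx": {str(k): v for k, v in cb_idx.items()},
            "gate_idx": {str(k): v for k, v in gate_idx.items()},
        },
    )


@dataclass
class ToyTrajectory:
    """Per-frame 3-D coordinates for all beads of a toy topology."""

    topology: ToyTopology
    coords: np.ndarray  # (F, A, 3) A
    box: np.ndarray  # (3,) A
    provenance: LatentTrajectory | str = "external"

    def __post_init__(self):
        if self.coords.ndim != 3 or self.coords.shape[1] != self.topology.n_atoms:
            raise InvalidConfigError("coordinate array inconsistent with topology")
        if np.any(self.box <= 0):
            raise InvalidConfigError("box lengths must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def protein_com(self) -> np.ndarray:
        """Unit-mass center of mass of protein heavy beads, per frame."""
        return self.coords[:, self.topology.protein_atoms].mean(axis=1)


def _frame_protein_coords(topology: ToyTopology, d_ec: float, d_ic: float) -> np.ndarray:
    lay = topology.layout
    coords = np.zeros((topology.n_atoms, 3))
    r_up = lay["ring_radius"] + lay["ring_coupling"] * (d_ec - lay["gate_ref"][0])
    r_lo = lay["ring_radius"] + lay["ring_coupling"] * (d_ic - lay["gate_ref"][1])
    ca_idx = {int(k): v for k, v in lay["ca_idx"].items()}
    cb_idx = {int(k): v for k, v in lay["cb_idx"].items()}
    channel = list(topology.channel_residues)
    for ring_i, sign in ((0, +1), (1, -1)):
        rr = r_up if ring_i == 0 else r_lo
        for j in range(6):
            rid2 = channel[ring_i * 6 + j]
            ang = np.deg2rad(60.0 * j + (30.0 if ring_i else 0.0))
            u = np.array([np.cos(ang), np.sin(ang), 0.0])
            pos = rr * u + np.array([0.0, 0.0, sign * lay["ring_z"]])
            coords[ca_idx[rid2]] = pos
            if rid2 in cb_idx:
                coords[cb_idx[rid2]] = (rr + 1.0) * u + np.array(
                    [0.0, 0.0, sign * lay["ring_z"]]
                )
    # aromatic ring: vertical hexagon around the PHE CB of the upper ring
    if topology.rings:
        ring = topology.rings[0]
        center = coords[ring[0] - 1].copy()  # CB precedes first ring atom
        phe_u = center[:2] / np.linalg.norm(center[:2])
        e1 = np.array([phe_u[0], phe_u[1], 0.0])
        e2 = np.array([0.0, 0.0, 1.0])
        for k, ai in enumerate(ring):
            ang = np.deg2rad(60.0 * k)
            coords[ai] = center + 1.4 * (np.cos(ang) * e1 + np.sin(ang) * e2)
    gate_idx = {int(k): v for k, v in lay["gate_idx"].items()}
    gz = lay["gate_z"]
    coords[gate_idx[GATE_EC[0]]] = [+d_ec / 2, 0.0, gz]
    coords[gate_idx[GATE_EC[1]]] = [-d_ec / 2, 0.0, gz]
    coords[gate_idx[GATE_IC[0]]] = [0.0, +d_ic / 2, -gz]
    coords[gate_idx[GATE_IC[1]]] = [0.0, -d_ic / 2, -gz]
    return coords


def _place_ligand(coords, topology, copy_i, center_atom_pos, direction):
    """Place one 6-bead ligand copy: reference atom at ``center_atom_pos``,
    copy COM displaced by ``-arm * direction`` from it (unit masses)."""
    lay = topology.layout
    atoms = topology.ligand_copies[copy_i]
    a = np.asarray(center_atom_pos, dtype=float)
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    com = a - lay["ligand_arm"] * u
    n = len(atoms)
    rest_centroid = (n * com - a) / (n - 1)
    # orthonormal frame perpendicular to u
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, u)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    coords[atoms[0]] = a
    m = n - 1
    for k in range(m):
        ang = 2.0 * np.pi * k / m
        coords[atoms[k + 1]] = rest_centroid + lay["ligand_ring_radius"] * (
            np.cos(ang) * e1 + np.sin(ang) * e2
        )


def embed_coordinates(latent: LatentTrajectory, topology: ToyTopology) -> ToyTrajectory:
    """Realize latent (d_ec, d_ic, z_lig, theta_face) frames as 3-D beads.

    Per frame the gate bead pairs are exactly ``d_ec`` and ``d_ic`` apart, the
    designated ligand copy's reference atom sits at ``z = z_lig`` relative to
    the protein center of mass, the ligand orientation realizes
    ``theta_face`` in the yz plane, and decoy copies sit in bulk outside the
    channel cylinder.  Measurement of these quantities from the embedded
    coordinates reproduces the latents to machine precision.
    """
    names = latent.dim_names
    for req in TRANSPORTER_DIMS:
        if req not in names:
            raise EmbeddingError(f"latent trajectory lacks dimension {req!r}")
    lay = topology.layout
    d_ec = latent.column("d_ec")
    d_ic = latent.column("d_ic")
    z_lig = latent.column("z_lig")
    theta = latent.column("theta_face")
    if np.any(d_ec <= 0.1) or np.any(d_ic <= 0.1):
        raise EmbeddingError("gating distance below embeddable range (0.1 A)")
    if np.any(np.abs(z_lig) > lay["channel_z_extent"]):
        raise EmbeddingError("ligand z outside embeddable channel extent")

    n_frames = len(latent)
    coords = np.zeros((n_frames, topology.n_atoms, 3))
    n_copies = len(topology.ligand_copies)
    for f in range(n_frames):
        frame = _frame_protein_coords(topology, d_ec[f], d_ic[f])
        com = frame[topology.protein_atoms].mean(axis=0)
        th = np.deg2rad(theta[f])
        # facial direction in the yz plane: A - O_lig = arm * (0, cos, sin)
        a_pos = com + np.array([lay["ref_atom_offset_x"], 0.0, z_lig[f]])
        _place_ligand(frame, topology, 0, a_pos, np.array([0.0, np.cos(th), np.sin(th)]))
        for c in range(1, n_copies):
            phi = 2.0 * np.pi * c / max(n_copies - 1, 1)
            decoy_a = com + np.array(
                [lay["decoy_radius"] * np.cos(phi), lay["decoy_radius"] * np.sin(phi), 0.0]
            )
            _place_ligand(frame, topology, c, decoy_a, np.array([0.0, 1.0, 0.0]))
        coords[f] = frame
    box = np.array([2.5 * lay["decoy_radius"]] * 2 + [2.0 * lay["channel_z_extent"] + 20.0])
    return ToyTrajectory(topology=topology, coords=coords, box=box, provenance=latent)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------


def default_dataset_config() -> dict:
    return {
        "potential": default_transporter_config(),
        "n_traj": 3,
        "n_steps": 500,
        "dt": 0.02,
        "friction": 1.0,
        "x0": "deepest",  # start every trajectory at the deepest basin center
        "n_ligand_copies": 3,
    }


def generate_dataset(config: dict | None = None, seed: int = 0, outdir: str | Path | None = None):
    """Generate a reproducible set of embedded toy trajectories.

    Returns ``(trajectories, ground_truth)`` where ``ground_truth`` is a
    JSON-serializable record of the potential config and per-trajectory
    seeds.  With ``outdir`` set, writes one array archive per trajectory
    (coords, cvs, times) plus ``ground_truth.json``; outputs are pure
    functions of ``(config, seed)`` and byte-identical across runs.
    """
    cfg = copy.deepcopy(config) if config is not None else default_dataset_config()
    potential = make_transporter_potential(cfg["potential"])
    topology = make_toy_topology(n_ligand_copies=cfg.get("n_ligand_copies", 3))
    if cfg.get("x0", "deepest") == "deepest":
        x0 = potential.centers[int(np.argmax(potential.depths))]
    else:
        x0 = np.asarray(cfg["x0"], dtype=float)

    n_traj = int(cfg["n_traj"])
    traj_seeds = [int(s) for s in np.random.SeedSequence(seed).generate_state(n_traj) % (2**31)]
    trajectories = []
    for ts in traj_seeds:
        lat = simulate_langevin(
            potential, x0, n_steps=int(cfg["n_steps"]) - 1,
            dt=float(cfg["dt"]), friction=float(cfg["friction"]), seed=ts,
        )
        trajectories.append(embed_coordinates(lat, topology))

    ground_truth = {
        "schema": "sweetmsm/dataset-v1",
        "config": cfg,
        "seed": int(seed),
        "trajectory_seeds": traj_seeds,
        "dim_names": list(potential.dim_names),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for i, traj in enumerate(trajectories):
            lat = traj.provenance
            _io.save_arrays(
                outdir / f"traj_{i:03d}.npz",
                coords=traj.coords, cvs=lat.cvs, times=lat.times,
            )
        _io.save_json(outdir / "ground_truth.json", ground_truth)
    return trajectories, ground_truth


def box_volume(box) -> float:
    """Volume of a rectangular simulation box from its axis lengths (A^3)."""
    lengths = np.asarray(box, dtype=float)
    if lengths.shape != (3,) or np.any(lengths <= 0):
        raise InvalidParameterError("box must be three positive axis lengths")
    return float(np.prod(lengths))


def binned_reference_free_energy(
    potential: ToyPotential, x_edges, y_edges, dims=(0, 1),
    fixed: dict | None = None, sub: int = 4,
) -> np.ndarray:
    """Analytic reference free energy on a 2-D bin grid.

    Integrates the Boltzmann weight ``exp(-U/kT)`` over each bin (midpoint
    quadrature with ``sub`` sub-points per axis), which is the quantity a
    weighted histogram estimates; remaining potential dimensions are held at
    the values in ``fixed`` (by name) or at the deepest basin's center.
    Returned free energies share an arbitrary additive constant.
    """
    x_edges = np.asarray(x_edges, dtype=float)
    y_edges = np.asarray(y_edges, dtype=float)
    base = potential.centers[int(np.argmax(potential.depths))].copy()
    if fixed:
        for name, val in fixed.items():
            base[potential.dim_names.index(name)] = val
    nx, ny = x_edges.size - 1, y_edges.size - 1
    G = np.empty((nx, ny))
    di, dj = dims
    for i in range(nx):
        xs = np.linspace(x_edges[i], x_edges[i + 1], sub + 1)
        xm = 0.5 * (xs[:-1] + xs[1:])
        for j in range(ny):
            ys = np.linspace(y_edges[j], y_edges[j + 1], sub + 1)
            ym = 0.5 * (ys[:-1] + ys[1:])
            XX, YY = np.meshgrid(xm, ym, indexing="ij")
            pts = np.tile(base, (sub, sub, 1))
            pts[..., di] = XX
            pts[..., dj] = YY
            U = potential.energy(pts)
            G[i, j] = -potential.kT * np.log(np.exp(-U / potential.kT).mean())
    return G


def load_ground_truth(path: str | Path) -> dict:
    obj = json.loads(Path(path).read_text())
    if obj.get("schema") != "sweetmsm/dataset-v1":
        raise InvalidConfigError(f"unrecognized ground-truth schema in {path}")
    return obj
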