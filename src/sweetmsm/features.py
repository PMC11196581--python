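"""Collective-variable and descriptor extraction.

Gating distances between the gate residue pairs, inverse pairwise C-beta
distances over the channel residue set, metastable-state harvesting from
binned free-energy landscapes, k-medoids filtering of harvested frames, and
the agnostic z-score descriptor selection: of all candidate residue-residue
inverse distances, keep those whose dispersion across the extracted
metastable states stands more than three standard deviations above the mean
dispersion — i.e. the pairs with the largest dynamical range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .errors import (
    DegenerateGeometryError,
    InvalidParameterError,
    NoMinimaError,
    TopologyLookupError,
)
from .toysim import ToyTopology, ToyTrajectory

# ---------------------------------------------------------------------------
# gating distances
# ---------------------------------------------------------------------------


@dataclass
class GatingSeries:
    d_ec: np.ndarray  # (F,) A
    d_ic: np.ndarray  # (F,) A
    extra_pair: tuple[int, int]
    intra_pair: tuple[int, int]
    atom_rule: str = "CA"

    def __post_init__(self):
        for arr in (self.d_ec, self.d_ic):
            if np.any(~np.isfinite(arr)) or np.any(arr < 0):
                raise InvalidParameterError("gating distances must be finite and >= 0")


def _residue_point(traj: ToyTrajectory, resid: int, atom_rule: str) -> np.ndarray:
    """Per-frame reference point of a residue: its CA atom (default) or the
    centroid of its sidechain heavy atoms."""
    top = traj.topology
    try:
        atoms = top.atoms_of_residue(resid)
    except Exception as exc:
        raise TopologyLookupError(f"residue {resid} not found") from exc
    if atom_rule == "CA":
        names = [top.atom_name[i] for i in atoms]
        if "CA" not in names:
            raise TopologyLookupError(f"residue {resid} has no CA atom")
        return traj.coords[:, atoms[names.index("CA")]]
    if atom_rule == "sidechain_centroid":
        side = [i for i in atoms if not top.backbone[i]]
        if not side:  # glycine-like: fall back to backbone
            side = list(atoms)
        return traj.coords[:, side].mean(axis=1)
    raise InvalidParameterError(f"unknown atom_rule {atom_rule!r}")


def gating_distances(
    traj: ToyTrajectory,
    extra_pair: tuple[int, int] | None = None,
    intra_pair: tuple[int, int] | None = None,
    atom_rule: str = "CA",
) -> GatingSeries:
    """Per-frame extracellular and intracellular gate apertures (A)."""
    top = traj.topology
    if extra_pair is None:
        extra_pair = tuple(top.gating_pairs["extracellular"])
    if intra_pair is None:
        intra_pair = tuple(top.gating_pairs["intracellular"])
    d = {}
    for key, (a, b) in (("ec", extra_pair), ("ic", intra_pair)):
        pa = _residue_point(traj, a, atom_rule)
        pb = _residue_point(traj, b, atom_rule)
        d[key] = np.linalg.norm(pa - pb, axis=1)
    return GatingSeries(d_ec=d["ec"], d_ic=d["ic"], extra_pair=extra_pair,
                        intra_pair=intra_pair, atom_rule=atom_rule)


# ---------------------------------------------------------------------------
# inverse pairwise C-beta distances
# ---------------------------------------------------------------------------


@dataclass
class FeatureMatrix:
    values: np.ndarray  # (F, P)
    names: list[str]
    units: str = "1/A"

    def __post_init__(self):
        if np.any(~np.isfinite(self.values)):
            raise InvalidParameterError("feature matrix contains non-finite values")
        if len(self.names) != self.values.shape[1]:
            raise InvalidParameterError("feature name count != column count")
        if len(set(self.names)) != len(self.names):
            raise InvalidParameterError("feature names must be unique")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


def _cbeta_index(top: ToyTopology, resid: int) -> int:
    """C-beta atom index of a residue; C-alpha for glycines."""
    atoms = top.atoms_of_residue(resid)
    names = [top.atom_name[i] for i in atoms]
    if "CB" in names and top.resname[atoms[0]] != "GLY":
        return int(atoms[names.index("CB")])
    if "CA" in names:
        return int(atoms[names.index("CA")])
    raise TopologyLookupError(f"residue {resid} has neither CB nor CA")


def inverse_pairwise_cbeta_distances(
    traj: ToyTrajectory, residue_set=None
) -> FeatureMatrix:
    """One feature per unordered residue pair, valued 1/d (A^-1).

    Uses each residue's C-beta bead and the C-alpha for glycines; produces
    n(n-1)/2 columns named ``"<resid_i>-<resid_j>"``.
    """
    top = traj.topology
    if residue_set is None:
        residue_set = list(top.channel_residues)
    residue_set = list(residue_set)
    if len(residue_set) < 2:
        raise InvalidParameterError("need at least two residues")
    idx = [_cbeta_index(top, r) for r in residue_set]
    pts = traj.coords[:, idx]  # (F, n, 3)
    cols, names = [], []
    for (ai, ra), (bi, rb) in combinations(zip(range(len(idx)), residue_set), 2):
        d = np.linalg.norm(pts[:, ai] - pts[:, bi], axis=1)
        if np.any(d == 0):
            raise DegenerateGeometryError(f"coincident residues {ra} and {rb}")
        cols.append(1.0 / d)
        names.append(f"{ra}-{rb}")
    return FeatureMatrix(values=np.column_stack(cols), names=names)


# ---------------------------------------------------------------------------
# metastable-state extraction from a binned landscape
# ---------------------------------------------------------------------------


@dataclass
class MetastableState:
    minimum_bin: tuple[int, int]
    free_energy: float
    frames: np.ndarray  # global frame indices


def local_minima_bins(free_energy: np.ndarray) -> list[tuple[int, int]]:
    """Bins strictly lower than every finite 8-neighbor (NaN = empty)."""
    G = np.asarray(free_energy, dtype=float)
    nx, ny = G.shape
    minima = []
    for i in range(nx):
        for j in range(ny):
            if not np.isfinite(G[i, j]):
                continue
            ok = True
            has_neighbor = False
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == 0 and dj == 0:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < nx and 0 <= jj < ny and np.isfinite(G[ii, jj]):
                        has_neighbor = True
                        if G[ii, jj] <= G[i, j]:
                            ok = False
            if ok and has_neighbor:
                minima.append((i, j))
            elif ok and not has_neighbor:
                minima.append((i, j))  # isolated finite bin is its own minimum
    return minima


def extract_minima_states(landscape, frame_assignments, radius: int = 1):
    """Harvest the frames sitting at each local free-energy minimum.

    ``frame_assignments`` holds per-frame (ix, iy) bin indices (-1 for frames
    outside the grid).  Each state collects the frames assigned to the
    minimum bin and its neighbors within ``radius`` bins (Chebyshev).
    """
    G = landscape.free_energy
    if not np.any(np.isfinite(G)):
        raise NoMinimaError("landscape has no finite bin")
    minima = local_minima_bins(G)
    if not minima:
        raise NoMinimaError("no strict local minima on this landscape")
    fa = np.asarray(frame_assignments)
    states = []
    for (i, j) in sorted(minima, key=lambda b: G[b]):
        near = (np.abs(fa[:, 0] - i) <= radius) & (np.abs(fa[:, 1] - j) <= radius)
        near &= fa[:, 0] >= 0
        states.append(MetastableState(minimum_bin=(i, j), free_energy=float(G[i, j]),
                                      frames=np.nonzero(near)[0]))
    return states


# ---------------------------------------------------------------------------
# k-medoids filtering (PAM)
# ---------------------------------------------------------------------------


def states_to_json(states: list[MetastableState], path) -> None:
    """Export metastable states as a frame-index JSON document."""
    from . import io as _io

    _io.save_json(path, {
        "schema": "sweetmsm/states-v1",
        "states": [
            {"minimum_bin": list(s.minimum_bin),
             "free_energy": s.free_energy,
             "frames": [int(f) for f in s.frames]}
            for s in states
        ],
    })


def kmedoids_filter(X: np.ndarray, k: int, seed: int = 0, n_restarts: int = 100):
    """Seeded PAM k-medoids under Euclidean distance; returns the sorted
    indices of the ``k`` medoid rows.  Ties break toward the lowest index."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k <= 0:
        raise InvalidParameterError("k must be positive")
    if k > n:
        raise InvalidParameterError(f"k={k} exceeds {n} candidate frames")
    if k == n:
        return np.arange(n)
    diff = X[:, None, :] - X[None, :, :]
    D = np.sqrt(np.sum(diff**2, axis=-1))
    rng = np.random.default_rng(seed)
    best_cost, best_medoids = np.inf, None
    for _ in range(n_restarts):
        medoids = np.sort(rng.choice(n, size=k, replace=False))
        for _ in range(200):
            assign = np.argmin(D[:, medoids], axis=1)
            new_medoids = medoids.copy()
            for c in range(k):
                members = np.nonzero(assign == c)[0]
                if members.size == 0:
                    continue
                within = D[np.ix_(members, members)].sum(axis=0)
                new_medoids[c] = members[np.argmin(within)]  # argmin -> lowest index tie
            new_medoids = np.sort(new_medoids)
            if np.array_equal(new_medoids, medoids):
                break
            medoids = new_medoids
        cost = D[np.arange(n), medoids[np.argmin(D[:, medoids], axis=1)]].sum()
        key = (cost, tuple(medoids))
        if best_medoids is None or key < (best_cost, tuple(best_medoids)):
            best_cost, best_medoids = cost, medoids
    return best_medoids


# ---------------------------------------------------------------------------
# agnostic descriptor selection
# ---------------------------------------------------------------------------


@dataclass
class DescriptorSet:
    selected: list[str]
    dispersion: np.ndarray  # per candidate pair
    z_scores: np.ndarray
    threshold: float
    candidates: list[str]

    def __post_init__(self):
        if not set(self.selected) <= set(self.candidates):
            raise InvalidParameterError("selected features must be candidates")


def select_agnostic_descriptors(
    distances: np.ndarray,
    names: list[str],
    threshold: float = 3.0,
    inverse: bool = True,
) -> DescriptorSet:
    """Z-score descriptor selection across extracted metastable states.

    ``distances`` is (n_states, n_pairs) of raw residue-residue distances.
    The inverse transform is applied for sensitivity, the per-pair standard
    deviation across states is the dispersion statistic, dispersions are
    z-scored across pairs, and pairs with z > ``threshold`` are selected.
    """
    distances = np.asarray(distances, dtype=float)
    if distances.ndim != 2 or distances.shape[0] < 2 or distances.shape[1] < 2:
        raise InvalidParameterError("need >=2 states and >=2 candidate pairs")
    if len(names) != distances.shape[1]:
        raise InvalidParameterError("name count != pair count")
    vals = 1.0 / distances if inverse else distances
    disp = vals.std(axis=0, ddof=0)
    scale = disp.std(ddof=0)
    if scale == 0:
        warnings.warn("all pairs have identical dispersion; empty descriptor set")
        z = np.zeros_like(disp)
    else:
        z = (disp - disp.mean()) / scale
    selected = [names[i] for i in np.nonzero(z > threshold)[0]]
    return DescriptorSet(selected=selected, dispersion=disp, z_scores=z,
                         threshold=float(threshold), candidates=list(names))
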