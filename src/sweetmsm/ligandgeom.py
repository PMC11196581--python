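"""Ligand-centric selectivity analyses.

θ angles quantify substrate positioning inside the transmembrane channel:
``theta_xy`` (atom versus protein center of mass in the XY plane) measures
ligand spinning / positional selectivity -- which channel sector the atom
occupies; ``theta_xz`` / ``theta_yz`` (atom versus ligand center of mass)
measure ligand flipping / facial selectivity, with the 180° boundary
separating the two faces.  Angles are measured counterclockwise from the
first named axis and mapped to [0, 360).

Also here: transported-copy selection among interchangeable ligand copies,
atom z position relative to the protein COM (+z extracellular), per-residue
RMSD comparisons between metastable states with Welch significance tests,
contact classification (vdW / hydrogen bond / CH···π with precedence
hbond > CH···π > vdW), and Lennard-Jones linear interaction energies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.transform import Rotation

from .errors import (
    InvalidParameterError,
    SingularGeometryError,
    TopologyLookupError,
    UnderdeterminedFitError,
)

# ---------------------------------------------------------------------------
# transported-copy selection
# ---------------------------------------------------------------------------


@dataclass
class ChannelSpec:
    """Axis-aligned cylinder around the channel: center in the xy plane
    (per frame, usually the protein COM), radius, and z extent relative to
    the protein COM z."""

    radius: float = 6.0
    z_min: float = -25.0
    z_max: float = 25.0


def select_transported_ligand(traj, channel: ChannelSpec | None = None) -> np.ndarray:
    """Per-frame index of the ligand copy inside the channel cylinder.

    The copy whose center of mass lies in the cylinder is selected; among
    several, the one nearest the channel axis wins (ties toward the lower
    copy index); -1 marks frames with no copy inside.
    """
    if channel is None:
        channel = ChannelSpec()
    top = traj.topology
    if not top.ligand_copies:
        raise InvalidParameterError("topology defines no ligand copies")
    com = traj.protein_com()  # (F, 3)
    n_frames = traj.n_frames
    choice = np.full(n_frames, -1, dtype=int)
    best_r = np.full(n_frames, np.inf)
    for ci, atoms in enumerate(top.ligand_copies):
        c = traj.coords[:, atoms].mean(axis=1) - com
        r_xy = np.linalg.norm(c[:, :2], axis=1)
        inside = (r_xy <= channel.radius) & (c[:, 2] >= channel.z_min) & (
            c[:, 2] <= channel.z_max
        )
        better = inside & (r_xy < best_r)  # strict: ties keep the lower index
        choice[better] = ci
        best_r[better] = r_xy[better]
    return choice


# ---------------------------------------------------------------------------
# theta angles and z position
# ---------------------------------------------------------------------------


@dataclass
class ThetaSeries:
    theta: np.ndarray  # degrees in [0, 360); NaN where undefined
    z: np.ndarray | None  # paired atom z position (A), optional
    mode: str  # "xy" | "xz" | "yz"
    origin: str  # "protein_com" | "ligand_com"
    atom: str = ""

    def __post_init__(self):
        ok = np.isfinite(self.theta)
        if np.any((self.theta[ok] < 0) | (self.theta[ok] >= 360)):
            raise InvalidParameterError("theta must lie in [0, 360)")


_PLANES = {"xy": (0, 1), "xz": (0, 2), "yz": (1, 2)}


def _plane_angle(delta: np.ndarray, plane: str) -> np.ndarray:
    i, j = _PLANES[plane]
    a = np.degrees(np.arctan2(delta[:, j], delta[:, i])) % 360.0
    zero = (delta[:, i] == 0) & (delta[:, j] == 0)
    a[zero] = np.nan
    return a


def theta_xy(atom_coords: np.ndarray, protein_com: np.ndarray,
             z: np.ndarray | None = None, atom: str = "") -> ThetaSeries:
    """Spinning angle: atom versus protein COM in the XY plane, measured
    counterclockwise from +X; frames with zero planar offset flag NaN."""
    delta = np.asarray(atom_coords, dtype=float) - np.asarray(protein_com, dtype=float)
    return ThetaSeries(theta=_plane_angle(delta, "xy"), z=z, mode="xy",
                       origin="protein_com", atom=atom)


def theta_face(atom_coords: np.ndarray, ligand_com: np.ndarray, plane: str = "yz",
               z: np.ndarray | None = None, atom: str = "") -> ThetaSeries:
    """Flipping/facial angle: atom versus ligand COM in the XZ or YZ plane."""
    if plane not in ("xz", "yz"):
        raise InvalidParameterError("plane must be 'xz' or 'yz'")
    delta = np.asarray(atom_coords, dtype=float) - np.asarray(ligand_com, dtype=float)
    return ThetaSeries(theta=_plane_angle(delta, plane), z=z, mode=plane,
                       origin="ligand_com", atom=atom)


def atom_z_position(atom_coords: np.ndarray, protein_com: np.ndarray) -> np.ndarray:
    """Atom z relative to the protein COM; positive toward the
    extracellular side."""
    return np.asarray(atom_coords, dtype=float)[:, 2] - np.asarray(
        protein_com, dtype=float
    )[:, 2]


# ---------------------------------------------------------------------------
# per-residue RMSD between states
# ---------------------------------------------------------------------------


def _superpose(mobile: np.ndarray, ref: np.ndarray, align_idx: np.ndarray):
    """Least-squares rigid superposition of ``mobile`` onto ``ref`` fit on
    ``align_idx``; returns transformed mobile coordinates."""
    mc = mobile[align_idx].mean(axis=0)
    rc = ref[align_idx].mean(axis=0)
    rot, _ = Rotation.align_vectors(ref[align_idx] - rc, mobile[align_idx] - mc)
    return rot.apply(mobile - mc) + rc


def per_residue_rmsd(frames_a: np.ndarray, frames_b: np.ndarray, topology,
                     align_selection=None) -> pd.DataFrame:
    """Mean ± SD per-residue heavy-atom RMSD over all frame pairs (a, b).

    Every pair is optimally superposed on ``align_selection`` (atom indices;
    default: all protein atoms) before the per-residue RMSD is taken; the
    table reports mean, SD and n = |A| x |B| pairwise comparisons.
    """
    frames_a = np.asarray(frames_a, dtype=float)
    frames_b = np.asarray(frames_b, dtype=float)
    if frames_a.ndim == 2:
        frames_a = frames_a[None]
    if frames_b.ndim == 2:
        frames_b = frames_b[None]
    if frames_a.shape[0] == 0 or frames_b.shape[0] == 0:
        raise InvalidParameterError("both frame sets must be nonempty")
    if align_selection is None:
        align_selection = topology.protein_atoms
    align_idx = np.asarray(align_selection, dtype=int)
    if align_idx.size < 3:
        raise UnderdeterminedFitError("alignment selection needs >= 3 atoms")
    prot_resids = sorted(set(int(r) for r in topology.resid[topology.protein_atoms]))
    res_atoms = {r: topology.atoms_of_residue(r) for r in prot_resids}
    per_pair = np.empty((frames_a.shape[0] * frames_b.shape[0], len(prot_resids)))
    row = 0
    for fa in frames_a:
        for fb in frames_b:
            fb_fit = _superpose(fb, fa, align_idx)
            d2 = np.sum((fb_fit - fa) ** 2, axis=1)
            for ri, r in enumerate(prot_resids):
                per_pair[row, ri] = np.sqrt(d2[res_atoms[r]].mean())
            row += 1
    return pd.DataFrame({
        "residue": prot_resids,
        "mean_rmsd": per_pair.mean(axis=0),
        "sd_rmsd": per_pair.std(axis=0, ddof=1) if row > 1 else np.zeros(len(prot_resids)),
        "n": row,
    })


def rmsd_significance(table_a: pd.DataFrame, table_b: pd.DataFrame,
                      alphas=(0.05, 0.01)) -> pd.DataFrame:
    """Two-sided Welch t-test per residue from the summary statistics of two
    RMSD tables; flags "none", "p<0.05", "p<0.01" or "untestable"."""
    alphas = sorted(alphas, reverse=True)
    merged = table_a.merge(table_b, on="residue", suffixes=("_a", "_b"))
    flags, pvals, tvals = [], [], []
    for _, r in merged.iterrows():
        if r["n_a"] < 2 or r["n_b"] < 2:
            flags.append("untestable")
            pvals.append(np.nan)
            tvals.append(np.nan)
            continue
        t, p = scipy.stats.ttest_ind_from_stats(
            r["mean_rmsd_a"], r["sd_rmsd_a"], r["n_a"],
            r["mean_rmsd_b"], r["sd_rmsd_b"], r["n_b"],
            equal_var=False,
        )
        flag = "none"
        for a in alphas:
            if p < a:
                flag = f"p<{a:g}"
        flags.append(flag)
        pvals.append(float(p))
        tvals.append(float(t))
    return pd.DataFrame({"residue": merged["residue"], "t": tvals,
                         "p": pvals, "flag": flags})


# ---------------------------------------------------------------------------
# contact classification
# ---------------------------------------------------------------------------


@dataclass
class ContactCriteria:
    vdw_margin: float = 0.5  # A beyond r_i + r_j
    hbond_distance: float = 3.5  # donor-acceptor A
    hbond_angle: float = 110.0  # D-H...A degrees, if an H is present
    chpi_distance: float = 4.5  # carbon to ring centroid A
    chpi_angle: float = 60.0  # |angle(ring normal, C->centroid)| degrees


@dataclass
class ContactRecord:
    frame: int
    residue: int
    contact_class: str  # vdw | hbond_sidechain | hbond_backbone | ch_pi
    atoms: tuple[int, int]


def _ring_geometry(coords: np.ndarray, ring: list[int]):
    pts = coords[ring]
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # plane normal: smallest singular direction
    _, _, vt = np.linalg.svd(centered)
    return centroid, vt[2]


def classify_contacts(frame_coords: np.ndarray, topology,
                      criteria: ContactCriteria | None = None,
                      frame_index: int = 0,
                      hydrogen_positions: dict | None = None) -> list[ContactRecord]:
    """Classify ligand-protein atom contacts in one frame.

    Each ligand-atom/protein-atom pair receives at most one class by the
    precedence hbond > CH···π > vdW.  Hydrogen-bond geometry uses the
    D-H···A angle when ``hydrogen_positions`` maps a donor atom index to its
    H coordinate; otherwise the distance criterion alone applies (bead
    topologies carry no hydrogens).
    """
    if criteria is None:
        criteria = ContactCriteria()
    top = topology
    coords = np.asarray(frame_coords, dtype=float)
    lig = top.ligand_atoms
    prot = top.protein_atoms
    if lig.size == 0:
        raise InvalidParameterError("topology has no ligand atoms")
    for arr, what in ((top.vdw_radius, "radius"), (top.donor, "donor flag")):
        if len(arr) != top.n_atoms:
            raise TopologyLookupError(f"missing {what} information")
    rings = [(r, *_ring_geometry(coords, r)) for r in top.rings]
    prot_ring_atoms = set(a for r in top.rings for a in r)

    def hbond_ok(d_idx, a_idx) -> bool:
        d = np.linalg.norm(coords[d_idx] - coords[a_idx])
        if d > criteria.hbond_distance:
            return False
        if hydrogen_positions and d_idx in hydrogen_positions:
            h = np.asarray(hydrogen_positions[d_idx], dtype=float)
            v1 = coords[d_idx] - h
            v2 = coords[a_idx] - h
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            return ang >= criteria.hbond_angle
        return True

    records = []
    for la in lig:
        for pa in prot:
            d = np.linalg.norm(coords[la] - coords[pa])
            cls = None
            # hydrogen bond, either direction
            if (top.donor[la] and top.acceptor[pa] and hbond_ok(la, pa)) or (
                top.donor[pa] and top.acceptor[la] and hbond_ok(pa, la)
            ):
                cls = "hbond_backbone" if top.backbone[pa] else "hbond_sidechain"
            elif (
                top.atom_name[la].startswith("C")
                and pa in prot_ring_atoms
            ):
                for ring, centroid, normal in rings:
                    if pa not in ring:
                        continue
                    v = centroid - coords[la]
                    dist = np.linalg.norm(v)
                    if dist == 0 or dist > criteria.chpi_distance:
                        continue
                    cosang = abs(np.dot(v / dist, normal))
                    ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                    if ang <= criteria.chpi_angle:
                        cls = "ch_pi"
                        break
            if cls is None and d <= top.vdw_radius[la] + top.vdw_radius[pa] + criteria.vdw_margin:
                cls = "vdw"
            if cls is not None:
                records.append(ContactRecord(frame=frame_index,
                                             residue=int(top.resid[pa]),
                                             contact_class=cls,
                                             atoms=(int(la), int(pa))))
    return records


def contact_frequency_filter(records: list[ContactRecord], frames_total: int,
                             min_fraction: float = 0.01):
    """Per-residue contact frequencies with low-frequency rows dropped.

    Returns ``(table, overall_composition)``: the table has one row per
    residue that contacts the ligand in at least ``min_fraction`` of frames,
    with its contact fraction and per-class composition; the overall
    composition is the percentage of all records per class.
    """
    if frames_total < 1:
        raise InvalidParameterError("frames_total must be >= 1")
    classes = ["vdw", "hbond_sidechain", "hbond_backbone", "ch_pi"]
    by_res: dict[int, dict] = {}
    for rec in records:
        e = by_res.setdefault(rec.residue, {"frames": set(), **{c: 0 for c in classes}})
        e["frames"].add(rec.frame)
        e[rec.contact_class] += 1
    rows = []
    for res in sorted(by_res):
        e = by_res[res]
        frac = len(e["frames"]) / frames_total
        if frac < min_fraction:
            continue
        total = sum(e[c] for c in classes)
        row = {"residue": res, "fraction": frac}
        for c in classes:
            row[f"pct_{c}"] = 100.0 * e[c] / total if total else 0.0
        rows.append(row)
    table = pd.DataFrame(rows, columns=["residue", "fraction"] +
                         [f"pct_{c}" for c in classes])
    n_rec = len(records)
    overall = {c: 100.0 * sum(1 for r in records if r.contact_class == c) / n_rec
               for c in classes} if n_rec else {c: 0.0 for c in classes}
    return table, overall


# ---------------------------------------------------------------------------
# Lennard-Jones linear interaction energy
# ---------------------------------------------------------------------------


@dataclass
class LIEResult:
    residue: int | str
    energies: np.ndarray  # per-frame kcal/mol
    trimmed_mean: float
    sd: float
    n_frames: int
    outlier_count: int


def lie_vdw(frames: np.ndarray, ligand_atoms, residue_atoms, lj_epsilon,
            lj_sigma, cutoff: float = 12.0, residue: int | str = "") -> LIEResult:
    """Per-frame Lennard-Jones interaction energy between a ligand and a
    residue selection, with Lorentz-Berthelot combining.

    ``E = sum_pairs 4 eps_ij [(sig_ij/r)^12 - (sig_ij/r)^6]`` for r <= cutoff.
    The summary is the mean ± SD after dropping frames outside 1.5 x IQR of
    the per-frame energy distribution.
    """
    if cutoff <= 0:
        raise InvalidParameterError("cutoff must be positive")
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    la = np.asarray(ligand_atoms, dtype=int)
    ra = np.asarray(residue_atoms, dtype=int)
    eps = np.asarray(lj_epsilon, dtype=float)
    sig = np.asarray(lj_sigma, dtype=float)
    eps_ij = np.sqrt(np.outer(eps[la], eps[ra]))
    sig_ij = 0.5 * (sig[la][:, None] + sig[ra][None, :])
    energies = np.empty(frames.shape[0])
    for f, frame in enumerate(frames):
        d = np.linalg.norm(frame[la][:, None, :] - frame[ra][None, :, :], axis=-1)
        if np.any(d == 0):
            raise SingularGeometryError(f"zero interatomic distance in frame {f}")
        mask = d <= cutoff
        sr6 = (sig_ij[mask] / d[mask]) ** 6
        energies[f] = np.sum(4.0 * eps_ij[mask] * (sr6**2 - sr6))
    q1, q3 = np.percentile(energies, [25, 75])
    iqr = q3 - q1
    keep = (energies >= q1 - 1.5 * iqr) & (energies <= q3 + 1.5 * iqr)
    if not np.any(keep):
        keep = np.ones_like(keep)
    kept = energies[keep]
    return LIEResult(residue=residue, energies=energies,
                     trimmed_mean=float(kept.mean()),
                     sd=float(kept.std(ddof=1)) if kept.size > 1 else 0.0,
                     n_frames=int(kept.size),
                     outlier_count=int((~keep).sum()))
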