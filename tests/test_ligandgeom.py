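"""Ligand selectivity geometry: transported-copy selection, theta angles,
atom z, per-residue RMSD with significance, contact classification, and
Lennard-Jones interaction energies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sweetmsm import ligandgeom, toysim
from sweetmsm.errors import (
    InvalidParameterError,
    SingularGeometryError,
    UnderdeterminedFitError,
)

# ---------------------------------------------------------------------------
# transported-copy selection
# ---------------------------------------------------------------------------


class TestSelectTransported:
    def test_single_copy_inside(self, embedded):
        sel = ligandgeom.select_transported_ligand(embedded)
        assert np.all(sel == 0)

    def test_tie_goes_to_lower_index(self):
        # hand-built system: protein COM exactly at the origin, two 1-atom
        # ligand copies exactly equidistant from the channel axis
        top = toysim.ToyTopology(
            resid=np.array([1, 1, 2, 3]),
            resname=["ALA", "ALA", "LIG", "LIG"],
            atom_name=["CA", "CB", "C1", "C1"],
            backbone=np.array([True, False, False, False]),
            vdw_radius=np.full(4, 1.7), lj_epsilon=np.full(4, 0.1),
            lj_sigma=np.full(4, 3.4), donor=np.zeros(4, bool),
            acceptor=np.zeros(4, bool), rings=[],
            ligand_copies=[np.array([2]), np.array([3])],
            channel_residues=np.array([1]), gating_pairs={})
        coords = np.array([[[-1.0, 0, 0], [1.0, 0, 0],
                            [2.0, 0, 3.0], [-2.0, 0, 3.0]]])
        traj = toysim.ToyTrajectory(topology=top, coords=coords,
                                    box=np.array([50.0, 50.0, 50.0]))
        sel = ligandgeom.select_transported_ligand(traj)
        assert np.all(sel == 0)

    def test_switch_detected_at_exact_frame(self, topology):
        lat = toysim.LatentTrajectory(
            cvs=np.array([[8.0, 8.0, 0.0, 0.0]] * 200), times=np.arange(200),
            seed=0, dim_names=toysim.TRANSPORTER_DIMS)
        traj = toysim.embed_coordinates(lat, topology)
        com = traj.protein_com()
        atoms0 = topology.ligand_copies[0]
        atoms1 = topology.ligand_copies[1]
        # from frame 100 on, swap which copy sits in the channel
        c0 = traj.coords[:, atoms0].copy()
        c1 = traj.coords[:, atoms1].copy()
        traj.coords[100:, atoms0] = c1[100:]
        traj.coords[100:, atoms1] = c0[100:]
        sel = ligandgeom.select_transported_ligand(traj)
        assert np.all(sel[:100] == 0) and np.all(sel[100:] == 1)


# ---------------------------------------------------------------------------
# theta angles
# ---------------------------------------------------------------------------


class TestTheta:
    @pytest.mark.parametrize("offset,expect", [
        ((1.0, 0.0), 0.0), ((0.0, 1.0), 90.0), ((-1.0, -1.0), 225.0),
    ])
    def test_theta_xy_unit_cases(self, offset, expect):
        atom = np.array([[offset[0], offset[1], 3.0]])
        com = np.zeros((1, 3))
        ts = ligandgeom.theta_xy(atom, com)
        assert ts.theta[0] == pytest.approx(expect, abs=1e-8)

    def test_theta_xy_origin_flagged_nan(self):
        ts = ligandgeom.theta_xy(np.array([[0.0, 0.0, 5.0]]), np.zeros((1, 3)))
        assert np.isnan(ts.theta[0])

    @pytest.mark.parametrize("yz,expect", [
        ((1.0, 0.0), 0.0), ((0.0, 1.0), 90.0),
    ])
    def test_theta_face_yz_unit_cases(self, yz, expect):
        atom = np.array([[0.0, yz[0], yz[1]]])
        ts = ligandgeom.theta_face(atom, np.zeros((1, 3)), plane="yz")
        assert ts.theta[0] == pytest.approx(expect, abs=1e-8)

    def test_theta_face_invalid_plane(self):
        with pytest.raises(InvalidParameterError):
            ligandgeom.theta_face(np.zeros((1, 3)), np.zeros((1, 3)),
                                  plane="xy")

    def test_embedded_round_trip_with_boundary_crossing(self, topology):
        """Latent facial angles crossing the 180 degree face boundary are
        reproduced exactly by measurement."""
        thetas = np.array([170.0, 178.0, 181.0, 225.0, 359.5, 0.5])
        cvs = np.column_stack([
            np.full(6, 8.0), np.full(6, 8.0), np.zeros(6), thetas])
        lat = toysim.LatentTrajectory(cvs=cvs, times=np.arange(6), seed=0,
                                      dim_names=toysim.TRANSPORTER_DIMS)
        traj = toysim.embed_coordinates(lat, topology)
        atoms = topology.ligand_copies[0]
        lig_com = traj.coords[:, atoms].mean(axis=1)
        ts = ligandgeom.theta_face(traj.coords[:, atoms[0]], lig_com,
                                   plane="yz")
        np.testing.assert_allclose(ts.theta, thetas, atol=1e-8)
        crosses = (thetas[:-1] < 180) != (thetas[1:] < 180)
        measured_crosses = (ts.theta[:-1] < 180) != (ts.theta[1:] < 180)
        np.testing.assert_array_equal(crosses, measured_crosses)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(phi=st.floats(0.0, 359.99), shift=st.floats(-50, 50))
    def test_rigid_motion_equivariance(self, phi, shift):
        """Translation leaves theta_xy unchanged; rotating the whole system
        by phi about z shifts every theta_xy by phi (mod 360)."""
        rng = np.random.default_rng(0)
        atom = rng.normal(size=(5, 3)) + np.array([3, 0, 0])
        com = rng.normal(scale=0.1, size=(5, 3))
        base = ligandgeom.theta_xy(atom, com).theta
        t = np.array([shift, -shift, shift])
        shifted = ligandgeom.theta_xy(atom + t, com + t).theta
        np.testing.assert_allclose(shifted, base, atol=1e-6)
        c, s = np.cos(np.deg2rad(phi)), np.sin(np.deg2rad(phi))
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        rot = ligandgeom.theta_xy(atom @ R.T, com @ R.T).theta
        diff = (rot - base - phi + 180) % 360 - 180
        np.testing.assert_allclose(diff, 0, atol=1e-6)


class TestAtomZ:
    def test_com_plane_zero_and_translation_invariance(self):
        atom = np.array([[1.0, 2.0, 7.0]])
        com = np.array([[0.0, 0.0, 7.0]])
        assert ligandgeom.atom_z_position(atom, com)[0] == 0.0
        z1 = ligandgeom.atom_z_position(atom + [0, 0, 5.0], com + [0, 0, 5.0])
        assert z1[0] == 0.0

    def test_embedded_round_trip(self, latent_short, embedded):
        atoms = embedded.topology.ligand_copies[0]
        z = ligandgeom.atom_z_position(embedded.coords[:, atoms[0]],
                                       embedded.protein_com())
        np.testing.assert_allclose(z, latent_short.column("z_lig"), atol=1e-8)


# ---------------------------------------------------------------------------
# per-residue RMSD
# ---------------------------------------------------------------------------


class TestPerResidueRMSD:
    def test_self_comparison_zero(self, embedded):
        top = embedded.topology
        frame = embedded.coords[:1, top.protein_atoms]
        table = ligandgeom.per_residue_rmsd(frame, frame, _ProteinView(top))
        assert np.all(table["mean_rmsd"] < 1e-10)

    def test_rigid_motion_removed_by_superposition(self, embedded):
        top = _ProteinView(embedded.topology)
        a = embedded.coords[:1, embedded.topology.protein_atoms]
        rng = np.random.default_rng(0)
        from scipy.spatial.transform import Rotation

        R = Rotation.random(random_state=1).as_matrix()
        b = a @ R.T + np.array([3.0, -2.0, 7.0])
        table = ligandgeom.per_residue_rmsd(a, b, top)
        assert np.all(table["mean_rmsd"] < 1e-8)

    def test_single_displaced_residue(self, embedded):
        full_top = embedded.topology
        top = _ProteinView(full_top)
        a = embedded.coords[:1, full_top.protein_atoms]
        b = a.copy()
        resid = int(full_top.channel_residues[0])
        moved = np.nonzero(top.resid == resid)[0]
        align = np.setdiff1d(np.arange(a.shape[1]), moved)
        b[:, moved] += np.array([0.0, 0.0, 2.0])
        table = ligandgeom.per_residue_rmsd(a, b, top, align_selection=align)
        row = table.set_index("residue").loc[resid]
        assert row["mean_rmsd"] == pytest.approx(2.0, abs=1e-8)
        others = table[table["residue"] != resid]["mean_rmsd"]
        assert np.all(others < 1e-8)

    def test_symmetry_in_arguments(self, embedded):
        top = _ProteinView(embedded.topology)
        a = embedded.coords[:2, embedded.topology.protein_atoms]
        b = embedded.coords[2:4, embedded.topology.protein_atoms]
        tab_ab = ligandgeom.per_residue_rmsd(a, b, top)
        tab_ba = ligandgeom.per_residue_rmsd(b, a, top)
        np.testing.assert_allclose(tab_ab["mean_rmsd"], tab_ba["mean_rmsd"],
                                   atol=1e-10)

    def test_underdetermined_alignment(self, embedded):
        top = _ProteinView(embedded.topology)
        a = embedded.coords[:1, embedded.topology.protein_atoms]
        with pytest.raises(UnderdeterminedFitError):
            ligandgeom.per_residue_rmsd(a, a, top, align_selection=[0, 1])


class _ProteinView:
    """Protein-only view of a toy topology (ligand atoms stripped), so frame
    arrays indexed over protein atoms line up with residue lookups."""

    def __init__(self, top):
        idx = top.protein_atoms
        self.resid = top.resid[idx]
        self.atom_name = [top.atom_name[i] for i in idx]
        self.n_atoms = len(idx)

    @property
    def protein_atoms(self):
        return np.arange(self.n_atoms)

    def atoms_of_residue(self, resid):
        return np.nonzero(self.resid == resid)[0]


class TestRMSDSignificance:
    @staticmethod
    def _table(mean, sd, n):
        import pandas as pd

        return pd.DataFrame({"residue": [1], "mean_rmsd": [mean],
                             "sd_rmsd": [sd], "n": [n]})

    def test_identical_distributions_not_significant(self):
        out = ligandgeom.rmsd_significance(self._table(1.0, 0.2, 30),
                                           self._table(1.0, 0.2, 30))
        assert out["flag"][0] == "none"

    def test_widely_separated_means_significant(self):
        out = ligandgeom.rmsd_significance(self._table(1.0, 0.1, 30),
                                           self._table(2.0, 0.1, 30))
        assert out["flag"][0] == "p<0.01"

    def test_matches_welch_formula(self):
        """Oracle: from-scratch Welch t statistic."""
        m1, s1, n1, m2, s2, n2 = 1.3, 0.4, 25, 1.1, 0.5, 31
        out = ligandgeom.rmsd_significance(self._table(m1, s1, n1),
                                           self._table(m2, s2, n2))
        t_expect = (m1 - m2) / np.sqrt(s1**2 / n1 + s2**2 / n2)
        assert out["t"][0] == pytest.approx(t_expect, abs=1e-10)

    def test_untestable_with_single_sample(self):
        out = ligandgeom.rmsd_significance(self._table(1.0, 0.0, 1),
                                           self._table(1.0, 0.2, 30))
        assert out["flag"][0] == "untestable"


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------


def tiny_contact_topology():
    """Minimal hand-built topology: 2 protein residues (one with an aromatic
    ring, one donor/acceptor pair) and a 1-atom ligand 'copy'."""
    n = 11
    resid = np.array([1] * 7 + [2, 2] + [9, 9])
    resname = ["PHE"] * 7 + ["SER"] * 2 + ["LIG"] * 2
    atom_name = ["CA", "C1", "C2", "C3", "C4", "C5", "C6", "CA", "OG",
                 "C1", "O1"]
    return toysim.ToyTopology(
        resid=resid, resname=resname, atom_name=atom_name,
        backbone=np.array([True] + [False] * 6 + [True, False, False, False]),
        vdw_radius=np.full(n, 1.7),
        lj_epsilon=np.full(n, 0.1),
        lj_sigma=np.full(n, 3.4),
        donor=np.array([False] * 8 + [False, False, True]),
        acceptor=np.array([False] * 8 + [True, False, True]),
        rings=[[1, 2, 3, 4, 5, 6]],
        ligand_copies=[np.array([9, 10])],
        channel_residues=np.array([1, 2]),
        gating_pairs={},
    )


def ring_coords(center, radius=1.4):
    pts = []
    for k in range(6):
        a = np.deg2rad(60 * k)
        pts.append(center + radius * np.array([np.cos(a), np.sin(a), 0.0]))
    return pts


class TestClassifyContacts:
    def _coords(self):
        top = tiny_contact_topology()
        coords = np.zeros((top.n_atoms, 3))
        coords[0] = [-3, 0, 0]  # PHE CA
        for i, p in enumerate(ring_coords(np.zeros(3)), start=1):
            coords[i] = p
        coords[7] = [10, 0, 0]  # SER CA
        coords[8] = [11, 0, 0]  # SER OG
        coords[9] = [50, 0, 0]  # ligand C1 (far away by default)
        coords[10] = [60, 0, 0]  # ligand O1
        return top, coords

    def test_vdw_at_radius_sum(self):
        top, coords = self._coords()
        coords[9] = coords[7] + [1.7 + 1.7, 0, 0]  # exactly r_i + r_j apart
        recs = ligandgeom.classify_contacts(coords, top)
        pairs = {(r.atoms[0], r.atoms[1]): r.contact_class for r in recs}
        assert pairs[(9, 7)] == "vdw"

    def test_textbook_hydrogen_bond(self):
        top, coords = self._coords()
        coords[10] = coords[8] + [2.8, 0, 0]  # O1 near OG
        h = {10: coords[10] - np.array([1.0, 0, 0])}  # D-H...A at 180 degrees
        recs = ligandgeom.classify_contacts(coords, top, hydrogen_positions=h)
        cls = {r.atoms: r.contact_class for r in recs}
        assert cls[(10, 8)] == "hbond_sidechain"

    def test_bent_hydrogen_bond_rejected(self):
        top, coords = self._coords()
        coords[10] = coords[8] + [2.8, 0, 0]
        h = {10: coords[10] + np.array([0, 1.0, 0])}  # ~90 degree angle
        recs = ligandgeom.classify_contacts(coords, top, hydrogen_positions=h)
        cls = {r.atoms: r.contact_class for r in recs}
        assert cls.get((10, 8)) != "hbond_sidechain"

    def test_ch_pi_along_ring_normal(self):
        top, coords = self._coords()
        coords[9] = [0, 0, 4.0]  # carbon on the ring normal
        recs = ligandgeom.classify_contacts(coords, top)
        assert any(r.contact_class == "ch_pi" and r.atoms[0] == 9
                   for r in recs)

    def test_one_class_per_pair(self):
        top, coords = self._coords()
        coords[9] = [0, 0, 3.0]
        recs = ligandgeom.classify_contacts(coords, top)
        seen = [r.atoms for r in recs]
        assert len(seen) == len(set(seen))


class TestContactFrequency:
    def test_below_threshold_dropped(self):
        recs = [ligandgeom.ContactRecord(frame=0, residue=7,
                                         contact_class="vdw", atoms=(0, 1))]
        table, _ = ligandgeom.contact_frequency_filter(recs, frames_total=200)
        assert len(table) == 0  # 1/200 = 0.005 < 0.01

    def test_every_frame_kept(self):
        recs = [ligandgeom.ContactRecord(frame=f, residue=7,
                                         contact_class="vdw", atoms=(0, 1))
                for f in range(50)]
        table, _ = ligandgeom.contact_frequency_filter(recs, frames_total=50)
        assert table.iloc[0]["fraction"] == 1.0

    def test_overall_composition(self):
        recs = [ligandgeom.ContactRecord(frame=f, residue=7,
                                         contact_class="vdw", atoms=(0, 1))
                for f in range(85)]
        recs += [ligandgeom.ContactRecord(frame=f, residue=8,
                                          contact_class="hbond_sidechain",
                                          atoms=(0, 2)) for f in range(15)]
        _, overall = ligandgeom.contact_frequency_filter(recs, frames_total=85)
        assert overall["vdw"] == pytest.approx(85.0)
        assert overall["hbond_sidechain"] == pytest.approx(15.0)


# ---------------------------------------------------------------------------
# LIE
# ---------------------------------------------------------------------------


class TestLIE:
    def test_single_pair_at_lj_minimum(self):
        eps = np.array([0.2, 0.3])
        sig = np.array([3.0, 3.4])
        sig_ij = 0.5 * (sig[0] + sig[1])
        eps_ij = np.sqrt(eps[0] * eps[1])
        r = 2 ** (1 / 6) * sig_ij
        frame = np.array([[0, 0, 0], [r, 0, 0]], dtype=float)
        res = ligandgeom.lie_vdw(frame, [0], [1], eps, sig, cutoff=20.0)
        assert res.energies[0] == pytest.approx(-eps_ij, abs=1e-12)

    def test_beyond_cutoff_zero(self):
        frame = np.array([[0, 0, 0], [30.0, 0, 0]])
        res = ligandgeom.lie_vdw(frame, [0], [1], np.ones(2), np.full(2, 3.4),
                                 cutoff=12.0)
        assert res.energies[0] == 0.0

    def test_matches_brute_force_double_loop(self):
        """Oracle: explicit pair loop without any cutoff."""
        rng = np.random.default_rng(4)
        n_l, n_r = 4, 6
        coords = rng.uniform(0, 8, size=(3, n_l + n_r, 3))
        eps = rng.uniform(0.05, 0.3, n_l + n_r)
        sig = rng.uniform(2.5, 3.8, n_l + n_r)
        res = ligandgeom.lie_vdw(coords, range(n_l), range(n_l, n_l + n_r),
                                 eps, sig, cutoff=1e6)
        for f in range(3):
            expect = 0.0
            for i in range(n_l):
                for j in range(n_l, n_l + n_r):
                    r = np.linalg.norm(coords[f, i] - coords[f, j])
                    e = np.sqrt(eps[i] * eps[j])
                    s = 0.5 * (sig[i] + sig[j])
                    expect += 4 * e * ((s / r) ** 12 - (s / r) ** 6)
            assert res.energies[f] == pytest.approx(expect, abs=1e-10)

    def test_pairwise_additivity(self):
        rng = np.random.default_rng(5)
        coords = rng.uniform(0, 6, size=(1, 9, 3))
        eps = rng.uniform(0.05, 0.3, 9)
        sig = rng.uniform(2.5, 3.8, 9)
        whole = ligandgeom.lie_vdw(coords, [0, 1], range(2, 9), eps, sig,
                                   cutoff=1e6)
        parts = [ligandgeom.lie_vdw(coords, [0, 1], grp, eps, sig, cutoff=1e6)
                 for grp in ([2, 3, 4], [5, 6], [7, 8])]
        assert whole.energies[0] == pytest.approx(
            sum(p.energies[0] for p in parts), abs=1e-10)

    def test_zero_distance_raises(self):
        frame = np.zeros((2, 3))
        with pytest.raises(SingularGeometryError):
            ligandgeom.lie_vdw(frame, [0], [1], np.ones(2), np.ones(2))

    def test_outlier_trimming(self):
        frames = np.zeros((10, 2, 3))
        frames[:, 1, 0] = 2 ** (1 / 6) * 3.4
        frames[9, 1, 0] = 3.4 * 0.8  # one strongly repulsive outlier frame
        res = ligandgeom.lie_vdw(frames, [0], [1], np.full(2, 0.2),
                                 np.full(2, 3.4), cutoff=20.0)
        assert res.outlier_count == 1
        assert res.trimmed_mean == pytest.approx(res.energies[0], abs=1e-12)
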