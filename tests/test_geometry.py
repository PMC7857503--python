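"""Bilayer/protein coordinate metrics: planes, depths, angles, contacts."""

import numpy as np
import pytest

from conftest import brute_force_contacts, make_random_contact_frame

from lipbind.errors import MissingAtomError, MissingSelectionError
from lipbind.geometry import (
    ContactCriteria,
    ContactSeries,
    DEFAULT_LOOPS,
    Frame,
    HeadgroupSpec,
    LoopDefinition,
    basic_residue_contact_total,
    contact_time_statistics,
    interloop_angle,
    lipid_contacts,
    loop_tip_position,
    phosphate_plane_z,
    protein_com_height,
    residue_depth,
)
from lipbind.synthetic import build_membrane_protein_frames


def simple_frame(atoms):
    """atoms: list of (name, resname, resid, segid, xyz[, mass])."""
    names, resnames, resids, segids, xyz, masses = [], [], [], [], [], []
    for rec in atoms:
        names.append(rec[0])
        resnames.append(rec[1])
        resids.append(rec[2])
        segids.append(rec[3])
        xyz.append(rec[4])
        masses.append(rec[5] if len(rec) > 5 else 12.0)
    return Frame(
        atom_names=np.array(names, dtype=object),
        resnames=np.array(resnames, dtype=object),
        resids=np.array(resids, dtype=int),
        segids=np.array(segids, dtype=object),
        xyz=np.array(xyz, dtype=float),
        masses=np.array(masses),
    )


class TestPhosphatePlane:
    def test_mean_of_same_leaflet(self):
        frame = simple_frame(
            [
                ("P", "POPC", 1, "MEMB", (0, 0, 19.0)),
                ("P", "POPC", 2, "MEMB", (5, 0, 21.0)),
                ("CA", "GLY", 10, "PROT", (0, 0, 45.0)),
            ]
        )
        assert phosphate_plane_z(frame, "upper") == pytest.approx(20.0)

    def test_protein_facing_leaflet_selection(self):
        frame = simple_frame(
            [
                ("P", "POPC", 1, "MEMB", (0, 0, 20.0)),
                ("P", "POPC", 2, "MEMB", (0, 8, -20.0)),
                ("CA", "GLY", 10, "PROT", (0, 0, 45.0)),
            ]
        )
        assert phosphate_plane_z(frame, "protein_facing") == pytest.approx(20.0)
        assert phosphate_plane_z(frame, "lower") == pytest.approx(-20.0)

    def test_missing_phosphorus(self):
        frame = simple_frame([("CA", "GLY", 10, "PROT", (0, 0, 45.0))])
        with pytest.raises(MissingSelectionError):
            phosphate_plane_z(frame, "upper")


class TestHeightsAndDepths:
    def test_point_mass_height(self):
        frame = simple_frame(
            [
                ("P", "POPC", 1, "MEMB", (0, 0, 20.0)),
                ("CA", "GLY", 10, "PROT", (0, 0, 45.0)),
            ]
        )
        assert protein_com_height(frame, 20.0) == pytest.approx(25.0)

    def test_translation_invariance_of_height(self):
        rng = np.random.default_rng(4)
        frame = make_random_contact_frame(rng)
        plane = 10.0
        h0 = protein_com_height(frame, plane)
        shifted = Frame(
            atom_names=frame.atom_names, resnames=frame.resnames,
            resids=frame.resids, segids=frame.segids,
            xyz=frame.xyz + np.array([3.0, -2.0, 7.0]), masses=frame.masses,
        )
        assert protein_com_height(shifted, plane + 7.0) == pytest.approx(h0, abs=1e-9)

    def test_com_against_brute_force(self):
        rng = np.random.default_rng(11)
        n = 1000
        frame = Frame(
            atom_names=np.array(["CA"] * n, dtype=object),
            resnames=np.array(["GLY"] * n, dtype=object),
            resids=np.arange(1, n + 1),
            segids=np.array(["PROT"] * n, dtype=object),
            xyz=rng.normal(0, 10, (n, 3)),
            masses=rng.uniform(1, 20, n),
        )
        expected = sum(m * z for m, z in zip(frame.masses, frame.xyz[:, 2])) / sum(
            frame.masses
        )
        assert protein_com_height(frame, 0.0) == pytest.approx(expected, abs=1e-9)

    def test_depth_sign_convention(self):
        frame = simple_frame(
            [
                ("CA", "PHE", 452, "PROT", (0, 0, 20.0)),
                ("CZ", "PHE", 452, "PROT", (0, 0, 17.5)),
            ]
        )
        assert residue_depth(frame, 452, 20.0) == pytest.approx(0.0)
        assert residue_depth(
            frame, 452, 20.0, representation="named_atom", atom_name="CZ"
        ) == pytest.approx(-2.5)

    def test_missing_atom(self):
        frame = simple_frame([("CB", "PHE", 452, "PROT", (0, 0, 20.0))])
        with pytest.raises(MissingAtomError):
            residue_depth(frame, 452, 20.0)


class TestLoopTipsAndAngles:
    def test_centroid(self):
        frame = simple_frame(
            [
                ("CA", "GLU", 388, "PROT", (0, 0, 0)),
                ("CA", "ALA", 389, "PROT", (3, 0, 0)),
                ("CA", "LYS", 390, "PROT", (6, 0, 0)),
            ]
        )
        loop = LoopDefinition("beta2-beta3", (388, 389, 390))
        assert np.allclose(loop_tip_position(frame, loop), (3, 0, 0))

    def test_tip_order_invariance(self):
        frame = simple_frame(
            [
                ("CA", "GLU", 388, "PROT", (1, 2, 3)),
                ("CA", "ALA", 389, "PROT", (-4, 0, 2)),
                ("CA", "LYS", 390, "PROT", (0, 5, -1)),
            ]
        )
        a = loop_tip_position(frame, LoopDefinition("x", (388, 389, 390)))
        b = loop_tip_position(frame, LoopDefinition("x", (390, 388, 389)))
        assert np.allclose(a, b)

    def test_right_angle_and_collinear(self):
        # one heavy ballast atom at origin dominates the COM
        atoms = [("CA", "GLY", 1, "PROT", (0, 0, 0), 1e9)]
        for resid, pos in zip((388, 389, 390), [(10, 0, 0)] * 3):
            atoms.append(("CA", "GLU", resid, "PROT", pos, 1e-9))
        for resid, pos in zip((450, 451, 452), [(0, 10, 0)] * 3):
            atoms.append(("CA", "GLY", resid, "PROT", pos, 1e-9))
        for resid, pos in zip((406, 407, 408), [(0, -10, 0)] * 3):
            atoms.append(("CA", "SER", resid, "PROT", pos, 1e-9))
        frame = simple_frame(atoms)
        alpha = interloop_angle(
            frame, DEFAULT_LOOPS["beta2-beta3"], DEFAULT_LOOPS["beta6-beta7"]
        )
        straight = interloop_angle(
            frame, DEFAULT_LOOPS["beta6-beta7"], DEFAULT_LOOPS["beta3-beta4"]
        )
        assert alpha == pytest.approx(90.0, abs=1e-6)
        assert straight == pytest.approx(180.0, abs=1e-6)

    def test_rigid_transform_invariance(self):
        frames, truth = build_membrane_protein_frames(n_frames=1, seed=5)
        frame = frames[0]
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        shift = rng.normal(0, 30, 3)
        moved = Frame(
            atom_names=frame.atom_names, resnames=frame.resnames,
            resids=frame.resids, segids=frame.segids,
            xyz=frame.xyz @ q.T + shift, masses=frame.masses,
        )
        for la, lb in (("beta2-beta3", "beta6-beta7"), ("beta6-beta7", "beta3-beta4")):
            before = interloop_angle(frame, DEFAULT_LOOPS[la], DEFAULT_LOOPS[lb])
            after = interloop_angle(moved, DEFAULT_LOOPS[la], DEFAULT_LOOPS[lb])
            assert after == pytest.approx(before, abs=1e-6)


class TestContacts:
    def frame_with_lipid_at(self, distance):
        return simple_frame(
            [
                ("NZ", "LYS", 398, "PROT", (0, 0, 0), 14.0),
                ("CA", "LYS", 398, "PROT", (0, 0, 3.0), 12.0),
                ("O13", "POPS", 1, "MEMB", (distance, 0, 0), 16.0),
            ]
        )

    def test_cutoff_boundary(self):
        inside = lipid_contacts(self.frame_with_lipid_at(4.9))
        outside = lipid_contacts(self.frame_with_lipid_at(5.1))

        def count(df):
            return int(df[(df.residue == "K398") & (df.lipid_type == "POPS")]["count"].iloc[0])

        assert count(inside) == 1
        assert count(outside) == 0

    def test_per_molecule_binarisation(self):
        frame = simple_frame(
            [
                ("NZ", "LYS", 398, "PROT", (0, 0, 0), 14.0),
                ("O13", "POPS", 1, "MEMB", (2.0, 0, 0), 16.0),
                ("O14", "POPS", 1, "MEMB", (0, 2.0, 0), 16.0),
                ("P", "POPS", 1, "MEMB", (0, 0, 2.0), 31.0),
            ]
        )
        df = lipid_contacts(frame)
        assert int(df[(df.residue == "K398") & (df.lipid_type == "POPS")]["count"].iloc[0]) == 1

    def test_non_headgroup_atoms_ignored(self):
        frame = simple_frame(
            [
                ("NZ", "LYS", 398, "PROT", (0, 0, 0), 14.0),
                ("C21", "POPS", 1, "MEMB", (2.0, 0, 0), 12.0),  # acyl carbon
            ]
        )
        df = lipid_contacts(frame)
        assert int(df[(df.residue == "K398") & (df.lipid_type == "POPS")]["count"].iloc[0]) == 0

    def test_oracle_equivalence_50_fixtures(self):
        criteria = ContactCriteria()
        headgroups = HeadgroupSpec()
        for seed in range(50):
            rng = np.random.default_rng(seed)
            frame = make_random_contact_frame(rng)
            got = lipid_contacts(frame, criteria, headgroups)
            expected = brute_force_contacts(frame, criteria, headgroups)
            present_types = set(frame.resnames[~frame.is_protein()].astype(str))
            for _, row in got.iterrows():
                key = (row["residue"], row["lipid_type"])
                assert row["count"] == expected[key], (seed, key)
            # every expected pair for present lipid types was reported
            reported = {(r["residue"], r["lipid_type"]) for _, r in got.iterrows()}
            for key, cnt in expected.items():
                if key[1] in present_types:
                    assert key in reported

    def test_cutoff_monotonicity(self):
        rng = np.random.default_rng(123)
        frame = make_random_contact_frame(rng)
        small = lipid_contacts(frame, ContactCriteria(3.0, 3.0, 3.0))
        large = lipid_contacts(frame, ContactCriteria(8.0, 8.0, 8.0))
        merged = small.merge(
            large, on=["residue", "resid", "lipid_type"], suffixes=("_s", "_l")
        )
        assert (merged["count_l"] >= merged["count_s"]).all()

    def test_counts_bounded_by_lipid_population(self):
        rng = np.random.default_rng(7)
        frame = make_random_contact_frame(rng)
        df = lipid_contacts(frame, ContactCriteria(50.0, 50.0, 50.0))
        lipid_mask = ~frame.is_protein()
        for lipid_type, grp in df.groupby("lipid_type"):
            n_mols = len(
                set(frame.resids[lipid_mask & (frame.resnames.astype(str) == lipid_type)])
            )
            assert (grp["count"] <= n_mols).all()
            assert (grp["count"] >= 0).all()


class TestContactStatistics:
    def make_series(self, schedule, n_frames=10):
        frames, truth = build_membrane_protein_frames(
            n_frames=n_frames, contact_schedule=schedule, seed=2
        )
        return ContactSeries.from_trajectory(frames), truth

    def test_constant_schedule_stats(self):
        series, _ = self.make_series({(410, "POPS"): [1] * 10})
        stats = contact_time_statistics(series, {"last_fraction": 0.5})
        row = stats[(stats.resid == 410) & (stats.lipid_type == "POPS")]
        assert float(row["mean"].iloc[0]) == pytest.approx(1.0)
        assert float(row["sd"].iloc[0]) == pytest.approx(0.0)

    def test_alternating_schedule_mean(self):
        series, _ = self.make_series({(410, "POPS"): [0, 1] * 5})
        stats = contact_time_statistics(series, {"last_fraction": 1.0})
        row = stats[(stats.resid == 410) & (stats.lipid_type == "POPS")]
        assert float(row["mean"].iloc[0]) == pytest.approx(0.5)

    def test_scheduled_table_matches_analytic(self):
        schedule = {
            (398, "PIP2"): [0, 0, 1, 1, 1, 1, 1, 1, 1, 1],
            (410, "POPS"): [2, 2, 2, 1, 1, 1, 0, 0, 0, 0],
        }
        series, truth = self.make_series(schedule)
        stats = contact_time_statistics(series, {"last_fraction": 0.5})
        for (resid, lipid), counts in schedule.items():
            window = np.array(counts[5:], dtype=float)
            row = stats[(stats.resid == resid) & (stats.lipid_type == lipid)]
            assert float(row["mean"].iloc[0]) == pytest.approx(window.mean())
            assert float(row["sd"].iloc[0]) == pytest.approx(window.std())

    def test_basic_residue_totals(self):
        schedule = {
            (398, "POPS"): [2] * 10,
            (410, "POPS"): [1] * 10,
            (412, "POPS"): [2] * 10,
            (398, "PIP2"): [1] * 10,
        }
        series, _ = self.make_series(schedule)
        totals = basic_residue_contact_total(series)
        ps = totals[totals.lipid_type == "POPS"]["n_residues"]
        pip2 = totals[totals.lipid_type == "PIP2"]["n_residues"]
        assert (ps == 3).all()  # three residues, regardless of 2 lipids each
        assert (pip2 == 1).all()

    def test_no_contacts_gives_zero(self):
        series, _ = self.make_series({})
        totals = basic_residue_contact_total(series)
        assert (totals["n_residues"] == 0).all()
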