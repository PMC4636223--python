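"""Contacts, distances, buried interface area, states, stress steps."""

import numpy as np
import pytest

import mechanofak as mf
from mechanofak.structural_observables import ValidationError, _sasa
from mechanofak.synthetic_data import synth_two_domain_coordinates

from _oracles import brute_force_contacts, brute_force_min_distance


def pair_coords(distance):
    return mf.CoordinateSet(
        coords=np.array([[0.0, 0.0, 0.0], [distance, 0.0, 0.0]]),
        radius=np.array([0.17, 0.17]),
        residue_index=np.array([1, 2]),
        groups={"A": np.array([0]), "B": np.array([1])},
    )


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


class TestContactCount:
    def test_single_pair_inside_cutoff(self):
        assert mf.contact_count(pair_coords(0.5), "A", "B") == 1

    def test_pair_exactly_at_cutoff_excluded(self):
        """'Closer than 0.6 nm' is a strict inequality."""
        assert mf.contact_count(pair_coords(0.6), "A", "B") == 0
        assert mf.contact_count(pair_coords(0.6 - 1e-9), "A", "B") == 1

    def test_unknown_group_rejected(self):
        with pytest.raises(ValidationError):
            mf.contact_count(pair_coords(0.5), "A", "nope")

    @pytest.mark.parametrize("seed", range(0, 50, 1))
    def test_matches_brute_force_oracle(self, seed):
        cs = synth_two_domain_coordinates(
            n_atoms_per_domain=250, separation=0.2, seed=seed
        )
        a, b = cs.groups["F2"], cs.groups["C"]
        expected = brute_force_contacts(cs.coords[a], cs.coords[b], 0.6)
        assert mf.contact_count(cs, "F2", "C") == expected

    def test_symmetric_is_sum_of_directions(self):
        cs = synth_two_domain_coordinates(150, separation=0.1, seed=7)
        both = mf.contact_count(cs, "F2", "C", symmetric=True)
        assert both == mf.contact_count(cs, "F2", "C") + mf.contact_count(
            cs, "C", "F2"
        )

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(3)
        cs = synth_two_domain_coordinates(100, separation=0.3, seed=3)
        R = random_rotation(rng)
        moved = mf.CoordinateSet(
            coords=cs.coords @ R.T + np.array([5.0, -2.0, 1.0]),
            radius=cs.radius,
            residue_index=cs.residue_index,
            groups=cs.groups,
        )
        assert mf.contact_count(moved, "F2", "C") == mf.contact_count(cs, "F2", "C")


class TestMinDistance:
    def test_shared_point_gives_zero(self):
        assert mf.min_distance(pair_coords(0.0), "A", "B") == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        cs = synth_two_domain_coordinates(200, separation=0.4, seed=seed)
        a, b = cs.groups["F2"], cs.groups["C"]
        expected = brute_force_min_distance(cs.coords[a], cs.coords[b])
        assert mf.min_distance(cs, "F2", "C") == pytest.approx(expected, abs=1e-12)

    def test_rigid_motion_invariance_tight(self):
        """Rotation+translation changes the distance by < 1e-9 nm."""
        rng = np.random.default_rng(9)
        cs = synth_two_domain_coordinates(120, separation=0.7, seed=9)
        d0 = mf.min_distance(cs, "F2", "C")
        R = random_rotation(rng)
        moved = mf.CoordinateSet(
            coords=cs.coords @ R.T + rng.normal(size=3),
            radius=cs.radius,
            residue_index=cs.residue_index,
            groups=cs.groups,
        )
        assert abs(mf.min_distance(moved, "F2", "C") - d0) < 1e-9


class TestBuriedInterfaceArea:
    def test_far_apart_groups_bury_nothing(self):
        cs = synth_two_domain_coordinates(60, separation=10.0, seed=1)
        assert mf.buried_interface_area(cs, "F2", "C") == 0.0

    def test_single_sphere_sasa_analytic(self):
        area = _sasa(np.zeros((1, 3)), np.array([0.17]), 0.14, 960)
        assert area == pytest.approx(4 * np.pi * 0.31**2, rel=0.01)

    def test_point_density_convergence(self):
        """Doubling points per atom moves the buried area by < 2%."""
        cs = synth_two_domain_coordinates(40, separation=0.05, seed=5, cloud_size=0.8)
        a1 = mf.buried_interface_area(cs, "F2", "C", points_per_atom=960)
        a2 = mf.buried_interface_area(cs, "F2", "C", points_per_atom=1920)
        assert a1 > 0
        assert abs(a2 - a1) / a1 < 0.02

    def test_zero_iff_beyond_reach(self):
        probe, rmax = 0.14, 0.17
        just_touching = 2 * (rmax + probe) - 0.01
        cs_near = synth_two_domain_coordinates(
            50, separation=just_touching, seed=2, cloud_size=0.6
        )
        assert mf.buried_interface_area(cs_near, "F2", "C") > 0
        cs_far = synth_two_domain_coordinates(
            50, separation=2 * (rmax + probe) + 0.01, seed=2, cloud_size=0.6
        )
        assert mf.buried_interface_area(cs_far, "F2", "C") == 0.0

    def test_cross_check_against_biotite_sasa(self):
        """Independent Shrake-Rupley implementation agrees on the buried
        area of a two-cluster fixture."""
        import biotite.structure as struc

        cs = synth_two_domain_coordinates(30, separation=0.05, seed=8, cloud_size=0.6)
        ours = mf.buried_interface_area(cs, "F2", "C", points_per_atom=960)

        def biotite_sasa(idx):
            n = len(idx)
            arr = struc.AtomArray(n)
            arr.coord = cs.coords[idx] * 10.0  # nm -> Angstrom
            arr.element = np.array(["C"] * n)
            arr.res_id = np.arange(1, n + 1)
            arr.atom_name = np.array(["CA"] * n)
            arr.res_name = np.array(["GLY"] * n)
            arr.chain_id = np.array(["A"] * n)
            vdw = np.full(n, 1.7)
            return struc.sasa(
                arr, probe_radius=1.4, vdw_radii=vdw, point_number=960
            ).sum() / 100.0  # A^2 -> nm^2

        ia, ib = cs.groups["F2"], cs.groups["C"]
        theirs = 0.5 * (
            biotite_sasa(ia) + biotite_sasa(ib) - biotite_sasa(np.arange(60))
        )
        assert ours == pytest.approx(theirs, rel=0.05)

    def test_rotation_changes_sampled_area_marginally(self):
        """The sphere-point sampling is quasi- (not exactly) rotation
        invariant; a rigid motion moves the area by well under 2%."""
        rng = np.random.default_rng(4)
        cs = synth_two_domain_coordinates(40, separation=0.1, seed=4, cloud_size=0.8)
        a0 = mf.buried_interface_area(cs, "F2", "C")
        moved = mf.CoordinateSet(
            coords=cs.coords @ random_rotation(rng).T + rng.normal(size=3),
            radius=cs.radius,
            residue_index=cs.residue_index,
            groups=cs.groups,
        )
        a1 = mf.buried_interface_area(moved, "F2", "C")
        assert abs(a1 - a0) / a0 < 0.02


class TestClassifyState:
    @pytest.mark.parametrize(
        "n_iface,n_mem,expected",
        [
            (120, 50, ("i", "b")),  # autoinhibited, membrane-anchored
            (0, 50, ("a", "b")),  # force-activated, still anchored
            (0, 0, ("a", "u")),  # fully detached (low-PIP2 outcome)
            (30, 0, ("i", "u")),
        ],
    )
    def test_mapping(self, n_iface, n_mem, expected):
        iface, anchor = mf.classify_state(n_iface, n_mem)
        assert (iface.value, anchor.value) == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            mf.classify_state(-1, 0)


class TestAssignStressSteps:
    def test_constructed_drop_assignments(self):
        matrix, labels = mf.synth_stress_matrix(
            n_residues=8,
            labels=["step1", "step2", "elsewhere", "none"] * 2,
            seed=0,
            noise_sd=0.5,
        )
        out = mf.assign_stress_steps(matrix)
        assert out == labels

    def test_flat_trace_is_none(self):
        t = np.linspace(0, 100, 400)
        matrix = mf.StressMatrix(
            residue_index=np.array([175]),
            time=t,
            stress=np.full((1, t.size), 50.0),
            step1_time=40.0,
            step2_time=60.0,
        )
        assert mf.assign_stress_steps(matrix) == {175: "none"}

    def test_seeded_recovery_rate(self):
        """>= 95% of labelled residues recovered across 20 seeds."""
        total, correct = 0, 0
        for seed in range(20):
            matrix, labels = mf.synth_stress_matrix(n_residues=20, seed=seed)
            out = mf.assign_stress_steps(matrix)
            for res, lab in labels.items():
                total += 1
                correct += out[res] == lab
        assert correct / total >= 0.95

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValidationError):
            mf.StressMatrix(
                residue_index=np.array([], dtype=int),
                time=np.array([]),
                stress=np.zeros((0, 0)),
                step1_time=1.0,
                step2_time=2.0,
            )

    def test_csv_round_trip(self, tmp_path):
        matrix, _ = mf.synth_stress_matrix(n_residues=5, seed=3)
        path = tmp_path / "stress.csv"
        matrix.to_csv(path)
        back = mf.StressMatrix.from_csv(path, matrix.step1_time, matrix.step2_time)
        np.testing.assert_allclose(back.stress, matrix.stress, rtol=1e-12)
        np.testing.assert_array_equal(back.residue_index, matrix.residue_index)


class TestFromPdb:
    def test_groups_from_selection(self, tmp_path):
        pdb = tmp_path / "toy.pdb"
        lines = []
        coords = [(0.0, 0.0, 0.0), (3.0, 0.0, 0.0), (3.5, 0.0, 0.0), (9.0, 0.0, 0.0)]
        for i, (x, y, z) in enumerate(coords, start=1):
            lines.append(
                f"ATOM  {i:>5}  CA  GLY A{i:>4}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
        pdb.write_text("\n".join(lines) + "\nEND\n")
        sel = {
            "F2": {"chain": "A", "residues": [[1, 2]]},
            "C": {"chain": "A", "residues": [[3, 4]]},
        }
        cs = mf.CoordinateSet.from_pdb(pdb, sel)
        assert len(cs.group("F2")) == 2 and len(cs.group("C")) == 2
        # 3.5 A between residues 2 and 3 -> 0.35 nm
        assert mf.min_distance(cs, "F2", "C") == pytest.approx(0.05, abs=1e-6)
        assert mf.contact_count(cs, "F2", "C", cutoff=0.1) == 1
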