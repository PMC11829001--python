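"""Distance-window filtration, score surrogates and the sequential chain."""

import math

import numpy as np
import pytest

from ternadock.errors import ConfigurationError, PipelineStageError
from ternadock.scoring import (
    ComplexSASA,
    DistanceWindow,
    FilterConfig,
    _complex_protein,
    interaction_energy,
    interaction_zscores,
    interface_quality,
    lennard_jones_energy,
    rough_ligand_filter,
    sasa_score,
    sequential_filter,
    stability_score,
)
from ternadock.fcc import interface_contacts
from ternadock.structure import Pose, RigidTransform, Structure
from ternadock.synthetic import SyntheticSpec, make_decoys

from conftest import atom


def shifted_pose(native_pose, offset, pid="p"):
    return Pose(
        pid, pid, native_pose.transform.then_translation(np.asarray(offset)),
        provenance="translated",
    )


def axis_pose(toy_input, native_pose, distance, pid="p"):
    """Pose whose anchor--warhead distance is exactly ``distance`` Å."""
    from ternadock.grid import moiety_distance

    base = moiety_distance(toy_input, native_pose)  # 6.0 along +x
    return shifted_pose(native_pose, [distance - base, 0.0, 0.0], pid)


class TestRoughLigandFilter:
    @pytest.mark.parametrize(
        "distance,kept",
        [(2.9, False), (3.0, True), (20.0, True), (20.1, False), (6.0, True)],
    )
    def test_window_boundaries_inclusive(
        self, toy_input, native_pose, distance, kept
    ):
        pose = axis_pose(toy_input, native_pose, distance)
        result = rough_ligand_filter(toy_input, [pose], DistanceWindow())
        assert (len(result) == 1) is kept

    def test_all_inside_is_identity_and_idempotent(self, toy_input, native_pose):
        poses = [
            axis_pose(toy_input, native_pose, d, pid=f"p{d}")
            for d in (3.0, 6.0, 12.0, 20.0)
        ]
        kept = rough_ligand_filter(toy_input, poses, DistanceWindow())
        assert kept == poses
        assert rough_ligand_filter(toy_input, kept, DistanceWindow()) == kept


class TestSasa:
    def test_isolated_sphere_analytic(self):
        st = Structure([atom(1, "C", "C", [0, 0, 0])])
        import gemmi

        r = gemmi.Element("C").vdw_r + 1.4
        assert sasa_score(st) == pytest.approx(4 * math.pi * r**2, rel=0.01)

    def test_two_distant_atoms_additive(self):
        st = Structure(
            [atom(1, "C", "C", [0, 0, 0]), atom(2, "O", "O", [20, 0, 0])]
        )
        total = sasa_score(Structure([st.atoms[0]])) + sasa_score(
            Structure([st.atoms[1]])
        )
        assert sasa_score(st) == pytest.approx(total, rel=0.01)

    def test_enclosed_atom_contributes_nothing(self):
        # dense cage: caged-vs-empty difference isolates the centre's area
        from ternadock.scoring import _unit_sphere

        cage = [
            atom(i + 2, "C", "C", 2.0 * d)
            for i, d in enumerate(_unit_sphere(80))
        ]
        with_centre = Structure([atom(1, "C", "C", [0, 0, 0])] + cage)
        centre_contribution = sasa_score(with_centre) - sasa_score(
            Structure(cage)
        )
        import gemmi

        single = 4 * math.pi * (gemmi.Element("C").vdw_r + 1.4) ** 2
        assert abs(centre_contribution) < 0.01 * single

    def test_rigid_motion_invariance(self, toy_input):
        from scipy.spatial.transform import Rotation

        st = _complex_protein(
            toy_input, Pose("n", "n", RigidTransform.identity())
        )
        R = Rotation.from_euler("xyz", [31, -57, 101], degrees=True).as_matrix()
        moved = st.with_coords(st.coords @ R.T + np.array([5.0, -3.0, 11.0]))
        a, b = sasa_score(st, n_points=240), sasa_score(moved, n_points=240)
        assert abs(a - b) / a < 0.005

    def test_matches_independent_biotite_implementation(self, toy_input):
        """Cross-check against biotite's Shrake–Rupley on the native
        complex; tolerances cover the differing vdW radii tables and
        sphere-point layouts."""
        import biotite.structure as bst

        st = _complex_protein(
            toy_input, Pose("n", "n", RigidTransform.identity())
        )
        arr = bst.AtomArray(len(st))
        arr.coord = st.coords
        arr.element = np.array([a.element for a in st])
        arr.atom_name = np.array([a.name for a in st])
        arr.res_name = np.array([a.residue_name for a in st])
        arr.res_id = np.array([a.residue_seq for a in st])
        arr.chain_id = np.array([a.chain_id for a in st])
        reference = float(
            bst.sasa(
                arr, probe_radius=1.4, point_number=960, vdw_radii="Single"
            ).sum()
        )
        assert sasa_score(st, n_points=960) == pytest.approx(
            reference, rel=0.02
        )

    def test_incremental_scorer_matches_direct(self, toy_input, native_pose):
        poses, _ = make_decoys(
            toy_input, SyntheticSpec(seed=2, n_decoys=4, far_fraction=0.0)
        )
        scorer = ComplexSASA(toy_input, n_points=240)
        for pose in poses:
            direct = sasa_score(_complex_protein(toy_input, pose), n_points=240)
            assert scorer.score(pose) == pytest.approx(direct, rel=0.01)


class TestInteractionEnergy:
    def test_separated_proteins_zero(self, toy_input, native_pose):
        far = shifted_pose(native_pose, [100.0, 0.0, 0.0])
        assert interaction_energy(toy_input, far) == 0.0

    def test_pair_at_minimum_is_minus_epsilon(self):
        x_c, d_c = 3.851, 0.105  # carbon UFF well position/depth
        a = Structure([atom(1, "C", "C", [0, 0, 0])])
        b = Structure([atom(2, "C", "C", [x_c, 0, 0], chain="B")])
        assert lennard_jones_energy(a, b, cutoff=None) == pytest.approx(-d_c)

    def test_matches_brute_force_sum(self, toy_input, native_pose):
        # independent oracle: explicit double loop over all pairs
        receptor = toy_input.receptor_protein
        mobile = toy_input.mobile_protein
        from ternadock.scoring import UFF_VDW

        expected = 0.0
        for ra in receptor:
            for ma in mobile:
                x1, d1 = UFF_VDW[ra.element.upper()]
                x2, d2 = UFF_VDW[ma.element.upper()]
                xij, dij = math.sqrt(x1 * x2), math.sqrt(d1 * d2)
                r = float(np.linalg.norm(ra.coordinates - ma.coordinates))
                s6 = (xij / r) ** 6
                expected += dij * (s6**2 - 2 * s6)
        got = lennard_jones_energy(receptor, mobile, cutoff=None)
        assert got == pytest.approx(expected, abs=1e-3)


class TestStability:
    def test_clash_free_native_is_zero(self, toy_input, native_pose):
        assert stability_score(toy_input, native_pose) == 0.0

    def test_overlap_is_strictly_negative(self, toy_input, native_pose):
        onto = shifted_pose(native_pose, [-9.0, 0.0, 0.0])  # mobile onto receptor
        assert stability_score(toy_input, onto) < 0

    def test_constructed_clash_count(self, make_pair_input):
        receptor = [atom(i, "CA", "C", [3.0 * i, 0, 0], resseq=i)
                    for i in range(1, 4)]
        mobile = [atom(10 + i, "CA", "C", [3.0 * i, 1.0, 0], chain="B",
                       resseq=i) for i in range(1, 4)]
        inp = make_pair_input(receptor, mobile)
        pose = Pose("s", "s", RigidTransform.identity())
        # brute-force oracle
        expected = -sum(
            1
            for ra in inp.receptor_protein
            for ma in inp.mobile_protein
            if np.linalg.norm(ra.coordinates - ma.coordinates) < 2.5
        )
        assert expected == -3
        assert stability_score(inp, pose) == expected


class TestZScoresAndQuality:
    def test_identical_poses_all_zero(self, toy_input, native_pose):
        poses = [
            Pose(f"p{i}", f"p{i}", native_pose.transform) for i in range(3)
        ]
        with pytest.warns(UserWarning, match="degenerate"):
            z = interaction_zscores(toy_input, poses)
        assert all(v == 0.0 for v in z.values())

    def test_population_zscore_against_oracle(self, toy_input, native_pose):
        poses = [
            shifted_pose(native_pose, [dx, 0, 0], pid=f"p{dx}")
            for dx in (0.0, 2.0, 4.0)
        ]
        z = interaction_zscores(toy_input, poses)
        # independent oracle: brute-force contact counts + population z
        counts = []
        for pose in poses:
            placed = toy_input.mobile_protein.with_coords(
                pose.transform.apply(toy_input.mobile_protein.coords)
            )
            pairs = set()
            for ra in toy_input.receptor_protein:
                for ma in placed:
                    if np.linalg.norm(ra.coordinates - ma.coordinates) <= 5.0:
                        pairs.add((ra.residue_id, ma.residue_id))
            counts.append(len(pairs))
        counts = np.array(counts, dtype=float)
        expected = (counts - counts.mean()) / counts.std()
        for pose, e in zip(poses, expected):
            assert z[pose.id] == pytest.approx(e)

    def test_quality_surrogate_equals_contact_count(self, toy_input, native_pose):
        assert interface_quality(toy_input, native_pose) == float(
            len(interface_contacts(toy_input, native_pose, 5.0))
        )


@pytest.fixture(scope="module")
def hundred_poses(toy_input):
    poses, _ = make_decoys(
        toy_input, SyntheticSpec(seed=9, n_decoys=100, far_fraction=0.0)
    )
    return poses


class TestSequentialFilter:
    def test_retention_one_is_identity(self, toy_input, hundred_poses,
                                       fast_filters):
        config = FilterConfig(
            components=("stability", "energy"),
            retention={"stability": 1.0, "energy": 1.0},
        )
        kept, table = sequential_filter(toy_input, hundred_poses, config)
        assert [p.id for p in kept] == [p.id for p in hundred_poses]
        assert all(table.has(p.id, "energy") for p in kept)

    def test_ceiling_chain_survivor_counts(self, toy_input, hundred_poses):
        # ceil-chain oracle: 100 -> 75 -> 57 -> 43 -> 33
        expected = []
        n = 100
        for _ in range(4):
            n = math.ceil(0.75 * n)
            expected.append(n)
        assert expected == [75, 57, 43, 33]
        counts = []
        for k in range(1, 5):
            config = FilterConfig(
                components=("stability", "energy", "pizsa", "sasa")[:k],
                sasa_points=120,
            )
            kept, _ = sequential_filter(toy_input, hundred_poses, config)
            counts.append(len(kept))
        assert counts == expected

    def test_component_order_changes_survivors(self, toy_input, hundred_poses):
        a = FilterConfig(components=("stability", "energy"),
                         retention={"stability": 0.3, "energy": 0.3})
        b = FilterConfig(components=("energy", "stability"),
                         retention={"stability": 0.3, "energy": 0.3})
        kept_a, _ = sequential_filter(toy_input, hundred_poses, a)
        kept_b, _ = sequential_filter(toy_input, hundred_poses, b)
        assert {p.id for p in kept_a} != {p.id for p in kept_b}

    def test_empty_input_names_stage(self, toy_input):
        with pytest.raises(PipelineStageError, match="stability"):
            sequential_filter(toy_input, [], FilterConfig())

    def test_missing_external_binary_is_config_error(
        self, toy_input, hundred_poses
    ):
        config = FilterConfig(
            components=("energy",),
            providers={"energy": "external:definitely-not-a-real-tool"},
        )
        with pytest.raises(ConfigurationError, match="not found"):
            sequential_filter(toy_input, hundred_poses[:2], config)

    def test_joint_rigid_motion_invariance(self, toy_input, native_pose):
        """Energy and stability depend only on relative geometry."""
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("xyz", [20, 45, -30], degrees=True).as_matrix()
        t = np.array([7.0, -2.0, 3.0])
        import dataclasses

        def moved(st):
            return st.with_coords(st.coords @ R.T + t)

        moved_input = dataclasses.replace(
            toy_input,
            receptor=moved(toy_input.receptor),
            mobile=moved(toy_input.mobile),
            _splits={},
        )
        identity = Pose("n", "n", RigidTransform.identity())
        assert interaction_energy(moved_input, identity) == pytest.approx(
            interaction_energy(toy_input, identity), rel=1e-9
        )
        assert stability_score(moved_input, identity) == stability_score(
            toy_input, identity
        )
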