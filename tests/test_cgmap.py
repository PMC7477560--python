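"""Iterative unique-nearest-neighbour coarse-graining: oracle and invariants."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hgdpd.cgmap import (assign_frame, initialize_beads, map_trajectory,
                         update_bead_positions)
from hgdpd.synthetic import GeneratorSpec, generate_brownian_water
from hgdpd.trajectory import Trajectory


def _oracle_assign(bead_pos, mol_pos, box, ratio):
    """Literal re-implementation of the round/conflict rules.

    cg_ratio sequential rounds; in each round every bead acquires one new
    molecule via iterated claims: each bead claims its nearest unassigned
    molecule, a contested molecule goes to the closest claimant (ties to the
    lower bead index), losers re-search.  Distances are minimum-image.
    """
    def dist(b, m):
        d = bead_pos[b] - mol_pos[m]
        d = d - box * np.rint(d / box)
        return float(np.sqrt((d * d).sum()))

    n_beads = len(bead_pos)
    unassigned = set(range(len(mol_pos)))
    members = [[] for _ in range(n_beads)]
    for _ in range(ratio):
        need = list(range(n_beads))
        while need:
            claims: dict[int, list[int]] = {}
            for b in need:
                target = min(sorted(unassigned), key=lambda m: (dist(b, m), m))
                claims.setdefault(target, []).append(b)
            winners = set()
            for m, bs in claims.items():
                w = min(bs, key=lambda b: (dist(b, m), b))
                members[w].append(m)
                unassigned.discard(m)
                winners.add(w)
            need = [b for b in need if b not in winners]
    return members


class TestAssignFrame:
    def test_two_well_separated_clouds_partition_cleanly(self):
        # two clusters far apart: each bead collects its own four molecules
        box = np.full(3, 20.0)
        beads = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        mols = np.array([[x, 0.0, 0.0] for x in
                         (0.1, 0.2, 0.3, 0.4, 9.6, 9.7, 9.8, 9.9)])
        a = assign_frame(beads, mols, box, cg_ratio=4)
        assert sorted(a.members[0]) == [0, 1, 2, 3]
        assert sorted(a.members[1]) == [4, 5, 6, 7]

    def test_contested_molecule_goes_to_lower_index_on_exact_tie(self):
        box = np.full(3, 20.0)
        beads = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        # molecule 0 is the nearest for BOTH beads at exactly equal distance;
        # the lower-index bead wins and the other re-searches
        mols = np.array([[1.0, 0, 0], [0.0, 2.5, 0], [2.0, 1.5, 0]])
        a = assign_frame(beads, mols, box, cg_ratio=1)
        assert a.members[0][0] == 0
        assert a.members[1][0] == 2

    def test_equidistant_molecules_resolve_to_lower_molecule_id(self):
        box = np.full(3, 20.0)
        beads = np.array([[0.0, 0.0, 0.0]])
        mols = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0.0, 3.0, 0]])
        a = assign_frame(beads, mols, box, cg_ratio=2)
        assert a.members[0].tolist() == [0, 1]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4, 5])
    def test_matches_literal_oracle_on_random_instances(self, seed):
        rng = np.random.RandomState(seed)
        n_mol = rng.randint(20, 50)
        ratio = rng.choice([2, 3, 4])
        n_beads = (n_mol - rng.randint(1, 4)) // ratio
        box = np.full(3, 10.0)
        mols = rng.uniform(0, 10, (n_mol, 3))
        beads = mols[rng.choice(n_mol, n_beads, replace=False)]
        ours = assign_frame(beads, mols, box, ratio)
        oracle = _oracle_assign(beads, mols, box, ratio)
        assert [m.tolist() for m in ours.members] == oracle

    @given(seed=st.integers(0, 300))
    def test_partition_property_holds_for_all_instances(self, seed):
        rng = np.random.RandomState(seed)
        n_mol = rng.randint(12, 40)
        ratio = int(rng.choice([2, 3]))
        n_beads = max(1, (n_mol - 1) // ratio)
        box = np.full(3, 8.0)
        mols = rng.uniform(0, 8, (n_mol, 3))
        beads = mols[rng.choice(n_mol, n_beads, replace=False)]
        a = assign_frame(beads, mols, box, ratio)
        flat = a.members.ravel()
        assert flat.size == n_beads * ratio
        assert np.unique(flat).size == flat.size          # no double ownership
        assert np.all(a.members >= 0)                     # every slot filled

    def test_insufficient_molecules_rejected_with_margin_advice(self):
        rng = np.random.RandomState(0)
        mols = rng.uniform(0, 5, (10, 3))
        with pytest.raises(ValueError, match="stability margin"):
            assign_frame(mols[:3], mols, np.full(3, 5.0), cg_ratio=4)


class TestInitializeBeads:
    def test_reference_water_leaves_seven_free_molecules(self):
        rng = np.random.RandomState(1)
        frame = rng.uniform(0, 31.036, (967, 3))
        beads = initialize_beads(frame, 240, 4, seed=5)
        assert beads.shape == (240, 3)
        assert np.unique(beads, axis=0).shape[0] == 240
        assert 967 - 240 * 4 == 7

    def test_zero_margin_warns_but_is_valid(self, caplog):
        rng = np.random.RandomState(2)
        frame = rng.uniform(0, 5, (12, 3))
        with caplog.at_level("WARNING", logger="hgdpd.cgmap"):
            beads = initialize_beads(frame, 3, 4, seed=0)
        assert beads.shape == (3, 3)
        assert any("margin" in r.message for r in caplog.records)

    def test_overcommitted_beads_rejected(self):
        rng = np.random.RandomState(3)
        frame = rng.uniform(0, 5, (11, 3))
        with pytest.raises(ValueError, match="stability margin"):
            initialize_beads(frame, 3, 4, seed=0)


class TestUpdateBeadPositions:
    def test_square_cloud_centres_on_square_centre(self):
        box = np.full(3, 10.0)
        beads = np.array([[1.0, 1.0, 0.0]])
        mols = np.array([[0.5, 0.5, 0], [1.5, 0.5, 0], [0.5, 1.5, 0],
                         [1.5, 1.5, 0]])
        a = assign_frame(beads, mols, box, cg_ratio=4)
        new = update_bead_positions(a, mols, box)
        assert new[0] == pytest.approx([1.0, 1.0, 0.0])

    def test_cloud_straddling_boundary_lands_on_short_arc(self):
        box = np.full(3, 20.0)
        beads = np.array([[0.0, 0.0, 0.0]])
        mols = np.array([[0.3, 0, 0], [19.9, 0, 0]])
        a = assign_frame(beads, mols, box, cg_ratio=2)
        new = update_bead_positions(a, mols, box)
        assert new[0, 0] == pytest.approx(0.1)            # not 10.1

    def test_single_member_cloud_sits_on_the_member(self):
        box = np.full(3, 10.0)
        beads = np.array([[2.0, 2.0, 2.0]])
        mols = np.array([[2.5, 2.0, 2.0], [8.0, 8.0, 8.0]])
        a = assign_frame(beads, mols, box, cg_ratio=1)
        new = update_bead_positions(a, mols, box)
        assert new[0] == pytest.approx([2.5, 2.0, 2.0])


class TestMapTrajectory:
    def test_static_clouds_give_identical_frames(self):
        # distinct molecular clouds, one bead per cloud: the partition is
        # unambiguous, so re-processing the same (static) frame from the
        # updated bead positions reproduces assignments and positions exactly
        rng = np.random.RandomState(4)
        centres = np.stack(np.meshgrid(*[[2.0, 5.0, 8.0]] * 2, [5.0],
                                       indexing="ij"), axis=-1).reshape(-1, 3)
        pos = (centres[:, None, :] + rng.uniform(-0.4, 0.4, (9, 3, 3))
               ).reshape(-1, 3)
        pos = np.vstack([pos, [[0.2, 0.2, 0.2]]])          # one free molecule
        box = np.full(3, 10.0)
        first = assign_frame(centres, pos, box, cg_ratio=3)
        beads1 = update_bead_positions(first, pos, box)
        second = assign_frame(beads1, pos, box, cg_ratio=3)
        beads2 = update_bead_positions(second, pos, box)
        assert np.array_equal(np.sort(first.members, axis=1),
                              np.sort(second.members, axis=1))
        assert np.allclose(beads1, beads2)

    def test_static_random_molecules_reach_a_fixed_point(self):
        # for interpenetrating clouds the first updates can re-partition;
        # chaining must still settle onto a stable assignment within a few
        # frames (Lloyd-style fixed point)
        rng = np.random.RandomState(4)
        pos = rng.uniform(0, 10, (30, 3))
        fine = Trajectory(positions=np.stack([pos] * 6), box=np.full(3, 10.0),
                          velocities=np.zeros((6, 30, 3)), frame_interval=1.0,
                          units="real")
        cg = map_trajectory(fine, cg_ratio=3, n_beads=9, seed=8)
        assert np.allclose(cg.positions[-1], cg.positions[-2])
        members = cg.metadata["members"]
        assert np.array_equal(members[-1], members[-2])

    def test_partition_invariant_on_brownian_trajectory(self, brownian_fine):
        sub = Trajectory(positions=brownian_fine.positions[:10],
                         box=brownian_fine.box,
                         velocities=brownian_fine.velocities[:10],
                         frame_interval=brownian_fine.frame_interval,
                         units="real")
        cg = map_trajectory(sub, cg_ratio=4, n_beads=240, seed=2)
        members = cg.metadata["members"]
        for t in range(cg.n_frames):
            flat = members[t].ravel()
            assert flat.size == 960 and np.unique(flat).size == 960

    def test_same_seed_gives_identical_cg_trajectory(self, brownian_fine):
        sub = Trajectory(positions=brownian_fine.positions[:5],
                         box=brownian_fine.box,
                         velocities=brownian_fine.velocities[:5],
                         frame_interval=brownian_fine.frame_interval,
                         units="real")
        a = map_trajectory(sub, cg_ratio=4, n_beads=200, seed=3)
        b = map_trajectory(sub, cg_ratio=4, n_beads=200, seed=3)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.velocities, b.velocities)

    def test_bead_motion_bounded_by_molecule_motion_plus_cloud_radius(self):
        # slowly moving molecules: beads track their clouds, so the mean bead
        # displacement cannot exceed mean molecule displacement + cloud size
        spec = GeneratorSpec(n_molecules=200, box=15.0, target_diffusivity=0.05,
                             frame_interval=1.0, n_frames=6, seed=9)
        fine = generate_brownian_water(spec)
        cg = map_trajectory(fine, cg_ratio=4, n_beads=45, seed=1)
        mol_step = np.abs(np.diff(fine.unwrapped, axis=0)).mean()
        bead_step = np.abs(np.diff(cg.unwrapped, axis=0)).mean()
        cloud_radius = 15.0 / 45 ** (1 / 3)   # generous typical cloud extent
        assert bead_step <= mol_step + cloud_radius

    def test_displacement_velocity_mode_matches_frame_differences(self):
        # tight, well-separated molecule pairs drifting rigidly: every bead
        # follows its own pair, so the displacement estimate is exactly the
        # drift divided by the frame interval
        rng = np.random.RandomState(6)
        centres = rng.uniform(1.0, 9.0, (12, 3))
        pos0 = np.repeat(centres, 2, axis=0)
        pos0[::2, 0] += 0.05
        drift = np.array([0.1, 0.0, 0.0])
        fine = Trajectory(positions=np.stack([pos0, pos0 + drift, pos0 + 2 * drift]) % 10.0,
                          box=np.full(3, 10.0), frame_interval=2.0, units="real")
        cg = map_trajectory(fine, cg_ratio=2, n_beads=10, seed=0,
                            velocity_mode="displacement")
        assert np.allclose(cg.velocities[0], drift / 2.0, atol=1e-9)

    def test_member_mean_mode_requires_fine_velocities(self):
        fine = Trajectory(positions=np.zeros((2, 10, 3)) + 1.0,
                          box=np.full(3, 5.0), frame_interval=1.0, units="real")
        with pytest.raises(ValueError, match="velocities"):
            map_trajectory(fine, cg_ratio=2, n_beads=4, seed=0)
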