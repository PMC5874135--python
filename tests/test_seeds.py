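"""Seed-table fixture, coordinate mapping and cubical ROI extraction."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import seedpls
from seedpls.errors import (
    EmptyROIError,
    MidlineSeedError,
    OutOfBoundsError,
    UnsupportedAffineError,
)
from seedpls.seeds import SeedSpec, extract_cube, mirror_seed, mm_to_voxel


class TestSeedTable:
    def test_four_seeds_per_network(self):
        table = seedpls.builtin_seed_table()
        assert len(table) == 24
        for net in table.networks:
            assert len(table.network_seeds(net)) == 4

    def test_bilateral_pairs_mirror(self):
        """Every non-midline seed's contralateral partner is in the table."""
        table = seedpls.builtin_seed_table()
        coords = {(s.network, s.x, s.y, s.z) for s in table}
        for s in table:
            if s.x == 0:
                continue
            partner = (s.network, -s.x, s.y, s.z)
            if s.network == "default" and s.x == -7:
                # anterior/posterior midline-adjacent seeds have no mirror
                assert partner not in coords
            else:
                assert partner in coords

    def test_laterality_consistent_with_x_sign(self):
        for s in seedpls.builtin_seed_table():
            assert s.laterality == ("L" if s.x < 0 else "R")

    def test_tsv_round_trip(self, tmp_path):
        table = seedpls.builtin_seed_table()
        path = tmp_path / "seeds.tsv"
        table.to_tsv(path)
        again = seedpls.SeedTable.from_tsv(path)
        assert [s.coord_mm for s in again] == [s.coord_mm for s in table]

    def test_inconsistent_laterality_rejected(self):
        with pytest.raises(ValueError):
            SeedSpec("visual", -3, -74, 23, "R", "bad")


class TestMirrorSeed:
    @pytest.mark.parametrize(
        "coord, mirrored",
        [((-40, 50, 7), (40, 50, 7)), ((-3, -74, 23), (3, -74, 23))],
    )
    def test_known_pairs(self, coord, mirrored):
        s = SeedSpec("frontoparietal", *coord, "L", "x")
        m = mirror_seed(s)
        assert (m.x, m.y, m.z) == mirrored
        assert m.laterality == "R"

    @given(
        x=st.floats(min_value=1, max_value=70),
        y=st.floats(min_value=-100, max_value=70),
        z=st.floats(min_value=-50, max_value=80),
    )
    def test_involution(self, x, y, z):
        s = SeedSpec("visual", x, y, z, "R", "p")
        assert mirror_seed(mirror_seed(s)) == s

    def test_midline_rejected(self):
        s = SeedSpec("default", 0, 49, 18, "L", "midline")
        with pytest.raises(MidlineSeedError):
            mirror_seed(s)


class TestMmToVoxel:
    def test_identity_affine_origin(self):
        assert mm_to_voxel(np.eye(4), (0, 0, 0), (5, 5, 5)) == (0, 0, 0)

    def test_two_mm_grid(self):
        """2 mm isotropic grid with the origin at voxel (45, 54, 45)."""
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        affine[:3, 3] = (-90, -108, -90)
        assert mm_to_voxel(affine, (-22, -8, 54), (91, 109, 91)) == (34, 50, 72)

    def test_round_half_away_from_zero(self):
        affine = np.eye(4)
        affine[:3, 3] = -2.0
        # fractional index 2.5 rounds to 3 (away from zero), not banker's 2
        assert mm_to_voxel(affine, (0.5, -0.5, 0.0), (7, 7, 7)) == (3, 2, 2)

    def test_out_of_bounds(self):
        affine = np.eye(4)
        with pytest.raises(OutOfBoundsError):
            mm_to_voxel(affine, (5.0, 0, 0), (5, 5, 5))

    def test_rotated_affine_rejected(self):
        affine = np.eye(4)
        affine[0, 1] = 0.3
        with pytest.raises(UnsupportedAffineError):
            mm_to_voxel(affine, (0, 0, 0), (5, 5, 5))


def _centered_affine(shape, vs):
    affine = np.diag([vs, vs, vs, 1.0])
    affine[:3, 3] = -vs * (np.asarray(shape) - 1) / 2.0
    return affine


class TestExtractCube:
    def test_voxel_membership_matches_enumeration(self):
        """10.5 mm cube on a 1.5 mm grid: mean equals a brute-force oracle."""
        shape = (15, 15, 15)
        vs = 1.5
        affine = _centered_affine(shape, vs)
        rng = np.random.default_rng(0)
        vol = rng.normal(size=shape)
        got = extract_cube(vol, affine, (0.0, 0.0, 0.0), 10.5)
        # oracle: enumerate voxel centers within 5.25 mm per axis
        vals = []
        for i in range(shape[0]):
            for j in range(shape[1]):
                for k in range(shape[2]):
                    mm = affine[:3, 3] + vs * np.array([i, j, k])
                    if np.all(np.abs(mm) <= 10.5 / 2 + 1e-9):
                        vals.append(vol[i, j, k])
        assert len(vals) == 343  # 7 voxels per axis
        assert got == pytest.approx(np.mean(vals), abs=1e-12)

    def test_constant_volume(self):
        affine = _centered_affine((9, 9, 9), 2.0)
        assert extract_cube(np.full((9, 9, 9), 3.25), affine, (0, 0, 0), 10.5) == 3.25

    def test_sub_voxel_cube_is_single_voxel(self):
        shape = (9, 9, 9)
        affine = _centered_affine(shape, 2.0)
        vol = np.zeros(shape)
        vol[4, 4, 4] = 7.0
        assert extract_cube(vol, affine, (0, 0, 0), 1.0) == 7.0

    def test_empty_mask_intersection(self):
        shape = (9, 9, 9)
        affine = _centered_affine(shape, 2.0)
        with pytest.raises(EmptyROIError):
            extract_cube(np.ones(shape), affine, (0, 0, 0), 4.0,
                         mask=np.zeros(shape, dtype=bool))

    def test_partial_mask_warns_and_averages(self):
        shape = (9, 9, 9)
        affine = _centered_affine(shape, 2.0)
        vol = np.ones(shape)
        mask = np.zeros(shape, dtype=bool)
        mask[4, 4, 4] = True
        with pytest.warns(UserWarning, match="partially"):
            assert extract_cube(vol, affine, (0, 0, 0), 10.0, mask=mask) == 1.0

    def test_translation_consistency(self):
        """Shifting volume and center by one voxel leaves the value unchanged."""
        shape = (13, 13, 13)
        vs = 2.0
        affine = _centered_affine(shape, vs)
        rng = np.random.default_rng(1)
        vol = rng.normal(size=shape)
        v0 = extract_cube(vol, affine, (0.0, 0.0, 0.0), 9.0)
        shifted = np.roll(vol, 1, axis=0)
        v1 = extract_cube(shifted, affine, (vs, 0.0, 0.0), 9.0)
        assert v0 == pytest.approx(v1, abs=1e-12)


class TestNetworkSeedAverage:
    def test_mean_of_four_cubes(self, small_dataset, tiny_table):
        """Seed cubes painted 1,2,3,4 average to 2.5."""
        ds = small_dataset
        vol = np.zeros(ds.grid_shape)
        seeds = tiny_table.network_seeds("ventral_attention")
        for value, seed in enumerate(seeds, start=1):
            idx = seedpls.mm_to_voxel(ds.affine, seed.coord_mm, ds.grid_shape)
            vol[idx[0] - 1 : idx[0] + 2, idx[1] - 1 : idx[1] + 2, idx[2] - 1 : idx[2] + 2] = value
        one = seedpls.GrayMatterDataset(
            volumes=vol[None],
            mask=ds.mask,
            affine=ds.affine,
            participants=ds.participants.iloc[:1],
        )
        y = seedpls.network_seed_average(one, tiny_table, "ventral_attention", edge_mm=5.0)
        assert y.values[0] == pytest.approx(2.5)

    def test_permutation_equivariance(self, small_dataset, tiny_table):
        ds = small_dataset
        y = seedpls.network_seed_average(ds, tiny_table, "ventral_attention").values
        order = np.random.default_rng(3).permutation(ds.n_participants)
        shuffled = seedpls.GrayMatterDataset(
            volumes=ds.volumes[order],
            mask=ds.mask,
            affine=ds.affine,
            participants=ds.participants.iloc[order].reset_index(drop=True),
        )
        y2 = seedpls.network_seed_average(shuffled, tiny_table, "ventral_attention").values
        np.testing.assert_allclose(y2, y[order], atol=1e-12)

    def test_unknown_network(self, small_dataset, tiny_table):
        with pytest.raises(KeyError):
            seedpls.network_seed_average(small_dataset, tiny_table, "somatomotor")
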