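"""Normalization, VOI extraction, splitting and anti-leakage slice policies."""

import numpy as np
import pytest

import mrproton as mp
from mrproton.preprocessing import (
    first_half_slices,
    second_half_slices,
    voi_for_insert,
)
from mrproton.synthetic_imaging import VolumeImage


def uniform_image(value, shape=(4, 5, 5)):
    return VolumeImage(np.full(shape, float(value)), (1.0, 1.0, 1.0), channel="T1-D-P-W")


class TestNormalizeByWater:
    def test_uniform_water_maps_to_one(self):
        img = uniform_image(200.0)
        mask = np.ones(img.grid.shape, dtype=bool)
        out = mp.normalize_by_water(img, mask)
        assert np.allclose(out.grid, 1.0)
        assert out.normalized

    def test_simple_ratio(self):
        grid = np.full((2, 2, 2), 200.0)
        grid[0, 0, 0] = 300.0
        mask = np.ones_like(grid, dtype=bool)
        mask[0, 0, 0] = False
        out = mp.normalize_by_water(VolumeImage(grid, (1, 1, 1), "c"), mask)
        assert out.grid[0, 0, 0] == pytest.approx(1.5)

    def test_water_mean_is_one_to_tolerance(self, small_scene):
        _, labels = small_scene
        img = mp.render_sequence(labels, mp.DEFAULT_SIGNAL_TABLE, "T1-D-P-W", seed=2)
        mask = mp.water_mask(labels)
        out = mp.normalize_by_water(img, mask)
        assert abs(out.grid[mask].mean() - 1.0) < 1e-9

    def test_idempotent(self):
        img = uniform_image(123.0)
        mask = np.ones(img.grid.shape, dtype=bool)
        once = mp.normalize_by_water(img, mask)
        twice = mp.normalize_by_water(once, mask)
        assert np.allclose(once.grid, twice.grid, atol=1e-9)

    def test_empty_mask_rejected(self):
        img = uniform_image(1.0)
        with pytest.raises(ValueError, match="empty"):
            mp.normalize_by_water(img, np.zeros(img.grid.shape, dtype=bool))


class TestSlicePolicies:
    def test_even_halving(self):
        assert list(first_half_slices(60)) == list(range(30))
        assert list(second_half_slices(60)) == list(range(30, 60))

    def test_odd_extra_slice_goes_to_application(self):
        assert len(list(first_half_slices(7))) == 3
        assert len(list(second_half_slices(7))) == 4

    def test_two_slice_volume(self):
        assert list(second_half_slices(2)) == [1]

    def test_single_slice_rejected(self):
        with pytest.raises(ValueError):
            first_half_slices(1)

    def test_halves_cover_and_do_not_overlap(self):
        for n in (2, 3, 60, 253):
            first = set(first_half_slices(n))
            second = set(second_half_slices(n))
            assert first | second == set(range(n))
            assert not first & second

    def test_application_mask_is_second_half(self, small_scene):
        _, labels = small_scene
        mask = mp.application_mask(labels)
        half = labels.n_slices // 2
        assert not mask[:half].any()
        assert mask[half:].all()


class TestExtraction:
    def test_row_count_and_targets(self, small_scene, small_channels, tissues):
        _, labels = small_scene
        table = mp.extract_voi_voxels(
            small_channels, labels, tissues, n_per_phantom=300, radius=8, seed=0
        )
        assert len(table) == 600  # 2 phantoms x 300
        assert table.channels.shape == (600, 3)
        muscle = table.tissue == "Muscle"
        assert muscle.sum() == 300
        assert np.all(table.density[muscle] == 1.064)
        assert np.all(table.rsp[muscle] == 1.056)

    def test_rows_come_from_allowed_slices(self, small_scene, small_channels, tissues):
        _, labels = small_scene
        table = mp.extract_voi_voxels(
            small_channels, labels, tissues, n_per_phantom=300, radius=8, seed=0,
            slice_policy="first_half",
        )
        assert table.provenance["slice"].max() < labels.n_slices // 2

    def test_deterministic_per_seed(self, small_scene, small_channels, tissues):
        _, labels = small_scene
        t1 = mp.extract_voi_voxels(small_channels, labels, tissues, 200, radius=8, seed=5)
        t2 = mp.extract_voi_voxels(small_channels, labels, tissues, 200, radius=8, seed=5)
        assert np.array_equal(t1.channels, t2.channels)
        assert t1.provenance.equals(t2.provenance)

    def test_shortfall_names_phantom(self, small_scene, small_channels, tissues):
        _, labels = small_scene
        with pytest.raises(ValueError, match="Muscle"):
            mp.extract_voi_voxels(
                small_channels, labels, tissues, n_per_phantom=10**6, radius=8, seed=0
            )

    def test_noiseless_signature_is_nominal_vector(self, small_scene, small_channels):
        cfg, labels = small_scene
        table = mp.extract_voi_voxels(
            small_channels, labels, mp.load_tissues(), 100, radius=8, seed=1
        )
        for name in ("Muscle", "Adipose"):
            rows = table.channels[table.tissue == name]
            nominal = [mp.DEFAULT_SIGNAL_TABLE.signal(name, s) for s in cfg.sequences]
            assert np.allclose(rows, nominal, atol=1e-6)

    def test_scale_invariance_of_normalized_extraction(self, small_scene, tissues):
        """Global positive rescaling of the raw image cannot change the table."""
        cfg, labels = small_scene
        raw = mp.render_sequence(labels, mp.DEFAULT_SIGNAL_TABLE, "T2-STIR", seed=4)
        mask = mp.water_mask(labels)
        scaled = VolumeImage(raw.grid * 7.3, raw.spacing, raw.channel)
        t1 = mp.extract_voi_voxels(
            [mp.normalize_by_water(raw, mask)], labels, tissues, 200, radius=8, seed=9
        )
        t2 = mp.extract_voi_voxels(
            [mp.normalize_by_water(scaled, mask)], labels, tissues, 200, radius=8, seed=9
        )
        assert np.allclose(t1.channels, t2.channels, atol=1e-12)

    def test_unnormalized_channels_rejected(self, small_scene, tissues):
        _, labels = small_scene
        raw = mp.render_sequence(labels, mp.DEFAULT_SIGNAL_TABLE, "T2-STIR", seed=4)
        with pytest.raises(ValueError, match="normalized"):
            mp.extract_voi_voxels([raw], labels, tissues, 100, radius=8)

    def test_voi_stays_inside_insert(self, small_scene, tissues):
        _, labels = small_scene
        voi = voi_for_insert(labels, "Muscle", radius=8)
        mask = mp.preprocessing.voi_mask(labels, "Muscle", voi)
        assert mask.sum() > 0
        assert np.all(labels.grid[mask] == labels.id_of("Muscle"))


class TestSplit:
    def test_75_25_partition(self, small_scene, small_channels, tissues):
        _, labels = small_scene
        table = mp.extract_voi_voxels(small_channels, labels, tissues, 200, radius=8, seed=0)
        train, val = mp.split_train_val(table, 0.75, seed=0)
        assert len(train) == 300 and len(val) == 100
        # per-phantom stratification
        assert (train.tissue == "Muscle").sum() == 150
        # disjoint and exhaustive on provenance keys
        key = lambda t: set(zip(t.provenance["scene"], t.provenance["voxel"]))
        assert not key(train) & key(val)
        assert key(train) | key(val) == key(table)

    def test_fraction_one_gives_empty_validation(self, small_scene, small_channels, tissues):
        _, labels = small_scene
        table = mp.extract_voi_voxels(small_channels, labels, tissues, 50, radius=8, seed=0)
        train, val = mp.split_train_val(table, 1.0, seed=0)
        assert len(train) == 100 and len(val) == 0

    def test_deterministic(self, small_scene, small_channels, tissues):
        _, labels = small_scene
        table = mp.extract_voi_voxels(small_channels, labels, tissues, 100, radius=8, seed=0)
        a = mp.split_train_val(table, 0.75, seed=3)
        b = mp.split_train_val(table, 0.75, seed=3)
        assert np.array_equal(a[0].channels, b[0].channels)
        assert np.array_equal(a[1].channels, b[1].channels)

    def test_empty_table_rejected(self, small_scene, small_channels, tissues):
        _, labels = small_scene
        table = mp.extract_voi_voxels(small_channels, labels, tissues, 10, radius=8, seed=0)
        with pytest.raises(ValueError):
            mp.split_train_val(table.select(np.array([], dtype=int)), 0.75)


class TestVoxelTableIO:
    def test_csv_round_trip(self, small_scene, small_channels, tissues, tmp_path):
        _, labels = small_scene
        table = mp.extract_voi_voxels(small_channels, labels, tissues, 50, radius=8, seed=0)
        table.to_csv(tmp_path / "t.csv")
        back = mp.VoxelTable.from_csv(tmp_path / "t.csv", table.channel_names)
        assert np.allclose(back.channels, table.channels)
        assert np.array_equal(back.tissue, table.tissue)

    def test_channel_restriction_orders_columns(self, small_scene, small_channels, tissues):
        _, labels = small_scene
        table = mp.extract_voi_voxels(small_channels, labels, tissues, 20, radius=8, seed=0)
        sub = table.restrict_channels(["T2-STIR", "T1-D-P-W"])
        assert sub.channel_names == ("T2-STIR", "T1-D-P-W")
        i, j = table.channel_names.index("T2-STIR"), table.channel_names.index("T1-D-P-W")
        assert np.array_equal(sub.channels[:, 0], table.channels[:, i])
        assert np.array_equal(sub.channels[:, 1], table.channels[:, j])

    def test_missing_channel_reported(self, small_scene, small_channels, tissues):
        _, labels = small_scene
        table = mp.extract_voi_voxels(small_channels, labels, tissues, 20, radius=8, seed=0)
        with pytest.raises(KeyError, match="ZTE"):
            table.restrict_channels(["ZTE"])
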