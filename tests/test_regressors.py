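"""FCNN training, linear baseline and DECT empirical conversion models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mrproton as mp
from mrproton.fcnn import FCNN, FCNNConfig
from mrproton.preprocessing import VoxelTable

SMALL = FCNNConfig(hidden_layers=2, width=16, batch_size=64, max_epochs=60, epochs_used=60, seed=0)


def make_table(signatures, targets, n=80, noise=0.0, seed=0, channels=("c1", "c2")):
    rng = np.random.default_rng(seed)
    X, dens, names = [], [], []
    for name, sig in signatures.items():
        x = np.tile(sig, (n, 1)) + (rng.normal(0, noise, (n, len(sig))) if noise else 0.0)
        X.append(x)
        dens.append(np.full(n, targets[name]))
        names += [name] * n
    X = np.vstack(X)
    dens = np.concatenate(dens)
    return VoxelTable(
        channels=X,
        channel_names=tuple(channels),
        density=dens,
        rsp=dens,  # same targets for these unit tests
        tissue=np.array(names, dtype=object),
        provenance=pd.DataFrame({"phantom": names, "scene": "s", "slice": 0, "voxel": np.arange(len(dens))}),
    )


class TestDectEmpiricalDensity:
    def test_substitutions(self):
        assert mp.dect_empirical_density(1.0) == pytest.approx(1.0014, rel=1e-12)
        assert mp.dect_empirical_density(0.0) == pytest.approx(-0.1746, rel=1e-12)
        assert mp.dect_empirical_density(2.0) - mp.dect_empirical_density(1.0) == pytest.approx(
            1.176, rel=1e-12
        )

    def test_affine_in_rho_e(self):
        x = np.linspace(0.2, 2.0, 11)
        out = mp.dect_empirical_density(x)
        # second differences of an affine map vanish
        assert np.allclose(np.diff(out, 2), 0.0, atol=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            mp.dect_empirical_density(np.nan)


class TestDectEmpiricalRSP:
    @pytest.mark.parametrize(
        "rho_e, z_eff, expected",
        [
            (1.0, 9.0, 0.9905),  # third branch
            (1.0, 0.2, 1.0),  # first branch returns rho_e
            (1.35, 12.0, (1.1117 - 0.0116 * 12.0) * 1.35),  # fourth branch
            (1.0, 7.0, 1.1114 - 0.0148 * 7.0),  # second branch
        ],
    )
    def test_branch_values(self, rho_e, z_eff, expected):
        assert mp.dect_empirical_rsp(rho_e, z_eff) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("edge, below, at", [
        (0.5, lambda r: r, lambda r: (1.1114 - 0.0148 * 0.5) * r),
        (8.5, lambda r: (1.1114 - 0.0148 * 8.5) * r, lambda r: 0.9905 * r),
        (10.0, lambda r: 0.9905 * r, lambda r: (1.1117 - 0.0116 * 10.0) * r),
    ])
    def test_half_open_interval_edges(self, edge, below, at):
        r = 1.2
        assert mp.dect_empirical_rsp(r, edge) == pytest.approx(at(r), rel=1e-12)
        assert mp.dect_empirical_rsp(r, np.nextafter(edge, 0)) == pytest.approx(
            below(np.float64(r)), rel=1e-9
        )

    def test_vectorized_matches_scalar_oracle(self):
        rng = np.random.default_rng(123)
        rho = rng.uniform(0.0, 2.0, 100_000)
        zeff = rng.uniform(0.0, 20.0, 100_000)

        def scalar(r, z):
            if z < 0.5:
                return r
            if z < 8.5:
                return (1.1114 - 0.0148 * z) * r
            if z < 10.0:
                return 0.9905 * r
            return (1.1117 - 0.0116 * z) * r

        expected = np.array([scalar(r, z) for r, z in zip(rho, zeff)])
        assert np.array_equal(mp.dect_empirical_rsp(rho, zeff), expected)

    def test_negative_z_eff_rejected(self):
        with pytest.raises(ValueError):
            mp.dect_empirical_rsp(1.0, -1.0)

    @given(st.floats(0.1, 2.0), st.floats(0.0, 20.0), st.floats(0.1, 3.0))
    def test_homogeneous_degree_one_in_rho_e(self, rho, zeff, c):
        assert mp.dect_empirical_rsp(c * rho, zeff) == pytest.approx(
            c * mp.dect_empirical_rsp(rho, zeff), rel=1e-12
        )


class TestLinearBaseline:
    def test_exact_line_recovered(self):
        sigs = {f"t{i}": (s,) for i, s in enumerate([0.2, 0.5, 1.0, 1.5])}
        targets = {k: 2.0 * v[0] + 0.5 for k, v in sigs.items()}
        table = make_table(sigs, targets, channels=("T1-D-P-W",))
        model = mp.regressors.linear_baseline(table, "density")
        assert model.slope == pytest.approx(2.0, abs=1e-9)
        assert model.intercept == pytest.approx(0.5, abs=1e-9)

    def test_constant_target(self):
        sigs = {"a": (0.3,), "b": (1.2,)}
        table = make_table(sigs, {"a": 1.1, "b": 1.1}, channels=("T1-D-P-W",))
        model = mp.regressors.linear_baseline(table, "density")
        assert model.slope == pytest.approx(0.0, abs=1e-9)
        assert model.intercept == pytest.approx(1.1, abs=1e-9)

    def test_degenerate_channel_rejected(self):
        table = make_table({"a": (1.0,)}, {"a": 1.0}, channels=("T1-D-P-W",))
        with pytest.raises(ValueError, match="constant"):
            mp.regressors.linear_baseline(table, "density")


class TestFCNN:
    def test_constant_target_converges(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 2, size=(256, 3))
        y = np.full(256, 1.3)
        # full-batch with a larger step size: enough optimizer travel for the
        # network output to flatten onto the degenerate constant optimum
        cfg = FCNNConfig(hidden_layers=2, width=16, batch_size=256, learning_rate=2e-2,
                         max_epochs=4000, epochs_used=4000, seed=0)
        model = FCNN(3, 1, cfg)
        hist = model.fit(X, y)
        assert hist["train_loss"][-1] < 1e-6
        assert np.allclose(model.predict(X), 1.3, atol=1e-2)

    def test_history_finite_and_nonnegative(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 1, (128, 2))
        y = X.sum(axis=1)
        model = FCNN(2, 1, SMALL)
        hist = model.fit(X[:96], y[:96], X[96:], y[96:])
        assert len(hist["val_loss"]) == SMALL.max_epochs
        assert all(np.isfinite(v) and v >= 0 for v in hist["train_loss"])
        assert all(np.isfinite(v) and v >= 0 for v in hist["val_loss"])

    def test_reproducible_per_seed(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, (200, 2))
        y = 0.5 * X[:, 0] + 1.0
        m1, m2 = FCNN(2, 1, SMALL), FCNN(2, 1, SMALL)
        h1 = m1.fit(X, y)
        h2 = m2.fit(X, y)
        assert h1["train_loss"] == h2["train_loss"]
        assert np.array_equal(m1.predict(X), m2.predict(X))

    def test_prediction_deterministic(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0, 1, (100, 2))
        model = FCNN(2, 1, SMALL)
        model.fit(X, X[:, 0])
        assert np.array_equal(model.predict(X), model.predict(X))

    def test_channel_count_mismatch_rejected(self):
        model = FCNN(4, 1, SMALL)
        with pytest.raises(ValueError, match="4"):
            model.predict(np.zeros((5, 3)))

    def test_epochs_used_must_not_exceed_max(self):
        with pytest.raises(ValueError, match="epochs_used"):
            FCNNConfig(max_epochs=100, epochs_used=200)

    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 1, (100, 2))
        model = FCNN(2, 1, SMALL)
        model.fit(X, X[:, 0] + 0.2)
        model.save(tmp_path / "m")
        back = FCNN.load(tmp_path / "m")
        assert np.array_equal(back.predict(X), model.predict(X))


class TestBundle:
    def test_schemas_match_published_channel_sets(self):
        assert mp.SCHEMAS["A"].channels == ("T1-D-P-W", "T1-D-P-F", "T2-STIR")
        assert mp.SCHEMAS["B"].channels == ("T1-D-P-W", "T1-D-P-F", "T2-STIR", "ZTE")
        assert mp.SCHEMAS["A"].targets == ("density", "rsp")
        assert mp.SCHEMAS["C"].targets == ("density",)

    def test_parameter_recovery_on_distinct_signatures(self):
        sigs = {
            "a": (0.3, 2.0), "b": (1.2, 0.4), "c": (1.8, 1.5), "d": (0.7, 0.9),
        }
        dens = {"a": 0.94, "b": 1.06, "c": 1.42, "d": 1.09}
        table = make_table(sigs, dens, n=120, channels=("T1-D-P-W", "T2-STIR"))
        train, val = mp.split_train_val(table, 0.75, seed=0)
        cfg = FCNNConfig(hidden_layers=3, width=24, batch_size=100, max_epochs=150,
                         epochs_used=150, seed=1)
        bundle = mp.train_bundle(train, val, cfg, schema="C")
        pred = mp.predict_table(bundle, val, "density")
        errs = np.abs(pred - val.density) / val.density * 100
        assert errs.max() < 0.5

    def test_wrong_channel_count_rejected(self):
        cfg = FCNNConfig(hidden_layers=1, width=4, max_epochs=1, epochs_used=1)
        table = make_table({"a": (0.5, 1.0)}, {"a": 1.0}, channels=("T1-D-P-W", "T2-STIR"))
        bundle = mp.train_bundle(table, None, cfg, schema="C", epochs=1)
        with pytest.raises(ValueError, match="channels"):
            bundle.predict(np.zeros((3, 3)), "density")

    def test_joint_two_output_variant(self):
        sigs = {"a": (0.3, 2.0), "b": (1.2, 0.4)}
        dens = {"a": 0.94, "b": 1.42}
        table = make_table(sigs, dens, n=100, channels=("T1-D-P-W", "T2-STIR"))
        cfg = FCNNConfig(hidden_layers=2, width=16, batch_size=50, max_epochs=120,
                         epochs_used=120, seed=2)
        # schema C only targets density; use A-style dual targets on 2 channels
        schema = mp.ModelSchema("C2", ("T1-D-P-W", "T2-STIR"), ("density", "rsp"))
        bundle = mp.train_bundle(table, None, cfg, schema=schema, joint=True)
        pred_d = mp.predict_table(bundle, table, "density")
        pred_r = mp.predict_table(bundle, table, "rsp")
        assert np.abs(pred_d - table.density).max() < 0.02
        assert np.abs(pred_r - table.rsp).max() < 0.02

    def test_predict_map_masks_and_schema(self, small_scene, small_channels, tissues):
        _, labels = small_scene
        table = mp.extract_voi_voxels(small_channels, labels, tissues, 150, radius=8, seed=0)
        cfg = FCNNConfig(hidden_layers=2, width=16, batch_size=100, max_epochs=80,
                         epochs_used=80, seed=3)
        bundle = mp.train_bundle(table, None, cfg, schema="A")
        vol = mp.predict_map(bundle, small_channels, labels.container_mask(), "density")
        assert vol.grid.shape == labels.shape
        assert np.all(vol.grid[~labels.container_mask()] == 0.0)
        again = mp.predict_map(bundle, small_channels, labels.container_mask(), "density")
        assert np.array_equal(vol.grid, again.grid)
        with pytest.raises(ValueError, match="schema"):
            mp.predict_map(bundle, small_channels[:2], labels.container_mask(), "density")
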