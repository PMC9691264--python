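"""Volume I/O, fold manifests, configuration, and the CLI pipeline."""

import json

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from choroidseg.cli import main
from choroidseg.config import load_config
from choroidseg.io import load_volume, make_folds, save_volume
from choroidseg.synthetic import SimConfig, write_dataset


class TestVolumeIO:
    def test_round_trip_bit_exact(self, tmp_path, rng):
        vol = rng.integers(0, 4096, size=(3, 16, 16)).astype(np.uint16)
        p = save_volume(tmp_path / "vol.tif", vol, axial_spacing=4.0,
                        lateral_spacing=6.0, slice_spacing=24.0, bit_depth=12)
        loaded = load_volume(p)
        assert np.array_equal(
            np.round(loaded.data * 4095).astype(np.uint16), vol)
        assert loaded.axial_spacing == 4.0 and loaded.bit_depth == 12

    def test_low_bit_depth_range(self, tmp_path, small_config):
        cfg = small_config.replace(bit_depth=6, n_bscans=2)
        out = write_dataset(tmp_path / "ds", cfg)
        vol = load_volume(out)
        raw = np.round(vol.data * 63)
        assert raw.max() <= 63 and vol.data.max() <= 1.0

    def test_directory_and_multipage_agree(self, tmp_path, small_config):
        from choroidseg.synthetic import generate_volume

        cfg = small_config.replace(n_bscans=3)
        volume, _, _ = generate_volume(cfg)
        d = write_dataset(tmp_path / "dir_form", cfg)
        save_volume(tmp_path / "vol.tif", volume,
                    axial_spacing=cfg.axial_spacing,
                    lateral_spacing=cfg.lateral_spacing,
                    slice_spacing=cfg.slice_spacing, bit_depth=cfg.bit_depth)
        a = load_volume(d)
        b = load_volume(tmp_path / "vol.tif")
        assert np.array_equal(a.data, b.data)

    def test_missing_metadata_names_keys(self, tmp_path):
        (tmp_path / "x.tif").write_bytes(b"")
        with pytest.raises(FileNotFoundError, match="axial_spacing_um"):
            load_volume(tmp_path / "x.tif")
        (tmp_path / "x.json").write_text(json.dumps({"bit_depth": 8}))
        with pytest.raises(KeyError, match="lateral_spacing_um"):
            load_volume(tmp_path / "x.tif")


class TestFolds:
    def test_sizes_disjoint_union(self):
        folds = make_folds(8, k=4, seed=0)
        vals = [set(f["val"]) for f in folds]
        assert all(len(v) == 2 for v in vals)
        assert set().union(*vals) == set(range(8))
        for i in range(4):
            for j in range(i + 1, 4):
                assert not vals[i] & vals[j]
            assert not set(folds[i]["train"]) & vals[i]

    def test_deterministic_under_seed(self):
        assert make_folds(20, seed=5) == make_folds(20, seed=5)
        assert make_folds(20, seed=5) != make_folds(20, seed=6)

    def test_grouping_keeps_volumes_together(self):
        groups = ["v0"] * 5 + ["v1"] * 5 + ["v2"] * 5 + ["v3"] * 5
        folds = make_folds(20, k=4, seed=1, groups=groups)
        for f in folds:
            val_groups = {groups[i] for i in f["val"]}
            train_groups = {groups[i] for i in f["train"]}
            assert not val_groups & train_groups

    def test_too_few_items_or_groups(self):
        with pytest.raises(ValueError):
            make_folds(3, k=4)
        with pytest.raises(ValueError):
            make_folds(8, k=4, groups=["a"] * 4 + ["b"] * 4)


class TestConfig:
    def test_defaults_load_without_file(self):
        cfg = load_config(None)
        assert cfg.train.batch_size == 8
        assert cfg.train.lr == 5e-4
        assert cfg.folds == 4

    def test_seed_override_propagates(self, tmp_path):
        f = tmp_path / "c.yaml"
        f.write_text(yaml.safe_dump({"seed": 3, "sim": {"width": 32}}))
        cfg = load_config(f, seed=99)
        assert cfg.seed == 99 and cfg.sim.seed == 99
        assert cfg.sim.width == 32

    def test_unknown_keys_rejected(self, tmp_path):
        f = tmp_path / "c.yaml"
        f.write_text(yaml.safe_dump({"sim": {"nonsense": 1}}))
        with pytest.raises(ValueError, match="nonsense"):
            load_config(f)


@pytest.mark.timeout(600)
def test_cli_pipeline_end_to_end(tmp_path):
    """simulate -> pointmap -> train (tiny) -> predict -> evaluate ->
    morphometry on a 20-slice synthetic volume, checking every declared
    output file appears."""
    runner = CliRunner()
    cfg = {
        "seed": 7,
        "depth": 2,
        "base_channels": 8,
        "sim": {
            "width": 32, "height": 32, "n_bscans": 20,
            "axial_spacing": 10.0, "lateral_spacing": 94.0,
            "slice_spacing": 100.0, "mean_choroid_thickness": 100.0,
            "boundary_smoothness": 16.0, "csi_contrast": 0.8,
            "speckle_shape": 32.0, "bit_depth": 8, "seed": 7,
            "bm_mean_row_frac": 0.3, "boundary_amplitude": 2.0,
            "thickness_variation": 20.0,
        },
        "train": {"steps": 4, "batch_size": 4, "k_points": 6, "sigma": 3.0,
                  "seed": 7},
    }
    cfg_file = tmp_path / "cfg.yaml"
    cfg_file.write_text(yaml.safe_dump(cfg))
    data = tmp_path / "data"
    run = tmp_path / "run"
    preds = tmp_path / "preds"
    rep = tmp_path / "report.csv"
    morph = tmp_path / "morph"

    r = runner.invoke(main, ["simulate", "--config", str(cfg_file),
                             "--out", str(data)])
    assert r.exit_code == 0, r.output
    assert (data / "meta.json").exists()
    assert len(list((data / "images").glob("*.png"))) == 20

    r = runner.invoke(main, ["pointmap", "--traces", str(data / "traces"),
                             "--k", "6", "--sigma", "3", "--shape", "32", "32",
                             "--out", str(tmp_path / "pmaps")])
    assert r.exit_code == 0, r.output
    assert len(list((tmp_path / "pmaps").glob("*.npy"))) == 20

    r = runner.invoke(main, ["train", "--config", str(cfg_file),
                             "--data", str(data), "--out", str(run)])
    assert r.exit_code == 0, r.output
    assert (run / "checkpoint.pkl").exists()
    assert (run / "history.csv").exists()
    assert (run / "run_config.json").exists()

    r = runner.invoke(main, ["predict", "--checkpoint",
                             str(run / "checkpoint.pkl"),
                             "--images", str(data), "--out", str(preds)])
    assert r.exit_code == 0, r.output
    assert len(list(preds.glob("*_prob.tif"))) == 20

    r = runner.invoke(main, ["evaluate", "--pred", str(preds),
                             "--gt", str(data / "masks"), "--out", str(rep)])
    assert r.exit_code == 0, r.output
    assert rep.exists()

    r = runner.invoke(main, ["morphometry", "--traces", str(data / "traces"),
                             "--meta", str(data / "meta.json"),
                             "--out", str(morph)])
    assert r.exit_code == 0, r.output
    for name in ("thickness_um.tif", "thickness_um.csv", "etdrs.json",
                 "features.json"):
        assert (morph / name).exists(), name

    r = runner.invoke(main, ["crossval", "--n-items", "20",
                             "--out", str(tmp_path / "folds.json")])
    assert r.exit_code == 0, r.output
    assert len(json.loads((tmp_path / "folds.json").read_text())) == 4


def test_cli_config_error_exit_code(tmp_path):
    bad = tmp_path / "bad.yaml"
    bad.write_text(yaml.safe_dump({"sim": {"bit_depth": 7}}))
    r = CliRunner().invoke(main, ["simulate", "--config", str(bad),
                                  "--out", str(tmp_path / "o")])
    assert r.exit_code == 2
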