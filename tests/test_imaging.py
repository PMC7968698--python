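"""Frame partitioning and image/manifest round trips."""

import numpy as np
import pandas as pd
import pytest
from PIL import Image

from trapnet.data import TrapDataset, TILE
from trapnet.imaging import (
    FramePartitionSpec,
    load_manifest,
    load_split_directory,
    partition_frame,
    read_image,
    save_manifest,
    write_image,
)


@pytest.fixture()
def frame(rng):
    return rng.random((960, 1280))


def test_partition_returns_one_tile_per_anchor(frame, rng):
    # about a hundred trap anchors laid out on a grid, as on a real chip
    anchors = [(60 + 85 * r, 20 + 95 * c) for r in range(8) for c in range(13)]
    spec = FramePartitionSpec(anchors=anchors)
    tiles = partition_frame(frame, spec)
    assert tiles.shape == (104, TILE, TILE)
    for (r, c), tile in zip(anchors, tiles):
        np.testing.assert_array_equal(tile, frame[r : r + TILE, c : c + TILE])
        assert tile.sum() == pytest.approx(frame[r : r + TILE, c : c + TILE].sum())


def test_partition_identity_crop(frame):
    tiles = partition_frame(frame, FramePartitionSpec(anchors=[(0, 0)]))
    np.testing.assert_array_equal(tiles[0], frame[:TILE, :TILE])


def test_partition_rejects_out_of_bounds(frame):
    spec = FramePartitionSpec(anchors=[(0, 0), (901, 0)])  # 901 + 60 > 960
    with pytest.raises(ValueError, match="anchor 1"):
        partition_frame(frame, spec)


def test_partition_rejects_wrong_frame_size(rng):
    with pytest.raises(ValueError):
        partition_frame(rng.random((100, 100)), FramePartitionSpec(anchors=[(0, 0)]))


def test_anchor_csv_roundtrip(tmp_path):
    path = tmp_path / "anchors.csv"
    path.write_text("row,col\n0,0\n60,120\n")
    spec = FramePartitionSpec.from_csv(path)
    assert spec.anchors == [(0, 0), (60, 120)]


def test_image_write_read_roundtrip_8bit(tmp_path, rng):
    img = rng.random((TILE, TILE))
    for name in ("a.png", "a.tif"):
        write_image(img, tmp_path / name)
        back = read_image(tmp_path / name)
        assert back.shape == (TILE, TILE)
        # 8-bit quantization is the only loss
        assert np.max(np.abs(back - img)) <= 1 / 255 + 1e-12


def test_16bit_input_normalized(tmp_path):
    arr = np.full((TILE, TILE), 2 ** 15, dtype=np.uint16)
    Image.fromarray(arr).save(tmp_path / "deep.png")
    img = read_image(tmp_path / "deep.png")
    assert img.max() <= 1.0
    assert img.min() >= 0.0


def test_manifest_roundtrip(tmp_path, small_easy_dataset):
    ds = small_easy_dataset.take(range(10))
    man_path = save_manifest(ds, tmp_path)
    back = load_manifest(man_path)
    assert back.labels == ds.labels
    assert list(back.manifest["split"]) == list(ds.manifest["split"])
    assert np.max(np.abs(back.images - ds.images)) <= 1 / 255 + 1e-12


def test_save_with_masks_writes_label_images(tmp_path):
    from trapnet.synthetic import SceneParams, generate_dataset

    ds = generate_dataset({"mduC": 2}, SceneParams(), (1.0, 0, 0), seed=3)
    ds.save(tmp_path, with_masks=True)
    masks = sorted((tmp_path / "masks").glob("*.png"))
    assert len(masks) == 2
    lab = np.asarray(Image.open(masks[0]))
    assert set(np.unique(lab)) == {0, 1, 2}  # background, mother, daughter


def test_manifest_unknown_label_rejected(tmp_path, small_easy_dataset):
    ds = small_easy_dataset.take(range(3))
    man_path = save_manifest(ds, tmp_path)
    man = pd.read_csv(man_path)
    man.loc[1, "label5"] = "xyz"
    man.to_csv(man_path, index=False)
    with pytest.raises(ValueError, match="row 1"):
        load_manifest(man_path)


def test_manifest_wrong_image_shape_rejected(tmp_path, rng):
    bad = (rng.random((61, 60)) * 255).astype(np.uint8)
    Image.fromarray(bad, mode="L").save(tmp_path / "bad.png")
    (tmp_path / "manifest.csv").write_text("path,label5\nbad.png,nC\n")
    with pytest.raises(ValueError, match="bad.png"):
        load_manifest(tmp_path / "manifest.csv")


def test_missing_manifest_rejected(tmp_path):
    with pytest.raises(FileNotFoundError):
        load_manifest(tmp_path / "nope.csv")


def _make_split_tree(root, sizes):
    rng = np.random.default_rng(0)
    for split, per_cat in sizes.items():
        for cat, n in per_cat.items():
            d = root / split / cat
            d.mkdir(parents=True)
            for i in range(n):
                img = (rng.random((TILE, TILE)) * 255).astype(np.uint8)
                Image.fromarray(img, mode="L").save(d / f"{i}.png")


def test_split_directory_counts(tmp_path):
    """The packaged-release directory layout reports per-split counts."""
    sizes = {
        "train": {"nC": 4, "mC": 3, "mduC": 2, "mddC": 2, "exC": 1},
        "val": {"nC": 2, "mC": 1},
        "test": {"nC": 3, "exC": 2},
    }
    _make_split_tree(tmp_path, sizes)
    report = load_split_directory(tmp_path)
    assert report["train"]["total"] == 12
    assert report["val"]["total"] == 3
    assert report["test"]["total"] == 5
    assert report["test"]["exC"] == 2


def test_split_directory_rejects_unknown_category(tmp_path):
    (tmp_path / "train" / "weird").mkdir(parents=True)
    with pytest.raises(ValueError, match="weird"):
        load_split_directory(tmp_path)
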