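"""Feature-bank dimensionality, canonical ordering and provenance round-trips."""

import numpy as np
import pytest

from chmcs import cooccurrence, lbp
from chmcs.featurebank import (
    FeatureBank,
    FeatureProvenance,
    RepresentationSpec,
    dimensionality,
    enumerate_provenance,
    extract_dataset,
    extract_image,
    full_chmcs_spec,
    mpmc_spec,
    spsc_spec,
)
from chmcs.synthdata import make_texture_dataset


@pytest.mark.parametrize(
    "spec,expected",
    [
        (spsc_spec("RGB", "RSCCM", (1, 16)), 78),
        (spsc_spec("HSV", "EOCLBP", (8, 1)), 153),
        (RepresentationSpec(use_eoclbp=False, rsccm_settings=((1, 16),)), 390),
        (RepresentationSpec(use_rsccm=False, eoclbp_settings=((8, 1),)), 765),
        (RepresentationSpec(spaces=("RGB",), use_eoclbp=False), 1950),
        (RepresentationSpec(spaces=("RGB",), use_rsccm=False), 1989),
        (mpmc_spec("RSCCM"), 9750),
        (mpmc_spec("EOCLBP"), 9945),
        (full_chmcs_spec(), 19695),
    ],
)
def test_dimensionality_table(spec, expected):
    assert dimensionality(spec) == expected
    assert len(enumerate_provenance(spec)) == expected


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        RepresentationSpec(spaces=())
    with pytest.raises(ValueError):
        RepresentationSpec(use_rsccm=False, use_eoclbp=False)
    with pytest.raises(ValueError):
        RepresentationSpec(rsccm_settings=((4, 16),))
    with pytest.raises(ValueError):
        RepresentationSpec(eoclbp_settings=((8, 4),))


def test_provenance_names_round_trip():
    spec = RepresentationSpec(spaces=("HSV",), rsccm_settings=((2, 64),),
                              eoclbp_settings=((12, 3),))
    for rec in enumerate_provenance(spec):
        back = FeatureProvenance.from_name(rec.name, rec.index)
        assert back == rec


def test_extract_matches_per_pair_calls(rng):
    """SPSC extraction equals independently concatenated per-pair features."""
    img = rng.integers(0, 256, size=(32, 32, 3), dtype=np.uint8)
    spec = spsc_spec("RGB", "RSCCM", (2, 32))
    vec = extract_image(img, spec)
    expected = []
    planes = [cooccurrence.quantize_channel(img[:, :, g], 32) for g in range(3)]
    for g, gp in cooccurrence.RSCCM_PAIRS:
        m = cooccurrence.compute_rsccm(planes[g - 1], planes[gp - 1], (2, 32))
        expected.append(cooccurrence.haralick13(m))
    np.testing.assert_array_equal(vec, np.concatenate(expected))


def test_extract_lbp_matches_direct(rng):
    img = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
    spec = spsc_spec("RGB", "EOCLBP", (8, 2))
    vec = extract_image(img, spec)
    g, gp = lbp.LBP_PAIRS[3]  # first between-component pair
    direct = lbp.stats17(lbp.lbp_histogram(
        lbp.compute_lbp(img[:, :, g - 1], img[:, :, gp - 1], (8, 2))))
    np.testing.assert_array_equal(vec[3 * 17:4 * 17], direct)


def test_constant_image_zero_spread_statistics():
    img = np.full((16, 16, 3), 77, dtype=np.uint8)
    spec = spsc_spec("RGB", "EOCLBP", (8, 1))
    vec = extract_image(img, spec)
    prov = enumerate_provenance(spec)
    for rec, v in zip(prov, vec):
        if rec.feature in ("std", "iqr", "idr"):
            assert v == 0.0


def test_determinism(random_rgb):
    spec = RepresentationSpec(spaces=("RGB", "YCbCr"), rsccm_settings=((1, 16),),
                              eoclbp_settings=((8, 1),))
    np.testing.assert_array_equal(extract_image(random_rgb, spec),
                                  extract_image(random_rgb, spec))


def test_undersized_image_names_offending_setting():
    img = np.zeros((12, 12, 3), dtype=np.uint8)
    with pytest.raises(ValueError, match="delta=10"):
        extract_image(img, spsc_spec("RGB", "RSCCM", (10, 16)))


def test_provenance_column_recomputes_itself(rng):
    """Each column's provenance record regenerates exactly that column."""
    img = rng.integers(0, 256, size=(24, 24, 3), dtype=np.uint8)
    spec = RepresentationSpec(spaces=("RGB", "HSV"), rsccm_settings=((1, 32), (3, 16)),
                              eoclbp_settings=((8, 1), (8, 3)))
    vec = extract_image(img, spec)
    prov = enumerate_provenance(spec)
    for idx in [0, 57, 200, len(vec) - 1]:
        rec = prov[idx]
        single = RepresentationSpec(
            spaces=(rec.space,),
            use_rsccm=rec.descriptor == "RSCCM",
            use_eoclbp=rec.descriptor == "EOCLBP",
            rsccm_settings=(rec.setting,) if rec.descriptor == "RSCCM" else ((1, 16),),
            eoclbp_settings=(rec.setting,) if rec.descriptor == "EOCLBP" else ((8, 1),),
        )
        sub_vec = extract_image(img, single)
        sub_prov = enumerate_provenance(single)
        match = [k for k, r in enumerate(sub_prov)
                 if (r.descriptor, r.pair, r.feature) == (rec.descriptor, rec.pair, rec.feature)]
        assert len(match) == 1
        assert sub_vec[match[0]] == vec[idx]


@pytest.fixture(scope="module")
def tiny_dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("texdata")
    make_texture_dataset(2, 4, size=24, seed=7, out_dir=str(out))
    return out


class TestDataset:
    def test_bank_shape_and_order(self, tiny_dataset):
        spec = spsc_spec("RGB", "EOCLBP", (8, 1))
        bank = extract_dataset(str(tiny_dataset / "manifest.csv"), spec)
        assert bank.X.shape == (8, 153)
        assert list(bank.labels[:4]) == ["class0"] * 4

    def test_shuffled_manifest_shuffles_rows(self, tiny_dataset):
        import pandas as pd

        spec = spsc_spec("RGB", "RSCCM", (1, 16))
        manifest = pd.read_csv(tiny_dataset / "manifest.csv")
        b1 = extract_dataset(manifest, spec, root=str(tiny_dataset))
        order = [3, 1, 0, 2, 7, 6, 5, 4]
        b2 = extract_dataset(manifest.iloc[order], spec, root=str(tiny_dataset))
        np.testing.assert_array_equal(b2.X, b1.X[order])
        np.testing.assert_array_equal(b2.labels, b1.labels[order])

    def test_empty_manifest_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError, match="no rows"):
            extract_dataset(pd.DataFrame(columns=["path", "label", "split"]),
                            spsc_spec("RGB", "RSCCM", (1, 16)))

    def test_missing_image_named_in_error(self, tiny_dataset):
        import pandas as pd

        manifest = pd.DataFrame([{"path": "nope.png", "label": "a", "split": "train"}])
        with pytest.raises(ValueError, match="nope.png"):
            extract_dataset(manifest, spsc_spec("RGB", "RSCCM", (1, 16)),
                            root=str(tiny_dataset))

    def test_csv_round_trip(self, tiny_dataset, tmp_path):
        spec = spsc_spec("RGB", "RSCCM", (1, 16))
        bank = extract_dataset(str(tiny_dataset / "manifest.csv"), spec)
        path = tmp_path / "bank.csv"
        bank.to_csv(str(path))
        back = FeatureBank.from_csv(str(path))
        np.testing.assert_allclose(back.X, bank.X)
        assert back.feature_names == bank.feature_names
        np.testing.assert_array_equal(back.splits, bank.splits)
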