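import numpy as np
import pandas as pd
import pytest

from lesionfield import (
    ConfigurationError,
    GridError,
    LesionMask,
    Parcellation,
    REGION_NAMES,
    SchemaError,
    SpaceError,
    compute_reil,
    lesion_frequency_map,
    lesion_volume_ml,
    reil_table,
)


def native(data, dims=(1.0, 1.0, 1.0)):
    return LesionMask(data=data, voxel_dims_mm=dims, space="native")


class TestLesionVolume:
    def test_unit_voxels(self):
        data = np.zeros((10, 10, 10), dtype=bool)
        data.flat[:1000] = True
        assert lesion_volume_ml(native(data)) == pytest.approx(1.0)

    def test_empty_mask(self):
        assert lesion_volume_ml(native(np.zeros((4, 4, 4)))) == 0.0

    def test_anisotropic_voxels(self):
        data = np.zeros((10, 10, 10), dtype=bool)
        data.flat[:100] = True
        assert lesion_volume_ml(native(data, (2.0, 2.0, 2.0))) == pytest.approx(0.8)

    def test_scales_linearly_with_voxel_volume(self, rng):
        data = rng.random((8, 8, 8)) < 0.3
        v1 = lesion_volume_ml(native(data, (1.0, 1.0, 1.0)))
        v2 = lesion_volume_ml(native(data, (0.651, 0.651, 7.0)))
        assert v2 == pytest.approx(v1 * 0.651 * 0.651 * 7.0)

    def test_atlas_space_rejected(self):
        mask = LesionMask(np.zeros((4, 4, 4)), (1, 1, 1), "atlas")
        with pytest.raises(SpaceError):
            lesion_volume_ml(mask)

    def test_nonbinary_rejected(self):
        with pytest.raises(SchemaError):
            LesionMask(np.full((3, 3, 3), 2.0), (1, 1, 1), "native")


class TestComputeReil:
    def test_full_region_involvement(self, toy_atlas):
        region = toy_atlas.region_mask("calcarine", "left")
        mask = LesionMask(region, (2.0, 2.0, 2.0), "atlas")
        reil = compute_reil(mask, toy_atlas, "left")
        assert reil["calcarine"] == pytest.approx(100.0)
        assert (reil.drop("calcarine") == 0).all()

    def test_disjoint_mask(self, toy_atlas):
        mask = LesionMask(
            np.zeros_like(toy_atlas.labels, dtype=bool), (2, 2, 2), "atlas"
        )
        assert (compute_reil(mask, toy_atlas, "right") == 0).all()

    def test_matches_per_voxel_counting_oracle(self, toy_atlas, rng):
        """Random masks against an independent brute-force voxel loop."""
        labels = toy_atlas.labels
        name_of = {
            int(r.region_id): (r.region_name, r.hemisphere)
            for r in toy_atlas.regions.itertuples()
        }
        for _ in range(3):
            mask = rng.random(labels.shape) < 0.15
            for side in ("left", "right"):
                got = compute_reil(
                    LesionMask(mask, (2, 2, 2), "atlas"), toy_atlas, side
                )
                hit = {n: 0 for n in REGION_NAMES}
                tot = {n: 0 for n in REGION_NAMES}
                for idx in np.ndindex(labels.shape):
                    lab = int(labels[idx])
                    if lab == 0:
                        continue
                    name, hemi = name_of[lab]
                    if hemi != side:
                        continue
                    tot[name] += 1
                    if mask[idx]:
                        hit[name] += 1
                for n in REGION_NAMES:
                    assert got[n] == pytest.approx(100.0 * hit[n] / tot[n])

    def test_relabeling_invariance(self, toy_atlas, rng):
        mask = rng.random(toy_atlas.labels.shape) < 0.1
        remap = {
            int(rid): int(rid) * 7 + 3 for rid in toy_atlas.regions["region_id"]
        }
        labels2 = np.zeros_like(toy_atlas.labels)
        for old, new in remap.items():
            labels2[toy_atlas.labels == old] = new
        regions2 = toy_atlas.regions.copy()
        regions2["region_id"] = regions2["region_id"].map(remap)
        parc2 = Parcellation(labels=labels2, regions=regions2)
        m = LesionMask(mask, (2, 2, 2), "atlas")
        pd.testing.assert_series_equal(
            compute_reil(m, toy_atlas, "left"), compute_reil(m, parc2, "left")
        )

    def test_lesion_voxel_budget(self, toy_atlas, rng):
        """Sum of rEIL-implied voxels never exceeds the lesion size, with
        equality when the lesion lies entirely inside scored regions."""
        mask = rng.random(toy_atlas.labels.shape) < 0.2
        m = LesionMask(mask, (2, 2, 2), "atlas")
        implied = 0.0
        for side in ("left", "right"):
            reil = compute_reil(m, toy_atlas, side)
            for name in REGION_NAMES:
                n_region = int(toy_atlas.region_mask(name, side).sum())
                implied += reil[name] / 100.0 * n_region
        assert implied <= mask.sum() + 1e-6

        inside = mask & (toy_atlas.labels > 0)
        m2 = LesionMask(inside, (2, 2, 2), "atlas")
        implied2 = sum(
            compute_reil(m2, toy_atlas, side)[name]
            / 100.0
            * int(toy_atlas.region_mask(name, side).sum())
            for side in ("left", "right")
            for name in REGION_NAMES
        )
        assert implied2 == pytest.approx(inside.sum())

    def test_shape_mismatch_rejected(self, toy_atlas):
        m = LesionMask(np.zeros((4, 4, 4)), (2, 2, 2), "atlas")
        with pytest.raises(GridError):
            compute_reil(m, toy_atlas, "left")

    def test_unknown_side_rejected(self, toy_atlas):
        m = LesionMask(np.zeros_like(toy_atlas.labels, dtype=bool), (2, 2, 2), "atlas")
        with pytest.raises(ConfigurationError):
            compute_reil(m, toy_atlas, "bilateral")

    def test_zero_voxel_region_rejected(self, toy_atlas):
        regions = pd.concat(
            [
                toy_atlas.regions,
                pd.DataFrame(
                    [{"region_id": 999, "region_name": "lingual", "hemisphere": "left"}]
                ),
            ],
            ignore_index=True,
        )
        # replace left lingual's id so the name maps to an absent label
        regions = regions[regions["region_id"] != 1]
        parc = Parcellation(
            labels=np.where(toy_atlas.labels == 1, 0, toy_atlas.labels),
            regions=regions,
        )
        m = LesionMask(np.zeros_like(parc.labels, dtype=bool), (2, 2, 2), "atlas")
        with pytest.raises(SchemaError):
            compute_reil(m, parc, "left")


class TestReilTable:
    def test_wide_layout(self, toy_atlas):
        region = toy_atlas.region_mask("cuneus", "right")
        masks = [LesionMask(region, (2, 2, 2), "atlas")]
        table = reil_table(masks, toy_atlas, sides=["right"], patient_ids=["p0"])
        assert table.loc["p0", "reil_cuneus"] == pytest.approx(100.0)
        assert table.shape == (1, len(REGION_NAMES))


class TestFrequencyMap:
    def test_single_patient_identity(self, rng):
        data = rng.random((6, 6, 6)) < 0.4
        m = LesionMask(data, (2, 2, 2), "atlas")
        out = lesion_frequency_map([m], sides=["left"])
        assert np.array_equal(out, data.astype(float))

    def test_counting(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        b = np.zeros_like(a)
        c = np.zeros_like(a)
        a[1, 1, 1] = b[1, 1, 1] = True
        masks = [LesionMask(x, (2, 2, 2), "atlas") for x in (a, b, c)]
        out = lesion_frequency_map(masks, sides=["left"] * 3)
        assert out[1, 1, 1] == pytest.approx(2 / 3)
        assert out.sum() == pytest.approx(2 / 3)

    def test_right_lesions_mirrored(self):
        data = np.zeros((4, 4, 4), dtype=bool)
        data[3, 0, 0] = True
        m = LesionMask(data, (2, 2, 2), "atlas")
        out = lesion_frequency_map([m], sides=["right"], flip_to_common_side=True)
        assert out[0, 0, 0] == 1.0 and out[3, 0, 0] == 0.0
        out2 = lesion_frequency_map([m], flip_to_common_side=False)
        assert out2[3, 0, 0] == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(SchemaError):
            lesion_frequency_map([], sides=[])


class TestNiftiRoundTrip:
    def test_mask_and_parcellation_files(self, toy_atlas, tmp_path, rng):
        data = rng.random(toy_atlas.labels.shape) < 0.2
        mask = LesionMask(data, (2.0, 2.0, 2.0), "atlas")
        mask.to_nifti(tmp_path / "mask.nii.gz")
        back = LesionMask.from_nifti(tmp_path / "mask.nii.gz")
        assert np.array_equal(back.data, data)
        assert back.voxel_dims_mm == (2.0, 2.0, 2.0)

        toy_atlas.to_files(tmp_path / "atlas.nii.gz", tmp_path / "regions.csv")
        back_parc = Parcellation.from_files(
            tmp_path / "atlas.nii.gz", tmp_path / "regions.csv"
        )
        assert np.array_equal(back_parc.labels, toy_atlas.labels)
        assert len(back_parc.regions) == len(toy_atlas.regions)
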