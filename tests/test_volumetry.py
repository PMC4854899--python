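"""Label merging, propagation and volume quantification."""

import numpy as np
import pandas as pd
import pytest

from atlasvol import tables
from atlasvol.image_io import LabelMap, LabelTable, load_study_label_table
from atlasvol.registration import AffineTransform, TransformChain, identity_chain
from atlasvol.volumetry import (
    RegionVolumeRecord,
    compute_volumes,
    merge_labels,
    propagate_labels,
    records_to_frame,
    summarize_volumes,
)

SP = (0.08, 0.08, 0.08)  # study voxel size


def _labels(data):
    return LabelMap(np.asarray(data, dtype=np.int32), spacing=SP)


class TestMergeLabels:
    def test_ventricle_compartments_merge_conserving_voxels(self):
        data = np.zeros((20, 20, 20), dtype=np.int32)
        # 100 voxels for each of the four ventricle sub-labels
        for i, lab in enumerate([1, 2, 3, 4]):
            data[i * 5:(i + 1) * 5, :5, :4] = lab
        merged = merge_labels(_labels(data), load_study_label_table())
        assert (merged.data == 1).sum() == 400

    def test_identity_table_unchanged(self):
        df = pd.DataFrame({"label_id": [1, 2], "label_name": ["a", "b"],
                           "structure_id": [1, 2],
                           "structure_name": ["a", "b"]})
        data = np.zeros((6, 6, 6), dtype=np.int32)
        data[:3] = 1
        data[3:, :, :3] = 2
        merged = merge_labels(_labels(data), LabelTable(df))
        assert np.array_equal(merged.data, data)

    def test_study_table_on_atlas_gives_19_structures(self, atlas):
        _, labels39, table = atlas
        merged = merge_labels(labels39, table)
        assert len(merged.label_census()) == 19

    def test_unknown_label_rejected_by_name(self):
        data = np.zeros((4, 4, 4), dtype=np.int32)
        data[0, 0, 0] = 99
        with pytest.raises(ValueError, match="99"):
            merge_labels(_labels(data), load_study_label_table())

    def test_total_foreground_conserved(self, atlas):
        _, labels39, table = atlas
        merged = merge_labels(labels39, table)
        assert (merged.data > 0).sum() == (labels39.data > 0).sum()


class TestComputeVolumes:
    def test_voxel_count_arithmetic(self):
        data = np.zeros((10, 10, 10), dtype=np.int32)
        data.ravel()[:1000] = 1
        rec = compute_volumes(_labels(data), 0.0, "s1")
        assert np.isclose(rec.whole_brain_mm3, 1000 * 0.08**3)
        assert np.isclose(rec.whole_brain_mm3, 0.512)

    def test_ellipsoid_volume_within_2pct_of_analytic(self):
        a, b, c = 24.0, 21.0, 20.0
        n = 56
        grid = np.meshgrid(*[np.arange(n) - (n - 1) / 2] * 3, indexing="ij")
        ell = (grid[0] / a) ** 2 + (grid[1] / b) ** 2 + (grid[2] / c) ** 2 <= 1
        rec = compute_volumes(_labels(ell.astype(np.int32)), 0.0, "s")
        analytic = 4.0 / 3.0 * np.pi * a * b * c * 0.08**3
        assert abs(rec.whole_brain_mm3 - analytic) / analytic < 0.02

    def test_single_structure_normalized_100(self):
        data = np.ones((5, 5, 5), dtype=np.int32)
        rec = compute_volumes(_labels(data), 0.0, "s")
        assert np.isclose(list(rec.normalized_pct.values())[0], 100.0)

    def test_normalized_sums_to_100(self, atlas):
        _, labels39, table = atlas
        merged = merge_labels(labels39, table)
        rec = compute_volumes(merged, 0.0, "s")
        assert abs(sum(rec.normalized_pct.values()) - 100.0) < 0.2

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError, match="zero whole-brain"):
            compute_volumes(_labels(np.zeros((4, 4, 4))), 0.0, "s")

    def test_global_scale_cubes_volumes(self):
        from atlasvol.synthetic import DoseEffectSpec, PhantomSpec, make_cohort
        s = 0.9  # linear scale; volumes scale by s^3
        effects = DoseEffectSpec(
            doses_gy=(0.0, 1.0), group_sizes=(2, 2),
            volume_scales=(1.0, s**3), warp_amplitude_vox=0.0,
            bias_amplitude=0.0, noise_sd=0.0, subject_volume_cv=0.0,
            protrusion_top_dose=False)
        subjects = make_cohort(PhantomSpec(), effects)
        base = next(x for x in subjects if x.dose_gy == 0.0).truth
        scaled = next(x for x in subjects if x.dose_gy == 1.0).truth
        for name, v0 in base.absolute_mm3.items():
            if v0 / (0.16**3) < 100:  # voxelization dominates tiny regions
                continue
            ratio = scaled.absolute_mm3[name] / v0
            assert abs(ratio - s**3) / s**3 < 0.03, name


class TestPropagation:
    def test_identity_chain_unchanged(self, atlas):
        _, labels39, _ = atlas
        out = propagate_labels(labels39, identity_chain(), labels39)
        assert np.array_equal(out.data, labels39.data)

    def test_isotropic_shrink_scales_counts(self, atlas):
        _, labels39, table = atlas
        merged = merge_labels(labels39, table)
        # a pure 10% shrink chain (subject->template scale 0.9, pull-back)
        # inflates the propagated foreground by (1/0.9)^3 on the subject grid
        sc = AffineTransform(scale=[0.9] * 3, center=merged.center_world)
        out = propagate_labels(merged, TransformChain([sc]), merged)
        ratio = (out.data > 0).sum() / (merged.data > 0).sum()
        assert abs(ratio - (1 / 0.9) ** 3) < 0.05


class TestSummaries:
    def _records_from_published(self):
        """Per-subject records engineered so group means equal Table means."""
        absolute = tables.load_absolute_volume_summaries()
        structures = [s for s in absolute["structure"].unique()
                      if s != "total_brain"]
        wb = absolute[absolute["structure"] == "total_brain"]
        records = []
        for dose, n in zip(tables.DOSE_GROUPS_GY, tables.GROUP_SIZES):
            wb_mean = float(wb[wb["dose_gy"] == dose]["mean"].iloc[0])
            means = {s: float(absolute[(absolute["structure"] == s)
                                       & (absolute["dose_gy"] == dose)]["mean"].iloc[0])
                     for s in structures}
            for i in range(n):
                # +/- epsilon around the mean keeps SEM finite, mean exact
                eps = 0.001 if i % 2 == 0 else -0.001
                records.append(RegionVolumeRecord(
                    f"{dose}-{i}", dose,
                    {s: m + eps for s, m in means.items()},
                    wb_mean + eps * len(structures)))
        return records

    def test_published_percent_changes_reproduced(self):
        summary = summarize_volumes(self._records_from_published())
        absolute = summary[summary["kind"] == "absolute"].set_index("structure")
        assert round(absolute.loc["total_brain", "percent_change"]) == 23
        assert round(absolute.loc["cerebellum", "percent_change"]) == 33
        assert round(absolute.loc["striatum", "percent_change"]) == 32
        assert round(absolute.loc["pons", "percent_change"]) == 12
        norm = summary[summary["kind"] == "normalized"].set_index("structure")
        assert norm.loc["ventricles", "direction"] == "increase"
        assert round(norm.loc["ventricles", "percent_change"]) == 44
        # sham normalized posterior cerebral cortex reproduces 22.8%
        assert np.isclose(norm.loc["posterior_cerebral_cortex",
                                   "ratio_of_means_0.00Gy"], 22.8, atol=0.06)

    def test_identical_groups_zero_change(self):
        recs = []
        for dose in (0.0, 1.0):
            for i in range(3):
                recs.append(RegionVolumeRecord(f"{dose}-{i}", dose,
                                               {"a": 10.0, "b": 5.0}, 15.0))
        summary = summarize_volumes(recs)
        assert np.allclose(summary["percent_change"], 0.0)
        assert np.allclose(summary.filter(like="sem_").to_numpy(float), 0.0)

    def test_missing_control_rejected(self):
        recs = [RegionVolumeRecord("s", 1.0, {"a": 1.0}, 1.0),
                RegionVolumeRecord("t", 0.5, {"a": 1.0}, 1.0)]
        with pytest.raises(ValueError, match="control"):
            summarize_volumes(recs)

    def test_record_invariant_normalized_consistency(self):
        rec = RegionVolumeRecord("s", 0.0, {"a": 25.0, "b": 75.0}, 100.0)
        assert rec.normalized_pct == {"a": 25.0, "b": 75.0}
        frame = records_to_frame([rec])
        assert set(frame["structure"]) == {"total_brain", "a", "b"}
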