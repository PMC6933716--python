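"""Generator determinism, ground-truth bookkeeping, design arithmetic."""

import numpy as np
import pytest

from paniclepheno.errors import CapacityError, ValidationError
from paniclepheno.io import LABEL_PANICLE
from paniclepheno.synthetic import (DEFAULT_GROUPS, SyntheticPanicleSpec,
                                    make_cohort, make_scan, make_scene,
                                    panicle_layout_volume, render_views,
                                    stage_color)


class TestMakeScene:
    def test_fixed_seed_reproduces_scene_exactly(self):
        spec = SyntheticPanicleSpec(rng_seed=9)
        a, ta = make_scene(spec)
        b, tb = make_scene(spec)
        np.testing.assert_array_equal(a.points, b.points)
        np.testing.assert_array_equal(a.colors, b.colors)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert ta.true_volume == tb.true_volume

    def test_zero_branches_gives_reference_geometry_only(self):
        spec = SyntheticPanicleSpec(n_branches=0, seeds_per_branch=0,
                                    rng_seed=2)
        cloud, truth = make_scene(spec)
        assert truth.n_panicle_points == 0
        assert truth.true_volume == 0.0
        assert (cloud.labels == LABEL_PANICLE).sum() == 0
        assert len(cloud) > 0

    def test_doubling_seed_axes_scales_volume_eightfold(self):
        base = dict(n_branches=4, seeds_per_branch=2, position_jitter=0.0,
                    rng_seed=7)
        spec1 = SyntheticPanicleSpec(seed_semi_axes=(0.9, 0.4, 0.35), **base)
        spec2 = SyntheticPanicleSpec(seed_semi_axes=(1.8, 0.8, 0.7), **base)
        _, t1 = make_scene(spec1, truth_cell=0.05)
        _, t2 = make_scene(spec2, truth_cell=0.05)
        assert t2.true_volume / t1.true_volume == pytest.approx(8.0, rel=0.01)

    def test_week_multiplier_scales_volume_exactly(self):
        spec1 = SyntheticPanicleSpec(rng_seed=4, layout_seed=77, week=1)
        spec3 = SyntheticPanicleSpec(rng_seed=4, layout_seed=77, week=3)
        v1 = spec1.volume_multiplier * panicle_layout_volume(spec1)
        v3 = spec3.volume_multiplier * panicle_layout_volume(spec3)
        assert v3 / v1 == pytest.approx(
            spec3.volume_multiplier / spec1.volume_multiplier)

    def test_color_schedule_interpolates_green_to_yellow(self):
        assert tuple(stage_color(0.0)) == (50, 160, 60)
        assert tuple(stage_color(1.0)) == (210, 180, 60)
        mid = stage_color(0.5)
        assert 50 < mid[0] < 210

    @pytest.mark.parametrize("bad", [
        dict(week_scale=(2.0, 1.5, 3.0)),
        dict(color_stage=1.5),
        dict(week=4),
        dict(seed_semi_axes=(1.0, -0.5, 0.4)),
    ])
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValidationError):
            SyntheticPanicleSpec(**bad)


class TestRenderViews:
    def test_view_count_and_azimuth_coverage(self, scene):
        cloud, _ = scene
        images, masks, truth = render_views(cloud, n_views=120)
        assert len(images) == len(masks) == len(truth.pixel_counts) == 120

    def test_truth_counts_equal_mask_sums(self, scene):
        cloud, _ = scene
        _, masks, truth = render_views(cloud, n_views=6)
        assert [int(m.sum()) for m in masks] == truth.pixel_counts

    def test_empty_panicle_renders_black(self):
        spec = SyntheticPanicleSpec(n_branches=0, seeds_per_branch=0,
                                    rng_seed=1)
        cloud, _ = make_scene(spec)
        images, masks, truth = render_views(cloud, n_views=4)
        assert all(not m.any() for m in masks)
        assert all((im == 0).all() for im in images)
        assert truth.pixel_counts == [0, 0, 0, 0]

    def test_distractors_drawn_outside_truth(self, scene):
        cloud, _ = scene
        images, masks, truth = render_views(cloud, n_views=4,
                                            distractor_squares=4)
        for image, mask, count in zip(images, masks, truth.pixel_counts):
            drawn = (image.sum(axis=2) > 0).sum()
            assert int(mask.sum()) == count
            assert drawn > count  # squares add pixels beyond the panicle


class TestMakeScan:
    def test_truth_count_by_construction(self):
        _, truth = make_scan(30, rng_seed=0)
        assert truth.seed_count == 30
        assert truth.centers.shape == (30, 2)

    def test_zero_seeds_black_image(self):
        image, truth = make_scan(0, rng_seed=0)
        assert (image == 0).all()
        assert truth.seed_count == 0 and truth.foreground_px == 0

    def test_overfull_canvas_raises_capacity_error(self):
        with pytest.raises(CapacityError):
            make_scan(500, rng_seed=0, image_size=(200, 200))

    def test_deterministic_given_seed(self):
        a, _ = make_scan(10, rng_seed=3)
        b, _ = make_scan(10, rng_seed=3)
        np.testing.assert_array_equal(a, b)


class TestMakeCohort:
    def test_default_design_has_55_plants(self):
        cohort = make_cohort(rng_seed=0)
        assert len(cohort.plants) == 55            # 11 genotypes x (3 + 2)
        assert len(cohort.manual_table) == 55
        assert len({p.genotype for p in cohort.plants}) == 11
        assert {p.treatment for p in cohort.plants} == {"control", "HNT"}

    def test_every_plant_has_three_weekly_specs(self):
        cohort = make_cohort(n_genotypes=4, reps=(1,),
                             treatments=("control",), rng_seed=0)
        for plant in cohort.plants:
            assert sorted(plant.specs) == [1, 2, 3]
            scales = [plant.specs[w].volume_multiplier for w in (1, 2, 3)]
            assert scales[0] < scales[1] < scales[2]

    def test_true_volume_proportional_to_multiplier(self):
        cohort = make_cohort(n_genotypes=4, reps=(1,),
                             treatments=("control",), rng_seed=0)
        tv = cohort.truth.true_volumes
        for plant in cohort.plants:
            for week in (1, 2, 3):
                row = tv[(tv["genotype"] == plant.genotype)
                         & (tv["week"] == week)
                         & (tv["treatment"] == plant.treatment)]
                expected = plant.specs[week].volume_multiplier \
                    * cohort.truth.layout_volume
                assert row["true_volume"].iloc[0] == pytest.approx(expected)

    def test_noiseless_endpoints_proportional_to_final_volume(self):
        cohort = make_cohort(n_genotypes=6, reps=(1,),
                             treatments=("control",), rng_seed=0,
                             noise_sd=0.0)
        tv = cohort.truth.true_volumes
        week3 = tv[tv["week"] == 3].set_index("genotype")["true_volume"]
        manual = cohort.manual_table.set_index("genotype")
        ratio = manual["total_seed_weight"] / week3
        assert ratio.max() / ratio.min() == pytest.approx(1.0, abs=1e-12)

    def test_groups_partition_genotypes(self):
        cohort = make_cohort(rng_seed=0)
        groups = set(cohort.truth.genotype_groups.values())
        assert groups == {g.name for g in DEFAULT_GROUPS}

    def test_hnt_advances_maturation_stage(self):
        cohort = make_cohort(n_genotypes=2, reps=(1, 1), rng_seed=0)
        by_key = {(p.genotype, p.treatment): p for p in cohort.plants}
        for g in ("G01", "G02"):
            control = by_key[(g, "control")].specs[1].color_stage
            hnt = by_key[(g, "HNT")].specs[1].color_stage
            assert hnt > control
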