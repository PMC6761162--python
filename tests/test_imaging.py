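import numpy as np
import pandas as pd
import pytest
from scipy import stats

from colonscape.imaging import (
    BiovolumeProfile,
    ImageStack,
    biovolume_profile,
    cluster_stats,
    enrichment_extent,
    goblet_biovolume,
    mean_cell_area,
    mucus_thickness,
    normalize_profiles,
    read_stack,
    segment_channel,
    write_stack,
)
from colonscape.sim import ImageSimParams, simulate_fish_image


def flat_stack(rows=200, cols=100, scale=0.5, band_um=20.0, tissue_um=10.0,
               channels=None):
    """Minimal stack with straight horizontal boundaries."""
    epi_row = rows - tissue_um / scale
    outer_row = epi_row - band_um / scale
    xs = np.array([0.0, cols - 1.0])
    boundaries = {
        "epithelial_surface": np.column_stack([xs, [epi_row, epi_row]]),
        "mucus_outer_edge": np.column_stack([xs, [outer_row, outer_row]]),
    }
    if channels is None:
        channels = {"total_bacteria": np.zeros((rows, cols))}
    return ImageStack(channels=channels, scale_um=scale, boundaries=boundaries)


class TestSimulatedScene:
    def test_deterministic(self):
        s1, t1 = simulate_fish_image(ImageSimParams(seed=4))
        s2, t2 = simulate_fish_image(ImageSimParams(seed=4))
        np.testing.assert_array_equal(
            s1.channels["total_bacteria"], s2.channels["total_bacteria"]
        )
        pd.testing.assert_frame_equal(t1.cells, t2.cells)

    def test_band_width_in_pixels(self):
        params = ImageSimParams(
            band_width_um=50.0, scale_um=0.5, undulation_amplitude_um=0.0, seed=0
        )
        stack, _ = simulate_fish_image(params)
        mucin = stack.channels["mucin_stain"] > 100
        rows_per_col = mucin.sum(axis=0)
        assert np.all(np.abs(rows_per_col - 100) <= 1)

    def test_no_clusters_truth_fraction_zero(self):
        _, truth = simulate_fish_image(ImageSimParams(kappa=0.0, seed=1))
        assert truth.fraction_in_clusters == 0.0

    def test_no_enrichment_flat_target_fraction(self):
        """With amplitude 0, the cell-level target rate does not depend on
        distance (regression slope indistinguishable from zero)."""
        slopes_p = []
        for seed in range(5):
            _, truth = simulate_fish_image(
                ImageSimParams(amplitude=0.0, cell_density=0.08, kappa=0.0, seed=seed)
            )
            cells = truth.cells
            res = stats.linregress(cells["distance_um"], cells["is_target"].astype(float))
            slopes_p.append(res.pvalue)
        assert np.mean([p > 0.05 for p in slopes_p]) >= 0.6

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            ImageSimParams(band_width_um=400.0, shape=(100, 100))
        with pytest.raises(ValueError):
            ImageSimParams(p0=1.5)
        with pytest.raises(ValueError):
            ImageSimParams(cell_density=-1.0)

    def test_stack_io_round_trip(self, tmp_path):
        stack, _ = simulate_fish_image(ImageSimParams(seed=2, shape=(240, 80)))
        write_stack(stack, tmp_path / "img.tiff", tmp_path / "img.json")
        back = read_stack(tmp_path / "img.tiff", tmp_path / "img.json")
        assert back.scale_um == stack.scale_um
        np.testing.assert_allclose(
            back.channels["target"], stack.channels["target"], atol=1e-5
        )
        np.testing.assert_allclose(
            back.boundaries["mucus_outer_edge"], stack.boundaries["mucus_outer_edge"]
        )


class TestSegmentation:
    def test_constant_image_rejected(self):
        stack = flat_stack(channels={"c": np.full((50, 50), 3.0)})
        with pytest.raises(ValueError, match="constant"):
            segment_channel(stack, "c")

    def test_two_level_image_segmented_exactly(self):
        img = np.zeros((40, 40))
        img[5:15, 5:15] = 100.0
        stack = flat_stack(channels={"c": img})
        mask = segment_channel(stack, "c")
        np.testing.assert_array_equal(mask, img > 50)

    def test_cells_recalled_on_generated_scene(self):
        stack, truth = simulate_fish_image(ImageSimParams(seed=3))
        mask = segment_channel(stack, "total_bacteria")
        rr = truth.cells["row"].round().astype(int).clip(0, stack.shape[0] - 1)
        cc = truth.cells["col"].round().astype(int).clip(0, stack.shape[1] - 1)
        assert mask[rr, cc].mean() >= 0.95

    def test_masks_invariant_to_intensity_rescaling(self):
        stack, _ = simulate_fish_image(ImageSimParams(seed=5, shape=(150, 100)))
        mask = segment_channel(stack, "total_bacteria")
        doubled = ImageStack(
            channels={"total_bacteria": 2.0 * stack.channels["total_bacteria"]},
            scale_um=stack.scale_um, boundaries=stack.boundaries,
        )
        np.testing.assert_array_equal(mask, segment_channel(doubled, "total_bacteria"))


class TestBiovolumeProfile:
    def test_target_equals_total_gives_unit_fractions(self):
        rng = np.random.default_rng(0)
        mask = rng.random((200, 100)) < 0.3
        stack = flat_stack()
        prof = biovolume_profile(mask, mask, stack, max_dist_um=60.0)
        vals = prof.fraction[np.isfinite(prof.fraction)]
        assert len(vals) > 10
        np.testing.assert_allclose(vals, 1.0)

    def test_empty_target_gives_zero(self):
        rng = np.random.default_rng(1)
        total = rng.random((200, 100)) < 0.3
        stack = flat_stack()
        prof = biovolume_profile(np.zeros_like(total), total, stack, max_dist_um=60.0)
        vals = prof.fraction[np.isfinite(prof.fraction)]
        np.testing.assert_allclose(vals, 0.0)

    def test_bin_geometry(self):
        stack = flat_stack()
        mask = np.ones((200, 100), bool)
        prof = biovolume_profile(mask, mask, stack)
        assert len(prof.bin_edges) == 76
        assert prof.bin_edges[1] - prof.bin_edges[0] == 2.0

    def test_conservation_of_target_pixels(self):
        rng = np.random.default_rng(2)
        total = rng.random((200, 100)) < 0.4
        target = total & (rng.random((200, 100)) < 0.5)
        stack = flat_stack()
        prof = biovolume_profile(target, total, stack, max_dist_um=150.0, min_support=1)
        from colonscape.imaging import _lumen_distance_um

        dist = _lumen_distance_um(stack)
        in_range = (dist > 0) & (dist < 150.0 + 2.0)
        # within bins, support * fraction re-sums to the joint pixel count
        got = np.nansum(prof.support * prof.fraction)
        dist_idx = np.floor(dist / 2.0).astype(int)
        expected = int((target & total & (dist > 0) & (dist_idx < 75)).sum())
        assert got == pytest.approx(expected)

    def test_all_empty_total_rejected(self):
        stack = flat_stack()
        empty = np.zeros((200, 100), bool)
        with pytest.raises(ValueError):
            biovolume_profile(empty, empty, stack)


class TestNormalizationAndExtent:
    def _profile(self, values):
        edges = np.arange(0.0, 2.0 * len(values) + 1, 2.0)
        return BiovolumeProfile(
            bin_edges=edges, fraction=np.asarray(values, float),
            support=np.full(len(values), 1000),
        )

    def test_constant_profile_normalises_to_one(self):
        profs = normalize_profiles([self._profile([0.2] * 60)], lumen_start_um=75.0)
        np.testing.assert_allclose(profs[0].fraction, 1.0)

    def test_scale_invariance(self):
        base = [0.4, 0.3] + [0.2] * 58
        p1 = normalize_profiles([self._profile(base)])[0]
        p2 = normalize_profiles([self._profile([2 * v for v in base])])[0]
        np.testing.assert_allclose(p1.fraction, p2.fraction)

    def test_unit_profiles_have_zero_extent(self):
        profs = [self._profile([1.0] * 40) for _ in range(4)]
        assert enrichment_extent(profs) == 0.0

    def test_extent_needs_three_profiles(self):
        with pytest.raises(ValueError):
            enrichment_extent([self._profile([1.0] * 10)] * 2)

    def test_normalized_edge_bin_doubles_at_unit_amplitude(self):
        # sparse scene: pixel overlap between target and non-target cells
        # compresses the ratio at high densities
        profiles = []
        for seed in range(10):
            params = ImageSimParams(
                amplitude=1.0, extent_um=30.0, cell_density=0.04, kappa=0.0, seed=seed
            )
            stack, _ = simulate_fish_image(params)
            total = segment_channel(stack, "total_bacteria")
            target = segment_channel(stack, "target")
            profiles.append(biovolume_profile(target, total, stack))
        normed = normalize_profiles(profiles)
        edge = np.nanmean([p.fraction[0] for p in normed])
        assert edge == pytest.approx(2.0, abs=0.4)


class TestCellsAndClusters:
    def test_isolated_disks_have_area_pi(self):
        from skimage.draw import disk

        mask = np.zeros((300, 300), bool)
        rng = np.random.default_rng(0)
        for _ in range(40):
            r, c = rng.uniform(20, 280, 2)
            rr, cc = disk((r, c), 2, shape=mask.shape)
            mask[rr, cc] = True
        area = mean_cell_area(mask, scale_um=0.5)
        assert area == pytest.approx(np.pi, rel=0.10)

    def test_too_few_components_rejected(self):
        mask = np.zeros((50, 50), bool)
        mask[10:12, 10:12] = True
        with pytest.raises(ValueError):
            mean_cell_area(mask, scale_um=0.5)

    def test_cluster_arithmetic(self):
        mask = np.zeros((60, 60), bool)
        mask[10:30, 10:30] = True  # 400 px = 100 um^2 at 0.5 um/px
        cs = cluster_stats(mask, scale_um=0.5, mean_cell_area_um2=2.0)
        assert cs.table.loc[0, "cells"] == 50
        assert bool(cs.table.loc[0, "is_cluster"])
        assert cs.fraction_in_clusters == 1.0

    def test_singletons_give_zero_fraction(self):
        mask = np.zeros((60, 60), bool)
        for r in range(5, 60, 12):
            mask[r, 5] = True
        cs = cluster_stats(mask, scale_um=0.5, mean_cell_area_um2=0.25)
        assert cs.fraction_in_clusters == 0.0

    def test_mixed_scene_estimates_generator_cell_area(self):
        params = ImageSimParams(seed=6, cell_density=0.01, kappa=0.0004)
        stack, _ = simulate_fish_image(params)
        mask = segment_channel(stack, "total_bacteria")
        area = mean_cell_area(mask, stack.scale_um)
        assert area == pytest.approx(np.pi * params.cell_radius_um**2, rel=0.15)


class TestThicknessAndGoblet:
    def test_parallel_boundaries(self):
        stack = flat_stack(band_um=50.0, rows=300)
        dists, mean, sd = mucus_thickness(stack)
        assert mean == pytest.approx(50.0, abs=0.5)
        assert sd < 0.5

    def test_generated_band_width_recovered(self):
        stack, truth = simulate_fish_image(ImageSimParams(band_width_um=40.0, seed=7))
        _, mean, _ = mucus_thickness(stack)
        assert abs(mean - truth.band_width_um) / truth.band_width_um < 0.05

    def test_missing_boundary_raises(self):
        stack = flat_stack()
        broken = ImageStack(
            channels=stack.channels, scale_um=stack.scale_um,
            boundaries={"epithelial_surface": stack.boundaries["epithelial_surface"]},
        )
        with pytest.raises(ValueError, match="mucus_outer_edge"):
            mucus_thickness(broken)

    def test_crossing_boundaries_raise(self):
        stack = flat_stack()
        swapped = ImageStack(
            channels=stack.channels, scale_um=stack.scale_um,
            boundaries={
                "epithelial_surface": stack.boundaries["mucus_outer_edge"],
                "mucus_outer_edge": stack.boundaries["epithelial_surface"],
            },
        )
        with pytest.raises(ValueError, match="cross"):
            mucus_thickness(swapped)

    @pytest.mark.parametrize(
        "stain_rows, expected", [((0, 10), 0.5), ((0, 0), 0.0), ((0, 20), 1.0)]
    )
    def test_goblet_biovolume(self, stain_rows, expected):
        tissue = np.zeros((20, 10), bool)
        tissue[:20] = True
        stain = np.zeros((20, 10), bool)
        stain[stain_rows[0]: stain_rows[1]] = True
        assert goblet_biovolume(stain, tissue) == pytest.approx(expected)

    def test_empty_tissue_rejected(self):
        with pytest.raises(ValueError):
            goblet_biovolume(np.ones((5, 5), bool), np.zeros((5, 5), bool))
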