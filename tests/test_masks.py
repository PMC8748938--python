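"""Mask thresholding, cell detection, marker assignment, positive fractions."""

import numpy as np
import pandas as pd
import pytest

from proximif import (BinaryMask, CellDetector, MaskStack, OverlapRule,
                      RenderConfig, SimConfig, assign_markers, detect_cells,
                      generate_tissue, positive_fraction, render_masks,
                      threshold_channel)


class TestThreshold:
    def test_all_zero_image(self):
        m = threshold_channel(np.zeros((5, 5)), 1.0)
        assert not m.grid.any()

    def test_fixed_threshold_closed(self):
        img = np.array([[0.0, 10.0], [5.0, 4.9]])
        m = threshold_channel(img, 5.0)
        np.testing.assert_array_equal(m.grid, [[False, True], [True, False]])

    def test_otsu_matches_exhaustive_between_class_variance_search(self, rng):
        """Otsu on a two-level image equals any fixed threshold in (lo, hi]."""
        img = rng.choice([2.0, 8.0], size=(30, 30))
        got = threshold_channel(img, "otsu").grid
        # independent oracle: scan candidate thresholds, maximize between-class
        # variance sigma_b^2 = w0 w1 (mu0 - mu1)^2 over the observed values
        vals = np.sort(np.unique(img))
        best_t, best_v = None, -1.0
        for t in (vals[1:] + vals[:-1]) / 2:
            lo, hi = img[img < t], img[img >= t]
            v = (lo.size * hi.size / img.size**2) * (lo.mean() - hi.mean()) ** 2
            if v > best_v:
                best_v, best_t = v, t
        np.testing.assert_array_equal(got, img >= best_t)

    def test_otsu_on_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            threshold_channel(np.full((4, 4), 7.0), "otsu")

    def test_negative_or_nonfinite_intensities_rejected(self):
        with pytest.raises(ValueError):
            threshold_channel(np.array([[-1.0, 2.0]]), 1.0)
        with pytest.raises(ValueError):
            threshold_channel(np.array([[np.nan, 2.0]]), 1.0)


def _flood_fill_components(grid: np.ndarray, connectivity: int) -> int:
    """Independent component-count oracle by explicit flood fill."""
    seen = np.zeros_like(grid, dtype=bool)
    if connectivity == 8:
        nbrs = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
                if (di, dj) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    n = 0
    for i in range(grid.shape[0]):
        for j in range(grid.shape[1]):
            if grid[i, j] and not seen[i, j]:
                n += 1
                stack = [(i, j)]
                seen[i, j] = True
                while stack:
                    ci, cj = stack.pop()
                    for di, dj in nbrs:
                        ni, nj = ci + di, cj + dj
                        if (0 <= ni < grid.shape[0] and 0 <= nj < grid.shape[1]
                                and grid[ni, nj] and not seen[ni, nj]):
                            seen[ni, nj] = True
                            stack.append((ni, nj))
    return n


class TestDetect:
    def test_empty_mask(self):
        det = detect_cells(BinaryMask(np.zeros((10, 10), bool), 1.0))
        assert len(det.cells) == 0

    def test_centroid_convention(self):
        grid = np.zeros((20, 20), bool)
        grid[10:13, 10:13] = True
        det = detect_cells(BinaryMask(grid, 0.5), min_area_px=1)
        assert len(det.cells) == 1
        row = det.cells.iloc[0]
        assert row["x_um"] == pytest.approx(5.75)
        assert row["y_um"] == pytest.approx(5.75)

    def test_diagonal_touch_connectivity(self):
        grid = np.zeros((5, 5), bool)
        grid[1, 1] = grid[2, 2] = True
        n8 = len(detect_cells(BinaryMask(grid, 1.0), min_area_px=1,
                              connectivity=8).cells)
        n4 = len(detect_cells(BinaryMask(grid, 1.0), min_area_px=1,
                              connectivity=4).cells)
        assert (n8, n4) == (1, 2)
        assert _flood_fill_components(grid, 8) == 1
        assert _flood_fill_components(grid, 4) == 2

    def test_component_counts_match_flood_fill_oracle(self, rng):
        grid = rng.random((40, 40)) < 0.3
        for conn in (4, 8):
            got = len(detect_cells(BinaryMask(grid, 1.0), min_area_px=1,
                                   connectivity=conn).cells)
            assert got == _flood_fill_components(grid, conn)

    def test_min_area_filters_debris(self):
        grid = np.zeros((10, 10), bool)
        grid[1, 1] = True          # 1-px speck
        grid[5:8, 5:8] = True      # 9-px nucleus
        det = detect_cells(BinaryMask(grid, 1.0), min_area_px=4)
        assert len(det.cells) == 1
        assert det.cells["area_px"].iloc[0] == 9

    def test_translation_invariance_of_count(self, rng):
        grid = np.zeros((60, 60), bool)
        inner = rng.random((40, 40)) < 0.2
        grid[10:50, 10:50] = inner
        base = len(detect_cells(BinaryMask(grid, 1.0), min_area_px=1).cells)
        shifted = np.roll(grid, (3, -2), axis=(0, 1))
        assert len(detect_cells(BinaryMask(shifted, 1.0), min_area_px=1).cells) == base

    def test_estimator_interface(self):
        grid = np.zeros((10, 10), bool)
        grid[2:5, 2:5] = True
        det = CellDetector(min_area_px=1).fit(BinaryMask(grid, 1.0))
        assert det.n_components_ == 1
        assert det.get_params()["connectivity"] == 8


class TestAssignMarkers:
    @staticmethod
    def _stack_with(nucleus, marker, px=1.0):
        return MaskStack(channels={"DAPI": nucleus, "PGRN": marker},
                         pixel_size_um=px)

    def test_all_false_marker_channel_gives_all_negative(self):
        nucleus = np.zeros((10, 10), bool)
        nucleus[3:6, 3:6] = True
        stack = self._stack_with(nucleus, np.zeros((10, 10), bool))
        det = detect_cells(BinaryMask(nucleus, 1.0), min_area_px=1)
        out = assign_markers(det, stack, OverlapRule(dilation_um=0))
        assert not out["PGRN"].any()

    def test_marker_superset_always_positive(self):
        nucleus = np.zeros((10, 10), bool)
        nucleus[3:6, 3:6] = True
        stack = self._stack_with(nucleus, np.ones((10, 10), bool))
        det = detect_cells(BinaryMask(nucleus, 1.0), min_area_px=1)
        out = assign_markers(det, stack, OverlapRule(0, min_overlap_fraction=1.0))
        assert out["PGRN"].all()

    def test_overlap_fraction_threshold_brute_force(self):
        """10-px nucleus, marker covering 3 px: positive at 0.25, not at 0.35."""
        nucleus = np.zeros((10, 10), bool)
        nucleus[2:4, 2:7] = True  # 10 px
        marker = np.zeros((10, 10), bool)
        marker[2, 2:5] = True     # 3 of those px
        assert int((nucleus & marker).sum()) == 3  # brute-force overlap count
        det = detect_cells(BinaryMask(nucleus, 1.0), min_area_px=1)
        stack = self._stack_with(nucleus, marker)
        pos = assign_markers(det, stack, OverlapRule(0, 0.25))["PGRN"].iloc[0]
        neg = assign_markers(det, stack, OverlapRule(0, 0.35))["PGRN"].iloc[0]
        assert bool(pos) and not bool(neg)

    def test_missing_channel_named_in_error(self):
        nucleus = np.zeros((10, 10), bool)
        nucleus[3:6, 3:6] = True
        stack = self._stack_with(nucleus, np.zeros((10, 10), bool))
        det = detect_cells(BinaryMask(nucleus, 1.0), min_area_px=1)
        with pytest.raises(KeyError, match="CD8"):
            assign_markers(det, stack, channels=["CD8"])

    def test_centroid_disk_fallback_without_footprints(self):
        marker = np.zeros((10, 10), bool)
        marker[4:7, 4:7] = True
        stack = self._stack_with(np.zeros((10, 10), bool), marker)
        cells = pd.DataFrame({"id": [0, 1], "x_um": [5.5, 1.0], "y_um": [5.5, 1.0]})
        out = assign_markers(cells, stack, OverlapRule(dilation_um=1.5))
        assert bool(out["PGRN"].iloc[0]) and not bool(out["PGRN"].iloc[1])


class TestPositiveFraction:
    def test_basic_fractions(self):
        cells = pd.DataFrame({"PGRN": [False] * 10})
        assert positive_fraction(cells, "PGRN") == 0.0
        cells = pd.DataFrame({"PGRN": [True, False, False, False]})
        assert positive_fraction(cells, "PGRN") == 0.25

    def test_empty_table_is_an_error(self):
        with pytest.raises(ValueError):
            positive_fraction(pd.DataFrame({"PGRN": []}), "PGRN")

    def test_invariant_to_order_and_duplication(self, small_tissue):
        f = positive_fraction(small_tissue, "PGRN")
        shuffled = small_tissue.sample(frac=1.0, random_state=0)
        doubled = pd.concat([small_tissue, small_tissue])
        assert positive_fraction(shuffled, "PGRN") == pytest.approx(f)
        assert positive_fraction(doubled, "PGRN") == pytest.approx(f)

    def test_simulated_marginal_recovered_within_binomial_error(self):
        cfg = SimConfig(window_um=(1600, 1600), lambda_stroma=0, lambda_cd8=0,
                        nest_parent_intensity=6e-5, nest_mean_cells=150,
                        p_nest_pgrn=1.0, p_pgrn_within=0.3, seed=21)
        cells = generate_tissue(cfg)
        n = len(cells)
        assert n >= 10_000
        se = np.sqrt(0.3 * 0.7 / n)
        assert abs(positive_fraction(cells, "PGRN") - 0.3) < 3 * se


def test_round_trip_recovers_cells_and_markers():
    """simulate -> render -> detect -> assign recovers non-overlapping nuclei.

    With marker disks equal to the nucleus disk and no dilation, cells whose
    nearest neighbor is farther than twice the nucleus radius must be
    recovered with exact marker flags (disjoint disks cannot bleed). On the
    raster, disjoint disks can still touch diagonally when the inter-disk gap
    is below one pixel diagonal, so the isolation cut carries a 2*sqrt(2)*px
    margin beyond 2*r.
    """
    from scipy.spatial import cKDTree

    cfg = SimConfig(window_um=(600, 600), lambda_stroma=3e-4,
                    nest_parent_intensity=2e-5, nest_mean_cells=40,
                    nest_sigma_um=50, lambda_cd8=3e-4, seed=13)
    cells = generate_tissue(cfg)
    r_nuc = 3.0
    render = RenderConfig.for_window(cfg.window_um, pixel_size_um=1.0,
                                     r_nucleus_um=r_nuc, r_marker_um=r_nuc)
    stack = render_masks(cells, render)
    det = detect_cells(BinaryMask(stack["DAPI"], stack.pixel_size_um))
    table = assign_markers(det, stack,
                           OverlapRule(dilation_um=0.0, min_overlap_fraction=0.5))

    xy = cells[["x_um", "y_um"]].to_numpy()
    d_nn, _ = cKDTree(xy).query(xy, k=2)
    margin = 2 * np.sqrt(2) * stack.pixel_size_um
    isolated = cells[d_nn[:, 1] > 2 * r_nuc + margin].reset_index(drop=True)
    assert len(isolated) > 100

    d, idx = cKDTree(table[["x_um", "y_um"]].to_numpy()).query(
        isolated[["x_um", "y_um"]].to_numpy())
    recovered = d <= r_nuc
    assert recovered.mean() >= 0.99
    matched = table.iloc[idx[recovered]]
    truth = isolated[recovered]
    for ch in ("PanCK", "PGRN", "MHCI", "CD8", "GzmB"):
        agree = (matched[ch].to_numpy() == truth[ch].to_numpy()).mean()
        assert agree >= 0.99, ch
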