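"""Benchmark experiments over the synthetic tissue and cohort generators.

Each function runs one self-contained study at desk scale and returns the
measured quantities: oracle-equivalence sweeps for the spatial pairing,
the full simulate→render→detect→assign round trip, recovery of the CD8
exclusion effect over seeds, type-I/power calibration of the per-image
MHCI-fraction comparison, and the transcriptome stratification benchmark.

All randomness is derived from a single integer seed; derived seeds stay
below 2**31.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .cohort import mann_whitney_two_tailed
from .expression import median_split_by_gene, paired_spearman, rle_cpm
from .masks import BinaryMask, OverlapRule, assign_markers, detect_cells
from .phenotype import classify_cells
from .simulate import (MARKER_CHANNELS, RenderConfig, SimConfig,
                       generate_tissue, render_masks, simulate_counts)
from .spatial import (conditional_marker_fraction, neighbor_summary,
                      pairs_within_radius)


def _derive(seed: int, salt: int) -> int:
    return int((seed * 1_000_003 + salt) % (2**31 - 1))


def pair_oracle_mismatches(seed: int, n_instances: int = 50,
                           max_cells: int = 1000,
                           radius_um: float = 50.0) -> dict:
    """Compare KD-tree pairing and neighbor counts with an O(n^2) oracle.

    Returns the number of instances (random point sets, up to ``max_cells``
    per side) on which either the pair set or any per-anchor unique-neighbor
    count differs from the brute-force all-pairs computation.
    """
    mismatches = 0
    total_pairs = 0
    for k in range(n_instances):
        rng = np.random.default_rng(_derive(seed, k))
        n_a = int(rng.integers(1, max_cells // 2 + 1))
        n_b = int(rng.integers(1, max_cells // 2 + 1))
        side = float(rng.uniform(100, 600))
        a = pd.DataFrame({"id": np.arange(n_a),
                          "x_um": rng.uniform(0, side, n_a),
                          "y_um": rng.uniform(0, side, n_a)})
        b = pd.DataFrame({"id": np.arange(n_a, n_a + n_b),
                          "x_um": rng.uniform(0, side, n_b),
                          "y_um": rng.uniform(0, side, n_b)})
        ps = pairs_within_radius(a, b, radius_um)
        got = set(zip(ps.pairs["anchor_id"], ps.pairs["partner_id"]))
        d = cdist(a[["x_um", "y_um"]], b[["x_um", "y_um"]])
        ii, jj = np.nonzero(d <= radius_um)
        expected = set(zip(a["id"].to_numpy()[ii], b["id"].to_numpy()[jj]))
        summ = neighbor_summary(ps, a["id"])
        counts_ok = all(
            summ.unique_partner_counts[aid] == int((d[k2] <= radius_um).sum())
            for k2, aid in enumerate(a["id"]))
        if got != expected or not counts_ok:
            mismatches += 1
        total_pairs += len(got)
    return {"mismatches": mismatches, "n_instances": n_instances,
            "total_pairs": total_pairs}


def roundtrip_recovery(seed: int) -> dict:
    """Simulate → render → detect → assign; score recovery of isolated nuclei.

    Cells whose nearest neighbor exceeds twice the nucleus radius plus one
    raster diagonal are scored for centroid recovery (within the nucleus
    radius) and exact marker-flag agreement.
    """
    cfg = SimConfig(window_um=(600, 600), lambda_stroma=3e-4,
                    nest_parent_intensity=2e-5, nest_mean_cells=40,
                    nest_sigma_um=50, lambda_cd8=3e-4, seed=_derive(seed, 901))
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
    d, idx = cKDTree(table[["x_um", "y_um"]].to_numpy()).query(
        isolated[["x_um", "y_um"]].to_numpy())
    recovered = d <= r_nuc
    matched = table.iloc[idx[recovered]]
    truth = isolated[recovered]
    flags_ok = np.ones(len(matched), dtype=bool)
    for ch in MARKER_CHANNELS:
        flags_ok &= matched[ch].to_numpy() == truth[ch].to_numpy()
    return {"n_isolated": int(len(isolated)),
            "recovery_pct": 100.0 * float(recovered.mean()),
            "recovered_with_correct_flags_pct":
                100.0 * float(recovered.mean() * flags_ok.mean())}


def exclusion_effect_over_seeds(seed: int, n_seeds: int = 20,
                                excl_radius_um: float = 50.0,
                                excl_floor: float = 0.0,
                                radius_um: float = 50.0) -> dict:
    """Mean unique CD8 neighbors around PGRN+ vs PGRN− tumor anchors, per seed.

    With an active exclusion ramp the PGRN+ anchors should see fewer CD8
    neighbors in nearly every seed; with ``excl_radius_um=0`` the per-seed
    differences should be centered at zero.
    """
    diffs = []
    wins = 0
    for s in range(n_seeds):
        cfg = SimConfig(excl_radius_um=excl_radius_um, excl_floor=excl_floor,
                        lambda_cd8=6e-4, seed=_derive(seed, 7000 + s))
        cells = generate_tissue(cfg)
        tumor = cells[cells["compartment"] == "tumor"]
        cd8 = cells[cells["CD8"]]
        means = {}
        for flag in (True, False):
            anchors = tumor[tumor["PGRN"] == flag]
            if len(anchors) == 0 or len(cd8) == 0:
                means[flag] = np.nan
                continue
            ps = pairs_within_radius(anchors, cd8, radius_um)
            means[flag] = neighbor_summary(ps, anchors["id"]).mean_unique_partners
        diff = means[True] - means[False]
        diffs.append(diff)
        wins += int(diff < 0)
    diffs = np.asarray(diffs)
    return {"n_seeds": n_seeds,
            "seeds_with_fewer_cd8_near_pgrn_pos": wins,
            "mean_diff": float(np.nanmean(diffs)),
            "se_diff": float(np.nanstd(diffs, ddof=1) / np.sqrt(n_seeds))}


def _cohort_cells(p_pos: float, p_neg: float, n_images: int,
                  seed: int) -> pd.DataFrame:
    frames = []
    for i in range(n_images):
        cfg = SimConfig(window_um=(400, 400), lambda_stroma=0, lambda_cd8=0,
                        nest_parent_intensity=6e-5, nest_mean_cells=70,
                        nest_sigma_um=40,
                        p_mhc_given_pgrn_pos=p_pos, p_mhc_given_pgrn_neg=p_neg,
                        seed=_derive(seed, i))
        frames.append(generate_tissue(cfg).assign(image=i))
    return classify_cells(pd.concat(frames, ignore_index=True))


def mhci_fraction_rejection_rate(seed: int, p_pos: float, p_neg: float,
                                 n_cohorts: int = 400, n_images: int = 8,
                                 alpha: float = 0.05) -> dict:
    """Fraction of simulated cohorts in which the per-image MHCI+ fraction
    comparison (PGRN+PanCK+ vs PGRN−PanCK+, two-tailed Mann–Whitney) rejects.

    With ``p_pos == p_neg`` this measures the type-I error of the whole
    per-image-then-across-images procedure; with separated probabilities,
    its power.
    """
    rejections = 0
    for c in range(n_cohorts):
        cells = _cohort_cells(p_pos, p_neg, n_images, _derive(seed, 31_000 + c))
        res = conditional_marker_fraction(cells, "tumor_pgrn_pos",
                                          "tumor_pgrn_neg", "MHCI")
        rejections += int(res.comparison.p_two_tailed < alpha)
    return {"n_cohorts": n_cohorts,
            "rejection_rate_pct": 100.0 * rejections / n_cohorts}


def stratification_benchmark(seed: int) -> dict:
    """Full transcriptome stratification on the synthetic paired cohort.

    RLE-CPM normalization, stroma-only median split on the designated gene,
    recovery of the generating component labels, and the paired
    epithelium/stroma correlation of that gene.
    """
    counts, annot, truth = simulate_counts(seed=_derive(seed, 77))
    res = rle_cpm(counts)
    stroma = annot.loc[annot["compartment"] == "stroma", "sample"].tolist()
    split = median_split_by_gene(res, "GRN", stroma)
    subj = annot.set_index("sample")["subject"]
    recovered = (split.labels.rename(index=subj)
                 == truth[subj[stroma].values]).mean()
    rho, p, n_pairs, _ = paired_spearman(res, "GRN", annot)
    return {"n_high": split.n_high, "n_low": split.n_low,
            "n_stroma_samples": len(stroma),
            "label_recovery_pct": 100.0 * float(recovered),
            "paired_spearman_rho": float(rho),
            "paired_spearman_p": float(p),
            "n_pairs": n_pairs,
            "size_factor_geomean": float(np.exp(np.log(res.size_factors).mean()))}


def mann_whitney_exact_error(max_n: int = 6) -> dict:
    """Largest deviation of the package p value from exhaustive enumeration
    over every tie-free rank configuration with n_x = n_y <= max_n."""
    import itertools
    import math

    worst = 0.0
    n_cases = 0
    for n in range(2, max_n + 1):
        ranks = np.arange(1, 2 * n + 1, dtype=float)
        # exact two-sided p for each achievable min-U via the U distribution
        us = np.array([sum(c) - n * (n + 1) / 2
                       for c in itertools.combinations(range(1, 2 * n + 1), n)])
        total = math.comb(2 * n, n)
        for comb in itertools.combinations(range(2 * n), n):
            x = ranks[list(comb)]
            y = np.delete(ranks, list(comb))
            got = mann_whitney_two_tailed(x, y)
            u_min = min(got.u_statistic, n * n - got.u_statistic)
            exact = np.minimum(us, n * n - us)
            p_exact = float((exact <= u_min).sum()) / total
            worst = max(worst, abs(got.p_two_tailed - p_exact))
            n_cases += 1
    return {"max_abs_error": worst, "n_cases": n_cases}
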