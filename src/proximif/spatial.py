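"""Fixed-radius proximity statistics between phenotype groups.

The core spatial computation: all anchor–partner cell pairs within a
Euclidean radius (50 µm by default convention of the tumor/T-cell analysis,
always an explicit argument here), per-anchor unique-neighbor counts, mean
pair distance, and phenotype-conditional marker fractions compared across
images with a two-tailed Mann–Whitney test.

Distances are centroid-to-centroid in µm; the radius threshold is closed
(a pair at exactly the radius counts). No edge correction is applied:
anchors near the field border simply have truncated neighborhoods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .cohort import GroupComparison, mann_whitney_two_tailed


@dataclass
class PairSet:
    """Anchor–partner pairs within ``radius_um`` (closed threshold)."""

    radius_um: float
    pairs: pd.DataFrame  # columns: anchor_id, partner_id, distance_um


@dataclass
class NeighborSummary:
    """Per-anchor unique partner counts plus group-level aggregates.

    ``mean_pair_distance_um`` is NaN when there are no pairs (the undefined
    case); anchors without any partner report a count of 0.
    """

    unique_partner_counts: pd.Series  # indexed by anchor id
    mean_pair_distance_um: float
    n_anchors: int
    n_partners: int
    n_pairs: int

    @property
    def mean_unique_partners(self) -> float:
        if self.n_anchors == 0:
            return float("nan")
        return float(self.unique_partner_counts.mean())


def _coords(cells: pd.DataFrame) -> np.ndarray:
    return cells[["x_um", "y_um"]].to_numpy(dtype=float)


def pairs_within_radius(anchors: pd.DataFrame, partners: pd.DataFrame,
                        radius_um: float) -> PairSet:
    """All anchor–partner pairs with Euclidean distance <= radius_um.

    A cell appearing in both groups (same ``id``) never pairs with itself.
    Swapping the anchor and partner roles transposes the pair list.
    """
    if radius_um <= 0 or not np.isfinite(radius_um):
        raise ValueError(f"radius_um must be positive and finite, got {radius_um}")
    for name, df in (("anchors", anchors), ("partners", partners)):
        if len(df) and df["id"].duplicated().any():
            raise ValueError(f"duplicate ids in {name}")
    empty = pd.DataFrame({"anchor_id": pd.Series(dtype=np.int64),
                          "partner_id": pd.Series(dtype=np.int64),
                          "distance_um": pd.Series(dtype=float)})
    if len(anchors) == 0 or len(partners) == 0:
        return PairSet(radius_um=radius_um, pairs=empty)
    ta = cKDTree(_coords(anchors))
    tp = cKDTree(_coords(partners))
    coo = ta.sparse_distance_matrix(tp, max_distance=radius_um,
                                    output_type="coo_matrix")
    a_ids = anchors["id"].to_numpy()[coo.row]
    p_ids = partners["id"].to_numpy()[coo.col]
    keep = a_ids != p_ids
    pairs = pd.DataFrame({"anchor_id": a_ids[keep].astype(np.int64),
                          "partner_id": p_ids[keep].astype(np.int64),
                          "distance_um": coo.data[keep]})
    pairs = pairs.sort_values(["anchor_id", "partner_id"], kind="mergesort",
                              ignore_index=True)
    return PairSet(radius_um=radius_um, pairs=pairs)


def neighbor_summary(pairset: PairSet, all_anchor_ids,
                     all_partner_ids=None) -> NeighborSummary:
    """Summarize a pair set over the full anchor universe.

    Anchors that formed no pair report a unique-neighbor count of 0, so
    the universe must include them explicitly.
    """
    anchor_index = pd.Index(np.asarray(all_anchor_ids, dtype=np.int64)).unique()
    pairs = pairset.pairs
    unknown = set(pairs["anchor_id"]) - set(anchor_index)
    if unknown:
        raise ValueError(f"pair anchors missing from anchor universe: {sorted(unknown)}")
    counts = (pairs.groupby("anchor_id")["partner_id"].nunique()
              .reindex(anchor_index, fill_value=0).astype(np.int64))
    counts.index.name = "anchor_id"
    if all_partner_ids is not None:
        n_partners = len(pd.Index(np.asarray(all_partner_ids)).unique())
    else:
        n_partners = int(pairs["partner_id"].nunique())
    mean_d = float(pairs["distance_um"].mean()) if len(pairs) else float("nan")
    return NeighborSummary(unique_partner_counts=counts,
                           mean_pair_distance_um=mean_d,
                           n_anchors=int(len(anchor_index)),
                           n_partners=n_partners,
                           n_pairs=int(len(pairs)))


@dataclass
class ConditionalFractionResult:
    """Marker-positive fractions within two phenotype groups, per image.

    ``fraction_a``/``fraction_b`` are the across-image means;
    ``comparison`` tests the per-image fractions between the groups.
    """

    per_image: pd.DataFrame  # image, frac_a, frac_b, n_a, n_b
    fraction_a: float
    fraction_b: float
    comparison: GroupComparison


def conditional_marker_fraction(cells: pd.DataFrame, group_a: str, group_b: str,
                                marker: str,
                                image_col: str = "image") -> ConditionalFractionResult:
    """Fraction of marker-positive cells in each phenotype group, per image.

    Fractions are computed within each image; the two per-image fraction
    samples are then compared with a two-tailed Mann–Whitney test. Images in
    which a group is empty contribute no fraction for that group; a group
    empty in every image is an error.
    """
    for col in (group_a, group_b, marker):
        if col not in cells.columns:
            raise KeyError(f"column {col!r} not present on the cell table")
    if image_col not in cells.columns:
        cells = cells.assign(**{image_col: 0})
    rows = []
    for image, sub in cells.groupby(image_col, sort=True):
        row = {"image": image}
        for tag, group in (("a", group_a), ("b", group_b)):
            members = sub[sub[group].astype(bool)]
            row[f"n_{tag}"] = len(members)
            row[f"frac_{tag}"] = (float(members[marker].astype(bool).mean())
                                  if len(members) else np.nan)
        rows.append(row)
    per_image = pd.DataFrame(rows)
    fa = per_image["frac_a"].dropna()
    fb = per_image["frac_b"].dropna()
    if fa.empty:
        raise ValueError(f"group {group_a!r} is empty in every image")
    if fb.empty:
        raise ValueError(f"group {group_b!r} is empty in every image")
    comparison = mann_whitney_two_tailed(fa.to_numpy(), fb.to_numpy())
    return ConditionalFractionResult(per_image=per_image,
                                     fraction_a=float(fa.mean()),
                                     fraction_b=float(fb.mean()),
                                     comparison=comparison)
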