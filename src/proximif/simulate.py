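"""Synthetic multiplexed-IF tissue: marked point patterns and rendered channel masks.

The simulator emulates the statistical structure of a tumor section stained
for DAPI, PanCK, PGRN, MHCI, CD8 and GzmB:

* tumor cells arranged in nests (a Thomas cluster process: Poisson parents,
  Poisson-distributed Gaussian-scattered offspring),
* nest-coherent PGRN status with per-cell positivity inside PGRN-high nests,
* MHCI positivity conditional on the cell's PGRN status,
* a homogeneous stromal background,
* CD8 T cells placed homogeneously and then thinned near PGRN+ tumor cells
  with a distance-dependent retention probability, modelling CD8 exclusion,
* GzmB positivity among retained CD8 cells.

Every cell class draws from its own counter-based random substream, so e.g.
switching CD8 simulation on or off never perturbs tumor placement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

NUCLEUS_CHANNEL = "DAPI"
MARKER_CHANNELS = ("PanCK", "PGRN", "MHCI", "CD8", "GzmB")

# substream indices (append-only: adding a class must not renumber others)
_STREAM_TUMOR_GEOM = 0
_STREAM_TUMOR_MARKS = 1
_STREAM_STROMA = 2
_STREAM_CD8_GEOM = 3
_STREAM_CD8_MARKS = 4


def _substream(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


@dataclass
class SimConfig:
    """Parameters of the synthetic tissue.

    Intensities are in cells/µm², lengths in µm, probabilities in [0, 1].

    Attributes
    ----------
    window_um:
        (width, height) of the simulated field in µm.
    lambda_stroma:
        Intensity of the homogeneous stromal background.
    nest_parent_intensity:
        Intensity of tumor-nest centers (Poisson parents).
    nest_mean_cells:
        Expected number of tumor cells per nest (Poisson offspring count).
    nest_sigma_um:
        Isotropic Gaussian spread of offspring around the nest center.
    p_nest_pgrn:
        Probability that a whole nest is PGRN-high.
    p_pgrn_within:
        Per-cell PGRN+ probability inside a PGRN-high nest (cells in
        PGRN-low nests are PGRN−).
    p_mhc_given_pgrn_pos, p_mhc_given_pgrn_neg:
        MHCI+ probability for a tumor cell conditional on its PGRN status.
    lambda_cd8:
        Intensity of CD8 candidates before exclusion thinning.
    excl_radius_um:
        Radius of CD8 exclusion around PGRN+ tumor cells; 0 disables
        thinning entirely.
    excl_floor:
        Retention probability at distance 0 from a PGRN+ tumor cell.
        Retention ramps linearly to 1 at ``excl_radius_um``.
    p_gzmb_given_cd8:
        GzmB+ probability among retained CD8 cells.
    seed:
        Integer seed; identical configs produce identical tables.
    """

    window_um: tuple[float, float] = (1000.0, 1000.0)
    lambda_stroma: float = 8e-4
    nest_parent_intensity: float = 2e-5
    nest_mean_cells: float = 150.0
    nest_sigma_um: float = 40.0
    p_nest_pgrn: float = 0.5
    p_pgrn_within: float = 0.9
    p_mhc_given_pgrn_pos: float = 0.2
    p_mhc_given_pgrn_neg: float = 0.7
    lambda_cd8: float = 6e-4
    excl_radius_um: float = 50.0
    excl_floor: float = 0.2
    p_gzmb_given_cd8: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.window_um
        if not (np.isfinite(w) and np.isfinite(h) and w > 0 and h > 0):
            raise ValueError(f"window dimensions must be positive and finite, got {self.window_um}")
        for name in ("lambda_stroma", "nest_parent_intensity", "nest_mean_cells",
                     "nest_sigma_um", "lambda_cd8", "excl_radius_um"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        for name in ("p_nest_pgrn", "p_pgrn_within", "p_mhc_given_pgrn_pos",
                     "p_mhc_given_pgrn_neg", "excl_floor", "p_gzmb_given_cd8"):
            v = getattr(self, name)
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["window_um"] = list(self.window_um)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "window_um" in d:
            d["window_um"] = tuple(d["window_um"])
        return cls(**d)


@dataclass
class RenderConfig:
    """How a cell table is rasterized into binary channel masks."""

    pixel_size_um: float = 1.0
    image_shape_px: tuple[int, int] = (1000, 1000)  # (rows, cols)
    r_nucleus_um: float = 3.0
    r_marker_um: float | dict[str, float] = 5.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.pixel_size_um) and self.pixel_size_um > 0):
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        nr, nc = self.image_shape_px
        if nr <= 0 or nc <= 0:
            raise ValueError(f"image_shape_px must be positive, got {self.image_shape_px}")
        if self.r_nucleus_um <= 0:
            raise ValueError("r_nucleus_um must be > 0")
        radii = (self.r_marker_um.values() if isinstance(self.r_marker_um, dict)
                 else [self.r_marker_um])
        if any(r <= 0 for r in radii):
            raise ValueError("marker radii must be > 0")

    @classmethod
    def for_window(cls, window_um: tuple[float, float], pixel_size_um: float = 1.0,
                   **kwargs) -> "RenderConfig":
        """Shape chosen so the image covers the whole simulation window."""
        w, h = window_um
        shape = (math.ceil(h / pixel_size_um), math.ceil(w / pixel_size_um))
        return cls(pixel_size_um=pixel_size_um, image_shape_px=shape, **kwargs)

    def marker_radius(self, channel: str) -> float:
        if isinstance(self.r_marker_um, dict):
            return self.r_marker_um[channel]
        return float(self.r_marker_um)


@dataclass
class MaskStack:
    """Co-registered binary masks, one per channel, at a shared pixel size."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        shapes = {name: m.shape for name, m in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel masks are not congruent: {shapes}")
        self.channels = {name: np.asarray(m, dtype=bool) for name, m in self.channels.items()}

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


_CELL_COLUMNS = ["id", "x_um", "y_um", *MARKER_CHANNELS, "compartment", "nest_id"]


def _empty_cell_table() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        _CELL_COLUMNS,
        [np.int64, np.float64, np.float64] + [np.bool_] * len(MARKER_CHANNELS)
        + [object, np.int64])})
    return df


def generate_tissue(config: SimConfig) -> pd.DataFrame:
    """Draw one synthetic tissue realization as a cell table.

    Returns a DataFrame with one row per cell: ``id``, planar coordinates
    ``x_um``/``y_um``, one boolean column per marker channel, the ground-truth
    ``compartment`` (tumor / stroma / immune) and the ``nest_id`` of tumor
    cells (-1 elsewhere). Deterministic given ``config`` (including seed).
    """
    w, h = config.window_um
    area = w * h
    parts: list[pd.DataFrame] = []
    tumor_df: pd.DataFrame | None = None

    # --- tumor nests (Thomas process) ---
    geom = _substream(config.seed, _STREAM_TUMOR_GEOM)
    marks = _substream(config.seed, _STREAM_TUMOR_MARKS)
    n_parents = geom.poisson(config.nest_parent_intensity * area)
    if n_parents > 0 and config.nest_mean_cells > 0:
        px = geom.uniform(0, w, n_parents)
        py = geom.uniform(0, h, n_parents)
        n_off = geom.poisson(config.nest_mean_cells, n_parents)
        nest_id = np.repeat(np.arange(n_parents), n_off)
        n_tot = int(n_off.sum())
        x = np.repeat(px, n_off) + geom.normal(0, config.nest_sigma_um, n_tot)
        y = np.repeat(py, n_off) + geom.normal(0, config.nest_sigma_um, n_tot)
        nest_high = marks.random(n_parents) < config.p_nest_pgrn
        pgrn = nest_high[nest_id] & (marks.random(n_tot) < config.p_pgrn_within)
        p_mhc = np.where(pgrn, config.p_mhc_given_pgrn_pos, config.p_mhc_given_pgrn_neg)
        mhc = marks.random(n_tot) < p_mhc
        inside = (x >= 0) & (x <= w) & (y >= 0) & (y <= h)
        tumor_df = pd.DataFrame({
            "x_um": x[inside], "y_um": y[inside],
            "PanCK": True, "PGRN": pgrn[inside], "MHCI": mhc[inside],
            "CD8": False, "GzmB": False,
            "compartment": "tumor", "nest_id": nest_id[inside]})
        parts.append(tumor_df)

    # --- stromal background ---
    rng_s = _substream(config.seed, _STREAM_STROMA)
    n_stroma = rng_s.poisson(config.lambda_stroma * area)
    if n_stroma > 0:
        parts.append(pd.DataFrame({
            "x_um": rng_s.uniform(0, w, n_stroma), "y_um": rng_s.uniform(0, h, n_stroma),
            "PanCK": False, "PGRN": False, "MHCI": False, "CD8": False, "GzmB": False,
            "compartment": "stroma", "nest_id": -1}))

    # --- CD8 cells with exclusion thinning around PGRN+ tumor cells ---
    rng_c = _substream(config.seed, _STREAM_CD8_GEOM)
    rng_cm = _substream(config.seed, _STREAM_CD8_MARKS)
    n_cd8 = rng_c.poisson(config.lambda_cd8 * area)
    if n_cd8 > 0:
        cx = rng_c.uniform(0, w, n_cd8)
        cy = rng_c.uniform(0, h, n_cd8)
        retain_p = np.ones(n_cd8)
        if (config.excl_radius_um > 0 and tumor_df is not None
                and bool(tumor_df["PGRN"].any())):
            src = tumor_df.loc[tumor_df["PGRN"].astype(bool), ["x_um", "y_um"]].to_numpy()
            d, _ = cKDTree(src).query(np.column_stack([cx, cy]), k=1)
            retain_p = (config.excl_floor
                        + (1.0 - config.excl_floor)
                        * np.minimum(1.0, d / config.excl_radius_um))
        keep = rng_cm.random(n_cd8) < retain_p
        gzmb = rng_cm.random(n_cd8) < config.p_gzmb_given_cd8
        parts.append(pd.DataFrame({
            "x_um": cx[keep], "y_um": cy[keep],
            "PanCK": False, "PGRN": False, "MHCI": False,
            "CD8": True, "GzmB": gzmb[keep],
            "compartment": "immune", "nest_id": -1}))

    if not parts:
        return _empty_cell_table()
    cells = pd.concat(parts, ignore_index=True)
    if cells.empty:
        return _empty_cell_table()
    cells.insert(0, "id", np.arange(len(cells), dtype=np.int64))
    for ch in MARKER_CHANNELS:
        cells[ch] = cells[ch].astype(bool)
    cells["nest_id"] = cells["nest_id"].astype(np.int64)
    return cells[_CELL_COLUMNS]


def _stamp_disks(grid: np.ndarray, xs: np.ndarray, ys: np.ndarray,
                 radius_um: float, pixel_size_um: float) -> None:
    """OR disks into grid: pixel true iff its center lies within radius of a cell.

    Pixel centers sit at (index + 0.5) * pixel_size, x along columns, y along rows.
    """
    nr, nc = grid.shape
    r_idx = radius_um / pixel_size_um
    for x, y in zip(xs, ys):
        ci = y / pixel_size_um - 0.5  # row of center in index coords
        cj = x / pixel_size_um - 0.5
        i0 = max(0, math.ceil(ci - r_idx))
        i1 = min(nr - 1, math.floor(ci + r_idx))
        j0 = max(0, math.ceil(cj - r_idx))
        j1 = min(nc - 1, math.floor(cj + r_idx))
        if i1 < i0 or j1 < j0:
            continue
        ii = np.arange(i0, i1 + 1)[:, None]
        jj = np.arange(j0, j1 + 1)[None, :]
        grid[i0:i1 + 1, j0:j1 + 1] |= (ii - ci) ** 2 + (jj - cj) ** 2 <= r_idx ** 2


def render_masks(cells: pd.DataFrame, render: RenderConfig,
                 channels: tuple[str, ...] = MARKER_CHANNELS) -> MaskStack:
    """Rasterize a cell table into co-registered binary masks.

    The DAPI channel is the union of nucleus disks at every cell; each marker
    channel is the union of marker disks at the cells positive for it.
    """
    nr, nc = render.image_shape_px
    px = render.pixel_size_um
    if len(cells):
        out = ((cells["x_um"] < 0) | (cells["x_um"] > nc * px)
               | (cells["y_um"] < 0) | (cells["y_um"] > nr * px))
        if out.any():
            bad = cells.loc[out, "id"].tolist()
            raise ValueError(f"cells outside the rendered field: ids {bad}")
    stack = {NUCLEUS_CHANNEL: np.zeros((nr, nc), dtype=bool)}
    if len(cells):
        _stamp_disks(stack[NUCLEUS_CHANNEL], cells["x_um"].to_numpy(),
                     cells["y_um"].to_numpy(), render.r_nucleus_um, px)
    for ch in channels:
        grid = np.zeros((nr, nc), dtype=bool)
        if len(cells) and ch in cells.columns:
            pos = cells[cells[ch].astype(bool)]
            if len(pos):
                _stamp_disks(grid, pos["x_um"].to_numpy(), pos["y_um"].to_numpy(),
                             render.marker_radius(ch), px)
        stack[ch] = grid
    return MaskStack(channels=stack, pixel_size_um=px)


def simulate_counts(n_subjects: int = 64, n_genes: int = 300,
                    strat_gene: str = "GRN", base_mean: float = 50.0,
                    strat_gene_mean: float = 300.0,
                    separation_fold: float = 4.0, dispersion: float = 0.06,
                    libsize_sigma: float = 0.3,
                    seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Negative-binomial bulk RNA-seq counts with a bimodal stratification gene.

    Emulates a laser-capture cohort: each subject contributes one epithelium
    and one stroma sample. Half the subjects are "high" for the designated
    gene in stroma (mean scaled by ``separation_fold``); epithelium abundance
    of that gene is drawn independently of the stromal component, so the two
    compartments are uncorrelated by construction.

    Returns ``(counts, annot, truth)``: a genes × samples integer DataFrame,
    a sample annotation table (sample, subject, compartment), and the
    ground-truth per-subject component labels ("high"/"low").
    """
    if n_subjects < 2 or n_subjects % 2:
        raise ValueError("n_subjects must be an even integer >= 2")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(100,)))
    genes = [strat_gene] + [f"G{i:04d}" for i in range(n_genes - 1)]
    gene_means = rng.lognormal(mean=np.log(base_mean), sigma=1.0, size=n_genes)
    # the stratification gene is a well-expressed secreted-protein gene, not a
    # random draw: its low-component abundance is an explicit parameter so the
    # bimodal separation is a property of the design rather than of one seed
    gene_means[0] = strat_gene_mean
    subjects = [f"S{i:02d}" for i in range(n_subjects)]
    truth = pd.Series(["high"] * (n_subjects // 2) + ["low"] * (n_subjects // 2),
                      index=subjects, name="component")
    truth = truth.sample(frac=1.0, random_state=int(rng.integers(2**31)))
    samples, cols = [], []
    r = 1.0 / dispersion
    for subj in subjects:
        for comp in ("epithelium", "stroma"):
            lib_factor = rng.lognormal(0.0, libsize_sigma)
            mu = gene_means * lib_factor
            mu = mu.copy()
            if comp == "stroma":
                mu[0] *= separation_fold if truth[subj] == "high" else 1.0
            else:
                # compartments independent for the stratification gene
                mu[0] *= separation_fold if rng.random() < 0.5 else 1.0
            counts = rng.negative_binomial(r, r / (r + mu))
            cols.append(counts)
            samples.append({"sample": f"{subj}_{comp[0].upper()}",
                            "subject": subj, "compartment": comp})
    annot = pd.DataFrame(samples)
    counts = pd.DataFrame(np.column_stack(cols), index=pd.Index(genes, name="gene"),
                          columns=annot["sample"].tolist())
    return counts, annot, truth
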