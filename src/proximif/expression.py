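"""Bulk RNA-seq cohort stratification.

Relative-log-expression (median-of-ratios) library-size normalization to
counts per million, median split of a cohort on one gene's CPM, paired
between-compartment Spearman correlation, and the signed ranking statistic
−log(p)·sign(log2FC) that orders genes for preranked enrichment testing.

The differential-expression fit itself is consumed as a table of
(gene, log2FC, p) — fitting count models is outside this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import DichotomyResult, dichotomize_by_median


@dataclass
class CPMResult:
    """RLE-normalized counts per million with the per-sample factors used.

    ``size_factors`` multiply the library sizes into effective library
    sizes; they have geometric mean 1, so normalization only redistributes
    scale between samples.
    """

    cpm: pd.DataFrame          # genes × samples
    size_factors: pd.Series    # per sample, geometric mean 1
    library_sizes: pd.Series   # per sample column sums


def rle_size_factors(counts: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Median-of-ratios size factors on count proportions.

    The reference is the per-gene geometric mean of count proportions over
    genes observed in every sample; each sample's raw factor is the median
    ratio of its proportions to the reference, rescaled so the factors have
    geometric mean 1. Genes with a zero anywhere are excluded from the
    reference only, not from downstream CPM values.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any() or not np.isfinite(arr).all():
        raise ValueError("counts must be finite and non-negative")
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"zero library size for samples: {bad}")
    props = counts / lib
    ref_genes = (counts > 0).all(axis=1)
    if not ref_genes.any():
        raise ValueError("no gene has positive counts in all samples; "
                         "RLE reference is undefined")
    logp = np.log(props.loc[ref_genes])
    log_ratios = logp.sub(logp.mean(axis=1), axis=0)
    raw = np.exp(log_ratios.median(axis=0))
    factors = raw / np.exp(np.log(raw).mean())
    factors.name = "size_factor"
    lib.name = "library_size"
    return factors, lib


def rle_cpm(counts: pd.DataFrame) -> CPMResult:
    """Counts per million on RLE-effective library sizes."""
    factors, lib = rle_size_factors(counts)
    cpm = counts / (lib * factors) * 1e6
    return CPMResult(cpm=cpm, size_factors=factors, library_sizes=lib)


class RLECPMNormalizer(BaseEstimator, TransformerMixin):
    """Transformer view of RLE-CPM in sklearn orientation (samples × genes).

    ``fit`` learns per-sample size factors and library sizes for the fitted
    samples; ``transform`` returns their CPM matrix. Stateless with respect
    to new samples by design — factors are a property of the cohort.
    """

    def fit(self, X: pd.DataFrame, y=None) -> "RLECPMNormalizer":
        res = rle_cpm(X.T)
        self.size_factors_ = res.size_factors
        self.library_sizes_ = res.library_sizes
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        lib = X.sum(axis=1)
        f = self.size_factors_.reindex(X.index)
        if f.isna().any():
            missing = f.index[f.isna()].tolist()
            raise ValueError(f"samples not seen during fit: {missing}")
        return (X.T / (lib * f) * 1e6).T


def median_split_by_gene(cpm: pd.DataFrame | CPMResult, gene_id: str,
                         samples: list[str] | None = None) -> DichotomyResult:
    """High/low split of a sample subset at the median CPM of one gene."""
    mat = cpm.cpm if isinstance(cpm, CPMResult) else cpm
    if gene_id not in mat.index:
        raise KeyError(f"gene {gene_id!r} not present in the CPM matrix")
    row = mat.loc[gene_id]
    if samples is not None:
        missing = [s for s in samples if s not in row.index]
        if missing:
            raise KeyError(f"samples not in the CPM matrix: {missing}")
        row = row.loc[samples]
    if row.size < 2:
        raise ValueError("need at least 2 samples in the subset")
    return dichotomize_by_median(row)


def paired_spearman(cpm: pd.DataFrame | CPMResult, gene_id: str,
                    annot: pd.DataFrame, pseudocount: float = 1.0,
                    compartments: tuple[str, str] = ("epithelium", "stroma"),
                    ) -> tuple[float, float, int, int]:
    """Spearman correlation of one gene's log2(CPM+pc) between paired compartments.

    ``annot`` maps each sample to (subject, compartment); subjects lacking
    either compartment are dropped and counted. Returns
    ``(rho, p_two_tailed, n_pairs, n_dropped_subjects)``; the p value uses
    the t-approximation on midranked data.
    """
    mat = cpm.cpm if isinstance(cpm, CPMResult) else cpm
    if gene_id not in mat.index:
        raise KeyError(f"gene {gene_id!r} not present in the CPM matrix")
    for col in ("sample", "subject", "compartment"):
        if col not in annot.columns:
            raise KeyError(f"annotation lacks column {col!r}")
    vals = np.log2(mat.loc[gene_id] + pseudocount)
    ann = annot[annot["sample"].isin(vals.index)]
    wide = (ann.assign(value=vals.loc[ann["sample"]].to_numpy())
            .pivot_table(index="subject", columns="compartment", values="value",
                         aggfunc="first"))
    for comp in compartments:
        if comp not in wide.columns:
            wide[comp] = np.nan
    complete = wide[list(compartments)].dropna()
    n_dropped = len(wide) - len(complete)
    if len(complete) < 3:
        raise ValueError(f"need >= 3 complete pairs, got {len(complete)}")
    rho, p = stats.spearmanr(complete[compartments[0]], complete[compartments[1]])
    return float(rho), float(p), int(len(complete)), int(n_dropped)


def rank_statistic(de: pd.DataFrame, log_base: float | None = None) -> pd.DataFrame:
    """Signed ranking statistic −log(p)·sign(log2FC) per gene, sorted descending.

    Natural log by default (any base is rank-equivalent). The input is a
    differential-expression table with columns ``gene``, ``log2FC`` and
    ``pvalue``; p must lie in (0, 1] — a p of exactly 0 is rejected, the
    caller must floor it. Ties are broken by gene id for determinism.
    """
    for col in ("gene", "log2FC", "pvalue"):
        if col not in de.columns:
            raise KeyError(f"DE table lacks column {col!r}")
    p = de["pvalue"].to_numpy(dtype=float)
    fc = de["log2FC"].to_numpy(dtype=float)
    if (p <= 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p values must lie in (0, 1]; floor zeros before ranking")
    if not np.isfinite(fc).all():
        raise ValueError("log2FC must be finite")
    logp = np.log(p) / (np.log(log_base) if log_base else 1.0)
    stat = -logp * np.sign(fc) + 0.0  # + 0.0 folds -0.0 (p == 1) into 0.0
    out = pd.DataFrame({"gene": de["gene"].astype(str), "rank_stat": stat})
    out = out.sort_values(["rank_stat", "gene"], ascending=[False, True],
                          kind="mergesort", ignore_index=True)
    return out


def write_rnk(ranking: pd.DataFrame, path) -> None:
    """Write a ranking table in the 2-column preranked-GSEA ``.rnk`` dialect."""
    ranking[["gene", "rank_stat"]].to_csv(path, sep="\t", header=False, index=False)
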