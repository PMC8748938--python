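"""Boolean phenotype rules over per-cell marker flags.

A phenotype is a conjunction of required-positive and required-negative
markers (e.g. a PGRN+PanCK+ tumor cell, or a CD8+GzmB+ cytotoxic T cell).
Markers a rule does not mention are "don't care", so one rule set serves
panels that differ only in channel naming. A cell may satisfy several
rules, or none.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin


@dataclass(frozen=True)
class PhenotypeRule:
    name: str
    require_pos: frozenset[str] = frozenset()
    require_neg: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "require_pos", frozenset(self.require_pos))
        object.__setattr__(self, "require_neg", frozenset(self.require_neg))
        both = self.require_pos & self.require_neg
        if both:
            raise ValueError(f"rule {self.name!r} requires {sorted(both)} both + and -")

    @property
    def channels(self) -> frozenset[str]:
        return self.require_pos | self.require_neg


#: The phenotype groups of the tumor / T-cell proximity analysis.
DEFAULT_RULES: tuple[PhenotypeRule, ...] = (
    PhenotypeRule("tumor", frozenset({"PanCK"})),
    PhenotypeRule("tumor_pgrn_pos", frozenset({"PanCK", "PGRN"})),
    PhenotypeRule("tumor_pgrn_neg", frozenset({"PanCK"}), frozenset({"PGRN"})),
    PhenotypeRule("tumor_pgrn_neg_mhc_pos", frozenset({"PanCK", "MHCI"}), frozenset({"PGRN"})),
    PhenotypeRule("tumor_pgrn_pos_mhc_neg", frozenset({"PanCK", "PGRN"}), frozenset({"MHCI"})),
    PhenotypeRule("cd8", frozenset({"CD8"})),
    PhenotypeRule("cd8_gzmb", frozenset({"CD8", "GzmB"})),
)


def classify_cells(cells: pd.DataFrame,
                   rules: tuple[PhenotypeRule, ...] = DEFAULT_RULES) -> pd.DataFrame:
    """Add one boolean column per rule; marker flags are left untouched.

    Idempotent: re-running with the same rules rewrites identical columns.
    """
    names = [r.name for r in rules]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate rule names: {names}")
    out = cells.copy()
    for rule in rules:
        for ch in sorted(rule.channels):
            if ch not in cells.columns:
                raise KeyError(f"rule {rule.name!r} references unknown channel {ch!r}")
        flag = np.ones(len(cells), dtype=bool)
        for ch in rule.require_pos:
            flag &= cells[ch].astype(bool).to_numpy()
        for ch in rule.require_neg:
            flag &= ~cells[ch].astype(bool).to_numpy()
        out[rule.name] = flag
    return out


class PhenotypeClassifier(BaseEstimator, TransformerMixin):
    """Estimator wrapper over :func:`classify_cells`."""

    def __init__(self, rules: tuple[PhenotypeRule, ...] = DEFAULT_RULES):
        self.rules = rules

    def fit(self, X: pd.DataFrame, y=None) -> "PhenotypeClassifier":
        missing = sorted({ch for r in self.rules for ch in r.channels}
                         - set(X.columns))
        if missing:
            raise KeyError(f"cell table lacks channels referenced by rules: {missing}")
        self.phenotype_names_ = [r.name for r in self.rules]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return classify_cells(X, self.rules)
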