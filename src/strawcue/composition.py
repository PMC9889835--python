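"""Chemical composition of organic amendments from pyrolysis-GC/MS tables.

Identifiable pyrolysates are aggregated into eight chemical groups (lignin,
phenol, carbohydrate, saturated/unsaturated hydrocarbon, N-containing,
aromatic and poly-aromatic hydrocarbon) and four carbon-skeleton classes —
alicyclic (Alic_C), aliphatic (Alip_C), aromatic (Arom_C) and heterocyclic
(Hete_C).  Class proportions are then correlated against downstream metrics
(CUE, F:B, ...) to ask which chemistry favours efficient straw-C use.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import pandas as pd
from scipy import stats

__all__ = [
    "CHEMICAL_GROUPS",
    "SKELETON_CLASSES",
    "OaComposition",
    "aggregate_pyrolysates",
    "composition_metric_correlation",
    "load_default_pyrolysate_classes",
]

CHEMICAL_GROUPS = (
    "lignin",
    "phenol",
    "carbohydrate",
    "saturated hydrocarbon",
    "unsaturated hydrocarbon",
    "N-containing",
    "aromatic hydrocarbon",
    "poly-aromatic hydrocarbon",
)

SKELETON_CLASSES = ("Alic_C", "Alip_C", "Arom_C", "Hete_C")

_SUM_TOL = 1e-9


def _check_proportions(name: str, mapping: Mapping[str, float], vocab) -> dict:
    unknown = set(mapping) - set(vocab)
    if unknown:
        raise ValueError(f"unknown {name} labels: {sorted(unknown)}")
    if any(v < 0 for v in mapping.values()):
        raise ValueError(f"{name} proportions must be >= 0")
    total = sum(mapping.values())
    if abs(total - 1.0) > _SUM_TOL:
        raise ValueError(f"{name} proportions sum to {total}, expected 1")
    return dict(mapping)


@dataclass
class OaComposition:
    """Composition of one organic amendment.

    ``group_proportions`` maps the eight chemical groups and
    ``class_proportions`` the four C-skeleton classes to proportions; each
    mapping must be non-negative and sum to 1 (±1e-9).
    """

    oa_label: str
    group_proportions: dict[str, float]
    class_proportions: dict[str, float]

    def __post_init__(self) -> None:
        self.group_proportions = _check_proportions(
            "group", self.group_proportions, CHEMICAL_GROUPS
        )
        self.class_proportions = _check_proportions(
            "class", self.class_proportions, SKELETON_CLASSES
        )

    def to_series(self) -> pd.Series:
        data = {f"group:{g}": self.group_proportions.get(g, 0.0) for g in CHEMICAL_GROUPS}
        data.update(
            {f"class:{c}": self.class_proportions.get(c, 0.0) for c in SKELETON_CLASSES}
        )
        return pd.Series(data, name=self.oa_label)


def load_default_pyrolysate_classes() -> pd.DataFrame:
    """Default compound → (group, class) mapping for common pyrolysates.

    This table is a package convention assembled from general pyrolysis-GC/MS
    practice — a synthetic stand-in for a study-specific assignment table —
    and is meant as a starting point; real analyses should supply their own
    compound assignments.
    """
    with resources.files("strawcue.data").joinpath(
        "synthetic_pyrolysate_classes.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def aggregate_pyrolysates(compounds: pd.DataFrame, oa_label: str = "OA") -> OaComposition:
    """Aggregate a compound table into group and class proportions.

    Parameters
    ----------
    compounds : DataFrame with columns ``compound``, ``group``, ``class`` and
        ``proportion`` (relative peak proportions, peak-area convention).
        Proportions need not sum to 1; they are renormalized after summation.
    """
    required = {"compound", "group", "class", "proportion"}
    missing = required - set(compounds.columns)
    if missing:
        raise ValueError(f"compound table missing columns: {sorted(missing)}")
    if compounds.empty:
        raise ValueError("compound table is empty")
    if (compounds["proportion"] < 0).any():
        raise ValueError("peak proportions must be >= 0")
    total = compounds["proportion"].sum()
    if total == 0:
        raise ValueError("all peak proportions are zero")
    unknown_g = set(compounds["group"]) - set(CHEMICAL_GROUPS)
    if unknown_g:
        raise ValueError(f"unknown group labels: {sorted(unknown_g)}")
    unknown_c = set(compounds["class"]) - set(SKELETON_CLASSES)
    if unknown_c:
        raise ValueError(f"unknown class labels: {sorted(unknown_c)}")
    by_group = compounds.groupby("group")["proportion"].sum() / total
    by_class = compounds.groupby("class")["proportion"].sum() / total
    groups = {g: float(by_group.get(g, 0.0)) for g in CHEMICAL_GROUPS}
    classes = {c: float(by_class.get(c, 0.0)) for c in SKELETON_CLASSES}
    return OaComposition(oa_label, groups, classes)


def composition_metric_correlation(
    class_proportions: pd.DataFrame,
    metric: pd.Series,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlate each C-skeleton class proportion against a metric.

    ``class_proportions`` has one row per sample (columns = skeleton classes,
    e.g. each OA-treated sample carrying its amendment's class proportions);
    ``metric`` is the per-sample value (CUE, F:B, ...).  Returns r and p per
    class; requires ≥4 paired observations.
    """
    common = class_proportions.index.intersection(metric.index)
    if len(common) < 4:
        raise ValueError(f"need >=4 paired observations, got {len(common)}")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    rows = []
    x = class_proportions.loc[common]
    y = metric.loc[common].to_numpy(dtype=float)
    for cls in x.columns:
        r, p = corr(x[cls].to_numpy(dtype=float), y)
        rows.append({"class": cls, "r": float(r), "p_value": float(p)})
    return pd.DataFrame(rows)
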