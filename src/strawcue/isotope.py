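"""Isotope partitioning of straw-derived carbon and microbial use efficiency.

A soil receives straw that is strongly ¹³C-enriched relative to the native
soil organic matter.  Any carbon pool sampled afterwards (trapped CO₂,
microbial biomass) is a two-component mixture of native soil C and straw C,
so its δ¹³C locates it on the line between the two endmembers:

    f = (δ − δ_soil) / (δ_straw − δ_soil)

where ``f`` is the straw-derived fraction of the pool.  The δ¹³C of microbial
biomass is not measured directly; it is obtained from the chloroform
fumigation–extraction mass balance

    δ_MBC = (δC_fum · C_fum − δC_nfum · C_nfum) / (C_fum − C_nfum)

and the biomass pool size from MBC = (C_fum − C_nfum) / kEC with the usual
extraction-efficiency factor kEC (default 0.45).  The microbial use
efficiency of straw-C is then

    CUE = ¹³C-MBC / (¹³C-MBC + ¹³C-CO₂)

with ¹³C-MBC = f_MBC · MBC and ¹³C-CO₂ = f_CO₂ · (cumulative CO₂-C up to the
sampling day).

The δ_soil endmember for each pool is estimated from the replicates that
received no labeled straw ("unlabeled arm") of the same treatment and
timepoint — those replicates exist precisely to partition mineralization and
assimilation of the label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from strawcue.errors import (
    DegenerateEndmembersError,
    MassBalanceError,
    MissingControlError,
    NegativeFractionWarning,
    UndefinedCueError,
    ZeroVarianceError,
)

__all__ = [
    "MixingEndmembers",
    "AnovaResult",
    "mixing_fraction",
    "delta13c_mbc",
    "mbc_from_fumigation",
    "straw_derived_amount",
    "cue",
    "partition_replicates",
    "partition_experiment",
    "treatment_anova",
]

#: default chloroform fumigation–extraction efficiency factor
DEFAULT_KEC = 0.45

ISOTOPE_COLUMNS = [
    "sample_id",
    "treatment",
    "timepoint_days",
    "arm",
    "delta_co2",
    "cum_co2_c",
    "c_fum",
    "c_nfum",
    "delta_fum",
    "delta_nfum",
]


@dataclass(frozen=True)
class MixingEndmembers:
    """δ¹³C endmembers of the two-pool mixing model (‰ vs VPDB).

    ``delta_soil`` is the native (unlabeled) endmember, ``delta_straw`` the
    label.  They must differ, otherwise the mixing line degenerates.
    """

    delta_soil: float
    delta_straw: float

    def __post_init__(self) -> None:
        if np.isclose(self.delta_straw, self.delta_soil):
            raise DegenerateEndmembersError(
                f"delta_straw ({self.delta_straw}‰) equals delta_soil "
                f"({self.delta_soil}‰); mixing fraction is undefined"
            )


def mixing_fraction(delta, endmembers: MixingEndmembers):
    """Straw-derived fraction f of a pool from its δ¹³C.

    Parameters
    ----------
    delta : float or array-like
        δ¹³C of the measured pool (‰).
    endmembers : MixingEndmembers
        Native-soil and straw endmembers.

    Returns
    -------
    float or ndarray
        f = (δ − δ_soil)/(δ_straw − δ_soil).  Values outside [0, 1] (possible
        under measurement noise) are returned as computed and reported with a
        :class:`~strawcue.errors.NegativeFractionWarning`; silently clamping
        them would bias downstream CUE estimates.
    """
    delta = np.asarray(delta, dtype=float)
    f = (delta - endmembers.delta_soil) / (endmembers.delta_straw - endmembers.delta_soil)
    out_of_range = (f < 0) | (f > 1)
    if np.any(out_of_range):
        warnings.warn(
            f"{int(np.count_nonzero(out_of_range))} mixing fraction(s) outside [0, 1]; "
            "returned as computed",
            NegativeFractionWarning,
            stacklevel=2,
        )
    return f if f.ndim else float(f)


def delta13c_mbc(c_fum, c_nfum, delta_fum, delta_nfum):
    """δ¹³C of microbial biomass from the fumigation–extraction mass balance.

    Returns (δC_fum·C_fum − δC_nfum·C_nfum)/(C_fum − C_nfum), the δ¹³C of the
    chloroform-released (biomass) C.  Requires ``c_fum > c_nfum``: a
    fumigation flush no larger than the background extract leaves no biomass
    C to attribute a δ value to.
    """
    c_fum = np.asarray(c_fum, dtype=float)
    c_nfum = np.asarray(c_nfum, dtype=float)
    if np.any(c_nfum < 0):
        raise MassBalanceError("non-fumigated extract C must be >= 0")
    if np.any(c_fum <= c_nfum):
        raise MassBalanceError(
            "fumigated extract C must exceed non-fumigated extract C "
            "(chloroform flush smaller than background)"
        )
    delta_fum = np.asarray(delta_fum, dtype=float)
    delta_nfum = np.asarray(delta_nfum, dtype=float)
    d = (delta_fum * c_fum - delta_nfum * c_nfum) / (c_fum - c_nfum)
    return d if d.ndim else float(d)


def mbc_from_fumigation(c_fum, c_nfum, kec: float = DEFAULT_KEC):
    """Microbial biomass C (mg C kg⁻¹) from extract C of fumigated and
    non-fumigated aliquots: MBC = (C_fum − C_nfum)/kEC.

    ``kec`` is the fraction of biomass C rendered extractable by fumigation;
    the conventional value 0.45 is the default.
    """
    if not 0 < kec <= 1:
        raise ValueError(f"kec must be in (0, 1], got {kec}")
    c_fum = np.asarray(c_fum, dtype=float)
    c_nfum = np.asarray(c_nfum, dtype=float)
    if np.any(c_fum < c_nfum):
        raise MassBalanceError("fumigated extract C below non-fumigated background")
    m = (c_fum - c_nfum) / kec
    return m if m.ndim else float(m)


def straw_derived_amount(f, total_pool):
    """Straw-derived amount of a pool: f × total pool size (mg C kg⁻¹)."""
    total_pool = np.asarray(total_pool, dtype=float)
    if np.any(total_pool < 0):
        raise ValueError("total_pool must be >= 0")
    a = np.asarray(f, dtype=float) * total_pool
    return a if a.ndim else float(a)


def cue(mbc13, co2_13, clamp_negative: bool = False):
    """Microbial use efficiency of straw-C: ¹³C-MBC/(¹³C-MBC + ¹³C-CO₂).

    Both arguments are straw-derived amounts (mg C kg⁻¹).  With non-negative
    inputs the result lies in [0, 1]: the fraction of processed straw-C
    retained in biomass rather than respired.  Negative inputs (propagated
    from a negative mixing fraction under noise) are reported with a warning
    and, if ``clamp_negative``, clamped to zero before the ratio.
    """
    mbc13 = np.asarray(mbc13, dtype=float)
    co2_13 = np.asarray(co2_13, dtype=float)
    if np.any((mbc13 < 0) | (co2_13 < 0)):
        warnings.warn(
            "negative straw-derived pool amount in CUE computation",
            NegativeFractionWarning,
            stacklevel=2,
        )
        if clamp_negative:
            mbc13 = np.maximum(mbc13, 0.0)
            co2_13 = np.maximum(co2_13, 0.0)
    denom = mbc13 + co2_13
    if np.any(denom == 0):
        raise UndefinedCueError("both 13C-MBC and 13C-CO2 are zero; CUE undefined")
    e = mbc13 / denom
    return e if e.ndim else float(e)


def _require_columns(samples: pd.DataFrame) -> None:
    missing = [c for c in ISOTOPE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"isotope sample table missing columns: {missing}")


def partition_replicates(
    samples: pd.DataFrame,
    kec: float = DEFAULT_KEC,
    clamp_negative_f: bool = False,
) -> pd.DataFrame:
    """Per-replicate straw-C partitioning for every treatment × timepoint.

    For each cell, the δ_soil endmember of the CO₂ pool is the unlabeled-arm
    mean of ``delta_co2``, and of the biomass pool the unlabeled-arm mean of
    the fumigation mass-balance δ.  The straw endmember is taken from the
    ``delta_straw`` column if present, else must be supplied by the caller
    via that column.

    Returns a table with one row per labeled replicate carrying f_co2, f_mbc,
    mbc, mbc13, co2_13 and cue.
    """
    _require_columns(samples)
    if "delta_straw" not in samples.columns:
        raise ValueError(
            "samples table must carry a 'delta_straw' column (the label's δ¹³C)"
        )
    rows = []
    for (trt, day), cell in samples.groupby(["treatment", "timepoint_days"], sort=False):
        labeled = cell[cell["arm"] == "labeled"]
        control = cell[cell["arm"] == "unlabeled"]
        if labeled.empty:
            continue
        if control.empty:
            raise MissingControlError(
                f"treatment {trt!r} day {day}: no unlabeled control replicates"
            )
        delta_straw = float(labeled["delta_straw"].iloc[0])
        d_soil_co2 = float(control["delta_co2"].mean())
        d_soil_mbc = float(
            np.mean(
                delta13c_mbc(
                    control["c_fum"], control["c_nfum"],
                    control["delta_fum"], control["delta_nfum"],
                )
            )
        )
        em_co2 = MixingEndmembers(d_soil_co2, delta_straw)
        em_mbc = MixingEndmembers(d_soil_mbc, delta_straw)
        for _, rep in labeled.iterrows():
            f_co2 = mixing_fraction(rep["delta_co2"], em_co2)
            d_mbc = delta13c_mbc(
                rep["c_fum"], rep["c_nfum"], rep["delta_fum"], rep["delta_nfum"]
            )
            f_mbc = mixing_fraction(d_mbc, em_mbc)
            mbc = mbc_from_fumigation(rep["c_fum"], rep["c_nfum"], kec)
            mbc13 = straw_derived_amount(f_mbc, mbc)
            co2_13 = straw_derived_amount(f_co2, rep["cum_co2_c"])
            rows.append(
                {
                    "sample_id": rep["sample_id"],
                    "treatment": trt,
                    "timepoint_days": day,
                    "f_co2": f_co2,
                    "f_mbc": f_mbc,
                    "mbc": mbc,
                    "mbc13": mbc13,
                    "co2_13": co2_13,
                    "cue": cue(mbc13, co2_13, clamp_negative=clamp_negative_f),
                }
            )
    return pd.DataFrame(rows)


def _ci_t(values: np.ndarray, level: float) -> tuple[float, float]:
    n = values.size
    m = float(values.mean())
    se = float(values.std(ddof=1)) / np.sqrt(n)
    half = stats.t.ppf(0.5 + level / 2, df=n - 1) * se
    return m - half, m + half


def _ci_bootstrap(
    values: np.ndarray, level: float, n_boot: int, rng: np.random.Generator
) -> tuple[float, float]:
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [100 * (0.5 - level / 2), 100 * (0.5 + level / 2)])
    return float(lo), float(hi)


def partition_experiment(
    samples: pd.DataFrame,
    kec: float = DEFAULT_KEC,
    n_boot: int = 1999,
    seed: int | None = None,
    ci_method: str = "t",
    ci_level: float = 0.95,
    clamp_negative_f: bool = False,
) -> pd.DataFrame:
    """Partition a whole incubation experiment and summarize per cell.

    Replicate-level results from :func:`partition_replicates` are averaged
    per treatment × timepoint; uncertainty of the mean CUE comes either from
    a Student-t interval over replicate CUEs (``ci_method="t"``, default —
    with the typical n = 3 replicates a percentile bootstrap is necessarily
    contained in the replicate range and undercovers badly) or from a seeded
    percentile bootstrap over replicates (``ci_method="bootstrap"``).

    Returns one row per treatment × timepoint with means of f fractions and
    pools, the mean CUE, its SD across replicates, the CI and the replicate
    count.
    """
    if ci_method not in ("t", "bootstrap"):
        raise ValueError("ci_method must be 't' or 'bootstrap'")
    reps = partition_replicates(samples, kec=kec, clamp_negative_f=clamp_negative_f)
    if reps.empty:
        raise ValueError("no labeled replicates found")
    rng = np.random.default_rng(seed)
    out = []
    for (trt, day), cell in reps.groupby(["treatment", "timepoint_days"], sort=False):
        vals = cell["cue"].to_numpy(dtype=float)
        if vals.size < 2:
            raise ValueError(
                f"treatment {trt!r} day {day}: need >=2 labeled replicates for a CI"
            )
        if ci_method == "t":
            lo, hi = _ci_t(vals, ci_level)
        else:
            lo, hi = _ci_bootstrap(vals, ci_level, n_boot, rng)
        out.append(
            {
                "treatment": trt,
                "timepoint_days": day,
                "f_co2": cell["f_co2"].mean(),
                "f_mbc": cell["f_mbc"].mean(),
                "mbc": cell["mbc"].mean(),
                "mbc13": cell["mbc13"].mean(),
                "co2_13": cell["co2_13"].mean(),
                "cue": vals.mean(),
                "cue_sd": vals.std(ddof=1),
                "ci_low": lo,
                "ci_high": hi,
                "n_reps": vals.size,
            }
        )
    return pd.DataFrame(out)


@dataclass
class AnovaResult:
    """One-way ANOVA with Tukey-HSD compact letter display.

    Groups that share no letter differ significantly at the chosen alpha.
    """

    f_statistic: float
    p_value: float
    letters: dict[str, str]
    alpha: float
    tukey: pd.DataFrame


def _compact_letters(
    groups: Sequence[str],
    means: Mapping[str, float],
    not_different: set[tuple[str, str]],
) -> dict[str, str]:
    """Letters from maximal cliques of the 'not significantly different' graph."""
    g = nx.Graph()
    g.add_nodes_from(groups)
    g.add_edges_from(not_different)
    cliques = list(nx.find_cliques(g))
    # order letters by descending mean of the clique's best group, as in
    # standard CLD output (highest group gets 'a')
    cliques.sort(key=lambda c: -max(means[m] for m in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, list[str]] = {grp: [] for grp in groups}
    for letter, clique in zip(alphabet, cliques):
        for member in clique:
            letters[member].append(letter)
    return {grp: "".join(sorted(ls)) for grp, ls in letters.items()}


def treatment_anova(
    values: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> AnovaResult:
    """Classical one-way ANOVA across treatment groups with letter display.

    Parameters
    ----------
    values : mapping group label → replicate values (each group needs ≥2).
    alpha : significance level for both the omnibus test and the pairwise
        Tukey HSD comparisons behind the letters (default 0.05).
    """
    groups = list(values)
    if len(groups) < 2:
        raise ValueError("need >=2 groups")
    arrays = {g: np.asarray(values[g], dtype=float) for g in groups}
    for g, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    pooled = np.concatenate(list(arrays.values()))
    if np.ptp(pooled) == 0:
        raise ZeroVarianceError("all observations identical; F undefined")
    f_stat, p_val = stats.f_oneway(*arrays.values())

    labels = np.concatenate([[g] * arrays[g].size for g in groups])
    tuk = pairwise_tukeyhsd(pooled, labels, alpha=alpha)
    tukey_df = pd.DataFrame(
        tuk.summary().data[1:], columns=[str(c) for c in tuk.summary().data[0]]
    )
    not_diff = {
        (str(r["group1"]), str(r["group2"]))
        for _, r in tukey_df.iterrows()
        if not bool(r["reject"])
    }
    means = {g: float(arrays[g].mean()) for g in groups}
    letters = _compact_letters(groups, means, not_diff)
    return AnovaResult(float(f_stat), float(p_val), letters, alpha, tukey_df)
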