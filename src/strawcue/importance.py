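"""Random-forest permutation importance linking community indicators to CUE.

The regression forest is assembled from sklearn decision trees with an
explicit bootstrap loop, which exposes each tree's out-of-bag (OOB) sample —
needed for the classical %IncMSE measure: for each predictor, permute its
values among a tree's OOB samples, record the increase in that tree's OOB
MSE, average over trees, and express as a percentage of the forest's
baseline OOB MSE.  Significance follows the response-permutation scheme of
the rfPermute R package: refit the whole forest under ``n_null`` permutations
of the response and compare each observed importance with its null
distribution (upper tail, add-one correction).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeRegressor

from strawcue.errors import AlignmentError, StrawCueWarning

__all__ = ["build_feature_table", "rf_importance", "correlate_indicators"]


def build_feature_table(
    cue: pd.Series,
    fb: pd.Series,
    cbhi_gh48: pd.Series,
    phylum_abundance: pd.DataFrame,
    module_abundance: pd.DataFrame,
    richness_bacterial: pd.Series,
    richness_fungal: pd.Series,
) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble the predictors × samples table and the aligned response.

    All inputs are indexed by sample id: ``cue`` is the response (per-sample
    straw-C use efficiency), ``fb`` and ``cbhi_gh48`` the community ratios,
    ``phylum_abundance`` per-sample relative abundances of phyla,
    ``module_abundance`` per-sample summed relative abundance of the top
    network modules, and the two richness series observed-ASV counts.
    Samples present in every input are kept; disjoint indices raise.
    """
    pieces: dict[str, pd.Series | pd.DataFrame] = {
        "FB_ratio": fb,
        "cbhI_GH48": cbhi_gh48,
        "richness_bacterial": richness_bacterial,
        "richness_fungal": richness_fungal,
    }
    x = pd.concat(
        [phylum_abundance, module_abundance]
        + [s.rename(name) for name, s in pieces.items()],
        axis=1,
        join="inner",
    )
    common = x.index.intersection(cue.index)
    if len(common) == 0:
        raise AlignmentError("no common sample ids between predictors and response")
    x = x.loc[common]
    if x.isna().any().any():
        raise AlignmentError("predictor table has missing values after alignment")
    return x, cue.loc[common].astype(float)


def _fit_forest(
    x: np.ndarray,
    y: np.ndarray,
    n_trees: int,
    mtry: int,
    rng: np.random.Generator,
    min_oob: int = 1,
):
    """Bootstrap-aggregated regression trees with per-tree OOB index sets."""
    n = x.shape[0]
    x = np.ascontiguousarray(x, dtype=np.float32)
    forest = []
    while len(forest) < n_trees:
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        if oob.size < min_oob:
            continue
        tree = DecisionTreeRegressor(
            max_features=mtry, random_state=int(rng.integers(0, 2**31 - 1))
        )
        tree.fit(x[boot], y[boot], check_input=False)
        forest.append((tree, oob))
    return forest


def _oob_importance(
    forest, x: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """%IncMSE per feature: mean per-tree OOB MSE increase under permutation,
    as a percentage of the forest's baseline OOB MSE."""
    n, p = x.shape
    x = np.ascontiguousarray(x, dtype=np.float32)
    inc = np.zeros(p)
    base_sq = 0.0
    n_oob_total = 0
    for tree, oob in forest:
        m = oob.size
        xo = x[oob]
        # one stacked predict per tree: [baseline; feature-1 permuted; ...]
        stack = np.tile(xo, (p + 1, 1))
        for j in range(p):
            perm = rng.permutation(m)
            stack[(j + 1) * m:(j + 2) * m, j] = xo[perm, j]
        pred = tree.predict(stack, check_input=False).reshape(p + 1, m)
        err = pred - y[oob][None, :]
        sq = (err * err).sum(axis=1)
        mse = sq / m
        base_sq += float(sq[0])
        n_oob_total += m
        inc += mse[1:] - mse[0]
    inc /= len(forest)
    baseline = base_sq / n_oob_total
    return 100.0 * inc / baseline


def rf_importance(
    features: pd.DataFrame,
    response: pd.Series,
    n_trees: int = 500,
    mtry: int | None = None,
    n_null: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """%IncMSE importance of each predictor with permutation p-values.

    Parameters
    ----------
    features, response : aligned predictors × samples table and response.
    n_trees : trees per forest (≥100; regression default 500).
    mtry : predictors tried per split; default ⌈p/3⌉ (regression convention).
    n_null : response permutations for the null distribution (rfPermute
        scheme: each permutation refits the entire forest).
    seed : seeds bootstrap draws, permutations and tree randomness.

    Returns a frame (predictor, pct_inc_mse, p_value) sorted by importance,
    with ``n_trees``/``n_null``/``seed`` in ``DataFrame.attrs``.
    """
    if n_trees < 100:
        raise ValueError("n_trees must be >= 100")
    if features.shape[0] < 8:
        raise ValueError("need >=8 observations")
    y = response.loc[features.index].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant response; importance undefined")
    zero_cols = features.columns[(features == 0).all(axis=0)]
    if len(zero_cols):
        warnings.warn(
            f"excluding all-zero predictor column(s): {list(zero_cols)}",
            StrawCueWarning,
            stacklevel=2,
        )
        features = features.drop(columns=zero_cols)
    x = features.to_numpy(dtype=float)
    p = x.shape[1]
    if mtry is None:
        mtry = max(1, int(np.ceil(p / 3)))
    rng = np.random.default_rng(seed)

    forest = _fit_forest(x, y, n_trees, mtry, rng)
    observed = _oob_importance(forest, x, y, rng)

    null = np.empty((n_null, p))
    for b in range(n_null):
        y_perm = y[rng.permutation(y.size)]
        forest_b = _fit_forest(x, y_perm, n_trees, mtry, rng)
        null[b] = _oob_importance(forest_b, x, y_perm, rng)
    p_values = (1.0 + (null >= observed[None, :]).sum(axis=0)) / (n_null + 1.0)

    out = pd.DataFrame(
        {
            "predictor": features.columns,
            "pct_inc_mse": observed,
            "p_value": p_values,
        }
    ).sort_values("pct_inc_mse", ascending=False, ignore_index=True)
    out.attrs.update({"n_trees": n_trees, "n_null": n_null, "seed": seed, "mtry": mtry})
    return out


def correlate_indicators(
    indicators: pd.DataFrame, values: pd.Series, method: str = "pearson"
) -> pd.DataFrame:
    """Correlation (r, p) of each community indicator against a metric.

    Default Pearson, matching the regression panels such indicators are
    usually shown in; Spearman available.  Requires ≥4 paired observations
    per indicator.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    rows = []
    for col in indicators.columns:
        pair = pd.concat([indicators[col], values], axis=1, join="inner").dropna()
        if pair.shape[0] < 4:
            raise ValueError(
                f"indicator {col!r}: need >=4 paired observations, got {pair.shape[0]}"
            )
        r, p = corr(pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy())
        rows.append({"indicator": col, "r": float(r), "p_value": float(p)})
    return pd.DataFrame(rows)
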