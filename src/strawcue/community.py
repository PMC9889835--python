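"""Community-level descriptors: abundances, richness, F:B, ordination, PERMANOVA.

These are the standard amplicon summaries linking amendment type to microbial
community structure.  Counts live in an :class:`AsvTable` (samples × ASVs with
taxonomy and per-sample metadata); distances are Bray–Curtis on relative
abundances; ordination is classical metric scaling (PCoA); group separation is
quantified by distance-based PERMANOVA reporting pseudo-F, R² and a
permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from strawcue.errors import AlignmentError

__all__ = [
    "AsvTable",
    "OrdinationResult",
    "relative_abundance",
    "richness",
    "fb_ratio",
    "bray_curtis",
    "pcoa_ordination",
    "permanova",
]


@dataclass
class AsvTable:
    """ASV count table with taxonomy and sample metadata.

    Attributes
    ----------
    counts : DataFrame, samples (rows) × ASVs (columns), non-negative integers.
    taxonomy : DataFrame indexed by ASV id; must contain a ``phylum`` column.
    domain_label : ``"bacterial"`` or ``"fungal"``.
    sample_metadata : DataFrame indexed by sample id with columns
        ``treatment``, ``timepoint_days``, ``replicate``.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    domain_label: str
    sample_metadata: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.domain_label not in ("bacterial", "fungal"):
            raise ValueError("domain_label must be 'bacterial' or 'fungal'")
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample or ASV names")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integral")
        missing_tax = self.counts.columns.difference(self.taxonomy.index)
        if len(missing_tax):
            raise ValueError(f"ASVs without taxonomy: {list(missing_tax)[:5]}")
        if self.sample_metadata is not None:
            missing_meta = self.counts.index.difference(self.sample_metadata.index)
            if len(missing_meta):
                raise AlignmentError(
                    f"samples without metadata: {list(missing_meta)[:5]}"
                )

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_asvs(self) -> int:
        return self.counts.shape[1]

    def subset_asvs(self, asv_ids) -> "AsvTable":
        """New table restricted to the given ASVs, order preserved."""
        keep = [a for a in self.counts.columns if a in set(asv_ids)]
        return AsvTable(
            counts=self.counts[keep].copy(),
            taxonomy=self.taxonomy.loc[keep].copy(),
            domain_label=self.domain_label,
            sample_metadata=self.sample_metadata,
        )

    def to_tsv(self, counts_path, taxonomy_path=None, metadata_path=None) -> None:
        """Write counts (ASVs as rows, samples as columns) and sidecars as TSV."""
        self.counts.T.rename_axis("asv_id").to_csv(counts_path, sep="\t")
        if taxonomy_path is not None:
            self.taxonomy.rename_axis("asv_id").to_csv(taxonomy_path, sep="\t")
        if metadata_path is not None and self.sample_metadata is not None:
            self.sample_metadata.rename_axis("sample_id").to_csv(
                metadata_path, sep="\t"
            )

    @classmethod
    def from_tsv(
        cls, counts_path, taxonomy_path, domain_label, metadata_path=None
    ) -> "AsvTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0).T
        taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col=0)
        meta = (
            pd.read_csv(metadata_path, sep="\t", index_col=0)
            if metadata_path is not None
            else None
        )
        return cls(counts, taxonomy, domain_label, meta)


@dataclass
class OrdinationResult:
    """PCoA coordinates plus PERMANOVA summary of group separation."""

    coordinates: pd.DataFrame
    explained: np.ndarray
    permanova_r2: float | None = None
    permanova_p: float | None = None
    n_permutations: int | None = None


def relative_abundance(table: AsvTable | pd.DataFrame) -> pd.DataFrame:
    """Per-sample relative abundances (each row sums to 1)."""
    counts = table.counts if isinstance(table, AsvTable) else table
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])[:5]
        raise ValueError(f"samples with zero total count: {bad}")
    return counts.div(totals, axis=0)


def richness(
    table: AsvTable | pd.DataFrame,
    rarefy_depth: int | None = None,
    seed: int | None = None,
) -> pd.Series:
    """Observed-ASV count per sample, optionally after seeded rarefaction.

    Rarefaction draws ``rarefy_depth`` reads per sample without replacement
    (multivariate hypergeometric); richness is the number of ASVs remaining
    with count > 0.  Without rarefaction, simply the number of non-zero ASVs.
    """
    counts = table.counts if isinstance(table, AsvTable) else table
    if rarefy_depth is None:
        return (counts > 0).sum(axis=1).rename("richness")
    totals = counts.sum(axis=1)
    if (rarefy_depth > totals).any():
        bad = list(totals.index[rarefy_depth > totals])[:5]
        raise ValueError(f"rarefy_depth {rarefy_depth} exceeds sample totals: {bad}")
    rng = np.random.default_rng(seed)
    out = {}
    for sample, row in counts.iterrows():
        sub = rng.multivariate_hypergeometric(
            row.to_numpy(dtype=np.int64), rarefy_depth
        )
        out[sample] = int(np.count_nonzero(sub))
    return pd.Series(out, name="richness")


def fb_ratio(fungal_abundance, bacterial_abundance):
    """Fungal-to-bacterial ratio (F:B).

    Applied identically to qPCR gene copies (ITS/16S) and to the
    cellulolytic-gene pair (cbhI/GH48).
    """
    fungal = np.asarray(fungal_abundance, dtype=float)
    bacterial = np.asarray(bacterial_abundance, dtype=float)
    if np.any(bacterial <= 0):
        raise ZeroDivisionError("bacterial abundance must be > 0")
    r = fungal / bacterial
    return r if r.ndim else float(r)


def bray_curtis(proportions: pd.DataFrame) -> pd.DataFrame:
    """Bray–Curtis distance matrix on relative abundances.

    BC(i, j) = 1 − 2·Σ min(p_i, p_j); symmetric, zero diagonal, in [0, 1].
    """
    if proportions.shape[0] < 2:
        raise ValueError("need >=2 samples for a distance matrix")
    d = squareform(pdist(proportions.to_numpy(dtype=float), metric="braycurtis"))
    return pd.DataFrame(d, index=proportions.index, columns=proportions.index)


def pcoa_ordination(distances: pd.DataFrame, n_axes: int | None = None) -> OrdinationResult:
    """Principal coordinate analysis (classical metric scaling).

    The squared distance matrix is double-centered (Gower), eigendecomposed,
    and coordinates are formed from the non-negative eigenvalues only;
    explained fractions are eigenvalues over the sum of positive eigenvalues
    (Bray–Curtis matrices are generally not Euclidean-embeddable, so small
    negative eigenvalues are expected and dropped).
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if n < 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distances must be a square matrix with >=2 samples")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    # Gower double-centering of -0.5 * D^2
    a = -0.5 * d**2
    centerer = np.eye(n) - np.ones((n, n)) / n
    b = centerer @ a @ centerer
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-10 * max(eigvals.max(), 1.0)
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    explained = eigvals[pos] / eigvals[pos].sum() if pos.any() else np.array([])
    if n_axes is not None:
        coords = coords[:, :n_axes]
        explained = explained[:n_axes]
    index = distances.index if isinstance(distances, pd.DataFrame) else range(n)
    coord_df = pd.DataFrame(
        coords, index=index, columns=[f"PCo{i + 1}" for i in range(coords.shape[1])]
    )
    return OrdinationResult(coord_df, explained)


def _permanova_ss(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(SS_within, SS_total) from squared distances and group labels."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    return ss_within, ss_total


def permanova(
    distances: pd.DataFrame,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
) -> dict:
    """Distance-based PERMANOVA: pseudo-F, R² and a permutation p-value.

    R² = SS_between / SS_total measures how much of the total distance
    variance the grouping explains; the p-value comes from ``n_permutations``
    seeded label shuffles (add-one correction).
    """
    d = np.asarray(distances, dtype=float)
    labels = np.asarray(groups)
    if labels.size != d.shape[0]:
        raise AlignmentError("group labels must match distance matrix size")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2 or (counts < 2).any():
        raise ValueError("need >=2 groups each with >=2 samples")
    n = d.shape[0]
    a = uniq.size
    d2 = d**2
    ss_w, ss_t = _permanova_ss(d2, labels)
    ss_b = ss_t - ss_w
    # ss_w can be exactly 0 (perfect separation): F is then +inf, and only
    # permutations reproducing the same partition tie with it
    with np.errstate(divide="ignore"):
        f_obs = (ss_b / (a - 1)) / (ss_w / (n - a))
    r2 = ss_b / ss_t
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        ss_w_p, _ = _permanova_ss(d2, perm)
        ss_b_p = ss_t - ss_w_p
        with np.errstate(divide="ignore"):
            f_p = (ss_b_p / (a - 1)) / (ss_w_p / (n - a))
        if f_p >= f_obs:
            exceed += 1
    p = (exceed + 1) / (n_permutations + 1)
    return {"pseudo_f": float(f_obs), "r2": float(r2), "p_value": float(p),
            "n_permutations": n_permutations}
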