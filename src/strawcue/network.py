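"""Cross-domain bacteria–fungi co-occurrence network.

Construction follows the dominant-phylotype convention: keep ASVs that are
both abundant (mean relative abundance above 0.1%) and ubiquitous (present
in more than half of all samples), normalize each domain to relative
abundances separately (so sequencing-depth differences between the 16S and
ITS assays cannot induce spurious cross-domain correlations), then connect
pairs whose correlation is strong (|r| > 0.6) and significant after
Benjamini–Hochberg adjustment of all pairwise p-values (adjusted p < 0.01).
Modules are communities maximizing modularity on the unsigned graph, ranked
by node count; the "top" modules are the largest ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from strawcue.community import AsvTable, relative_abundance
from strawcue.errors import ConstantTaxonWarning, StrawCueWarning

__all__ = [
    "CoNetwork",
    "filter_dominant",
    "combine_domain_tables",
    "correlation_edges",
    "detect_modules",
    "build_network",
    "module_sample_abundance",
    "module_stats",
    "sample_subnetwork",
]


@dataclass
class CoNetwork:
    """Co-occurrence network with module assignment.

    ``graph`` carries node attributes ``domain`` and ``phylum`` and edge
    attributes ``r``, ``p_raw``, ``p_adj`` and ``sign``; ``modules`` maps
    every node to a module id (1-based, 1 = largest non-singleton module);
    ``module_rank`` maps module id → rank among non-singleton modules.
    ``edges`` is the retained edge list as a tidy frame (i < j by node name).
    """

    graph: nx.Graph
    modules: dict[str, int]
    module_rank: dict[int, int]
    edges: pd.DataFrame

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def top_modules(self, k: int = 3) -> list[int]:
        """Module ids of the k largest (by node count) non-singleton modules."""
        ranked = sorted(self.module_rank, key=self.module_rank.get)
        if k > len(ranked):
            warnings.warn(
                f"requested top {k} modules but only {len(ranked)} exist",
                StrawCueWarning,
                stacklevel=2,
            )
        return ranked[:k]

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def filter_dominant(
    table: AsvTable,
    abund_threshold: float = 0.001,
    prevalence_fraction: float = 0.5,
) -> AsvTable:
    """Keep dominant phylotypes: abundant AND ubiquitous.

    An ASV passes if its mean relative abundance across all samples is
    strictly above ``abund_threshold`` (default 0.1%) and it is present
    (count > 0) in strictly more than ``prevalence_fraction`` of samples
    (default half).  Column order is preserved.
    """
    for name, thr in (("abund_threshold", abund_threshold),
                      ("prevalence_fraction", prevalence_fraction)):
        if not 0 <= thr <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {thr}")
    if table.n_asvs == 0:
        return table
    props = relative_abundance(table)
    mean_abund = props.mean(axis=0)
    prevalence = (table.counts > 0).mean(axis=0)
    keep = table.counts.columns[
        (mean_abund > abund_threshold) & (prevalence > prevalence_fraction)
    ]
    return table.subset_asvs(keep)


def combine_domain_tables(bacterial: AsvTable, fungal: AsvTable) -> pd.DataFrame:
    """Concatenate per-domain relative abundances into one samples × ASVs frame.

    Each domain is normalized within itself first, so the (arbitrary) depth
    difference between the two assays does not couple the domains.
    """
    if not bacterial.counts.index.equals(fungal.counts.index):
        raise ValueError("bacterial and fungal tables must share the same samples")
    return pd.concat(
        [relative_abundance(bacterial), relative_abundance(fungal)], axis=1
    )


def correlation_edges(
    proportions: pd.DataFrame,
    method: str = "spearman",
    r_threshold: float = 0.6,
    p_threshold: float = 0.01,
) -> pd.DataFrame:
    """All pairwise correlations with BH adjustment and the retention flag.

    BH is applied across the full family of pairwise tests before
    thresholding; an edge is retained iff |r| > r_threshold (strict) and
    adjusted p < p_threshold (strict).  Constant-abundance ASVs have no
    defined correlation and are excluded with a warning.

    Returns a tidy frame with columns i, j, r, p_raw, p_adj, sign, retained
    (i < j in column order of the input).
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    n_samples = proportions.shape[0]
    if n_samples < 4:
        raise ValueError("need >=4 samples for correlation edges")
    variances = proportions.var(axis=0)
    constant = variances[variances == 0].index
    if len(constant):
        warnings.warn(
            f"excluding {len(constant)} constant-abundance ASV(s) from correlation",
            ConstantTaxonWarning,
            stacklevel=2,
        )
        proportions = proportions.drop(columns=constant)
    cols = list(proportions.columns)
    x = proportions.to_numpy(dtype=float)
    if method == "spearman":
        res = stats.spearmanr(x)
        r_mat, p_mat = res.statistic, res.pvalue
        if np.ndim(r_mat) == 0:  # scipy collapses the 2-column case to scalars
            r_mat = np.array([[1.0, float(r_mat)], [float(r_mat), 1.0]])
            p_mat = np.array([[0.0, float(p_mat)], [float(p_mat), 0.0]])
    else:
        r_mat = np.corrcoef(x, rowvar=False)
        # t-test p-values for Pearson r
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r_mat * np.sqrt((n_samples - 2) / (1 - r_mat**2))
        p_mat = 2 * stats.t.sf(np.abs(t), df=n_samples - 2)
    iu, ju = np.triu_indices(len(cols), k=1)
    r = r_mat[iu, ju]
    p_raw = p_mat[iu, ju]
    p_adj = multipletests(p_raw, method="fdr_bh")[1]
    retained = (np.abs(r) > r_threshold) & (p_adj < p_threshold)
    return pd.DataFrame(
        {
            "i": np.array(cols, dtype=object)[iu],
            "j": np.array(cols, dtype=object)[ju],
            "r": r,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "sign": np.where(r >= 0, 1, -1),
            "retained": retained,
        }
    )


def detect_modules(
    graph: nx.Graph, algorithm: str = "greedy", seed: int | None = None
) -> tuple[dict[str, int], dict[int, int]]:
    """Modularity-based module assignment plus size ranking.

    ``greedy`` (default) is deterministic agglomerative modularity
    maximization; ``louvain`` uses the seeded Louvain heuristic.  Modules are
    detected on the unsigned (unweighted) graph.  Isolated nodes become
    singleton modules that are excluded from the ranking; among non-singleton
    modules, rank 1 is the largest, ties broken by smallest member node id.
    Returned module ids are renumbered so id == rank for ranked modules, with
    singletons numbered afterwards.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    connected = [n for n in graph.nodes if graph.degree(n) > 0]
    sub = graph.subgraph(connected)
    if sub.number_of_edges() == 0:
        communities: list[set] = []
    elif algorithm == "greedy":
        communities = [set(c) for c in nx.community.greedy_modularity_communities(sub)]
    elif algorithm == "louvain":
        communities = [set(c) for c in nx.community.louvain_communities(sub, seed=seed)]
    else:
        raise ValueError("algorithm must be 'greedy' or 'louvain'")
    # rank: size desc, ties by smallest node id
    communities.sort(key=lambda c: (-len(c), min(c)))
    modules: dict[str, int] = {}
    module_rank: dict[int, int] = {}
    for rank, comm in enumerate(communities, start=1):
        module_rank[rank] = rank
        for node in sorted(comm):
            modules[node] = rank
    next_id = len(communities) + 1
    for node in sorted(graph.nodes):
        if node not in modules:  # isolated → singleton, unranked
            modules[node] = next_id
            next_id += 1
    return modules, module_rank


def build_network(
    bacterial: AsvTable,
    fungal: AsvTable,
    method: str = "spearman",
    r_threshold: float = 0.6,
    p_threshold: float = 0.01,
    abund_threshold: float = 0.001,
    prevalence_fraction: float = 0.5,
    module_algorithm: str = "greedy",
    seed: int | None = None,
    treatments: list[str] | None = None,
) -> CoNetwork:
    """Full network construction: filter → combine → correlate → modules.

    By default the network pools all samples; pass ``treatments`` to restrict
    to a subset of treatment groups.
    """
    if treatments is not None:
        keep_b = bacterial.sample_metadata["treatment"].isin(treatments)
        bacterial = AsvTable(
            bacterial.counts.loc[keep_b],
            bacterial.taxonomy,
            "bacterial",
            bacterial.sample_metadata.loc[keep_b],
        )
        fungal = AsvTable(
            fungal.counts.loc[keep_b.index[keep_b]],
            fungal.taxonomy,
            "fungal",
            fungal.sample_metadata.loc[keep_b.index[keep_b]],
        )
    bact_dom = filter_dominant(bacterial, abund_threshold, prevalence_fraction)
    fung_dom = filter_dominant(fungal, abund_threshold, prevalence_fraction)
    combined = combine_domain_tables(bact_dom, fung_dom)
    edges = correlation_edges(combined, method, r_threshold, p_threshold)
    retained = edges[edges["retained"]]

    graph = nx.Graph()
    for table in (bact_dom, fung_dom):
        for asv in table.counts.columns:
            graph.add_node(
                asv,
                domain=table.domain_label,
                phylum=str(table.taxonomy.loc[asv, "phylum"]),
            )
    for _, e in retained.iterrows():
        graph.add_edge(
            e["i"], e["j"],
            r=float(e["r"]), p_raw=float(e["p_raw"]),
            p_adj=float(e["p_adj"]), sign=int(e["sign"]),
        )
    modules, module_rank = detect_modules(graph, module_algorithm, seed)
    nx.set_node_attributes(graph, modules, "module")
    return CoNetwork(graph, modules, module_rank,
                     retained.drop(columns="retained").reset_index(drop=True))


def module_stats(
    network: CoNetwork,
    bacterial: AsvTable,
    fungal: AsvTable,
    top_k: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts and per-treatment abundances of the top-k modules by domain.

    Returns ``(counts, abundances)``: counts has one row per module with the
    number of bacterial and fungal member ASVs (treatment-independent);
    abundances has one row per module × treatment × domain with the mean and
    SD (across that treatment's samples) of the summed relative abundance of
    member ASVs.
    """
    top = network.top_modules(top_k)
    domains = nx.get_node_attributes(network.graph, "domain")
    props = {
        "bacterial": relative_abundance(bacterial),
        "fungal": relative_abundance(fungal),
    }
    meta = bacterial.sample_metadata
    count_rows, abund_rows = [], []
    for mod in top:
        members = [n for n, m in network.modules.items() if m == mod]
        by_domain = {
            d: [n for n in members if domains[n] == d] for d in ("bacterial", "fungal")
        }
        count_rows.append(
            {
                "module": mod,
                "n_bacterial": len(by_domain["bacterial"]),
                "n_fungal": len(by_domain["fungal"]),
            }
        )
        for domain in ("bacterial", "fungal"):
            cols = by_domain[domain]
            summed = (
                props[domain][cols].sum(axis=1)
                if cols
                else pd.Series(0.0, index=props[domain].index)
            )
            for trt, idx in meta.groupby("treatment", sort=False).groups.items():
                vals = summed.loc[idx]
                abund_rows.append(
                    {
                        "module": mod,
                        "treatment": trt,
                        "domain": domain,
                        "mean_rel_abundance": float(vals.mean()),
                        "sd_rel_abundance": float(vals.std(ddof=1))
                        if len(vals) > 1
                        else 0.0,
                    }
                )
    return pd.DataFrame(count_rows), pd.DataFrame(abund_rows)


def module_sample_abundance(
    network: CoNetwork,
    bacterial: AsvTable,
    fungal: AsvTable,
    top_k: int = 3,
) -> pd.DataFrame:
    """Per-sample summed relative abundance of each top-k module's members.

    Member proportions are within-domain relative abundances (bacterial and
    fungal contributions added); columns are named ``module_1`` ... in rank
    order.  This is the per-sample counterpart of :func:`module_stats`,
    suitable as predictor columns.
    """
    top = network.top_modules(top_k)
    domains = nx.get_node_attributes(network.graph, "domain")
    props = {
        "bacterial": relative_abundance(bacterial),
        "fungal": relative_abundance(fungal),
    }
    out = {}
    for mod in top:
        members = [n for n, m in network.modules.items() if m == mod]
        total = pd.Series(0.0, index=bacterial.counts.index)
        for domain in ("bacterial", "fungal"):
            cols = [n for n in members if domains[n] == domain]
            if cols:
                total = total + props[domain][cols].sum(axis=1)
        out[f"module_{mod}"] = total
    return pd.DataFrame(out)


def sample_subnetwork(
    network: CoNetwork, sample: str, bacterial: AsvTable, fungal: AsvTable
) -> tuple[nx.Graph, dict]:
    """Induced subgraph on the phylotypes present in one soil sample.

    A node is preserved if its count in the sample is > 0 in its domain's
    table; metrics (nodes, edges, mean degree) are computed on the induced
    subgraph.
    """
    present: set[str] = set()
    for table in (bacterial, fungal):
        if sample not in table.counts.index:
            raise KeyError(f"sample {sample!r} not in {table.domain_label} table")
        row = table.counts.loc[sample]
        present |= set(row.index[row > 0])
    nodes = [n for n in network.graph.nodes if n in present]
    sub = network.graph.subgraph(nodes).copy()
    n = sub.number_of_nodes()
    metrics = {
        "sample": sample,
        "nodes": n,
        "edges": sub.number_of_edges(),
        "mean_degree": (2 * sub.number_of_edges() / n) if n else 0.0,
    }
    return sub, metrics
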