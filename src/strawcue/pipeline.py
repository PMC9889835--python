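"""One-config orchestration of the full analysis chain.

A run is described by a :class:`RunConfig` (YAML-loadable): either a
``synthetic`` block (virtual experiment parameters) or an ``inputs`` block
(paths to measurement tables), stage toggles, per-stage parameters and one
global seed.  Stages execute in dependency order

    data (synthetic or ingest) → isotope → community → network
        → importance → composition

and every output file lands in the output directory and is listed in a
manifest with its SHA-256 hash, so two runs with the same config + seed can
be compared byte-for-byte.  The global seed is split into per-stage child
seeds through a fixed derivation (``SeedSequence([seed, stage_id])``), so
toggling one stage never shifts another stage's randomness.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import strawcue
from strawcue import community as comm
from strawcue import composition as compo
from strawcue import importance as imp
from strawcue import isotope as iso
from strawcue import network as net
from strawcue import synthetic as syn
from strawcue.errors import ConfigError, DependencyError

__all__ = ["RunConfig", "run_pipeline"]

_STAGE_IDS = {
    "data": 1,
    "isotope": 2,
    "community": 3,
    "network": 4,
    "importance": 5,
    "composition": 6,
}
_ALL_STAGES = ("isotope", "community", "network", "importance", "composition")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic child seed for a stage (always < 2^31)."""
    ss = np.random.SeedSequence([seed, _STAGE_IDS[stage]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % 2**31)


@dataclass
class RunConfig:
    """Validated run configuration.

    Exactly one of ``synthetic`` (generator parameters) and ``inputs``
    (file paths) must be given.  ``params`` holds per-stage parameter blocks;
    unknown stage names or parameters raise at construction.
    """

    seed: int = 0
    output_dir: str = "strawcue_out"
    synthetic: dict | None = None
    inputs: dict | None = None
    stages: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ConfigError(
                "config must contain exactly one input source: "
                "'synthetic' or 'inputs'"
            )
        unknown = set(self.stages) - set(_ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stage toggles: {sorted(unknown)}")
        self.stages = {s: bool(self.stages.get(s, True)) for s in _ALL_STAGES}
        known_params = {"isotope", "community", "network", "importance", "composition"}
        unknown_p = set(self.params) - known_params
        if unknown_p:
            raise ConfigError(f"unknown parameter blocks: {sorted(unknown_p)}")
        if self.inputs is not None:
            required = {
                "isotope_samples",
                "bacterial_counts", "bacterial_taxonomy",
                "fungal_counts", "fungal_taxonomy", "sample_metadata",
                "gene_abundances",
            }
            missing = required - set(self.inputs)
            if missing:
                raise ConfigError(f"inputs block missing paths: {sorted(missing)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def check_dependencies(self) -> None:
        s = self.stages
        if s["importance"] and not (s["isotope"] and s["community"] and s["network"]):
            missing = [
                name for name in ("isotope", "community", "network") if not s[name]
            ]
            raise DependencyError("importance", missing[0])
        if s["composition"] and not s["isotope"]:
            raise DependencyError("composition", "isotope")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, outputs: dict, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index)
    outputs[path.name] = _sha256(path)


def _phylum_abundance(table: comm.AsvTable, prefix: str) -> pd.DataFrame:
    props = comm.relative_abundance(table)
    by_phylum = props.T.groupby(table.taxonomy["phylum"]).sum().T
    return by_phylum.rename(columns=lambda p: f"{prefix}:{p}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all enabled stages and return the run manifest.

    The manifest records the package version, the global and per-stage seeds,
    every output file with its SHA-256 content hash, and any warnings raised
    during the run.  Deterministic stages reproduce identical hashes when
    re-run with the same config and seed.
    """
    config.check_dependencies()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    caught: list[str] = []
    manifest: dict = {
        "package_version": strawcue.__version__,
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGE_IDS},
        "stages_run": [s for s, on in config.stages.items() if on],
    }

    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")

        # ---- data: synthetic generation or file ingest -------------------
        if config.synthetic is not None:
            syn_cfg = dict(config.synthetic)
            design_cfg = dict(syn_cfg.get("design", {}))
            design_cfg.setdefault("seed", stage_seed(config.seed, "data"))
            design = syn.ExperimentDesign.from_dict(design_cfg)
            truth = syn.default_truth(
                design,
                noise_sd_delta=syn_cfg.get("noise_sd_delta", 1.0),
                noise_cv_pools=syn_cfg.get("noise_cv_pools", 0.05),
            )
            samples = syn.generate_isotope_samples(design, truth)
            bact, fungi = syn.generate_asv_tables(design, truth)
            genes = syn.generate_gene_abundances(design, truth)
            compositions = syn.generate_oa_composition(design)
            data_dir = out_dir / "data"
            data_dir.mkdir(exist_ok=True)
            _write_csv(samples, data_dir / "isotope_samples.csv", outputs)
            bact.to_tsv(
                data_dir / "bacterial_counts.tsv",
                data_dir / "bacterial_taxonomy.tsv",
                data_dir / "sample_metadata.tsv",
            )
            fungi.to_tsv(data_dir / "fungal_counts.tsv", data_dir / "fungal_taxonomy.tsv")
            for name in (
                "bacterial_counts.tsv", "bacterial_taxonomy.tsv",
                "sample_metadata.tsv", "fungal_counts.tsv", "fungal_taxonomy.tsv",
            ):
                outputs[name] = _sha256(data_dir / name)
            _write_csv(genes, data_dir / "gene_abundances.csv", outputs)
            comp_df = pd.DataFrame([c.to_series() for c in compositions])
            comp_df.index.name = "oa_label"
            _write_csv(comp_df, data_dir / "oa_composition.csv", outputs, index=True)
        else:
            paths = config.inputs
            samples = pd.read_csv(paths["isotope_samples"])
            bact = comm.AsvTable.from_tsv(
                paths["bacterial_counts"], paths["bacterial_taxonomy"],
                "bacterial", paths["sample_metadata"],
            )
            fungi = comm.AsvTable.from_tsv(
                paths["fungal_counts"], paths["fungal_taxonomy"],
                "fungal", paths["sample_metadata"],
            )
            genes = pd.read_csv(paths["gene_abundances"])
            compositions = None
            if "oa_composition" in paths:
                comp_df = pd.read_csv(paths["oa_composition"], index_col=0)
                compositions = [
                    compo.OaComposition(
                        str(label),
                        {
                            g: float(row[f"group:{g}"])
                            for g in compo.CHEMICAL_GROUPS
                        },
                        {
                            c: float(row[f"class:{c}"])
                            for c in compo.SKELETON_CLASSES
                        },
                    )
                    for label, row in comp_df.iterrows()
                ]

        # ---- isotope partitioning ---------------------------------------
        cue_results = None
        cue_replicates = None
        if config.stages["isotope"]:
            p = config.params.get("isotope", {})
            cue_replicates = iso.partition_replicates(
                samples,
                kec=p.get("kec", iso.DEFAULT_KEC),
                clamp_negative_f=p.get("clamp_negative_f", False),
            )
            cue_results = iso.partition_experiment(
                samples,
                kec=p.get("kec", iso.DEFAULT_KEC),
                n_boot=p.get("n_boot", 1999),
                seed=stage_seed(config.seed, "isotope"),
                ci_method=p.get("ci_method", "t"),
                clamp_negative_f=p.get("clamp_negative_f", False),
            )
            _write_csv(cue_results, out_dir / "cue_results.csv", outputs)
            anova_rows = []
            for day, cell in cue_replicates.groupby("timepoint_days"):
                groups = {
                    trt: grp["cue"].to_numpy() for trt, grp in cell.groupby("treatment")
                }
                res = iso.treatment_anova(groups, alpha=p.get("alpha", 0.05))
                for trt, letter in res.letters.items():
                    anova_rows.append(
                        {
                            "timepoint_days": day,
                            "treatment": trt,
                            "mean_cue": float(np.mean(groups[trt])),
                            "letters": letter,
                            "anova_f": res.f_statistic,
                            "anova_p": res.p_value,
                        }
                    )
            _write_csv(pd.DataFrame(anova_rows), out_dir / "cue_anova.csv", outputs)

        # ---- community structure ----------------------------------------
        fb = None
        cbhi_gh48 = None
        rich = {}
        permanova_results = {}
        if config.stages["community"]:
            p = config.params.get("community", {})
            seed_c = stage_seed(config.seed, "community")
            genes_idx = genes.set_index("sample_id")
            fb = comm.fb_ratio(
                genes_idx["copies_its"], genes_idx["copies_16s"]
            )
            fb = pd.Series(fb, index=genes_idx.index, name="FB_ratio")
            cbhi_gh48 = pd.Series(
                comm.fb_ratio(genes_idx["copies_cbhi"], genes_idx["copies_gh48"]),
                index=genes_idx.index,
                name="cbhI_GH48",
            )
            perm_rows = []
            ord_frames = []
            for table in (bact, fungi):
                props = comm.relative_abundance(table)
                rich[table.domain_label] = comm.richness(table)
                dist = comm.bray_curtis(props)
                ordn = comm.pcoa_ordination(dist)
                res = comm.permanova(
                    dist,
                    table.sample_metadata.loc[dist.index, "treatment"],
                    n_permutations=p.get("n_permutations", 999),
                    seed=seed_c,
                )
                permanova_results[table.domain_label] = res
                perm_rows.append({"domain": table.domain_label, **res})
                coords = ordn.coordinates.iloc[:, :2].copy()
                coords.insert(0, "domain", table.domain_label)
                ord_frames.append(coords)
            _write_csv(pd.DataFrame(perm_rows), out_dir / "permanova.csv", outputs)
            _write_csv(
                pd.concat(ord_frames).rename_axis("sample_id"),
                out_dir / "ordination.csv",
                outputs,
                index=True,
            )
            gene_summary = genes_idx[["treatment", "timepoint_days"]].copy()
            gene_summary["FB_ratio"] = fb
            gene_summary["cbhI_GH48"] = cbhi_gh48
            _write_csv(
                gene_summary.rename_axis("sample_id"),
                out_dir / "community_ratios.csv",
                outputs,
                index=True,
            )

        # ---- co-occurrence network --------------------------------------
        conet = None
        if config.stages["network"]:
            p = config.params.get("network", {})
            conet = net.build_network(
                bact,
                fungi,
                method=p.get("method", "spearman"),
                r_threshold=p.get("r_threshold", 0.6),
                p_threshold=p.get("p_threshold", 0.01),
                abund_threshold=p.get("abund_threshold", 0.001),
                prevalence_fraction=p.get("prevalence_fraction", 0.5),
                module_algorithm=p.get("module_algo", "greedy"),
                seed=stage_seed(config.seed, "network"),
            )
            edge_path = out_dir / "network_edges.tsv"
            conet.edges.to_csv(edge_path, sep="\t", index=False)
            outputs[edge_path.name] = _sha256(edge_path)
            gml_path = out_dir / "network.graphml"
            conet.to_graphml(gml_path)
            outputs[gml_path.name] = _sha256(gml_path)
            module_df = pd.DataFrame(
                sorted(conet.modules.items()), columns=["asv_id", "module"]
            )
            _write_csv(module_df, out_dir / "modules.csv", outputs)
            counts_df, abund_df = net.module_stats(
                conet, bact, fungi, top_k=p.get("top_k", 3)
            )
            _write_csv(counts_df, out_dir / "module_counts.csv", outputs)
            _write_csv(abund_df, out_dir / "module_abundance.csv", outputs)

        # ---- predictor importance ---------------------------------------
        if config.stages["importance"]:
            p = config.params.get("importance", {})
            meta = bact.sample_metadata
            cell_cue = cue_replicates.groupby(["treatment", "timepoint_days"])[
                "cue"
            ].mean()
            cue_per_sample = pd.Series(
                [
                    cell_cue.loc[(row["treatment"], row["timepoint_days"])]
                    for _, row in meta.iterrows()
                ],
                index=meta.index,
                name="cue",
            )
            phyla = pd.concat(
                [_phylum_abundance(bact, "b"), _phylum_abundance(fungi, "f")], axis=1
            )
            module_abund = net.module_sample_abundance(
                conet, bact, fungi, top_k=p.get("top_k", 3)
            )
            features, response = imp.build_feature_table(
                cue_per_sample,
                fb,
                cbhi_gh48,
                phyla,
                module_abund,
                rich["bacterial"].rename("richness_bacterial"),
                rich["fungal"].rename("richness_fungal"),
            )
            imp_table = imp.rf_importance(
                features,
                response,
                n_trees=p.get("n_trees", 500),
                n_null=p.get("n_null", 100),
                seed=stage_seed(config.seed, "importance"),
            )
            _write_csv(imp_table, out_dir / "importance.csv", outputs)
            indicator_cols = ["FB_ratio", "cbhI_GH48"] + list(module_abund.columns)
            if "f:Ascomycota" in features.columns:
                indicator_cols.append("f:Ascomycota")
            corr_table = imp.correlate_indicators(
                features[indicator_cols], response,
                method=p.get("corr_method", "pearson"),
            )
            _write_csv(corr_table, out_dir / "indicator_correlations.csv", outputs)

        # ---- amendment composition correlations -------------------------
        if config.stages["composition"] and compositions:
            p = config.params.get("composition", {})
            class_by_oa = pd.DataFrame(
                {c.oa_label: c.class_proportions for c in compositions}
            ).T
            cell_cue = cue_replicates.groupby(["treatment", "timepoint_days"])[
                "cue"
            ].mean()
            rows = []
            for (trt, day), value in cell_cue.items():
                if trt in class_by_oa.index:
                    rows.append(
                        {"sample": f"{trt}_d{day}", "treatment": trt, "cue": value,
                         **class_by_oa.loc[trt].to_dict()}
                    )
            comp_samples = pd.DataFrame(rows).set_index("sample")
            corr = compo.composition_metric_correlation(
                comp_samples[list(compo.SKELETON_CLASSES)],
                comp_samples["cue"],
                method=p.get("method", "pearson"),
            )
            _write_csv(corr, out_dir / "composition_cue_correlation.csv", outputs)

        caught = sorted({f"{w.category.__name__}: {w.message}" for w in wrec})

    manifest["outputs"] = outputs
    manifest["warnings"] = caught
    if permanova_results:
        manifest["permanova"] = permanova_results
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
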