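"""End-to-end orchestration of the full analysis.

simulate/ingest -> copy-number normalization -> metagenome prediction ->
pathway collapse -> shared-function (Venn) accounting -> taxon attribution
-> organism-level traits -> three signature routes per gender stratum ->
co-occurrence networks per (group, gender) -> manifest.

Genders are always analyzed as separate strata.  Every produced artifact
is recorded in a manifest with its SHA-256 checksum, the stage parameters
and the seed, so identical configurations yield identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as iof
from .attribution import compute_contributions, summarize_attribution
from .cohort import CohortConfig, SyntheticBundle, generate_cohort
from .impute import (FunctionProfile, collapse_to_level, normalize_copy_number,
                     predict_metagenome, venn_functions)
from .network import (build_network, compute_metrics, hubs_to_frame,
                      pearson_matrix, permutation_pvalues, top_hubs)
from .signatures import (FilterConfig, css_normalize, difftests_to_frame,
                         filter_features, importance_rank, lefse,
                         signatures_to_frame, stamp_anova)
from .traits import aggregate_traits, group_trait_summary

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Defaults are the emulated study's printed analysis settings."""

    out_dir: str = "imputome_run"
    # input paths; all None -> simulate a default cohort
    otu_table: str | None = None
    taxonomy: str | None = None
    copy_numbers: str | None = None
    gene_content: str | None = None
    hierarchy: str | None = None
    traits: str | None = None
    metadata: str | None = None
    simulate: bool = True
    levels: tuple = ("L3", "L2")
    kw_alpha: float = 0.05
    lda_min: float = 2.0
    q_max: float = 0.05
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    n_trees: int = 200
    network_level: str = "L3"
    n_permutations: int = 10_000
    alpha_edge: float = 0.01
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "filter_config" in raw:
            raw["filter_config"] = FilterConfig(**raw["filter_config"])
        if "levels" in raw:
            raw["levels"] = tuple(raw["levels"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, out_dir: Path, cfg: RunConfig):
        self.out_dir = out_dir
        self.doc = {"seed": cfg.seed, "parameters": _cfg_dict(cfg),
                    "artifacts": {}, "stages": []}

    def add(self, name: str, path: Path) -> None:
        self.doc["artifacts"][name] = {
            "path": str(path.relative_to(self.out_dir)),
            "sha256": _sha256(path)}

    def stage_done(self, stage: str, **info) -> None:
        self.doc["stages"].append({"stage": stage, **info})

    def write(self) -> Path:
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps(self.doc, indent=2, sort_keys=True))
        return path


def _cfg_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["levels"] = list(cfg.levels)
    return d


def _write_profile(profile: FunctionProfile, path: Path) -> None:
    iof._write_matrix_tsv(profile.data, path, "sample_id")


def _load_inputs(cfg: RunConfig) -> SyntheticBundle:
    for name in ("otu_table", "taxonomy", "copy_numbers", "gene_content",
                 "hierarchy", "traits", "metadata"):
        p = getattr(cfg, name)
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"input {name!r} missing: {p}")
    metadata = iof.read_metadata(cfg.metadata)
    return SyntheticBundle(
        otu_table=iof.read_otu_table(cfg.otu_table, metadata=metadata),
        taxonomy=iof.read_lineages(cfg.taxonomy),
        copy_numbers=iof.read_copy_numbers(cfg.copy_numbers),
        gene_content=iof.read_gene_content(cfg.gene_content),
        hierarchy=iof.read_hierarchy(cfg.hierarchy),
        traits=iof.read_traits(cfg.traits),
        metadata=metadata,
        truth=pd.DataFrame(),
        config=None)


def write_bundle(bundle: SyntheticBundle, out_dir) -> dict[str, Path]:
    """Write every bundle component in its io format; returns name -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "otu_table": out / "otu_table.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "copy_numbers": out / "copy_numbers.tsv",
        "gene_content": out / "gene_content.tsv",
        "hierarchy": out / "hierarchy.tsv",
        "traits": out / "traits.tsv",
        "metadata": out / "metadata.tsv",
    }
    iof.write_otu_table(bundle.otu_table, paths["otu_table"])
    iof.write_lineages(bundle.taxonomy, paths["taxonomy"])
    iof.write_copy_numbers(bundle.copy_numbers, paths["copy_numbers"])
    iof.write_gene_content(bundle.gene_content, paths["gene_content"])
    iof.write_hierarchy(bundle.hierarchy, paths["hierarchy"])
    iof.write_traits(bundle.traits, paths["traits"])
    iof.write_metadata(bundle.metadata, paths["metadata"])
    if not bundle.truth.empty:
        paths["truth"] = out / "truth.tsv"
        bundle.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def run_all(cfg: RunConfig,
            cohort_config: CohortConfig | None = None) -> dict:
    """Run every stage; returns the manifest document.

    Any stage failure aborts with the stage named, after writing the
    partial manifest.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out, cfg)
    stage = "setup"
    try:
        # ---- simulate / ingest
        stage = "ingest"
        if cfg.simulate:
            bundle = generate_cohort(cohort_config, seed=cfg.seed)
            for name, path in write_bundle(bundle, out / "inputs").items():
                manifest.add(f"inputs/{name}", path)
        else:
            bundle = _load_inputs(cfg)
        meta = bundle.metadata
        manifest.stage_done(stage, n_samples=len(meta),
                            n_otus=bundle.otu_table.shape[1])

        # ---- imputation
        stage = "impute"
        norm = normalize_copy_number(bundle.otu_table, bundle.copy_numbers)
        gene_profile = predict_metagenome(norm, bundle.gene_content)
        profiles = {"gene": gene_profile}
        for level in ("L3", "L2", "L1"):
            profiles[level] = collapse_to_level(
                gene_profile, bundle.hierarchy, level)
        for level, prof in profiles.items():
            path = out / f"profile_{level}.tsv"
            _write_profile(prof, path)
            manifest.add(f"profile_{level}", path)
        manifest.stage_done(stage, n_functions=gene_profile.data.shape[1])

        # ---- shared-function accounting per gender
        stage = "venn"
        venn_doc = {}
        for gender in sorted(meta["gender"].unique()):
            sub = meta[meta["gender"] == gender]
            by_group = {
                g: gene_profile.data.loc[sub[sub["group"] == g].index]
                for g in sorted(sub["group"].unique())}
            regions = venn_functions(by_group)
            venn_doc[gender] = {
                "+".join(sorted(k)): v for k, v in regions.items()}
        path = out / "venn_functions.json"
        path.write_text(json.dumps(venn_doc, indent=2, sort_keys=True))
        manifest.add("venn_functions", path)
        manifest.stage_done(stage)

        # ---- attribution per gender
        stage = "attribution"
        for gender in sorted(meta["gender"].unique()):
            idx = meta[meta["gender"] == gender].index
            tensor = compute_contributions(
                norm.loc[idx], bundle.gene_content, bundle.taxonomy,
                bundle.hierarchy, rank="phylum")
            summary = summarize_attribution(tensor)
            path = out / f"attribution_phylum_{gender}.tsv"
            summary.to_frame().to_csv(path, sep="\t", index=False,
                                      float_format="%.6g")
            manifest.add(f"attribution_phylum_{gender}", path)
        manifest.stage_done(stage)

        # ---- traits
        stage = "traits"
        trait_profile = aggregate_traits(norm, bundle.traits)
        path = out / "trait_profile.tsv"
        iof._write_matrix_tsv(trait_profile, path, "sample_id")
        manifest.add("trait_profile", path)
        summary = group_trait_summary(trait_profile, meta)
        path = out / "trait_summary.tsv"
        summary.to_csv(path, sep="\t", index=False, float_format="%.6g")
        manifest.add("trait_summary", path)
        manifest.stage_done(stage)

        # ---- signatures per gender and level
        stage = "signatures"
        for gender in sorted(meta["gender"].unique()):
            idx = meta[meta["gender"] == gender].index
            groups = meta.loc[idx, "group"]
            for level in cfg.levels:
                prof = profiles[level].data.loc[idx]
                for mode in ("strict", "less-strict"):
                    recs = lefse(prof, groups, level=level,
                                 alpha=cfg.kw_alpha, lda_min=cfg.lda_min,
                                 mode=mode, seed=cfg.seed)
                    path = out / f"lefse_{mode}_{level}_{gender}.tsv"
                    signatures_to_frame(recs).to_csv(
                        path, sep="\t", index=False, float_format="%.6g")
                    manifest.add(f"lefse_{mode}_{level}_{gender}", path)
                    logger.info("lefse %s %s %s: %d signatures",
                                mode, level, gender, len(recs))
                results = stamp_anova(prof, groups, q_max=cfg.q_max)
                path = out / f"stamp_{level}_{gender}.tsv"
                difftests_to_frame(results).to_csv(
                    path, sep="\t", index=False, float_format="%.6g")
                manifest.add(f"stamp_{level}_{gender}", path)
                filtered = filter_features(prof, cfg.filter_config)
                logger.info("rf filter %s %s: %d -> %d features",
                            level, gender, prof.shape[1], filtered.shape[1])
                scaled = css_normalize(filtered,
                                       quantile=cfg.filter_config.css_quantile)
                imp = importance_rank(scaled, groups, n_trees=cfg.n_trees,
                                      seed=cfg.seed)
                path = out / f"rf_importance_{level}_{gender}.tsv"
                imp.ranking.to_csv(path, sep="\t", index=False,
                                   float_format="%.6g")
                manifest.add(f"rf_importance_{level}_{gender}", path)
        manifest.stage_done(stage)

        # ---- networks per (gender, group)
        stage = "network"
        net_rows = []
        for gender in sorted(meta["gender"].unique()):
            for group in sorted(meta[meta["gender"] == gender]["group"].unique()):
                idx = meta[(meta["gender"] == gender)
                           & (meta["group"] == group)].index
                prof = profiles[cfg.network_level].data.loc[idx]
                r = pearson_matrix(prof)
                p = permutation_pvalues(prof, B=cfg.n_permutations,
                                        seed=cfg.seed)
                net = build_network(r, p, alpha_edge=cfg.alpha_edge,
                                    group=group, gender=gender,
                                    n_permutations=cfg.n_permutations)
                metrics = compute_metrics(net)
                net_rows.append({"gender": gender, "group": group,
                                 **metrics.to_series().to_dict()})
                epath = out / f"network_{gender}_{group}_edges.tsv"
                iof.write_network_edgelist(net.graph, epath)
                manifest.add(f"network_{gender}_{group}_edges", epath)
                gpath = out / f"network_{gender}_{group}.graphml"
                iof.write_network_graphml(net.graph, gpath)
                manifest.add(f"network_{gender}_{group}_graphml", gpath)
                hpath = out / f"network_{gender}_{group}_hubs.tsv"
                hubs_to_frame(top_hubs(net)).to_csv(hpath, sep="\t",
                                                    index=False)
                manifest.add(f"network_{gender}_{group}_hubs", hpath)
        path = out / "network_metrics.tsv"
        pd.DataFrame(net_rows).to_csv(path, sep="\t", index=False,
                                      float_format="%.6g")
        manifest.add("network_metrics", path)
        manifest.stage_done(stage)
    except Exception as exc:
        manifest.doc["failed_stage"] = stage
        manifest.write()
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    manifest.write()
    return manifest.doc
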