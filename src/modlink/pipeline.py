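"""End-to-end orchestration: ingest -> DE -> network -> module-trait ->
cross-link -> enrich, with per-stage TSV outputs and a JSON run report.

The report contains the configuration echo and per-stage summary counts
(DEGs per week, module counts per tissue, modules of interest, pair tier
counts, key genes, enriched sets).  It contains no timestamps, so two
runs with identical configuration and seed produce byte-identical
reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as mio
from .containers import ExpressionMatrix, TraitTable
from .crosslink import CrossTissueModel, XlinkConfig, rank_interconnected, secretome_filter
from .diffexpr import differential_expression, shared_degs
from .enrich import enrichment_heatmap, fisher_enrichment
from .errors import ConfigError, ModlinkError
from .modtrait import ISLET_MIN_HITS, LIVER_MIN_HITS, ModuleTraitModel
from .network import CoexpressionNetwork, NetworkConfig

log = logging.getLogger(__name__)

STAGES = ("de", "network", "modtrait", "xlink", "enrich")


@dataclass
class RunConfig:
    """Paths, stage parameters, and stage toggles for one pipeline run."""

    counts_islet: str = ""
    counts_liver: str = ""
    metadata: str = ""
    traits: str = ""
    trait_categories: str = ""
    gene_sets: str | None = None
    secretome: str | None = None
    output_dir: str = "modlink_out"

    # filtering / normalization
    min_count: int = 5
    min_samples: int = 2
    top_k_by_variance: int | None = None

    # differential expression
    de_alpha: float = 0.05
    de_lfc_min: float = 1.0

    # network
    network: NetworkConfig = field(default_factory=NetworkConfig)

    # module-trait selection
    trait_alpha: float = 0.05
    interest_category: str = "insulin_secretion"
    islet_min_hits: int = ISLET_MIN_HITS
    liver_min_hits: int = LIVER_MIN_HITS

    # cross-tissue
    xlink: XlinkConfig = field(default_factory=XlinkConfig)

    # enrichment
    enrich_top_n: int = 40

    seed: int = 0
    stages: tuple[str, ...] = STAGES

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        net = NetworkConfig(**raw.pop("network", {}))
        xl = XlinkConfig(**raw.pop("xlink", {}))
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(network=net, xlink=xl, **raw)

    def validate_paths(self) -> None:
        required = {
            "counts_islet": self.counts_islet,
            "counts_liver": self.counts_liver,
            "metadata": self.metadata,
            "traits": self.traits,
            "trait_categories": self.trait_categories,
        }
        for name, p in required.items():
            if not p:
                raise ConfigError(f"config is missing required path {name!r}")
            if not Path(p).exists():
                raise ConfigError(f"{name} path does not exist: {p}")
        for name, p in (("gene_sets", self.gene_sets),
                        ("secretome", self.secretome)):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name} path does not exist: {p}")
        for s in self.stages:
            if s not in STAGES:
                raise ConfigError(f"unknown stage {s!r}")

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["network"]["candidate_powers"] = list(
            self.network.candidate_powers
        )
        return d


def _de_stage(em_log: ExpressionMatrix, config: RunConfig, outdir: Path,
              tissue: str) -> tuple[dict, dict[int, list[str]]]:
    weeks = sorted(set(em_log.meta()["week"]))
    results = []
    degs_per_week: dict[int, list[str]] = {}
    for week in weeks:
        res = differential_expression(
            em_log, week, alpha=config.de_alpha, lfc_min=config.de_lfc_min
        )
        results.append(res)
        degs_per_week[week] = res.deg_genes
        res.table.to_csv(
            outdir / f"de_{tissue}_week{week:02d}.tsv", sep="\t",
            index_label="gene_id",
        )
    summary = {
        "degs_per_week": {str(w): len(g) for w, g in degs_per_week.items()},
        "deg_union": len(set().union(*degs_per_week.values()))
        if degs_per_week else 0,
    }
    if len(results) >= 2:
        shared, _regions = shared_degs(results)
        summary["shared_all_weeks"] = len(shared)
    return summary, degs_per_week


def run_pipeline(
    config: RunConfig,
    islet: ExpressionMatrix | None = None,
    liver: ExpressionMatrix | None = None,
    traits: TraitTable | None = None,
) -> dict:
    """Run the configured stages; write outputs + report.json; return report.

    Inputs are read from the configured paths unless the in-memory
    objects are supplied.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if islet is None or liver is None or traits is None:
        config.validate_paths()
        islet = mio.read_counts_tsv(config.counts_islet, config.metadata)
        liver = mio.read_counts_tsv(config.counts_liver, config.metadata)
        traits = mio.read_trait_table(config.traits, config.trait_categories)

    report: dict = {"config": config.echo(), "stages": {}}

    # -- ingest (always on) -------------------------------------------
    log.info("[ingest] normalizing and filtering")
    ems_log: dict[str, ExpressionMatrix] = {}
    for tissue, em in (("islet", islet), ("liver", liver)):
        filtered = mio.filter_genes(
            em, config.min_count, config.min_samples, config.top_k_by_variance
        )
        ems_log[tissue] = mio.normalize_counts(filtered)
    design = mio.align_paired_samples(ems_log["islet"], ems_log["liver"])
    report["stages"]["ingest"] = {
        "genes": {t: ems_log[t].n_genes for t in ems_log},
        "samples": {t: ems_log[t].n_samples for t in ems_log},
        "paired_subjects": len(design),
        "dropped_subjects": design.n_dropped,
    }

    degs: dict[str, dict[int, list[str]]] = {}
    if "de" in config.stages:
        log.info("[de] per-week differential expression")
        de_summary = {}
        for tissue in ("islet", "liver"):
            de_summary[tissue], degs[tissue] = _de_stage(
                ems_log[tissue], config, outdir, tissue
            )
        report["stages"]["de"] = de_summary

    net_results = {}
    if "network" in config.stages:
        log.info("[network] co-expression networks per tissue")
        net_summary = {}
        for tissue in ("islet", "liver"):
            res = CoexpressionNetwork(ems_log[tissue], config.network).fit()
            net_results[tissue] = res
            res.partition.labels.to_frame().to_csv(
                outdir / f"modules_{tissue}.tsv", sep="\t",
                index_label="gene_id",
            )
            res.eigengenes.values.to_csv(
                outdir / f"eigengenes_{tissue}.tsv", sep="\t",
                index_label="module",
            )
            res.membership.to_csv(
                outdir / f"membership_{tissue}.tsv", sep="\t",
                index_label="gene_id",
            )
            net_summary[tissue] = {
                "power": res.power,
                "n_modules": res.partition.n_modules,
                "n_assigned": int(
                    (res.partition.labels != "unassigned").sum()
                ),
            }
        report["stages"]["network"] = net_summary

    interest = {"islet": [], "liver": []}
    if "modtrait" in config.stages:
        if not net_results:
            raise ConfigError(
                "modtrait stage requires the network stage to be enabled"
            )
        log.info("[modtrait] eigengene-trait regression")
        mt_summary = {}
        for tissue, min_hits in (
            ("islet", config.islet_min_hits),
            ("liver", config.liver_min_hits),
        ):
            res = ModuleTraitModel(
                net_results[tissue].eigengenes, traits, design, tissue=tissue
            ).fit()
            res.summary().to_csv(
                outdir / f"module_trait_{tissue}.tsv", sep="\t", index=False
            )
            try:
                interest[tissue] = res.select_modules(
                    config.interest_category,
                    min_hits=min_hits,
                    alpha=config.trait_alpha,
                )
            except ModlinkError:
                interest[tissue] = []
            mt_summary[tissue] = {
                "modules_of_interest": interest[tissue],
                "n_of_interest": len(interest[tissue]),
            }
        report["stages"]["modtrait"] = mt_summary

    if "xlink" in config.stages:
        if not net_results:
            raise ConfigError(
                "xlink stage requires the network stage to be enabled"
            )
        log.info("[xlink] cross-tissue module pairing")
        deg_sets = {
            t: set().union(*degs[t].values()) if degs.get(t) else set()
            for t in ("islet", "liver")
        }
        use_islet = interest["islet"] or net_results["islet"].partition.module_names
        use_liver = interest["liver"] or net_results["liver"].partition.module_names
        model = CrossTissueModel(
            net_results["islet"],
            net_results["liver"],
            ems_log["islet"],
            ems_log["liver"],
            design,
            islet_interest=use_islet,
            liver_interest=use_liver,
            config=config.xlink,
            deg_sets=deg_sets,
        )
        xres = model.fit()
        xres.pairs_table().to_csv(
            outdir / "pair_scores.tsv", sep="\t", index=False
        )
        xres.key_genes_table().to_csv(
            outdir / "key_genes.tsv", sep="\t", index=False
        )
        xl_summary = {
            "n_pairs_scored": len(xres.pair_scores),
            "tier_counts": xres.tier_counts(),
            "n_key_genes": int(
                sum(len(v) for v in xres.key_genes_per_pair.values())
            ),
        }
        if config.secretome and degs.get("liver"):
            secretome = mio.read_gene_list(config.secretome)
            liver_degs = sorted(deg_sets["liver"])
            secreted = secretome_filter(liver_degs, secretome)
            ranked = rank_interconnected(
                sorted(deg_sets["islet"]),
                secreted,
                ems_log["islet"],
                ems_log["liver"],
                design,
            )
            ranked.to_csv(outdir / "interconnected_candidates.tsv", sep="\t")
            xl_summary["n_secreted_degs"] = len(secreted)
            xl_summary["n_ranked_candidates"] = int(len(ranked))
        report["stages"]["xlink"] = xl_summary

    if "enrich" in config.stages:
        log.info("[enrich] gene-set enrichment per week")
        if not config.gene_sets:
            report["stages"]["enrich"] = {"skipped": "no gene_sets configured"}
        elif not degs:
            raise ConfigError(
                "enrich stage requires the de stage to be enabled"
            )
        else:
            collection = mio.read_gmt(config.gene_sets)
            en_summary = {}
            for tissue in ("islet", "liver"):
                universe = set(ems_log[tissue].gene_ids)
                per_week = {
                    w: fisher_enrichment(set(g), universe, collection)
                    for w, g in degs[tissue].items()
                }
                mat, rows, order = enrichment_heatmap(
                    per_week, top_n=config.enrich_top_n
                )
                mat.to_csv(
                    outdir / f"enrichment_heatmap_{tissue}.tsv", sep="\t",
                    index_label="gene_set",
                )
                flat = [
                    {
                        "week": w,
                        "gene_set": r.name,
                        "k": r.k,
                        "K": r.K,
                        "n": r.n,
                        "N": r.N,
                        "pvalue": r.pvalue,
                        "padj": r.padj,
                    }
                    for w in sorted(per_week)
                    for r in per_week[w]
                ]
                pd.DataFrame(flat).to_csv(
                    outdir / f"enrichment_{tissue}.tsv", sep="\t", index=False
                )
                en_summary[tissue] = {
                    "n_sets_tested": len(
                        next(iter(per_week.values()), [])
                    ),
                    "n_heatmap_rows": len(rows),
                    "significant_sets": {
                        str(w): int(sum(r.padj < 0.05 for r in res))
                        for w, res in per_week.items()
                    },
                }
            report["stages"]["enrich"] = en_summary

    (outdir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True) + "\n"
    )
    return report
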