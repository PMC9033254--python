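"""Staged orchestration of the alkali-tolerance analysis.

Stages (in dependency order): ``simulate`` (emit a synthetic dataset),
``traits`` (21-trait table + summaries), ``gwas`` (per-trait/panel mixed-model
scans), ``loci`` (locus clustering + candidate genes), ``haplotypes``
(gene-CDS-haplotype analysis), ``pyramid`` (favorable-haplotype
combinations), and ``all``.  Every run writes a JSON manifest recording the
config hash, seed, stage timings and artifact paths; result tables are TSV
with a commented header carrying the config hash so reruns are diffable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import germination_traits as gt
from . import haplotype_analysis as ha
from . import locus_mapping as lm
from . import mlm_gwas as mg
from .io_formats import (
    read_annotations,
    read_fasta,
    read_gff3,
    read_metadata,
    read_phenotype_table,
    read_vcf,
)
from .synthetic_data import CausalGene, SimConfig, simulate_dataset, write_dataset

logger = logging.getLogger(__name__)

STAGES = ("simulate", "traits", "gwas", "loci", "haplotypes", "pyramid", "all")
RUN_STAGES = STAGES[:-1]


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


class MissingArtifactError(FileNotFoundError):
    """An upstream stage's output is absent (CLI exit code 3)."""


@dataclass
class PipelineConfig:
    """Declarative configuration for a pipeline run."""

    outdir: Path = Path("alkagerm_run")
    seed: int = 0
    # input paths; default to the simulate stage's dataset directory
    paths: dict = field(default_factory=dict)
    # QC / analysis thresholds
    max_missing: float = 0.20
    min_maf: float = 0.05
    alpha: float = 0.05
    locus_half_window: int = 150_000
    hap_min_size: int = 10
    group_min_size: int = 15
    criterion2_min_traits: int = 4
    n_pcs: int = 3
    # scans to run
    gwas_traits: list = field(default_factory=lambda: ["RGE"])
    panels: list = field(default_factory=lambda: ["whole"])
    pyramid_n_genes: int = 3
    favorable_trait: str = "RGE"
    # synthetic-data generation (used by the simulate stage)
    sim: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if not 0 < self.max_missing <= 1 or not 0 <= self.min_maf < 0.5:
            raise ConfigError("QC thresholds out of range")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha out of range")
        if self.locus_half_window <= 0 or self.hap_min_size < 2 or self.group_min_size < 2:
            raise ConfigError("window/group thresholds out of range")
        bad = set(self.panels) - {"whole", "Xian", "Geng"}
        if bad:
            raise ConfigError(f"unknown panel(s): {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def sim_config(self) -> SimConfig:
        kw = dict(self.sim)
        if "causal_genes" in kw:
            kw["causal_genes"] = [CausalGene(*c) for c in kw["causal_genes"]]
        kw.setdefault("seed", self.seed)
        return SimConfig(**kw)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration.

        File locations (outdir, input paths) are excluded so identical
        analyses in different directories produce identical result tables.
        """
        payload = {
            k: v for k, v in self.__dict__.items() if k not in ("outdir", "paths")
        }
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:12]

    def path(self, key: str) -> Path:
        """Resolve an input path, defaulting into the simulate stage output."""
        defaults = {
            "vcf": "dataset/genotypes.vcf",
            "gff3": "dataset/genes.gff3",
            "fasta": "dataset/reference.fasta",
            "phenotypes": "dataset/phenotypes.tsv",
            "metadata": "dataset/metadata.tsv",
            "annotations": "dataset/annotations.tsv",
        }
        if key in self.paths:
            return Path(self.paths[key])
        return self.outdir / defaults[key]


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"required artifact {path} is missing; run the {producer!r} stage first"
        )
    return path


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig, stage: str,
               index: bool = False) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# alkagerm {stage}\n# config_hash={cfg.config_hash()}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g")
    return path


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig) -> dict[str, Any]:
    ds = simulate_dataset(cfg.sim_config())
    paths = write_dataset(ds, cfg.outdir / "dataset")
    return {"artifacts": {k: str(v) for k, v in paths.items()},
            "n_snps": ds.variants.n_snps, "n_accessions": ds.variants.n_samples}


def _stage_traits(cfg: PipelineConfig) -> dict[str, Any]:
    counts = read_phenotype_table(_require(cfg.path("phenotypes"), "simulate"))
    table = gt.compute_trait_table(counts)
    summary = gt.summarize_traits(table)
    corr = gt.correlate_traits(table[list(gt.ALL_TRAITS)])
    damage = gt.relative_damage(summary["mean"].to_dict())
    out = cfg.outdir / "traits"
    arts = {
        "trait_table": _write_tsv(table, out / "trait_table.tsv", cfg, "traits", index=True),
        "trait_summary": _write_tsv(summary, out / "trait_summary.tsv", cfg, "traits", index=True),
        "trait_correlation": _write_tsv(corr, out / "trait_correlation.tsv", cfg, "traits", index=True),
        "relative_damage": _write_tsv(damage, out / "relative_damage.tsv", cfg, "traits"),
    }
    return {"artifacts": {k: str(v) for k, v in arts.items()},
            "n_accessions": len(table)}


def _read_trait_table(cfg: PipelineConfig) -> pd.DataFrame:
    path = _require(cfg.outdir / "traits" / "trait_table.tsv", "traits")
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def run_panel_gwas(
    variants, metadata: pd.DataFrame, y: pd.Series, cfg: PipelineConfig,
    panel: str = "whole",
):
    """Complete mixed-model scan for one trait in one panel.

    Subsets accessions (panel + complete phenotype), refilters variants
    within the panel, prunes for kinship, fits the null REML model with
    intercept + kinship PCs, scans all filtered SNPs, and derives the 1/N
    suggestive threshold.  Returns (results DataFrame, threshold, extras).
    """
    if panel == "whole":
        panel_acc = metadata["accession_id"]
    else:
        panel_acc = metadata.loc[metadata["subpopulation"] == panel, "accession_id"]
    acc = [a for a in panel_acc if a in y.index and not np.isnan(y[a])]
    if len(acc) < 30:
        raise ConfigError(f"panel {panel!r} has only {len(acc)} phenotyped accessions")
    vt = variants.take_samples(acc)
    yv = y.loc[acc].to_numpy(dtype=float)

    vt_f, qc = mg.filter_variants(vt, cfg.max_missing, cfg.min_maf)
    kept = mg.ld_prune(vt_f)
    pruned = vt_f.take_snps(np.flatnonzero(vt_f.snps["snp_id"].isin(kept)))
    K = mg.ibs_kinship(pruned)
    pcs = mg.pca_covariates(K, cfg.n_pcs)
    X = np.column_stack([np.ones(len(acc)), pcs])
    vc = mg.reml_fit(yv, X, K)
    results = mg.association_scan(vt_f, yv, X, K, vc)
    n_eff = mg.effective_marker_number(vt_f)
    threshold = mg.significance_threshold(n_eff)
    lam, qq = mg.qq_lambda(results["p"].to_numpy()) if len(results) >= 100 else (np.nan, None)
    extras = {"qc": qc, "n_pruned": len(kept), "vc": vc, "n_effective": n_eff,
              "lambda_gc": lam, "qq": qq, "n_accessions": len(acc)}
    return results, threshold, extras


def _stage_gwas(cfg: PipelineConfig) -> dict[str, Any]:
    variants = read_vcf(_require(cfg.path("vcf"), "simulate"))
    metadata = read_metadata(_require(cfg.path("metadata"), "simulate"))
    table = _read_trait_table(cfg)
    out = cfg.outdir / "gwas"
    arts: dict[str, str] = {}
    thr_rows = []
    for panel in cfg.panels:
        for trait in cfg.gwas_traits:
            if trait not in table.columns:
                raise ConfigError(f"trait {trait!r} not in trait table")
            results, threshold, ex = run_panel_gwas(
                variants, metadata, table[trait], cfg, panel
            )
            tag = f"{trait}_{panel}"
            arts[f"assoc_{tag}"] = str(
                _write_tsv(results, out / f"assoc_{tag}.tsv", cfg, "gwas")
            )
            if ex["qq"] is not None:
                arts[f"qq_{tag}"] = str(
                    _write_tsv(ex["qq"], out / f"qq_{tag}.tsv", cfg, "gwas")
                )
            thr_rows.append({
                "trait": trait, "panel": panel, "n": ex["n_accessions"],
                "n_snps": ex["qc"].n_kept, "n_effective": ex["n_effective"],
                "threshold": threshold, "h2": ex["vc"].h2,
                "lambda_gc": ex["lambda_gc"],
            })
            logger.info("gwas %s/%s: %d SNPs, threshold %.3g", trait, panel,
                        ex["qc"].n_kept, threshold)
    arts["thresholds"] = str(
        _write_tsv(pd.DataFrame(thr_rows), out / "thresholds.tsv", cfg, "gwas")
    )
    return {"artifacts": arts}


def _significant_rows(cfg: PipelineConfig) -> pd.DataFrame:
    thr_path = _require(cfg.outdir / "gwas" / "thresholds.tsv", "gwas")
    thr = pd.read_csv(thr_path, sep="\t", comment="#")
    frames = []
    for row in thr.itertuples(index=False):
        tag = f"{row.trait}_{row.panel}"
        path = _require(cfg.outdir / "gwas" / f"assoc_{tag}.tsv", "gwas")
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
        df = df[df["p"] < row.threshold].copy()
        df["trait"], df["panel"] = row.trait, row.panel
        frames.append(df)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["snp_id", "chrom", "pos", "p", "trait", "panel"]
    )


def _stage_loci(cfg: PipelineConfig) -> dict[str, Any]:
    sig = _significant_rows(cfg)
    genes = read_gff3(_require(cfg.path("gff3"), "simulate"))
    ann_path = cfg.path("annotations")
    annotations = read_annotations(ann_path) if ann_path.exists() else None
    thr = pd.read_csv(cfg.outdir / "gwas" / "thresholds.tsv", sep="\t", comment="#")
    n_eff = int(thr["n_effective"].max())

    loci_by_run = {}
    for (trait, panel), sub in sig.groupby(["trait", "panel"]):
        loci_by_run[(trait, panel)] = lm.cluster_loci(
            sub, trait, panel, cfg.locus_half_window
        )
    merged = lm.merge_across_traits(loci_by_run, cfg.locus_half_window)
    candidates = lm.select_candidate_genes(
        sig, genes, annotations, n_eff, cfg.criterion2_min_traits
    )
    cand_df = pd.DataFrame(
        [{
            "gene_id": c.gene_id,
            "criteria": ",".join(map(str, sorted(c.criteria))),
            "best_snp": c.best_snp, "best_p": c.best_p,
            "traits": ",".join(sorted(c.traits)), "annotation": c.annotation,
        } for c in candidates]
    )
    out = cfg.outdir / "loci"
    arts = {
        "merged_loci": str(_write_tsv(merged, out / "merged_loci.tsv", cfg, "loci")),
        "candidate_genes": str(
            _write_tsv(cand_df, out / "candidate_genes.tsv", cfg, "loci")
        ),
    }
    return {"artifacts": arts, "n_loci": len(merged), "n_candidates": len(cand_df),
            "n_significant_snps": int(sig["snp_id"].nunique())}


def _stage_haplotypes(cfg: PipelineConfig) -> dict[str, Any]:
    cand_path = _require(cfg.outdir / "loci" / "candidate_genes.tsv", "loci")
    candidates = pd.read_csv(cand_path, sep="\t", comment="#")
    variants = read_vcf(_require(cfg.path("vcf"), "simulate"))
    genes = {g.gene_id: g for g in read_gff3(_require(cfg.path("gff3"), "simulate"))}
    reference = read_fasta(_require(cfg.path("fasta"), "simulate"))
    metadata = read_metadata(_require(cfg.path("metadata"), "simulate"))
    table = _read_trait_table(cfg)
    trait_values = table[cfg.favorable_trait].to_dict()

    out = cfg.outdir / "haplotypes"
    arts: dict[str, str] = {}
    fav_rows = []
    for gene_id in candidates["gene_id"]:
        gene = genes.get(gene_id)
        if gene is None:
            logger.warning("candidate %s has no gene model; skipped", gene_id)
            continue
        effects = ha.classify_cds_snps(gene, reference, variants)
        haps, _excluded = ha.build_haplotypes(
            gene, effects, variants, cfg.hap_min_size
        )
        retained = [h for h in haps if h.label != "rare"]
        if len(retained) < 2:
            logger.info("gene %s: <2 retained haplotypes; skipped", gene_id)
            continue
        hap_df = pd.DataFrame(
            [{
                "haplotype": h.label, "n": h.n,
                "alleles": "/".join(h.alleles) if h.alleles else "rare",
                "defining_snps": ",".join(h.defining_snps),
                "members": ",".join(h.members),
            } for h in haps]
        )
        arts[f"haps_{gene_id}"] = str(
            _write_tsv(hap_df, out / f"{gene_id}_haplotypes.tsv", cfg, "haplotypes")
        )
        freq = ha.haplotype_subpop_frequencies(haps, metadata)
        arts[f"subpop_{gene_id}"] = str(
            _write_tsv(freq, out / f"{gene_id}_subpop.tsv", cfg, "haplotypes")
        )
        groups = {
            h.label: [trait_values[a] for a in h.members
                      if a in trait_values and not np.isnan(trait_values[a])]
            for h in retained
        }
        groups = {k: v for k, v in groups.items() if len(v) >= 2}
        if len(groups) >= 2:
            dres = ha.duncan_mrt(groups, cfg.alpha)
            dd = pd.DataFrame(
                [{
                    "haplotype": k, "n": dres.ns[k], "mean": dres.means[k],
                    "letters": dres.letters[k],
                } for k in dres.means]
            ).sort_values("mean", ascending=False)
            dd.attrs["anova"] = (dres.anova_f, dres.anova_p)
            arts[f"duncan_{gene_id}"] = str(
                _write_tsv(dd, out / f"{gene_id}_duncan_{cfg.favorable_trait}.tsv",
                           cfg, "haplotypes")
            )
        try:
            fav = ha.favorable_haplotype(retained, trait_values)
        except ValueError:
            continue
        fav_rows.append({"gene_id": gene_id, "favorable_haplotype": fav,
                         "n_haplotypes": len(retained)})
    fav_df = pd.DataFrame(fav_rows)
    arts["favorable"] = str(
        _write_tsv(fav_df, out / "favorable.tsv", cfg, "haplotypes")
    )
    return {"artifacts": arts, "n_genes_analyzed": len(fav_rows)}


def _stage_pyramid(cfg: PipelineConfig) -> dict[str, Any]:
    fav_path = _require(cfg.outdir / "haplotypes" / "favorable.tsv", "haplotypes")
    fav = pd.read_csv(fav_path, sep="\t", comment="#")
    cand = pd.read_csv(
        _require(cfg.outdir / "loci" / "candidate_genes.tsv", "loci"),
        sep="\t", comment="#",
    )
    variants = read_vcf(_require(cfg.path("vcf"), "simulate"))
    genes = {g.gene_id: g for g in read_gff3(_require(cfg.path("gff3"), "simulate"))}
    reference = read_fasta(_require(cfg.path("fasta"), "simulate"))
    table = _read_trait_table(cfg)
    trait_values = table[cfg.favorable_trait].to_dict()

    ranked = [g for g in cand.sort_values("best_p")["gene_id"]
              if g in set(fav["gene_id"])][: cfg.pyramid_n_genes]
    if len(ranked) < 2:
        raise ConfigError("pyramiding needs at least 2 genes with favorable haplotypes")
    haps_by_gene, fav_by_gene = {}, {}
    fmap = fav.set_index("gene_id")["favorable_haplotype"]
    for gid in ranked:
        effects = ha.classify_cds_snps(genes[gid], reference, variants)
        haps, _ = ha.build_haplotypes(genes[gid], effects, variants, cfg.hap_min_size)
        haps_by_gene[gid] = haps
        fav_by_gene[gid] = str(fmap[gid])
    res = ha.combine_haplotypes(
        haps_by_gene, fav_by_gene, trait_values, cfg.group_min_size, cfg.alpha
    )
    df = pd.DataFrame(
        [{
            "group": f"Group {i + 1}",
            "pattern": g.pattern, "genes": ",".join(res.genes),
            "n": g.n, "n_favorable": g.n_favorable,
            f"mean_{cfg.favorable_trait}": g.mean_trait, "letters": g.letter,
        } for i, g in enumerate(res.groups)]
    )
    out = cfg.outdir / "pyramid"
    arts = {"combinations": str(
        _write_tsv(df, out / "combinations.tsv", cfg, "pyramid")
    )}
    return {"artifacts": arts, "n_groups": len(res.groups),
            "spearman_rho": res.spearman_rho,
            "anova_p": res.anova_p}


_IMPL = {
    "simulate": _stage_simulate,
    "traits": _stage_traits,
    "gwas": _stage_gwas,
    "loci": _stage_loci,
    "haplotypes": _stage_haplotypes,
    "pyramid": _stage_pyramid,
}


def run_stage(stage: str, cfg: PipelineConfig) -> dict[str, Any]:
    """Execute one stage (or ``all``) and write the run manifest."""
    if stage not in STAGES:
        raise ConfigError(f"unknown stage {stage!r}; expected one of {STAGES}")
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    to_run = list(RUN_STAGES) if stage == "all" else [stage]
    manifest = {
        "requested": stage,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": __version__,
        "inputs": {k: str(cfg.path(k)) for k in
                   ("vcf", "gff3", "fasta", "phenotypes", "metadata", "annotations")},
        "stages": [],
    }
    summary: dict[str, Any] = {}
    for name in STAGES:
        entry: dict[str, Any] = {"stage": name, "executed": name in to_run}
        if name in to_run:
            t0 = time.perf_counter()
            result = _IMPL[name](cfg)
            entry["wall_time_s"] = round(time.perf_counter() - t0, 3)
            entry.update(result)
            counts = {k: v for k, v in result.items() if k != "artifacts"}
            logger.info("stage %s done in %.2fs %s", name, entry["wall_time_s"], counts)
            summary[name] = result
        manifest["stages"].append(entry)
    (cfg.outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return summary
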