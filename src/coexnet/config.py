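"""Run configuration and the end-to-end pipeline.

:class:`RunConfig` gathers every tunable of the toolkit with the
published defaults -- variation threshold log2(1.5), presence cut-off
4.56, tier bounds top-3 / MR 5 / MR 30, clique size k = 5, module size
cap 500, enrichment alpha and FDR 0.05, 1000 motif background sets,
pattern z thresholds +/-1 with PCC floor 0.7, and interolog confidence
0.6.  :func:`run_pipeline` executes preprocess -> co-expression ->
modules -> enrichment (plus optional motif / pattern / integration
stages when their inputs are configured) and writes a manifest with
parameters, seed and SHA-256 checksums of every output, so a rerun with
the same inputs and seed can be verified byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import coexpression, enrichment, expression, integration, modules
from . import motifs as motifs_mod
from . import patterns as patterns_mod

log = logging.getLogger(__name__)

# captured before the dataclass body, whose `expression` field shadows
# the module name inside the class namespace
_DEFAULT_VARIATION = expression.VARIATION_THRESHOLD
_DEFAULT_PRESENCE = expression.PRESENCE_CUTOFF
_DEFAULT_UNIVERSE = enrichment.DEFAULT_UNIVERSE_SIZE


@dataclass
class RunConfig:
    # inputs (expression + samples required; the rest enable extra stages)
    expression: str = ""
    samples: str = ""
    probe_map: str | None = None
    gene_sets: str | None = None
    promoters: str | None = None
    motifs: str | None = None
    query_genes: str | None = None      # newline-separated ids for motif stage
    pattern_spec: str | None = None     # YAML: groups / levels / mode ...
    orthologs: str | None = None
    reference_ppis: str | None = None
    mirna_targets: str | None = None
    # stage parameters (published defaults)
    variation_threshold: float = _DEFAULT_VARIATION
    presence_cutoff: float = _DEFAULT_PRESENCE
    top_n: int = 3
    mr_level2: float = 5.0
    mr_level3: float = 30.0
    min_abs_pcc: float = 0.0
    k: int = 5
    max_module_size: int = 500
    alpha: float = 0.05
    fdr: float = 0.05
    n_background_sets: int = 1000
    z_hi: float = 1.0
    z_lo: float = -1.0
    pcc_min: float = 0.7
    min_conf: float = 0.6
    genome_size: int = _DEFAULT_UNIVERSE
    # run control
    seed: int = 0
    outdir: str = "coexnet_out"

    def __post_init__(self) -> None:
        self.tier_config  # validates top_n / mr levels
        if self.k < 3:
            raise ValueError("k must be >= 3")
        if self.max_module_size < self.k:
            raise ValueError("max_module_size must be >= k")
        for name in ("alpha", "fdr", "min_conf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not self.z_lo < self.z_hi:
            raise ValueError("require z_lo < z_hi")
        if self.n_background_sets < 2:
            raise ValueError("n_background_sets must be >= 2")
        if self.variation_threshold < 0:
            raise ValueError("variation_threshold must be >= 0")

    @property
    def tier_config(self) -> coexpression.TierConfig:
        return coexpression.TierConfig(
            top_n=self.top_n, mr_level2=self.mr_level2,
            mr_level3=self.mr_level3, min_abs_pcc=self.min_abs_pcc)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every configured stage and return the manifest dict."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    def stage(name):
        log.info("stage: %s", name)

    # -- preprocess ------------------------------------------------------
    stage("preprocess")
    pm = expression.load_probe_map(cfg.probe_map) if cfg.probe_map else None
    m = expression.load_expression_matrix(cfg.expression, probe_map=pm)
    ann = expression.load_sample_annotation(cfg.samples) if cfg.samples else None
    filtered = expression.variation_filter(m, cfg.variation_threshold)
    expression.write_expression_matrix(filtered, out / "filtered_expression.tsv")
    outputs.append(out / "filtered_expression.tsv")

    # -- co-expression ---------------------------------------------------
    stage("coexpression")
    edges, summary = coexpression.build_coexpression_network(
        filtered, cfg.tier_config, genome_size=cfg.genome_size)
    coexpression.write_edge_table(edges, out / "coexpression_edges.tsv")
    outputs.append(out / "coexpression_edges.tsv")

    # -- modules ---------------------------------------------------------
    stage("modules")
    g = modules.graph_from_edges(edges)
    ms = modules.filter_modules(modules.k_clique_communities(g, cfg.k),
                                cfg.max_module_size)
    ms.write(out / "modules.tsv")
    outputs.append(out / "modules.tsv")
    summary["n_modules"] = len(ms)
    summary["module_gene_coverage"] = len(ms.covered_genes)

    # -- enrichment ------------------------------------------------------
    if cfg.gene_sets:
        stage("enrichment")
        gsc = enrichment.read_gmt(cfg.gene_sets,
                                  universe_size=cfg.genome_size)
        if len(ms):
            annot = enrichment.annotate_modules(ms, gsc, p_max=cfg.alpha,
                                                q_max=cfg.fdr)
            annot.to_csv(out / "module_annotations.tsv", sep="\t", index=False)
            outputs.append(out / "module_annotations.tsv")

    # -- motif enrichment ------------------------------------------------
    if cfg.promoters and cfg.motifs and cfg.query_genes:
        stage("motifs")
        promoters = motifs_mod.read_promoters_fasta(cfg.promoters)
        motif_list = motifs_mod.read_motif_table(cfg.motifs)
        query = [l.strip() for l in open(cfg.query_genes) if l.strip()]
        res = motifs_mod.motif_enrichment(
            promoters, query, motif_list, n_sets=cfg.n_background_sets,
            alpha=cfg.alpha, seed=cfg.seed)
        res.to_csv(out / "motif_enrichment.tsv", sep="\t", index=False,
                   float_format="%.6g")
        outputs.append(out / "motif_enrichment.tsv")

    # -- pattern screen --------------------------------------------------
    if cfg.pattern_spec and ann is not None:
        stage("pattern")
        with open(cfg.pattern_spec) as fh:
            raw = yaml.safe_load(fh)
        spec = patterns_mod.PatternSpec(
            groups=tuple(raw["groups"]), levels=tuple(raw["levels"]),
            z_hi=raw.get("z_hi", cfg.z_hi), z_lo=raw.get("z_lo", cfg.z_lo),
            mode=raw.get("mode", "correlation"),
            pcc_min=raw.get("pcc_min", cfg.pcc_min),
            group_column=raw.get("group_column", "tissue"))
        res = patterns_mod.pattern_match(filtered, ann, spec)
        res.to_csv(out / "pattern_matches.tsv", sep="\t", index=False,
                   float_format="%.6g")
        outputs.append(out / "pattern_matches.tsv")

    # -- integration -----------------------------------------------------
    if cfg.orthologs and cfg.reference_ppis:
        stage("integration")
        import pandas as pd

        orth = pd.read_csv(cfg.orthologs, sep="\t")
        ppis = pd.read_csv(cfg.reference_ppis, sep="\t")
        projected = integration.project_interologs(ppis, orth, cfg.min_conf)
        mirna = (pd.read_csv(cfg.mirna_targets, sep="\t")
                 if cfg.mirna_targets else None)
        net = integration.merge_networks(edges, projected, mirna)
        net.to_sif(out / "network.sif")
        net.to_graphml(out / "network.graphml")
        net.to_tsv(out / "network_edges.tsv")
        outputs += [out / "network.sif", out / "network.graphml",
                    out / "network_edges.tsv"]
        summary["multinet"] = net.summary(genome_size=cfg.genome_size)

    manifest = {
        "coexnet_version": __version__,
        "seed": cfg.seed,
        "parameters": cfg.to_dict(),
        "summary": summary,
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest
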