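"""Synthetic data generation and the published CAD-network fixture.

Everything the pipeline consumes can be generated here without any
download: expression matrices with planted co-expression modules and a
tissue x genotype x replicate design, promoter sets with planted
motifs, gene-set collections, ortholog/PPI/miRNA pair tables, and a
transcribed fixture of the published co-expression neighbourhood of the
sorghum lignin-pathway CAD gene *Sobic.004G071000*.

Expression model
----------------
Module genes share a per-sample latent factor: a gene in module *m*
takes value ``mu_g + sqrt(r) * z_m(s) + sqrt(1 - r) * eps_gs`` with
``z_m`` and ``eps`` i.i.d. standard normal, so the expected pairwise
Pearson correlation inside a module is exactly the target ``r``.
Background genes are pure noise around their own baseline.  Baselines
sit near 8 on the log2 scale, far above the 4.56 presence cut-off, and
sample noise of unit scale gives every gene a max-min range well above
the log2(1.5) variation threshold, so the simulated matrices pass
preprocessing the way a real normalized microarray series would.

The default design emulates a multi-tissue, multi-genotype microarray
atlas: 4 tissues x 6 genotypes x 3 replicates = 72 samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .motifs import IUPAC_MATCH, validate_consensus

DEFAULT_TISSUES = ("shoot", "root", "leaf", "stem")
DEFAULT_GENOTYPES = ("Atlas", "R159", "Fremont", "PI152611", "AR2400", "PI455230")
CAD_QUERY_GENE = "Sobic.004G071000"


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for :func:`simulate_expression`."""

    n_genes: int = 500
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    genotypes: tuple[str, ...] = DEFAULT_GENOTYPES
    n_replicates: int = 3
    n_modules: int = 3
    module_size: int = 10
    r_within: float = 0.9
    noise_sd: float = 1.0
    base_mean: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("planted modules exceed n_genes")
        if not 0.0 <= self.r_within <= 0.99:
            raise ValueError("correlation target must lie in [0, 0.99]")

    @property
    def n_samples(self) -> int:
        return len(self.tissues) * len(self.genotypes) * self.n_replicates


def _annotation(cfg: SimulationConfig) -> pd.DataFrame:
    rows = []
    i = 0
    for genotype in cfg.genotypes:
        for tissue in cfg.tissues:
            for rep in range(1, cfg.n_replicates + 1):
                i += 1
                rows.append({
                    "sample_id": f"S{i:03d}",
                    "series_id": "SIM1",
                    "tissue": tissue,
                    "genotype": genotype,
                    "treatment": "none",
                    "replicate": rep,
                })
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_expression(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Expression matrix + sample annotation + ground-truth module labels.

    Labels are a Series gene_id -> module index (-1 for background).
    Deterministic for a given config (all randomness flows from
    ``cfg.seed``).
    """
    rng = np.random.default_rng(cfg.seed)
    ann = _annotation(cfg)
    n_s = cfg.n_samples
    genes = [f"G{i:05d}" for i in range(1, cfg.n_genes + 1)]
    labels = pd.Series(-1, index=pd.Index(genes, name="gene_id"), name="module")
    values = np.empty((cfg.n_genes, n_s))
    baselines = cfg.base_mean + rng.normal(0.0, 1.0, size=cfg.n_genes)
    r = cfg.r_within
    gi = 0
    # module gene = sqrt(r)*latent + noise_sd*sqrt(1-r)*eps: at noise_sd = 1
    # the expected pairwise PCC is exactly r; at 0 the module is noiseless.
    for mod in range(cfg.n_modules):
        latent = rng.normal(0.0, 1.0, size=n_s)
        for _ in range(cfg.module_size):
            eps = rng.normal(0.0, 1.0, size=n_s)
            values[gi] = (baselines[gi] + np.sqrt(r) * latent
                          + cfg.noise_sd * np.sqrt(1.0 - r) * eps)
            labels.iloc[gi] = mod
            gi += 1
    while gi < cfg.n_genes:
        values[gi] = baselines[gi] + cfg.noise_sd * rng.normal(0.0, 1.0, size=n_s)
        gi += 1
    m = pd.DataFrame(values, index=labels.index, columns=ann.index)
    return m, ann, labels


def simulate_patterned_expression(
    levels_by_group: dict[str, str],
    n_genes: int = 500,
    n_followers: int = 30,
    effect: float = 2.0,
    noise_sd: float = 1.0,
    n_replicates: int = 3,
    base_mean: float = 8.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Matrix where *n_followers* genes follow a high/even/low tissue pattern.

    Follower means shift by ``effect * (+1 / 0 / -1)`` per group; the
    other genes are flat noise.  Returns (matrix, annotation, follower ids).
    """
    from .patterns import LEVEL_VALUE

    groups = list(levels_by_group)
    rng = np.random.default_rng(seed)
    cols, rows = [], []
    for grp in groups:
        for rep in range(1, n_replicates + 1):
            cols.append(f"{grp}_{rep}")
            rows.append({"sample_id": f"{grp}_{rep}", "series_id": "SIM2",
                         "tissue": grp, "genotype": "Atlas",
                         "treatment": "none", "replicate": rep})
    ann = pd.DataFrame(rows).set_index("sample_id")
    genes = [f"G{i:05d}" for i in range(1, n_genes + 1)]
    ideal = np.repeat([LEVEL_VALUE[levels_by_group[g]] for g in groups],
                      n_replicates)
    values = base_mean + rng.normal(0.0, noise_sd, size=(n_genes, len(cols)))
    values[:n_followers] += effect * ideal
    m = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=cols)
    return m, ann, genes[:n_followers]


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

def _concrete_instance(consensus: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(IUPAC_MATCH[c].replace("N", "")))
                   for c in consensus.upper())


def simulate_promoters(
    n: int,
    length: int = 2000,
    motif: str = "CACGTG",
    carrier_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[dict[str, str], list[str]]:
    """Uniform-random promoters; carriers get one planted motif instance.

    Returns (gene_id -> sequence, carrier gene ids).  Chance background
    hits still occur at the expected ~(L - w + 1) / 4^w rate per strand.
    """
    if not 0.0 <= carrier_fraction <= 1.0:
        raise ValueError("carrier_fraction must lie in [0, 1]")
    validate_consensus(motif)
    if length < len(motif):
        raise ValueError("promoter length shorter than the motif")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(1, n + 1)]
    n_carriers = int(round(carrier_fraction * n))
    carriers = list(rng.choice(genes, size=n_carriers, replace=False))
    promoters = {}
    bases = np.array(list("ACGT"))
    for gene in genes:
        seq = rng.choice(bases, size=length)
        if gene in set(carriers):
            pos = int(rng.integers(0, length - len(motif) + 1))
            seq[pos:pos + len(motif)] = list(_concrete_instance(motif, rng))
        promoters[gene] = "".join(seq)
    return promoters, sorted(carriers)


# ---------------------------------------------------------------------------
# published CAD-network fixture
# ---------------------------------------------------------------------------

def load_cad_network() -> pd.DataFrame:
    """The published 46-gene co-expression/PPI neighbourhood of the
    sorghum CAD gene *Sobic.004G071000*, transcribed to a table.

    Columns: gene_a, gene_b, pcc, mr (printed values), edge_type
    (coexp_pos / coexp_neg / ppi_pred) and rank_product -- the integer
    ``a * b`` recovered from the printed MR (MR = sqrt(a*b) for integer
    rank positions), so ``sqrt(rank_product)`` is the exact MR.
    """
    with resources.files("coexnet.data").joinpath("cad_network.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t",
                            dtype={"gene_a": str, "gene_b": str})
    return table


def cad_fixture_frames() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fixture split into merge-ready (coexpression, predicted-PPI) tables."""
    table = load_cad_network()
    coexp = table[table["edge_type"] != "ppi_pred"].copy()
    coexp["sign"] = np.where(coexp["edge_type"] == "coexp_pos",
                             "positive", "negative")
    coexp["mr_exact"] = np.sqrt(coexp["rank_product"].astype(float))
    ppi = table[table["edge_type"] == "ppi_pred"][["gene_a", "gene_b"]].copy()
    ppi["evidence"] = "interolog"
    return coexp[["gene_a", "gene_b", "pcc", "mr", "mr_exact", "sign"]], ppi


# ---------------------------------------------------------------------------
# demo workspace
# ---------------------------------------------------------------------------

def write_workspace(outdir, seed: int = 0,
                    cfg: SimulationConfig | None = None) -> dict[str, str]:
    """Write a complete demo workspace of every input format.

    Produces the expression matrix and annotation, a GMT with the
    planted modules as gene sets (plus decoys), promoter FASTA + motif
    table, ortholog / reference-PPI / miRNA-target TSVs and the CAD
    fixture tables.  Returns {name: path}.
    """
    from pathlib import Path

    from . import expression, motifs as motif_io
    from .enrichment import GeneSetCollection, write_gmt

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = cfg if cfg is not None else SimulationConfig(seed=seed)
    rng = np.random.default_rng(seed + 1)
    paths: dict[str, str] = {}

    m, ann, labels = simulate_expression(cfg)
    expression.write_expression_matrix(m, out / "expression.tsv")
    ann.reset_index().to_csv(out / "samples.tsv", sep="\t", index=False)
    labels.reset_index().to_csv(out / "true_modules.tsv", sep="\t", index=False)
    paths.update(expression=str(out / "expression.tsv"),
                 samples=str(out / "samples.tsv"),
                 true_modules=str(out / "true_modules.tsv"))

    sets = {f"planted_module_{mod}": frozenset(labels.index[labels == mod])
            for mod in range(cfg.n_modules)}
    genes = list(labels.index)
    for d in range(5):  # decoy sets of random genes
        sets[f"decoy_{d}"] = frozenset(
            rng.choice(genes, size=cfg.module_size * 2, replace=False))
    gsc = GeneSetCollection(sets=sets, universe=frozenset(genes))
    write_gmt(gsc, out / "gene_sets.gmt")
    paths["gene_sets"] = str(out / "gene_sets.gmt")

    # promoter ids coincide with the simulated gene ids (G00001, ...)
    promoters, carriers = simulate_promoters(
        n=cfg.n_genes, motif="CACGTG", carrier_fraction=0.1, seed=seed + 2)
    motif_io.write_promoters_fasta(promoters, out / "promoters.fasta")
    pd.DataFrame({
        "motif_id": ["GBOX", "MYBCORE", "TATA"],
        "consensus": ["CACGTG", "CNGTTR", "TATAWAW"],
        "annotation": ["bHLH G-box", "MYB core site", "TATA box"],
    }).to_csv(out / "motifs.tsv", sep="\t", index=False)
    paths.update(promoters=str(out / "promoters.fasta"),
                 motifs=str(out / "motifs.tsv"))

    # small ortholog / reference-PPI / miRNA-target tables over the genes
    ref = [f"AT{i}G{j:05d}" for i, j in zip(rng.integers(1, 6, 20),
                                            rng.integers(1, 80000, 20))]
    target = list(rng.choice(genes, size=20, replace=False))
    orth = pd.DataFrame({"ref_gene": ref, "target_gene": target,
                         "confidence": rng.uniform(0.3, 1.0, 20).round(2)})
    orth.to_csv(out / "orthologs.tsv", sep="\t", index=False)
    ppi_rows = [(ref[i], ref[j], "refdb")
                for i, j in zip(rng.integers(0, 20, 15), rng.integers(0, 20, 15))
                if i != j]
    pd.DataFrame(ppi_rows, columns=["gene_a", "gene_b", "source"]).to_csv(
        out / "reference_ppis.tsv", sep="\t", index=False)
    mirna = pd.DataFrame({
        "mirna": [f"sbi-miR{n}" for n in rng.integers(156, 400, 10)],
        "target": rng.choice(genes, size=10, replace=False),
        "score": rng.uniform(0, 5, 10).round(2),
    })
    mirna.to_csv(out / "mirna_targets.tsv", sep="\t", index=False)
    paths.update(orthologs=str(out / "orthologs.tsv"),
                 reference_ppis=str(out / "reference_ppis.tsv"),
                 mirna_targets=str(out / "mirna_targets.tsv"))

    coexp, ppi = cad_fixture_frames()
    coexp.to_csv(out / "cad_coexpression.tsv", sep="\t", index=False)
    ppi.to_csv(out / "cad_ppis.tsv", sep="\t", index=False)
    paths.update(cad_coexpression=str(out / "cad_coexpression.tsv"),
                 cad_ppis=str(out / "cad_ppis.tsv"))
    return paths
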