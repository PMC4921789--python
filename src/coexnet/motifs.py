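"""Promoter motif scanning and Z-score enrichment against sampled backgrounds.

Motifs are IUPAC consensus strings (cis-regulatory elements) scanned
over promoter sequences -- by convention the 2 kb upstream of the
transcript start -- on both strands, all overlapping matches counted.
Significance of a motif in a query promoter set is measured against the
empirical distribution of its occurrence count in 1000 random promoter
sets of the same size drawn from the background collection:

    Z = (N_motif - mean_bg) / stdev_bg,     p = 1 - Phi(Z)

where ``N_motif`` is the count in the query promoters and
``mean_bg`` / ``stdev_bg`` summarise the 1000 background counts.  The
p-value is an upper tail, so only enrichment (not depletion) is tested;
depletion shows up as a negative Z.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq
from scipy.stats import norm

DEFAULT_N_BACKGROUND_SETS = 1000
DEFAULT_PROMOTER_LENGTH = 2000

#: motif letter -> set of concrete bases it matches in a sequence.  A
#: motif 'N' also matches an 'N' in the sequence; sequence 'N' matches
#: nothing else (an undetermined base is never evidence for a site).
IUPAC_MATCH: dict[str, str] = {
    letter: (values + "N" if letter == "N" else values)
    for letter, values in ambiguous_dna_values.items()
    if letter in "ACGTRYSWKMBDHVN"  # drop biopython's non-IUPAC 'X'
}


class MotifValidationError(ValueError):
    """Motif consensus contains a non-IUPAC character."""


@dataclass(frozen=True)
class Motif:
    motif_id: str
    consensus: str
    annotation: str = ""

    def __post_init__(self) -> None:
        validate_consensus(self.consensus)


def validate_consensus(consensus: str) -> None:
    if not consensus:
        raise MotifValidationError("empty motif consensus")
    bad = set(consensus.upper()) - set(IUPAC_MATCH)
    if bad:
        raise MotifValidationError(
            f"invalid IUPAC characters in motif: {sorted(bad)}"
        )


def _pattern(consensus: str) -> re.Pattern:
    # lookahead so overlapping matches are all found
    body = "".join(f"[{IUPAC_MATCH[c]}]" for c in consensus.upper())
    return re.compile(f"(?=({body}))")


def reverse_complement(consensus: str) -> str:
    """IUPAC-aware reverse complement (R<->Y, S<->S, ...)."""
    return str(Seq(consensus.upper()).reverse_complement())


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def scan_motif(seq: str, motif: Motif | str) -> list[tuple[int, int, str]]:
    """All matches of a consensus in *seq*, both strands.

    Returns ``(start, end, strand)`` with 0-based half-open intervals on
    the forward sequence.  A position matching on both strands (a
    palindromic site) is reported once, as '+': counting it twice would
    systematically inflate palindromic elements.
    """
    consensus = motif.consensus if isinstance(motif, Motif) else motif
    validate_consensus(consensus)
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    hits: list[tuple[int, int, str]] = []
    fwd_spans = set()
    for m in _pattern(consensus).finditer(seq):
        span = (m.start(), m.start() + len(consensus))
        fwd_spans.add(span)
        hits.append((*span, "+"))
    rc = reverse_complement(consensus)
    for m in _pattern(rc).finditer(seq):
        span = (m.start(), m.start() + len(consensus))
        if span not in fwd_spans:
            hits.append((*span, "-"))
    return sorted(hits)


def count_occurrences(promoters: Mapping[str, str], genes: Iterable[str],
                      motif: Motif | str) -> int:
    """Total strand-deduplicated hit count over the selected promoters."""
    genes = list(genes)
    unknown = [g for g in genes if g not in promoters]
    if unknown:
        raise KeyError(f"genes without promoters: {unknown}")
    return sum(len(scan_motif(promoters[g], motif)) for g in genes)


def _per_promoter_counts(promoters: Mapping[str, str],
                         motif: Motif | str) -> pd.Series:
    return pd.Series({g: len(scan_motif(s, motif))
                      for g, s in promoters.items()}).sort_index()


# ---------------------------------------------------------------------------
# background distribution and Z-score
# ---------------------------------------------------------------------------

def background_distribution(
    promoters: Mapping[str, str],
    set_size: int,
    motif: Motif | str,
    n_sets: int = DEFAULT_N_BACKGROUND_SETS,
    seed: int | None = None,
    _counts: pd.Series | None = None,
) -> tuple[float, float]:
    """Mean and stdev of motif counts over random background promoter sets.

    Each of the *n_sets* sets is drawn uniformly without replacement
    within the set (sets are independent of one another).  The standard
    deviation uses the population denominator ``n_sets``: the draws are
    the whole Monte-Carlo sample, not a subsample of something larger.
    """
    if set_size > len(promoters):
        raise ValueError("set_size exceeds the number of background promoters")
    if n_sets < 2:
        raise ValueError("n_sets must be >= 2")
    counts = _counts if _counts is not None else _per_promoter_counts(promoters, motif)
    values = counts.to_numpy()
    rng = np.random.default_rng(seed)
    totals = np.empty(n_sets, dtype=float)
    for i in range(n_sets):
        idx = rng.choice(len(values), size=set_size, replace=False)
        totals[i] = values[idx].sum()
    return float(totals.mean()), float(totals.std(ddof=0))


def motif_zscore(n_motif: float, mean_bg: float,
                 stdev_bg: float) -> tuple[float, float]:
    """Z = (N - mean)/stdev and its upper-tail normal p-value.

    Degenerate background (stdev 0): Z is 0 / +inf / -inf as N compares
    to the mean, with p 0.5 / 0 / 1.
    """
    if stdev_bg < 0:
        raise ValueError("stdev_bg must be >= 0")
    if stdev_bg == 0:
        if n_motif == mean_bg:
            return 0.0, 0.5
        return (float("inf"), 0.0) if n_motif > mean_bg else (float("-inf"), 1.0)
    z = (n_motif - mean_bg) / stdev_bg
    return float(z), float(norm.sf(z))


def motif_enrichment(
    promoters: Mapping[str, str],
    query_genes: Sequence[str],
    motifs: Iterable[Motif],
    n_sets: int = DEFAULT_N_BACKGROUND_SETS,
    alpha: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-motif query count, background mean/stdev, Z and p, sorted by p.

    Background sets match the query size and are drawn from *promoters*
    (the full promoter collection).  Reproducible for a given *seed*;
    each motif gets an independent child seed so adding or removing
    motifs does not perturb the others.
    """
    motifs = list(motifs)
    query = list(query_genes)
    rows = []
    child_seeds = np.random.SeedSequence(seed).spawn(len(motifs))
    for motif, child in zip(motifs, child_seeds):
        counts = _per_promoter_counts(promoters, motif)
        n_motif = int(counts.loc[list(query)].sum()) if query else 0
        mean_bg, sd_bg = background_distribution(
            promoters, len(query), motif, n_sets=n_sets,
            seed=np.random.default_rng(child).integers(2 ** 31),
            _counts=counts)
        z, p = motif_zscore(n_motif, mean_bg, sd_bg)
        rows.append((motif.motif_id, motif.consensus, n_motif, mean_bg, sd_bg,
                     z, p, motif.annotation))
    res = pd.DataFrame(rows, columns=["motif_id", "consensus", "n_motif",
                                      "mean_bg", "stdev_bg", "z", "p_value",
                                      "annotation"])
    res["significant"] = res["p_value"] <= alpha
    return res.sort_values(["p_value", "motif_id"], kind="mergesort",
                           ignore_index=True)


# ---------------------------------------------------------------------------
# IO and the promoter-extraction helper
# ---------------------------------------------------------------------------

def read_promoters_fasta(path) -> dict[str, str]:
    """FASTA of promoter sequences; record id = gene id."""
    promoters: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in promoters:
            raise ValueError(f"duplicate promoter id: {rec.id}")
        promoters[rec.id] = str(rec.seq).upper()
    return promoters


def write_promoters_fasta(promoters: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(promoters):
            fh.write(f">{gene}\n{promoters[gene]}\n")


def read_motif_table(path) -> list[Motif]:
    """TSV: motif_id <tab> IUPAC consensus <tab> annotation."""
    table = pd.read_csv(path, sep="\t", dtype=str,
                        names=["motif_id", "consensus", "annotation"],
                        header=0).fillna("")
    return [Motif(r.motif_id, r.consensus, r.annotation)
            for r in table.itertuples(index=False)]


def extract_promoters(genome_fasta, gff3_path,
                      length: int = DEFAULT_PROMOTER_LENGTH) -> dict[str, str]:
    """Optional helper: cut *length* bp upstream of each gene's start.

    Reads gene features from a GFF3 (1-based, strand-aware; the ID
    attribute names the gene), clips at chromosome ends, and returns
    forward-oriented promoter sequences (reverse-complemented for minus
    strand genes).  Motif statistics never depend on this helper --
    promoters can always be supplied directly as FASTA.
    """
    chroms = {rec.id: str(rec.seq).upper()
              for rec in SeqIO.parse(str(genome_fasta), "fasta")}
    promoters: dict[str, str] = {}
    with open(gff3_path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            chrom, start, end, strand = parts[0], int(parts[3]), int(parts[4]), parts[6]
            attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
            gene = attrs.get("ID", attrs.get("Name"))
            if gene is None or chrom not in chroms:
                continue
            seq = chroms[chrom]
            if strand == "-":
                lo, hi = end, min(len(seq), end + length)
                promoters[gene] = str(Seq(seq[lo:hi]).reverse_complement())
            else:
                lo, hi = max(0, start - 1 - length), start - 1
                promoters[gene] = seq[lo:hi]
    return promoters
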