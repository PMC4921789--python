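# Methods

This note documents the models, parameter semantics, numerical choices
and limitations of the toolkit. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Preprocessing

Expression matrices are log2-scale (microarray intensity or log2 FPKM),
genes as rows. Probe-level input is collapsed to one row per gene by
keeping the probe with the highest mean across samples. "Highest
intensity" could also be read per sample (taking each sample's maximum
over probes), but that would splice profiles from different probes into
one gene and distort correlations, so the whole-probe rule is used; ties
go to the lexicographically smaller probe id so the choice is
deterministic.

The variation filter keeps genes with max − min ≥ log2(1.5) over
non-missing samples. The exact value 0.5849… is used internally; user
interfaces display it at two decimals (0.58). Genes with fewer than two
non-missing values are excluded and logged rather than raising: such rows
are a data-quality property, not a caller error.

The presence call compares replicate values to a 4.56 log2-intensity
cut-off with strict inequalities: *expressed* if any replicate is above,
*not expressed* if all are below. A value exactly at the cut-off is
neither, and the gene is flagged *indeterminate*; condition-specific
network construction drops such genes. The call is applied to the
collapsed, gene-level matrix.

## Co-expression network

Pearson correlations are computed over pairwise-complete observations
with a minimum of three shared samples; a constant vector or fewer
complete pairs leaves the pair undefined (no edge). Correlations are
clipped to [−1, 1] against floating-point overshoot.

Mutual rank is `MR = sqrt(a·b)` where *a* is the 1-based position of gene
Y in X's PCC-sorted partner list and *b* the reverse. Ranking details
that MR depends on, all deterministic:

* positive and negative candidate lists are separate — the positive list
  ranks PCC > 0 partners descending, the negative list ranks PCC < 0
  partners ascending (most negative = rank 1). Ranking negatives by
  signed value rather than |PCC| is a choice; the published example
  values are consistent with either, and the two coincide whenever a
  gene's negative partners are considered among themselves.
* ties in PCC break by partner id ascending, dense rank assignment
  (1, 2, 3, …, no gaps).

Tier assignment is exclusive and ordered: tier 1 if either endpoint
ranks the other within `top_n` (default 3) — the union reading of "top
three partners", which is the inclusive interpretation; tier 2 if
MR ≤ 5; tier 3 if MR ≤ 30 (both bounds inclusive); otherwise the pair is
dropped. An optional `min_abs_pcc` floor (default 0) filters edges after
ranking, for users who want a hard correlation threshold on top of the
rank-based tiers.

## Module detection

CPM communities are computed exactly: all k-cliques are enumerated from
the maximal cliques (Bron–Kerbosch via networkx `find_cliques`) and
unioned through a disjoint-set structure keyed by (k−1)-node subsets,
which is precisely the percolation adjacency. Edge weights are ignored
— the MR/tier filters upstream decide graph membership. The input graph
defaults to the union of positive tiers 1–3.

Defaults: k = 5 and a 500-node cap applied after detection (the cap is
exclusive: a 501-node community is dropped, a 500-node one kept).
`k_selection_summary` reports, per candidate k in 3–8, the community
count, gene coverage, maximum community size and a mean pairwise Jaccard
overlap over community pairs sharing at least one node — the overlap
statistic is this package's choice of a concrete "overlap rate" for the
coverage-vs-distinctness trade-off that motivates k = 5.

## Gene-set enrichment

The enrichment p-value is the hypergeometric upper tail P(X ≥ k)
(identical to the one-sided Fisher exact test); the pmf is exposed
separately. Computation uses `scipy.stats.hypergeom`, which works in log
space, and the test suite pins it to exact rational arithmetic to 1e-12
for universes up to 60. FDR correction is Benjamini–Hochberg across all
sets tested in one call; only sets with a non-empty overlap are tested
and reported. The default universe size is 33,032 (the sorghum v2.1 gene
count), overridable per collection; when an explicit universe gene set is
supplied, query genes outside it are dropped with a warning. Module
annotation requires both p ≤ 0.05 and q ≤ 0.05.

## Motif enrichment

Motifs are IUPAC consensus strings scanned on both strands with all
overlapping matches reported. A position matching on both strands (a
palindromic site) is counted once — double-counting would systematically
inflate palindromic elements. An `N` in the sequence matches only a
motif `N`: an undetermined base is never taken as evidence for a site.

The background distribution draws 1000 random promoter subsets of the
query's size, uniformly without replacement within a set and
independently across sets, and summarises the per-set total counts with
mean and population (ddof = 0) standard deviation — the 1000 sets *are*
the Monte-Carlo sample, not a subsample. `Z = (N − mean)/stdev` and
`p = 1 − Φ(Z)` is upper-tail only, mirroring the one-sided formula;
depletion appears as negative Z but is not separately tested. Degenerate
backgrounds (stdev 0) define Z as 0 / ±∞ with p 0.5 / 0 / 1. Each motif
receives an independent child seed from the run seed, so the per-motif
background is unchanged when other motifs are added or removed.

Promoters are consumed as FASTA (id = gene id, default 2 kb). A helper
extracts 2 kb upstream of gene starts from genome FASTA + GFF3 (1-based,
strand-aware, clipped at chromosome ends); the statistics never depend
on it.

## Pattern screening

The tissue-form z-score for one gene is `(x̄_group − x̿)/stdev`, where
replicates are averaged per group first and x̿/stdev are taken over the
series' group means (population form); a constant gene gets z = 0. The
treatment form is `log2(x̄_T/x̄_C)` computed on the linear intensity
scale — stored values are log2, so means are taken after de-logging;
averaging the log2 values directly would compute a geometric mean and
understate fold-changes of noisy genes.

Levels are high (z ≥ +1), low (z ≤ −1, both inclusive), even otherwise;
the ±1 thresholds are exposed configuration, as is the match mode:
threshold mode keeps genes whose levels equal the requested pattern
exactly, correlation mode keeps genes whose group-mean profile has
PCC ≥ 0.7 against the ideal vector (high = +1, even = 0, low = −1). The
ideal-vector construction is this package's concrete reference vector
for pattern retrieval. Note the profile correlation is scale-free, so
its null distribution depends only on the number of groups: a 0.7 floor
is stringent over a dozen groups (null rate below 1%) but weak over
three (null rate ≈ 25%) — pattern queries should span enough sample
groups for the floor to be meaningful.

## Network integration

Interolog projection emits a target pair (a, b) for a reference PPI
(A, B) whenever a and b are orthologs of A and B with confidence ≥ 0.6.
The source phrase for the ortholog filter ("up to 60% bootstrap
support") is internally inconsistent with being "strict"; it is read as
*at least* 60%, and the threshold is configurable. Both endpoints must
individually pass (no pair-level score is defined in the inputs).
Duplicate projected pairs collapse with merged evidence; self-pairs are
kept but flagged, preserving information for the caller to drop.

The merged network is a `networkx.MultiGraph` whose edge key is the edge
type (`coexp_pos`, `coexp_neg`, `ppi_pred`, `mirna_target`), so one gene
pair can carry several relationship types but never two edges of one
type. Nodes are typed gene/miRNA by the `miR` id convention with an
explicit override table. Exports (SIF with `pp`/`nn`/`pd`/`mt` tokens,
GraphML with all attributes, TSV) order nodes and edges by sorted id,
making output byte-deterministic. miRNA–target pairs are consumed as
precomputed lists; target prediction is out of scope.

## Synthetic data generator

The generator emulates a multi-tissue, multi-genotype expression atlas:
4 tissues × 6 genotypes × 3 replicates = 72 samples (the reference
microarray series has 78 across the same kind of design), 500 genes of
which 3 planted modules × 10 genes, baselines near 8 on the log2 scale.
A module gene is `baseline + sqrt(r)·z_m(s) + noise_sd·sqrt(1−r)·ε`,
with `z_m` a per-module latent factor and everything i.i.d. standard
normal, so at `noise_sd = 1` the expected within-module pairwise PCC is
exactly the target r (default 0.9) and `noise_sd = 0` gives noiseless
modules. Background genes are independent noise. Promoter simulation
plants one concrete motif instance in a configurable carrier fraction of
uniform-random sequences.

What the generator does *not* emulate: probe- or batch-level microarray
artefacts, heteroscedastic intensity-dependent noise, realistic genomic
base composition, correlated background genes, or the long-tailed module
size distribution of real networks. Tests passing on these fixtures
demonstrate the algorithms' correctness and calibration under their own
assumptions, not performance on a real atlas; the published whole-genome
edge and module counts depend on the external microarray series and are
out of reach of desk-scale fixtures.

The transcribed CAD-network fixture carries printed PCC/MR values plus
the integer rank product recovered from each printed MR (MR² must be an
integer by construction), so tests can check MR identities exactly.

## Problem sizes and determinism

The test suite and acceptance script use desk-scale sizes chosen to keep
a full run in minutes: oracle sweeps over 200 random correlation tables
(≤ 30 genes) and 100 random graphs (≤ 25 nodes), 1000 null enrichment
queries against a universe of 4000, ten 500-promoter motif simulations
at 1000 background sets each, and ten 500-gene end-to-end recovery runs.
The null-query design (universe 4000, set 500, query 400) was chosen so
the discrete hypergeometric test's exact size (0.0497) sits as close to
the nominal 0.05 as the support allows, making the empirical-rate check
meaningful.

All randomness flows from explicit seeds (numpy `default_rng` /
`SeedSequence`; no global RNG state), every sort has a deterministic
tie-break, and the pipeline manifest records a SHA-256 checksum per
output so reruns are verifiable byte for byte.

## Known limitations

* Rank computation materializes dense n × n structures; the intended
  scale is 10³–10⁴ genes, not full transcriptomes on minimal hardware.
* CPM enumerates k-subsets of maximal cliques; pathologically dense
  graphs (huge cliques surviving the tier filters) can be expensive.
* Whether the source database computed MR from signed or absolute PCC
  ranks, and whether its tier levels were cumulative, is not stated in
  the available description; this package's choices are documented above
  and configurable where they matter.
* The enrichment q-values assume BH is the intended FDR procedure; the
  source names only "false discovery rate correction".
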