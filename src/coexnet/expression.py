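"""Expression-matrix preprocessing.

Loads gene x sample matrices of log2-scale expression values (microarray
intensities or log2 FPKM), collapses probe-level rows to genes, removes
low-variation genes, calls per-condition presence against an intensity
cut-off, and subsets samples by annotation groups.  Every downstream
stage (correlation, module detection, pattern screening) consumes the
matrices produced here.

Conventions
-----------
* Matrices are :class:`pandas.DataFrame` with genes as rows (index) and
  samples as columns.  Missing values are ``NaN`` (written as ``NA``).
* Sample annotations are a DataFrame indexed by ``sample_id`` with
  columns ``series_id``, ``tissue``, ``genotype``, ``treatment`` and
  ``replicate``.
* Probe maps are a :class:`pandas.Series` mapping probe_id -> gene_id.
"""

from __future__ import annotations

import logging
import math
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Default minimum (max - min) log2 range a gene must span to be kept.
#: log2(1.5) = 0.5849...; reported at two decimals as 0.58.
VARIATION_THRESHOLD: float = math.log2(1.5)

#: Default log2-intensity cut-off for calling a gene expressed in a
#: condition: expressed if any replicate exceeds it, not expressed if all
#: replicates fall below it.
PRESENCE_CUTOFF: float = 4.56

ANNOTATION_COLUMNS = ("series_id", "tissue", "genotype", "treatment", "replicate")


class MatrixParseError(ValueError):
    """A cell of an expression TSV could not be parsed as a number."""


class DuplicateGeneError(ValueError):
    """Duplicate row identifiers encountered without a probe map."""


class ProbeMapError(KeyError):
    """Probe rows present in the matrix but absent from the probe map."""


class InsufficientSamplesError(ValueError):
    """A sample selection matched fewer samples than the operation needs."""


# ---------------------------------------------------------------------------
# loading / writing
# ---------------------------------------------------------------------------

def load_expression_matrix(
    path,
    probe_map: pd.Series | None = None,
    transpose: bool = False,
) -> pd.DataFrame:
    """Read a TSV expression matrix (first column = gene/probe ids).

    Empty cells and ``NA`` are treated as missing.  Duplicate row ids are
    rejected unless *probe_map* is given, in which case rows are assumed
    to be probe-level and are collapsed with :func:`collapse_probes`.
    *transpose* accommodates files stored samples-as-rows.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if transpose:
        raw = raw.T
    values = pd.DataFrame(index=raw.index.astype(str), columns=raw.columns.astype(str),
                          dtype=float)
    for col in raw.columns:
        cell = raw[col].str.strip()
        missing = (cell == "") | (cell == "NA")
        parsed = pd.to_numeric(cell.where(~missing), errors="coerce")
        bad = parsed.isna() & ~missing
        if bad.any():
            row = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise MatrixParseError(
                f"malformed numeric cell at row {row!r}, column {col!r}: "
                f"{raw.loc[row, col]!r}"
            )
        values[col] = parsed
    if not values.columns.is_unique:
        dups = values.columns[values.columns.duplicated()].unique().tolist()
        raise MatrixParseError(f"duplicate sample ids: {dups}")
    if not values.index.is_unique:
        if probe_map is None:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise DuplicateGeneError(
                f"duplicate gene ids without a probe map: {dups}"
            )
    if probe_map is not None:
        values = collapse_probes(values, probe_map)
    values.index.name = "gene_id"
    return values


def write_expression_matrix(m: pd.DataFrame, path) -> None:
    """Write a matrix in the same TSV dialect ``load_expression_matrix`` reads."""
    m.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g")


def load_sample_annotation(path) -> pd.DataFrame:
    """Read a sample annotation TSV indexed by ``sample_id``."""
    ann = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in ann.columns:
        raise MatrixParseError("annotation table lacks a sample_id column")
    if ann["sample_id"].duplicated().any():
        raise MatrixParseError("annotation table repeats a sample_id")
    ann = ann.set_index("sample_id")
    if "replicate" in ann.columns:
        ann["replicate"] = ann["replicate"].astype(int)
        if (ann["replicate"] < 1).any():
            raise MatrixParseError("replicate indices must be positive integers")
    return ann


def load_probe_map(path) -> pd.Series:
    """Read a two-column probe_id -> gene_id TSV into a Series."""
    pm = pd.read_csv(path, sep="\t", dtype=str)
    pm.columns = ["probe_id", "gene_id"][: len(pm.columns)]
    if pm["probe_id"].duplicated().any():
        raise MatrixParseError("probe map repeats a probe_id")
    if (pm["gene_id"].str.len() == 0).any():
        raise MatrixParseError("probe map contains an empty gene_id")
    return pm.set_index("probe_id")["gene_id"]


# ---------------------------------------------------------------------------
# probe collapse
# ---------------------------------------------------------------------------

def collapse_probes(m: pd.DataFrame, probe_map: pd.Series) -> pd.DataFrame:
    """Collapse a probe-level matrix to one row per gene.

    For a gene measured by several probe sets the probe with the highest
    mean intensity across samples is retained whole, so the gene keeps a
    coherent profile; ties go to the lexicographically smaller probe id.
    Single-probe genes pass through unchanged.
    """
    unmapped = m.index.difference(probe_map.index)
    if len(unmapped):
        raise ProbeMapError(f"probes missing from probe map: {sorted(unmapped)}")
    means = m.mean(axis=1, skipna=True)
    order = pd.DataFrame({
        "gene_id": probe_map.reindex(m.index).to_numpy(),
        "mean": means.to_numpy(),
        "probe_id": m.index.to_numpy(),
    })
    # highest mean wins; ties -> smaller probe_id
    order = order.sort_values(["gene_id", "mean", "probe_id"],
                              ascending=[True, False, True], kind="mergesort")
    chosen = order.drop_duplicates("gene_id", keep="first")
    out = m.loc[chosen["probe_id"]]
    out.index = pd.Index(chosen["gene_id"], name="gene_id")
    return out.sort_index()


# ---------------------------------------------------------------------------
# filters and calls
# ---------------------------------------------------------------------------

def variation_filter(
    m: pd.DataFrame, threshold: float = VARIATION_THRESHOLD
) -> pd.DataFrame:
    """Keep genes whose (max - min) over non-missing samples is >= *threshold*.

    Genes with fewer than two non-missing values cannot show variation and
    are excluded (logged, not an error).  Idempotent for a fixed threshold.
    """
    if threshold < 0:
        raise ValueError("variation threshold must be >= 0")
    counts = m.notna().sum(axis=1)
    span = m.max(axis=1, skipna=True) - m.min(axis=1, skipna=True)
    keep = (counts >= 2) & (span >= threshold)
    removed = int((~keep).sum())
    if removed:
        log.info("variation_filter removed %d/%d genes (threshold %.2f)",
                 removed, len(m), threshold)
    return m.loc[keep]


def presence_call(
    m: pd.DataFrame,
    condition_samples: Iterable[str],
    cutoff: float = PRESENCE_CUTOFF,
) -> pd.Series:
    """Call each gene expressed / not_expressed / indeterminate in a condition.

    ``expressed``      -- any replicate value strictly above *cutoff*;
    ``not_expressed``  -- all replicate values strictly below *cutoff*;
    ``indeterminate``  -- neither (values exactly at the cut-off, or no
    non-missing replicate).
    """
    samples = list(condition_samples)
    if not samples:
        raise InsufficientSamplesError("condition_samples is empty")
    missing = [s for s in samples if s not in m.columns]
    if missing:
        raise KeyError(f"unknown samples: {missing}")
    sub = m[samples]
    any_above = (sub > cutoff).any(axis=1)
    all_below = ((sub < cutoff) | sub.isna()).all(axis=1) & sub.notna().any(axis=1)
    out = pd.Series("indeterminate", index=m.index, name="presence")
    out[all_below] = "not_expressed"
    out[any_above] = "expressed"
    return out


def subset_by_condition(
    m: pd.DataFrame,
    ann: pd.DataFrame,
    selector: Mapping[str, object] | Callable[[pd.Series], bool],
) -> pd.DataFrame:
    """Column-subset *m* to the samples matching *selector*, preserving order.

    *selector* is either a mapping of annotation column -> value (or list of
    values), all of which must hold, or a predicate over annotation rows.
    Used to build genotype- or tissue-specific networks; fewer than two
    matching samples is an error because no correlation can be formed.
    """
    if callable(selector):
        mask = ann.apply(selector, axis=1).astype(bool)
    else:
        mask = pd.Series(True, index=ann.index)
        for col, val in selector.items():
            if col not in ann.columns:
                raise KeyError(f"unknown annotation column: {col}")
            if isinstance(val, (list, tuple, set, frozenset)):
                mask &= ann[col].isin(list(val))
            else:
                mask &= ann[col] == val
    chosen = [s for s in m.columns if s in set(ann.index[mask])]
    if len(chosen) < 2:
        raise InsufficientSamplesError(
            f"selector matched {len(chosen)} sample(s); at least 2 required"
        )
    return m[chosen]
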