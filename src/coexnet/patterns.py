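"""Expression-pattern screening over sample groups.

Two per-gene z-score forms summarise a gene's behaviour across the
groups of a data series:

* tissue form:     z_g = (x̄_g - x̿) / stdev,  where x̄_g is the gene's
  mean over a group's replicates, x̿ the grand mean over the series'
  group means and *stdev* their standard deviation (a constant gene
  gets z = 0);
* treatment form:  z = log2(x̄_T / x̄_C) for a treated/control pair,
  computed on the linear intensity scale (stored values are log2, so
  means are taken after de-logging).

z-scores map to qualitative levels -- ``high`` (z >= z_hi, default +1),
``low`` (z <= z_lo, default -1), ``even`` otherwise -- and genes are
retrieved either by exact level match or by Pearson correlation of
their group-mean profile with the ideal pattern vector
(high = +1, even = 0, low = -1), thresholded at ``pcc_min`` (0.7).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LEVELS = ("high", "even", "low")
LEVEL_VALUE = {"high": 1.0, "even": 0.0, "low": -1.0}


class UndefinedZError(ValueError):
    """Treatment z-score undefined (non-positive linear-scale mean)."""


@dataclass(frozen=True)
class PatternSpec:
    """Desired level per ordered group, with thresholds and match mode."""

    groups: tuple[str, ...]
    levels: tuple[str, ...]
    z_hi: float = 1.0
    z_lo: float = -1.0
    mode: str = "correlation"          # or "threshold"
    pcc_min: float = 0.7
    group_column: str = "tissue"

    def __post_init__(self) -> None:
        if len(self.groups) != len(self.levels):
            raise ValueError("groups and levels differ in length")
        if not set(self.levels) <= set(LEVELS):
            raise ValueError(f"levels must be among {LEVELS}")
        if not self.z_lo < self.z_hi:
            raise ValueError("require z_lo < z_hi")
        if self.mode not in ("correlation", "threshold"):
            raise ValueError("mode must be 'correlation' or 'threshold'")

    @property
    def ideal_vector(self) -> np.ndarray:
        return np.array([LEVEL_VALUE[l] for l in self.levels])


def group_mean_matrix(m: pd.DataFrame, ann: pd.DataFrame,
                      group_column: str = "tissue",
                      groups: list[str] | None = None) -> pd.DataFrame:
    """Genes x groups matrix of replicate-mean expression."""
    if group_column not in ann.columns:
        raise ValueError(f"unknown annotation column: {group_column}")
    labels = ann.loc[[s for s in m.columns if s in ann.index], group_column]
    if groups is None:
        groups = list(pd.unique(labels))
    out = {}
    for grp in groups:
        cols = labels.index[labels == grp]
        if len(cols) == 0:
            raise ValueError(f"group {grp!r} matches no samples")
        out[grp] = m[list(cols)].mean(axis=1)
    return pd.DataFrame(out, index=m.index)


def tissue_zscores(group_means: pd.DataFrame) -> pd.DataFrame:
    """Tissue-form z per gene and group: (x̄ - x̿) / stdev over group means.

    Population (ddof=0) standard deviation over the group means of one
    series; rows with zero spread get z = 0 everywhere.
    """
    grand = group_means.mean(axis=1)
    sd = group_means.std(axis=1, ddof=0)
    z = group_means.sub(grand, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return z.fillna(0.0)


def treatment_zscore(m: pd.DataFrame, ann: pd.DataFrame, treated_group: str,
                     control_group: str,
                     group_column: str = "treatment") -> pd.Series:
    """Treatment-form z = log2(x̄_T / x̄_C) on the linear intensity scale."""
    means = group_mean_matrix(np.power(2.0, m), ann, group_column,
                              [treated_group, control_group])
    ratio = means[treated_group] / means[control_group]
    if (ratio <= 0).any() or not np.isfinite(ratio).all():
        bad = ratio.index[(ratio <= 0) | ~np.isfinite(ratio)].tolist()
        raise UndefinedZError(f"non-positive or undefined mean ratio for: {bad}")
    return np.log2(ratio).rename("z")


def classify_levels(z, z_hi: float = 1.0, z_lo: float = -1.0):
    """Map z to high (z >= z_hi) / low (z <= z_lo) / even; both inclusive.

    Accepts a scalar, Series or DataFrame and returns the same shape.
    """
    if not z_lo < z_hi:
        raise ValueError("require z_lo < z_hi")
    if np.isscalar(z):
        return "high" if z >= z_hi else ("low" if z <= z_lo else "even")
    if isinstance(z, pd.Series):
        out = pd.Series("even", index=z.index)
        return out.mask(z >= z_hi, "high").mask(z <= z_lo, "low")
    out = pd.DataFrame("even", index=z.index, columns=z.columns)
    return out.mask(z >= z_hi, "high").mask(z <= z_lo, "low")


def pattern_match(m: pd.DataFrame, ann: pd.DataFrame,
                  spec: PatternSpec) -> pd.DataFrame:
    """Genes matching the requested high/even/low pattern, ranked by score.

    The score is always the Pearson correlation between a gene's
    group-mean profile and the spec's ideal vector.  Selection depends
    on the mode: ``threshold`` keeps genes whose per-group levels equal
    the spec exactly; ``correlation`` keeps genes with score >= pcc_min.
    Output is sorted by score descending, ties by gene id.
    """
    missing = [g for g in spec.groups if g not in set(ann[spec.group_column])]
    if missing:
        raise ValueError(f"groups absent from annotation: {missing}")
    gm = group_mean_matrix(m, ann, spec.group_column, list(spec.groups))
    z = tissue_zscores(gm)
    levels = classify_levels(z, spec.z_hi, spec.z_lo)

    ideal = spec.ideal_vector
    centered = ideal - ideal.mean()
    if np.allclose(centered, 0):
        if spec.mode == "correlation":
            raise ValueError("all-even pattern has no direction; "
                             "use threshold mode")
        score = pd.Series(np.nan, index=m.index)
    else:
        X = gm.to_numpy() - gm.to_numpy().mean(axis=1, keepdims=True)
        denom = np.linalg.norm(X, axis=1) * np.linalg.norm(centered)
        with np.errstate(invalid="ignore", divide="ignore"):
            score = pd.Series(np.where(denom > 0, X @ centered / denom, np.nan),
                              index=m.index)

    if spec.mode == "threshold":
        want = pd.Series(dict(zip(spec.groups, spec.levels)))
        keep = (levels[list(spec.groups)] == want).all(axis=1)
    else:
        keep = score >= spec.pcc_min
    result = pd.DataFrame({"gene_id": m.index.to_numpy(),
                           "score": score.to_numpy()})
    for grp in spec.groups:
        result[f"z_{grp}"] = z[grp].to_numpy()
        result[f"level_{grp}"] = levels[grp].to_numpy()
    result = result[keep.to_numpy()]
    result = result.sort_values(["score", "gene_id"], ascending=[False, True],
                                kind="mergesort", ignore_index=True)
    return result
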