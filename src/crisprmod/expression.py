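"""Expression normalization, differential expression and qPCR quantification.

Covers the transcriptomic leg of the pipeline: quantile normalization of
linear-scale expression matrices, mimic-versus-control differential
expression summarised as percent change, ranked-list construction for
enrichment analysis, and relative quantification of qPCR Ct values by the
delta-delta-Ct method (fold change = 2^(-ddCt) after normalizing the target
gene to a reference gene and a control group).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "quantile_normalize",
    "differential_expression",
    "make_ranked_list",
    "delta_delta_ct",
]


@dataclass
class ExpressionMatrix:
    """Linear-scale gene x sample expression with a phenotype label per sample."""

    values: pd.DataFrame  # index = gene ids, columns = sample ids
    phenotypes: pd.Series  # sample id -> label (e.g. mimic / control)

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = self.values.columns.difference(self.phenotypes.index)
        if len(missing):
            raise ValueError(f"unlabelled samples: {list(missing)}")

    def samples_with(self, label: str) -> list:
        keep = self.phenotypes[self.phenotypes == label].index
        return [s for s in self.values.columns if s in set(keep)]


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every sample onto the cross-sample mean of sorted values.

    After normalization each column's sorted vector equals the reference
    (the row-wise mean of all columns' sorted vectors); within-column ranks
    are preserved and ties receive the mean of the reference values their
    rank span covers (average-rank convention).
    """
    if values.shape[1] < 2:
        warnings.warn("single sample: quantile normalization is the identity")
        return values.copy()
    arr = values.to_numpy(dtype=float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    ranks = values.rank(axis=0, method="average").to_numpy() - 1.0
    grid = np.arange(arr.shape[0], dtype=float)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        out[:, j] = np.interp(ranks[:, j], grid, reference)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def differential_expression(matrix: ExpressionMatrix, treated_label: str = "mimic",
                            control_label: str = "control",
                            altered_threshold: float = 20.0) -> pd.DataFrame:
    """Per-gene group means, treated/control ratio and percent change.

    percent_change = 100 * (treated - control) / control.  Genes whose control
    mean is zero have no defined ratio; they are flagged invalid and carry NaN
    ratio / percent change.  ``altered`` marks |percent change| strictly above
    ``altered_threshold`` (in percent).
    """
    treated = matrix.samples_with(treated_label)
    control = matrix.samples_with(control_label)
    if not treated or not control:
        raise ValueError("both phenotype groups must be present")
    cm = matrix.values[control].mean(axis=1)
    tm = matrix.values[treated].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = tm / cm
    valid = cm > 0
    ratio = ratio.where(valid)
    pct = 100.0 * (tm - cm) / cm.where(valid)
    direction = pd.Series("unchanged", index=cm.index)
    direction[pct > 0] = "up"
    direction[pct < 0] = "down"
    return pd.DataFrame({
        "control_mean": cm,
        "treated_mean": tm,
        "ratio": ratio,
        "percent_change": pct,
        "direction": direction,
        "valid": valid,
        "altered": pct.abs() > altered_threshold,
    })


def make_ranked_list(de: pd.DataFrame, metric: str = "log2_ratio") -> tuple[pd.Series, int]:
    """Descending ranked gene list for enrichment analysis.

    ``metric`` is ``log2_ratio`` (log2 of treated/control) or
    ``percent_change``.  Genes with undefined metric values (control mean 0)
    are excluded; the count of exclusions is returned alongside.  Ties are
    broken by gene id so the ordering is deterministic.
    """
    if metric == "log2_ratio":
        scores = np.log2(de["ratio"])
    elif metric == "percent_change":
        scores = de["percent_change"]
    else:
        raise ValueError(f"unknown ranking metric {metric!r}")
    scores = scores.replace([np.inf, -np.inf], np.nan)
    n_excluded = int(scores.isna().sum())
    scores = scores.dropna()
    order = sorted(scores.index, key=lambda g: (-scores[g], str(g)))
    return scores.loc[order].rename("score"), n_excluded


def delta_delta_ct(ct: pd.DataFrame, reference_gene: str, groups: pd.Series,
                   control_group: str = "control") -> pd.DataFrame:
    """Relative quantification 2^(-ddCt) of qPCR Ct values.

    ``ct`` is long-format with columns gene, sample, ct; ``groups`` maps
    sample -> group label.  Per sample, dCt = Ct_target - Ct_reference; the
    ddCt per gene is mean dCt (treated) - mean dCt (control) and the fold
    change is 2^(-ddCt).  A plate-wide Ct offset on any sample cancels in dCt.
    """
    required = {"gene", "sample", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    if (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    wide = ct.pivot_table(index="gene", columns="sample", values="ct")
    if reference_gene not in wide.index:
        raise ValueError(f"reference gene {reference_gene!r} absent from Ct table")
    ref = wide.loc[reference_gene]
    missing_ref = ref.index[ref.isna()]
    if len(missing_ref):
        raise ValueError(f"reference gene missing in sample(s): {list(missing_ref)}")
    dct = wide.drop(index=reference_gene).sub(ref, axis=1)
    control = [s for s in dct.columns if groups.get(s) == control_group]
    treated = [s for s in dct.columns if groups.get(s) is not None and groups[s] != control_group]
    if not control or not treated:
        raise ValueError("need samples in both the control group and a treated group")
    ddct = dct[treated].mean(axis=1) - dct[control].mean(axis=1)
    return pd.DataFrame({"ddct": ddct, "fold_change": np.power(2.0, -ddct)})
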