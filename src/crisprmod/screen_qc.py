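"""Guide-count normalization and sample-level QC for pooled CRISPR screens.

The screen's raw observable is an integer guide x sample count matrix with a
guide-to-gene map.  Counts are depth-normalized either by total count or by
the median-of-ratios method (ratios to the geometric-mean pseudo-reference
over guides detected in every sample), the default because it is robust to
composition shifts caused by strong selection.  QC reproduces the standard
battery: per-sample count summaries, CDF curves, PCA of log counts on the
first three components, and the pairwise Pearson matrix of log counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "GuideCountMatrix",
    "ScreenDesign",
    "NormalizedCounts",
    "QCReport",
    "normalize_counts",
    "qc_report",
]

VEHICLE_LABEL = "DMSO"


@dataclass
class GuideCountMatrix:
    """Integer guide x sample counts plus the guide -> gene map."""

    counts: pd.DataFrame  # index = guide ids, columns = sample ids
    gene_map: pd.Series  # guide id -> gene id

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate guide ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = self.counts.index.difference(self.gene_map.index)
        if len(missing):
            raise ValueError(f"guides without a gene: {list(missing[:5])}")

    @property
    def guide_ids(self):
        return self.counts.index

    @property
    def sample_ids(self):
        return self.counts.columns


@dataclass
class ScreenDesign:
    """Sample annotations: drug (or vehicle), dose and replicate index."""

    table: pd.DataFrame  # index = sample id; columns drug, dose, replicate
    vehicle_label: str = VEHICLE_LABEL

    def __post_init__(self) -> None:
        required = {"drug", "dose", "replicate"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"design table needs columns {sorted(required)}")
        if not (self.table["drug"] == self.vehicle_label).any():
            raise ValueError("design contains no vehicle sample")

    def vehicle_samples(self) -> list:
        return list(self.table.index[self.table["drug"] == self.vehicle_label])

    def screens(self) -> list[tuple]:
        """(drug, dose) conditions excluding vehicle and any day-0 sample."""
        mask = (self.table["drug"] != self.vehicle_label) & self.table["dose"].notna()
        sub = self.table.loc[mask, ["drug", "dose"]].drop_duplicates()
        return [tuple(r) for r in sub.itertuples(index=False)]

    def samples_for(self, drug, dose) -> list:
        mask = (self.table["drug"] == drug) & (self.table["dose"] == dose)
        return list(self.table.index[mask])


@dataclass
class NormalizedCounts:
    matrix: pd.DataFrame
    size_factors: pd.Series
    method: str
    gene_map: pd.Series | None = None


@dataclass
class QCReport:
    summaries: pd.DataFrame  # per sample: quartiles, zero fraction
    cdf: dict  # sample -> (sorted log counts, cumulative fraction)
    pca_coordinates: pd.DataFrame | None  # samples x first 3 PCs
    explained_variance_ratio: np.ndarray | None
    pearson: pd.DataFrame
    pseudocount: float
    warnings: list = field(default_factory=list)


def normalize_counts(counts: GuideCountMatrix | pd.DataFrame,
                     method: str = "median-ratio") -> NormalizedCounts:
    """Depth-normalize a guide count matrix.

    ``median-ratio``: size factor per sample is the median ratio to the
    geometric-mean reference over guides with nonzero counts in all samples,
    centred to geometric mean 1 across samples (making the map idempotent).
    ``total-count``: size factor is the sample total over the mean total, so
    normalized per-sample totals are equal.
    """
    gene_map = None
    if isinstance(counts, GuideCountMatrix):
        gene_map = counts.gene_map
        counts = counts.counts
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples to normalize")
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with all-zero counts: {list(zero.index)}")

    values = counts.to_numpy(dtype=float)
    if method == "total-count":
        size_factors = totals / totals.mean()
    elif method == "median-ratio":
        detected = (values > 0).all(axis=1)
        if not detected.any():
            raise ValueError("no guide detected in every sample; cannot build reference")
        ref = np.exp(np.log(values[detected]).mean(axis=1))
        ratios = values[detected] / ref[:, None]
        size_factors = pd.Series(np.median(ratios, axis=0), index=counts.columns)
        # centre to geometric mean 1 so renormalizing gives factors of exactly 1
        size_factors /= np.exp(np.log(size_factors).mean())
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    size_factors = size_factors.astype(float)
    if (size_factors <= 0).any():
        raise ValueError("non-positive size factor encountered")
    matrix = counts / size_factors
    return NormalizedCounts(matrix=matrix, size_factors=size_factors,
                            method=method, gene_map=gene_map)


def qc_report(norm: NormalizedCounts, design: ScreenDesign | None = None,
              pseudocount: float = 1.0) -> QCReport:
    """Sample-level QC battery on normalized counts.

    Pearson correlations and PCA are computed on log(norm + pseudocount);
    PCA uses guides as features with per-guide centering and no scaling.
    With fewer than 3 samples PCA is skipped and a warning recorded.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    m = norm.matrix
    if design is not None:
        extra = m.columns.difference(design.table.index)
        if len(extra):
            raise ValueError(f"samples missing from design: {list(extra)}")
    log_m = np.log(m + pseudocount)

    q = m.quantile([0.25, 0.5, 0.75]).T
    q.columns = ["q25", "median", "q75"]
    q["zero_fraction"] = (m == 0).mean(axis=0)
    q["total"] = m.sum(axis=0)

    cdf = {}
    n_guides = m.shape[0]
    frac = np.arange(1, n_guides + 1) / n_guides
    for s in m.columns:
        cdf[s] = (np.sort(log_m[s].to_numpy()), frac)

    warnings_list = []
    pca_coords = None
    evr = None
    if m.shape[1] >= 3:
        n_comp = min(3, m.shape[1] - 1, n_guides)
        pca = PCA(n_components=n_comp)
        coords = pca.fit_transform(log_m.T.to_numpy())
        pca_coords = pd.DataFrame(coords, index=m.columns,
                                  columns=[f"PC{i+1}" for i in range(n_comp)])
        evr = pca.explained_variance_ratio_
    else:
        warnings_list.append("fewer than 3 samples: PCA skipped")

    pearson = log_m.corr(method="pearson")
    return QCReport(summaries=q, cdf=cdf, pca_coordinates=pca_coords,
                    explained_variance_ratio=evr, pearson=pearson,
                    pseudocount=pseudocount, warnings=warnings_list)
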