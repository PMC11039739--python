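"""Fold-difference hit calling for drug-modifier CRISPR screens.

For every guide and every screen (drug x dose condition) the fold difference
FD = (mean normalized abundance under drug + c) / (mean under vehicle + c)
is computed, with pseudocount c.  A gene is enriched in a screen when at
least ``min_guides_passing`` of its guides exceed the FD threshold (strict
inequality).  Cross-screen intersection implements the "both drugs, either
dose" rule: a gene is a hit when, for every drug in the design, it is
enriched at one or more of that drug's doses.  Genes enriched in at least
``recurrence_min`` screens are flagged as top hits.  k-means clustering of
gene-level log2 FD profiles across screens groups common versus diverging
resistance mechanisms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .screen_qc import NormalizedCounts, ScreenDesign

__all__ = [
    "HitCallConfig",
    "GuideEnrichment",
    "HitIntersection",
    "ClusterAssignment",
    "guide_fold_differences",
    "call_gene_hits",
    "intersect_screens",
    "cluster_profiles",
    "rank_waterfall",
]


def screen_label(drug: str, dose) -> str:
    return f"{drug}@{dose:g}" if isinstance(dose, (int, float)) else f"{drug}@{dose}"


@dataclass(frozen=True)
class HitCallConfig:
    fd_threshold: float = 1.8
    min_guides_passing: int = 2
    pseudocount: float = 1.0
    recurrence_min: int = 3

    def __post_init__(self) -> None:
        if self.fd_threshold <= 0:
            raise ValueError("fd_threshold must be positive")
        if self.min_guides_passing < 1:
            raise ValueError("min_guides_passing must be at least 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")


@dataclass
class GuideEnrichment:
    """Per-guide FD (and log2 FD) for every screen, plus the guide -> gene map."""

    fd: pd.DataFrame  # guides x screen labels
    gene_map: pd.Series
    screens: list  # list of (drug, dose), order matches fd columns

    @property
    def log2_fd(self) -> pd.DataFrame:
        return np.log2(self.fd)


@dataclass
class HitIntersection:
    table: pd.DataFrame  # per gene: membership, n_screens, is_hit, is_top
    rule: str

    @property
    def hits(self) -> list:
        return list(self.table.index[self.table["is_hit"]])

    @property
    def top_hits(self) -> list:
        return list(self.table.index[self.table["is_top"]])


@dataclass
class ClusterAssignment:
    labels: pd.Series  # gene -> cluster index
    k: int
    wcss: float
    seed: int
    centers: np.ndarray = field(repr=False, default=None)


def guide_fold_differences(norm: NormalizedCounts, design: ScreenDesign,
                           pseudocount: float = 1.0) -> GuideEnrichment:
    """FD per guide per screen: replicate means of drug vs vehicle, pseudocounted."""
    vehicle = design.vehicle_samples()
    if not vehicle:
        raise ValueError("design has no vehicle samples")
    if norm.gene_map is None:
        raise ValueError("normalized counts carry no guide -> gene map")
    vehicle_mean = norm.matrix[vehicle].mean(axis=1)
    screens = design.screens()
    if not screens:
        raise ValueError("design has no drug screens")
    cols = {}
    for drug, dose in screens:
        samples = design.samples_for(drug, dose)
        drug_mean = norm.matrix[samples].mean(axis=1)
        cols[screen_label(drug, dose)] = (drug_mean + pseudocount) / (vehicle_mean + pseudocount)
    fd = pd.DataFrame(cols)
    if (fd.to_numpy() <= 0).any():
        raise ValueError("non-positive FD; use a positive pseudocount with zero counts")
    return GuideEnrichment(fd=fd, gene_map=norm.gene_map, screens=screens)


def call_gene_hits(enrich: GuideEnrichment, cfg: HitCallConfig = HitCallConfig()) -> pd.DataFrame:
    """Gene x screen table of guides passing FD > threshold and the enriched flag.

    Returns a long-format frame with columns gene, screen, n_guides,
    n_guides_passing, enriched.  The threshold comparison is strict, so guides
    sitting exactly at the threshold do not count.
    """
    passing = enrich.fd.gt(cfg.fd_threshold)
    genes = enrich.gene_map.loc[enrich.fd.index]
    n_pass = passing.groupby(genes.to_numpy()).sum()
    n_guides = enrich.fd.notna().groupby(genes.to_numpy()).sum()
    records = []
    for screen in enrich.fd.columns:
        for gene in n_pass.index:
            np_ = int(n_pass.loc[gene, screen])
            records.append({
                "gene": gene,
                "screen": screen,
                "n_guides": int(n_guides.loc[gene, screen]),
                "n_guides_passing": np_,
                "enriched": np_ >= cfg.min_guides_passing,
            })
    return pd.DataFrame.from_records(records)


def intersect_screens(calls: pd.DataFrame, cfg: HitCallConfig = HitCallConfig(),
                      rule: dict | None = None) -> HitIntersection:
    """Cross-screen hit intersection under the both-drug / either-dose rule.

    ``rule`` maps drug -> list of screen labels; by default it is derived from
    the screen labels themselves (label format ``drug@dose``).  A gene is a
    hit when enriched in at least one screen of every drug; it is a top hit
    when enriched in >= ``cfg.recurrence_min`` screens overall.
    """
    screens = list(calls["screen"].unique())
    if rule is None:
        rule = {}
        for s in screens:
            drug = s.rsplit("@", 1)[0]
            rule.setdefault(drug, []).append(s)
    else:
        for drug, labels in rule.items():
            unknown = set(labels) - set(screens)
            if unknown:
                raise ValueError(f"rule for {drug!r} references unknown screens {sorted(unknown)}")

    enriched = calls[calls["enriched"]]
    membership = enriched.groupby("gene")["screen"].agg(set)
    all_genes = calls["gene"].unique()
    rows = []
    for gene in sorted(all_genes):
        member = membership.get(gene, set())
        is_hit = all(any(s in member for s in labels) for labels in rule.values())
        rows.append({
            "gene": gene,
            "screens": ",".join(sorted(member)),
            "n_screens": len(member),
            "is_hit": is_hit and len(member) > 0,
            "is_top": len(member) >= cfg.recurrence_min,
        })
    table = pd.DataFrame(rows).set_index("gene")
    rule_str = " AND ".join(f"({' OR '.join(v)})" for v in rule.values())
    return HitIntersection(table=table, rule=rule_str)


def cluster_profiles(log2_fd: pd.DataFrame, k: int = 4, seed: int = 0) -> ClusterAssignment:
    """k-means (k-means++ init, Lloyd iterations) on gene x screen log2 FD profiles."""
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > log2_fd.shape[0]:
        raise ValueError(f"k={k} exceeds the number of genes ({log2_fd.shape[0]})")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(log2_fd.to_numpy(dtype=float))
    return ClusterAssignment(
        labels=pd.Series(labels, index=log2_fd.index, name="cluster"),
        k=k, wcss=float(km.inertia_), seed=seed, centers=km.cluster_centers_,
    )


def rank_waterfall(enrich: GuideEnrichment, screen: str) -> pd.DataFrame:
    """Guides ranked by descending FD for one screen, with log2 FD.

    Ties are broken by guide id (ascending), so the ordering is deterministic.
    """
    if screen not in enrich.fd.columns:
        raise KeyError(f"unknown screen {screen!r}")
    fd = enrich.fd[screen]
    table = pd.DataFrame({
        "guide": fd.index,
        "gene": enrich.gene_map.loc[fd.index].to_numpy(),
        "fd": fd.to_numpy(),
        "log2_fd": np.log2(fd.to_numpy()),
    })
    table = table.sort_values(["fd", "guide"], ascending=[False, True], kind="mergesort")
    table["rank"] = np.arange(1, len(table) + 1)
    return table.reset_index(drop=True)
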