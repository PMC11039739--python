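"""miRNA target triage funnel.

Candidate targets of a miRNA are narrowed in four stages: (1) keep genes
predicted to be bound (cumulative weighted context++ score at or below a
cutoff, default -0.01; more negative = stronger predicted repression);
(2) keep those downregulated in both cell lines' mimic-versus-control
differential expression; (3) keep those belonging to at least one designated
(e.g. cancer-associated) pathway; (4) keep those whose validation fold
change shows strictly more than a minimum fractional downregulation
(default 20%).  Each stage is a subset of the previous one, so stage counts
are monotone non-increasing along the funnel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "TriageResult",
    "filter_predictions",
    "intersect_downregulated",
    "pathway_filter",
    "validation_filter",
    "triage_funnel",
]


@dataclass
class TriageResult:
    predicted: set
    down_a: set  # predicted & downregulated in cell line A
    down_b: set
    intersection: set
    pathway_filtered: set
    validated: set | None = None
    unmapped_genes: set = field(default_factory=set)

    def stage_counts(self) -> dict:
        counts = {
            "predicted": len(self.predicted),
            "downregulated_A": len(self.down_a),
            "downregulated_B": len(self.down_b),
            "intersection": len(self.intersection),
            "pathway_filtered": len(self.pathway_filtered),
        }
        if self.validated is not None:
            counts["validated"] = len(self.validated)
        return counts

    def to_dict(self) -> dict:
        out = {stage: sorted(getattr(self, attr))
               for stage, attr in [("predicted", "predicted"),
                                   ("downregulated_A", "down_a"),
                                   ("downregulated_B", "down_b"),
                                   ("intersection", "intersection"),
                                   ("pathway_filtered", "pathway_filtered")]}
        if self.validated is not None:
            out["validated"] = sorted(self.validated)
        out["counts"] = self.stage_counts()
        return out


def filter_predictions(predictions: pd.DataFrame, cutoff: float = -0.01) -> set:
    """Genes whose context++ score is at or below ``cutoff`` (inclusive)."""
    if predictions.empty:
        return set()
    if not {"gene", "score"}.issubset(predictions.columns):
        raise ValueError("prediction table needs columns gene, score")
    keep = predictions.loc[predictions["score"] <= cutoff, "gene"]
    return set(keep)


def _downregulated(de: pd.DataFrame, threshold_pct: float) -> set:
    """Genes with percent change strictly below -threshold_pct."""
    valid = de["percent_change"].notna()
    return set(de.index[valid & (de["percent_change"] < -threshold_pct)])


def intersect_downregulated(de_a: pd.DataFrame, de_b: pd.DataFrame, predicted: set,
                            down_threshold_pct: float = 20.0) -> set:
    """Predicted genes downregulated in both differential-expression results.

    Genes absent from either result count as not downregulated.
    """
    down_a = _downregulated(de_a, down_threshold_pct)
    down_b = _downregulated(de_b, down_threshold_pct)
    return predicted & down_a & down_b


def pathway_filter(genes: set, pathway_members: dict, designated: set) -> tuple[set, set]:
    """Keep genes belonging to >= 1 designated pathway.

    ``pathway_members`` maps pathway id -> iterable of member genes;
    ``designated`` is the subset of pathway ids that count (e.g.
    cancer-associated).  Returns (kept genes, genes unmapped to any pathway).
    """
    for pid, members in pathway_members.items():
        if not members:
            raise ValueError(f"pathway {pid!r} has no members")
    mapped = set().union(*pathway_members.values()) if pathway_members else set()
    designated_members = set()
    for pid in designated:
        if pid not in pathway_members:
            raise ValueError(f"designated pathway {pid!r} missing from the map")
        designated_members |= set(pathway_members[pid])
    kept = genes & designated_members
    unmapped = genes - mapped
    return kept, unmapped


def validation_filter(fold_changes: pd.Series, min_down_fraction: float = 0.2) -> set:
    """Genes whose linear fold change shows > ``min_down_fraction`` downregulation.

    A fold change of 1 is unchanged; the comparison is strict, so a gene at
    exactly the boundary (fold = 1 - min_down_fraction) is excluded.
    """
    return set(fold_changes.index[fold_changes < (1.0 - min_down_fraction)])


def triage_funnel(predictions: pd.DataFrame, de_a: pd.DataFrame, de_b: pd.DataFrame,
                  pathway_members: dict, designated: set,
                  fold_changes: pd.Series | None = None,
                  prediction_cutoff: float = -0.01,
                  down_threshold_pct: float = 20.0,
                  min_down_fraction: float = 0.2) -> TriageResult:
    """Run the full funnel and return per-stage gene sets and counts."""
    predicted = filter_predictions(predictions, prediction_cutoff)
    down_a = predicted & _downregulated(de_a, down_threshold_pct)
    down_b = predicted & _downregulated(de_b, down_threshold_pct)
    intersection = down_a & down_b
    kept, unmapped = pathway_filter(intersection, pathway_members, designated)
    validated = None
    if fold_changes is not None:
        validated = kept & validation_filter(fold_changes, min_down_fraction)
    return TriageResult(predicted=predicted, down_a=down_a, down_b=down_b,
                        intersection=intersection, pathway_filtered=kept,
                        validated=validated, unmapped_genes=unmapped)
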