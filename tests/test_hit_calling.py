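"""Fold-difference calling, intersection rules and clustering oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from crisprmod import hit_calling, screen_qc
from crisprmod.hit_calling import HitCallConfig
from crisprmod.screen_qc import NormalizedCounts, ScreenDesign


def make_norm(values: dict, gene_map: dict) -> NormalizedCounts:
    df = pd.DataFrame(values)
    return NormalizedCounts(matrix=df, size_factors=pd.Series(1.0, index=df.columns),
                            method="none", gene_map=pd.Series(gene_map))


def make_design(rows: dict) -> ScreenDesign:
    table = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=["drug", "dose", "replicate"])
    return ScreenDesign(table=table)


class TestGuideFoldDifferences:
    design = make_design({
        "v1": ("DMSO", np.nan, 1), "v2": ("DMSO", np.nan, 2),
        "d1": ("brig", 300.0, 1), "d2": ("brig", 300.0, 2),
    })

    def test_fd_arithmetic(self):
        norm = make_norm({"v1": [100.0], "v2": [100.0], "d1": [190.0], "d2": [190.0]},
                         {0: "g"})
        enrich = hit_calling.guide_fold_differences(norm, self.design, pseudocount=0.0)
        assert enrich.fd.iloc[0, 0] == pytest.approx(1.9)

    def test_equal_means_give_unit_fd_for_any_pseudocount(self):
        norm = make_norm({"v1": [55.0], "v2": [55.0], "d1": [55.0], "d2": [55.0]},
                         {0: "g"})
        for c in (0.0, 1.0, 10.0):
            enrich = hit_calling.guide_fold_differences(norm, self.design, pseudocount=c)
            assert enrich.fd.iloc[0, 0] == pytest.approx(1.0)

    def test_pseudocount_guards_zero_vehicle(self):
        norm = make_norm({"v1": [0.0], "v2": [0.0], "d1": [190.0], "d2": [190.0]},
                         {0: "g"})
        enrich = hit_calling.guide_fold_differences(norm, self.design, pseudocount=1.0)
        assert enrich.fd.iloc[0, 0] == pytest.approx(191.0)

    def test_scale_invariance_without_pseudocount(self, small_screen):
        _, gcm, design, _ = small_screen
        norm = screen_qc.normalize_counts(gcm)
        fd1 = hit_calling.guide_fold_differences(norm, design, pseudocount=0.0).fd
        scaled = NormalizedCounts(matrix=norm.matrix * 13.0,
                                  size_factors=norm.size_factors, method=norm.method,
                                  gene_map=norm.gene_map)
        fd2 = hit_calling.guide_fold_differences(scaled, design, pseudocount=0.0).fd
        np.testing.assert_allclose(fd1, fd2, rtol=1e-10)


def calls_from_fds(fds: list, threshold=1.8, min_guides=2):
    """Gene call for one gene with the given guide FDs in one screen."""
    enrich = hit_calling.GuideEnrichment(
        fd=pd.DataFrame({"drug@300": fds}, index=[f"sg{i}" for i in range(len(fds))]),
        gene_map=pd.Series("gene1", index=[f"sg{i}" for i in range(len(fds))]),
        screens=[("drug", 300.0)],
    )
    cfg = HitCallConfig(fd_threshold=threshold, min_guides_passing=min_guides)
    return hit_calling.call_gene_hits(enrich, cfg)


class TestCallGeneHits:
    @pytest.mark.parametrize("fds,expected", [
        ([2.0, 1.9, 1.0], True),   # two guides above threshold
        ([1.9, 1.0, 1.0], False),  # only one
        ([1.8, 1.8, 1.8], False),  # boundary: strict > comparison
    ])
    def test_multi_guide_rule(self, fds, expected):
        calls = calls_from_fds(fds)
        assert bool(calls["enriched"].iloc[0]) is expected
        assert calls["n_guides"].iloc[0] == 3

    def test_hit_set_shrinks_as_threshold_rises(self, small_screen_enrichment):
        previous = None
        for tau in (1.5, 1.8, 2.5, 4.0):
            cfg = HitCallConfig(fd_threshold=tau)
            calls = hit_calling.call_gene_hits(small_screen_enrichment, cfg)
            hits = set(calls.loc[calls["enriched"], ["gene", "screen"]]
                       .itertuples(index=False))
            if previous is not None:
                assert hits <= previous
            previous = hits


def intersection_from_membership(membership: dict, recurrence_min=3):
    screens = ["brig@300", "brig@750", "cer@300", "cer@750"]
    rows = []
    for gene, member in membership.items():
        for s in screens:
            rows.append({"gene": gene, "screen": s, "n_guides": 3,
                         "n_guides_passing": 3 if s in member else 0,
                         "enriched": s in member})
    cfg = HitCallConfig(recurrence_min=recurrence_min)
    return hit_calling.intersect_screens(pd.DataFrame(rows), cfg)


class TestIntersectScreens:
    def test_both_drugs_either_dose(self):
        inter = intersection_from_membership({
            "g_both": {"brig@300", "cer@750"},
            "g_one_drug": {"brig@300", "brig@750"},
            "g_three": {"brig@300", "brig@750", "cer@300"},
            "g_none": set(),
        })
        t = inter.table
        assert bool(t.loc["g_both", "is_hit"])
        assert not bool(t.loc["g_one_drug", "is_hit"])
        assert bool(t.loc["g_three", "is_top"])  # >= 3 screens
        assert not bool(t.loc["g_both", "is_top"])
        assert not bool(t.loc["g_none", "is_hit"])

    def test_rule_with_unknown_screen_rejected(self):
        calls = pd.DataFrame([{"gene": "g", "screen": "brig@300", "n_guides": 3,
                               "n_guides_passing": 3, "enriched": True}])
        with pytest.raises(ValueError, match="unknown"):
            hit_calling.intersect_screens(calls, rule={"brig": ["nosuch@1"]})


class TestClusterProfiles:
    def test_separable_blobs_recovered(self, rng):
        blob1 = rng.normal(0.0, 0.1, size=(10, 3))
        blob2 = rng.normal(5.0, 0.1, size=(10, 3))
        data = pd.DataFrame(np.vstack([blob1, blob2]),
                            index=[f"g{i}" for i in range(20)])
        res = hit_calling.cluster_profiles(data, k=2, seed=0)
        first = set(res.labels.iloc[:10])
        second = set(res.labels.iloc[10:])
        assert len(first) == 1 and len(second) == 1 and first != second

    def test_determinism(self, rng):
        data = pd.DataFrame(rng.normal(size=(30, 4)))
        a = hit_calling.cluster_profiles(data, k=3, seed=5)
        b = hit_calling.cluster_profiles(data, k=3, seed=5)
        pd.testing.assert_series_equal(a.labels, b.labels)
        assert a.wcss == b.wcss

    def test_wcss_matches_exhaustive_two_partition_minimum(self, rng):
        points = rng.normal(size=(7, 2))
        data = pd.DataFrame(points)
        res = hit_calling.cluster_profiles(data, k=2, seed=1)
        best = np.inf
        for assignment in itertools.product([0, 1], repeat=7):
            assignment = np.array(assignment)
            if len(set(assignment)) < 2:
                continue
            wcss = 0.0
            for c in (0, 1):
                cluster = points[assignment == c]
                wcss += ((cluster - cluster.mean(axis=0)) ** 2).sum()
            best = min(best, wcss)
        assert res.wcss == pytest.approx(best, rel=1e-9)

    def test_k_larger_than_genes_rejected(self, rng):
        data = pd.DataFrame(rng.normal(size=(3, 2)))
        with pytest.raises(ValueError):
            hit_calling.cluster_profiles(data, k=5)


class TestRankWaterfall:
    @staticmethod
    def _enrich(fds, guides):
        return hit_calling.GuideEnrichment(
            fd=pd.DataFrame({"d@1": fds}, index=guides),
            gene_map=pd.Series("g", index=guides),
            screens=[("d", 1.0)],
        )

    def test_descending_order(self):
        table = hit_calling.rank_waterfall(
            self._enrich([1.0, 3.0, 2.0], ["sg1", "sg2", "sg3"]), "d@1")
        assert list(table["guide"]) == ["sg2", "sg3", "sg1"]

    def test_ties_broken_by_guide_id(self):
        table = hit_calling.rank_waterfall(
            self._enrich([2.0, 2.0, 2.0], ["sgC", "sgA", "sgB"]), "d@1")
        assert list(table["guide"]) == ["sgA", "sgB", "sgC"]

    def test_log2_column_consistent(self):
        table = hit_calling.rank_waterfall(
            self._enrich([0.5, 4.0], ["a", "b"]), "d@1")
        np.testing.assert_allclose(table["log2_fd"], np.log2(table["fd"]))
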