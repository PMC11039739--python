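"""Truth-recovery and calibration experiments on the synthetic generators.

Every experiment runs the full relevant pipeline stage on generated data
with planted ground truth and measures how well the planted signal is
recovered (or, for null configurations, how well false-positive behaviour
matches its nominal expectation).  These are the package's own benchmark
drivers; the problem sizes are the generators' default study conditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import expression, gsea, hit_calling, pharmacology, screen_qc, survival_util, synthetic
from .hit_calling import HitCallConfig

__all__ = [
    "hit_recovery",
    "null_calibration",
    "gsea_null_calibration",
    "loewe_offset_recovery",
    "ed50_recovery",
    "triage_recovery",
    "logrank_null_calibration",
    "logrank_power",
]


def _screen_hits(cfg: synthetic.ScreenSimConfig, call_cfg: HitCallConfig):
    gcm, design, truth = synthetic.simulate_screen(cfg)
    norm = screen_qc.normalize_counts(gcm)
    enrich = hit_calling.guide_fold_differences(norm, design,
                                                pseudocount=call_cfg.pseudocount)
    calls = hit_calling.call_gene_hits(enrich, call_cfg)
    inter = hit_calling.intersect_screens(calls, call_cfg)
    return enrich, calls, set(inter.hits), truth


def hit_recovery(seed: int = 0, n_genes: int = 1000, n_resistance: int = 20,
                 effect: float = 4.0, dispersion: float = 0.1,
                 depth: float = 500.0) -> dict:
    """Precision/recall of the FD > 1.8 / >=2-guide / both-drug pipeline."""
    cfg = synthetic.ScreenSimConfig(
        n_genes=n_genes, guides_per_gene=3, n_resistance_genes=n_resistance,
        resistance_effect=effect, dispersion=dispersion, mean_depth=depth,
        replicates_per_condition=2, seed=seed)
    _, _, hits, truth = _screen_hits(cfg, HitCallConfig())
    tp = len(hits & truth)
    precision = tp / len(hits) if hits else float("nan")
    recall = tp / len(truth)
    return {"precision": precision, "recall": recall,
            "n_hits": len(hits), "n_true": len(truth), "n_genes": n_genes}


def null_calibration(seed: int = 0, n_genes: int = 1000,
                     taus=(1.5, 1.8, 2.5)) -> dict:
    """False-call behaviour of the gene caller with no planted selection.

    For each screen and threshold the expected gene-level false-call rate is
    derived from the empirical per-guide FD tail mass q as
    P(>=2 of 3 guides pass) = 3 q^2 (1-q) + q^3; the observed number of
    enriched genes is compared against the central 95% binomial interval.
    Hit sets must also shrink monotonically as the threshold rises.
    """
    cfg = synthetic.ScreenSimConfig(n_genes=n_genes, n_resistance_genes=0,
                                    resistance_effect=1.0, seed=seed)
    gcm, design, _ = synthetic.simulate_screen(cfg)
    norm = screen_qc.normalize_counts(gcm)
    enrich = hit_calling.guide_fold_differences(norm, design, pseudocount=1.0)

    rows = []
    previous_sets = None
    monotone = True
    for tau in sorted(taus):
        call_cfg = HitCallConfig(fd_threshold=tau)
        calls = hit_calling.call_gene_hits(enrich, call_cfg)
        sets = {s: set(g.loc[g["enriched"], "gene"])
                for s, g in calls.groupby("screen")}
        if previous_sets is not None:
            monotone &= all(sets[s] <= previous_sets[s] for s in sets)
        previous_sets = sets
        for screen in enrich.fd.columns:
            q = float((enrich.fd[screen] > tau).mean())
            expected_rate = 3 * q**2 * (1 - q) + q**3
            observed = len(sets[screen])
            lo, hi = stats.binom.interval(0.95, n_genes, expected_rate)
            rows.append({"tau": tau, "screen": screen, "q_guide": q,
                         "expected_rate": expected_rate,
                         "observed": observed, "ci_low": int(lo), "ci_high": int(hi),
                         "within_ci": int(lo) <= observed <= int(hi)})
    table = pd.DataFrame(rows)
    return {"table": table, "all_within_ci": bool(table["within_ci"].all()),
            "monotone": monotone,
            "false_call_rate": float(
                table.loc[table["tau"] == 1.8, "observed"].mean() / n_genes)}


def gsea_null_calibration(seed: int = 0, n_sets: int = 1000, n_perm: int = 200,
                          list_size: int = 1000) -> dict:
    """Uniformity of the nominal permutation p under the null (KS test)."""
    rng = np.random.default_rng(seed)
    scores = np.sort(rng.normal(size=list_size))[::-1]
    ranked = pd.Series(scores, index=[f"g{i}" for i in range(list_size)])
    pvals = np.empty(n_sets)
    for i in range(n_sets):
        k = int(rng.integers(5, 11))
        members = set(rng.choice(ranked.index, size=k, replace=False))
        pvals[i] = gsea.gsea_enrichment(ranked, members, n_perm=n_perm,
                                        seed=rng).p_value
    ks = stats.kstest(pvals, "uniform")
    return {"ks_p": float(ks.pvalue), "ks_stat": float(ks.statistic),
            "n_sets": n_sets, "n_perm": n_perm}


def loewe_offset_recovery(seed: int = 0, offset: float = 15.0,
                          noise_sd: float = 2.0, n_matrices: int = 100,
                          tolerance: float = 2.0) -> dict:
    """Recovery of a planted interaction offset from noisy dose matrices.

    Each matrix is scored end to end: the monotherapy margins are refit with
    the 4PL model and the Loewe map recomputed from those fits.
    """
    expected_class = ("synergistic" if offset > 10 else
                      "antagonistic" if offset < -10 else "additive")
    recovered = []
    correct_class = 0
    rng = np.random.default_rng(seed)
    for _ in range(n_matrices):
        cfg = synthetic.DoseMatrixSimConfig(interaction_offset=offset,
                                            noise_sd=noise_sd,
                                            seed=int(rng.integers(2**31)))
        matrix = synthetic.simulate_dose_matrix(cfg)
        smap = pharmacology.synergy_map(matrix)  # refits margins internally
        recovered.append(smap.overall)
        correct_class += smap.classification == expected_class
    recovered = np.asarray(recovered)
    within = np.abs(recovered - offset) <= tolerance
    return {"mean_recovered": float(recovered.mean()),
            "fraction_within_tolerance": float(within.mean()),
            "fraction_correct_class": correct_class / n_matrices,
            "n_matrices": n_matrices}


def ed50_recovery(seed: int = 0, noise_cv: float = 0.10, n_fits: int = 100) -> dict:
    """ED50 relative error on the standard dose ladder, noiseless and noisy."""
    ladder = np.array([0.0, 1.0, 10.0, 30.0, 100.0, 300.0, 1000.0, 3000.0])
    truth = pharmacology.FourPL(1.0, 0.0, 100.0, 1.5)
    clean = pharmacology.fit_dose_response(doses=ladder, viability=truth(ladder))
    clean_err = abs(clean.ed50 - truth.ed50) / truth.ed50

    rng = np.random.default_rng(seed)
    errors = []
    for _ in range(n_fits):
        noisy = truth(ladder) * (1.0 + rng.normal(0.0, noise_cv, size=ladder.size))
        fit = pharmacology.fit_dose_response(doses=ladder,
                                             viability=np.clip(noisy, 0.0, None))
        if fit.converged:
            errors.append(abs(fit.ed50 - truth.ed50) / truth.ed50)
    return {"noiseless_rel_error": float(clean_err),
            "noisy_median_rel_error": float(np.median(errors)),
            "n_fits": n_fits, "n_converged": len(errors)}


def triage_recovery(seed: int = 0, noise_cv: float = 0.05,
                    n_genes: int = 2000, n_targets: int = 50) -> dict:
    """Recall of planted targets through the prediction + dual-downregulation join."""
    from . import triage as triage_mod

    cfg = synthetic.ExpressionSimConfig(n_genes=n_genes, n_true_targets=n_targets,
                                        downregulation_fraction=0.3,
                                        noise_cv=noise_cv, seed=seed)
    matrices, truth = synthetic.simulate_expression(cfg)
    des = [expression.differential_expression(m) for m in matrices.values()]
    genes = next(iter(matrices.values())).values.index
    preds = synthetic.simulate_target_predictions(truth, genes, n_decoys=100,
                                                  seed=seed)
    predicted = triage_mod.filter_predictions(preds)
    recovered = triage_mod.intersect_downregulated(des[0], des[1], predicted)
    recall = len(recovered & truth) / len(truth) if truth else float("nan")
    false_positives = len(recovered - truth)
    return {"recall": recall, "n_recovered": len(recovered),
            "false_positives": false_positives, "n_targets": n_targets,
            "exact": recovered == set(truth)}


def _simulated_logrank_p(cfg: synthetic.SurvivalSimConfig) -> float:
    cohort = synthetic.simulate_survival(cfg)
    cutoff = float(np.mean(cfg.mixture_means))
    cohort = survival_util.dichotomize_expression(cohort, absolute_cutoff=cutoff)
    if cohort["group"].nunique() < 2 or not cohort["event"].any():
        return float("nan")
    return survival_util.logrank_test(cohort).p_value


def logrank_null_calibration(seed: int = 0, n_reps: int = 500,
                             n_patients: int = 200) -> dict:
    """Uniformity of the log-rank p over repeated null simulations."""
    rng = np.random.default_rng(seed)
    pvals = [
        _simulated_logrank_p(synthetic.SurvivalSimConfig(
            n_patients=n_patients, hazard_ratio=1.0, censor_rate=0.1,
            seed=int(rng.integers(2**31))))
        for _ in range(n_reps)
    ]
    pvals = np.asarray([p for p in pvals if np.isfinite(p)])
    ks = stats.kstest(pvals, "uniform")
    return {"ks_p": float(ks.pvalue), "n_reps": int(pvals.size)}


def logrank_power(seed: int = 0, n_reps: int = 500, n_patients: int = 200,
                  hazard_ratio: float = 3.0, alpha: float = 0.05) -> dict:
    """Rejection rate at the given hazard ratio."""
    rng = np.random.default_rng(seed)
    rejections = 0
    n_valid = 0
    for _ in range(n_reps):
        p = _simulated_logrank_p(synthetic.SurvivalSimConfig(
            n_patients=n_patients, hazard_ratio=hazard_ratio, censor_rate=0.1,
            seed=int(rng.integers(2**31))))
        if np.isfinite(p):
            n_valid += 1
            rejections += p < alpha
    return {"power": rejections / n_valid, "n_reps": n_valid, "alpha": alpha}
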