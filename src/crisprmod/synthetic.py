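"""Synthetic inputs with planted ground truth for every pipeline stage.

Four generators emulate the data the pipeline consumes:

* a pooled CRISPR knockout screen — negative-binomial guide counts around a
  log-normally skewed library, with guides of planted resistance genes
  multiplicatively enriched under drug treatment but not vehicle;
* a two-cell-line mimic-versus-control expression experiment with a planted
  target set downregulated by a fixed fraction, log-normal noise at a stated
  coefficient of variation;
* a drug-combination dose matrix built from two 4PL monotherapies under
  exact Loewe additivity, plus a constant interaction offset (in viability
  percentage points) and Gaussian noise;
* a survival cohort whose expression covariate is a two-component Gaussian
  mixture and whose exponential event hazard is multiplied for the
  high-expression component.

All randomness flows through one seeded generator per call; identical
configurations and seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pharmacology
from .expression import ExpressionMatrix
from .pharmacology import FourPL
from .screen_qc import GuideCountMatrix, ScreenDesign, VEHICLE_LABEL

__all__ = [
    "ScreenSimConfig",
    "ExpressionSimConfig",
    "DoseMatrixSimConfig",
    "SurvivalSimConfig",
    "simulate_screen",
    "simulate_expression",
    "simulate_dose_matrix",
    "simulate_survival",
    "simulate_target_predictions",
]

DEFAULT_CONDITIONS = (
    ("brigatinib", 300.0),
    ("brigatinib", 750.0),
    ("ceritinib", 300.0),
    ("ceritinib", 750.0),
)

# library skew: log-normal spread of per-guide abundances
LIBRARY_SIGMA = 0.5


@dataclass(frozen=True)
class ScreenSimConfig:
    n_genes: int = 1000
    guides_per_gene: int = 3
    n_resistance_genes: int = 20
    resistance_effect: float = 4.0
    dispersion: float = 0.1
    mean_depth: float = 500.0
    conditions: tuple = DEFAULT_CONDITIONS
    replicates_per_condition: int = 2
    include_day0: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_resistance_genes > self.n_genes:
            raise ValueError("n_resistance_genes exceeds n_genes")
        if self.resistance_effect <= 0:
            raise ValueError("resistance_effect must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.guides_per_gene < 1 or self.replicates_per_condition < 1:
            raise ValueError("guides_per_gene and replicates_per_condition must be >= 1")


@dataclass(frozen=True)
class ExpressionSimConfig:
    n_genes: int = 2000
    n_true_targets: int = 50
    downregulation_fraction: float = 0.3
    noise_cv: float = 0.05
    n_replicates: int = 3
    cell_lines: tuple = ("cellA", "cellB")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.downregulation_fraction < 1.0:
            raise ValueError("downregulation_fraction must be in (0, 1)")
        if self.n_true_targets > self.n_genes:
            raise ValueError("n_true_targets exceeds n_genes")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")


@dataclass(frozen=True)
class DoseMatrixSimConfig:
    # default monotherapies and grids keep every combination cell on the
    # informative part of both curves (expected viability well inside the
    # [0, 110]% clip range), so a planted offset is representable everywhere
    fit_a: FourPL = field(default_factory=lambda: FourPL(1.0, 0.2, 100.0, 1.5))
    fit_b: FourPL = field(default_factory=lambda: FourPL(1.0, 0.2, 50.0, 1.2))
    dose_grid_a: tuple = (0.0, 30.0, 60.0, 120.0, 250.0, 500.0, 1000.0)
    dose_grid_b: tuple = (0.0, 30.0, 60.0, 120.0, 250.0, 500.0, 1000.0)
    interaction_offset: float = 0.0  # viability percentage points of extra killing
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for grid in (self.dose_grid_a, self.dose_grid_b):
            arr = np.asarray(grid, dtype=float)
            if (np.diff(arr) <= 0).any():
                raise ValueError("dose grids must be strictly increasing")
            if (arr < 0).any():
                raise ValueError("doses must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class SurvivalSimConfig:
    n_patients: int = 200
    mixture_means: tuple = (0.0, 4.0)
    mixture_sds: tuple = (1.0, 1.0)
    mixture_weight: float = 0.5  # probability of the high-expression component
    hazard_ratio: float = 3.0
    baseline_hazard: float = 0.02  # events per unit time for the low component
    censor_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must be in [0, 1)")
        if not 0.0 < self.mixture_weight < 1.0:
            raise ValueError("mixture_weight must be in (0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mean + dispersion * mean^2."""
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_screen(cfg: ScreenSimConfig) -> tuple[GuideCountMatrix, ScreenDesign, frozenset]:
    """Pooled-screen counts, design table and the planted resistance-gene set.

    Guide abundances are drawn log-normal (sigma 0.5, normalized to mean 1)
    to mimic uneven library representation.  In drug-treated samples the
    expected abundance of resistance-gene guides is multiplied by
    ``resistance_effect``; vehicle (and optional day-0) samples are
    unperturbed.  Counts are negative binomial around mean_depth x abundance.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"gene{i:05d}" for i in range(cfg.n_genes)]
    guides = [f"{g}_sg{j}" for g in genes for j in range(cfg.guides_per_gene)]
    gene_of_guide = np.repeat(np.arange(cfg.n_genes), cfg.guides_per_gene)
    gene_map = pd.Series([genes[i] for i in gene_of_guide], index=guides, name="gene")

    resistance_idx = rng.choice(cfg.n_genes, size=cfg.n_resistance_genes, replace=False)
    truth = frozenset(genes[i] for i in resistance_idx)
    resistance_guide = np.isin(gene_of_guide, resistance_idx)

    abundance = rng.lognormal(mean=-LIBRARY_SIGMA**2 / 2, sigma=LIBRARY_SIGMA, size=len(guides))
    base_mean = cfg.mean_depth * abundance

    design_rows = []
    columns = {}
    conditions = [(VEHICLE_LABEL, np.nan)] + [tuple(c) for c in cfg.conditions]
    if cfg.include_day0:
        mean = base_mean
        columns["day0"] = _nb_draw(rng, mean, cfg.dispersion)
        design_rows.append({"sample_id": "day0", "drug": "day0", "dose": np.nan, "replicate": 1})
    for drug, dose in conditions:
        for rep in range(1, cfg.replicates_per_condition + 1):
            if drug == VEHICLE_LABEL:
                sample = f"{VEHICLE_LABEL}_r{rep}"
                mean = base_mean
            else:
                sample = f"{drug}_{dose:g}_r{rep}"
                mean = np.where(resistance_guide, base_mean * cfg.resistance_effect, base_mean)
            columns[sample] = _nb_draw(rng, mean, cfg.dispersion)
            design_rows.append({"sample_id": sample, "drug": drug, "dose": dose, "replicate": rep})

    counts = pd.DataFrame(columns, index=guides)
    design = ScreenDesign(pd.DataFrame(design_rows).set_index("sample_id"))
    return GuideCountMatrix(counts=counts, gene_map=gene_map), design, truth


def simulate_expression(cfg: ExpressionSimConfig) -> tuple[dict, frozenset]:
    """Per-cell-line mimic-versus-control expression with a shared planted target set.

    Baseline gene means are log-normal; in the mimic arm true targets have
    expectation control mean x (1 - downregulation_fraction) before noise.
    Multiplicative log-normal noise with the configured CV is applied (mean
    preserved), so noise_cv = 0 reproduces the planted ratios exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"gene{i:05d}" for i in range(cfg.n_genes)]
    target_idx = rng.choice(cfg.n_genes, size=cfg.n_true_targets, replace=False)
    truth = frozenset(genes[i] for i in target_idx)
    is_target = np.zeros(cfg.n_genes, dtype=bool)
    is_target[target_idx] = True

    if cfg.noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(cfg.noise_cv**2)))
    else:
        sigma = 0.0

    matrices = {}
    for cell_line in cfg.cell_lines:
        base = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=cfg.n_genes)
        data = {}
        labels = {}
        for arm, label in (("control", "control"), ("mimic", "mimic")):
            mean = base if arm == "control" else np.where(
                is_target, base * (1.0 - cfg.downregulation_fraction), base)
            for rep in range(1, cfg.n_replicates + 1):
                sample = f"{cell_line}_{arm}_r{rep}"
                if sigma > 0:
                    noise = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=cfg.n_genes)
                else:
                    noise = 1.0
                data[sample] = mean * noise
                labels[sample] = label
        values = pd.DataFrame(data, index=genes)
        matrices[cell_line] = ExpressionMatrix(values=values, phenotypes=pd.Series(labels))
    return matrices, truth


def simulate_target_predictions(truth, all_genes, n_decoys: int = 100,
                                seed: int = 0) -> pd.DataFrame:
    """Synthetic target-prediction table (gene, context++ score).

    Planted true targets receive scores <= -0.01 (so the standard cutoff
    keeps them); ``n_decoys`` non-target genes also receive passing scores,
    and a further batch of genes gets scores above the cutoff.
    """
    rng = np.random.default_rng(seed)
    truth = sorted(truth)
    others = sorted(set(all_genes) - set(truth))
    decoys = list(rng.choice(others, size=min(n_decoys, len(others)), replace=False))
    rest = [g for g in others if g not in set(decoys)][: 2 * n_decoys]
    rows = [{"gene": g, "score": -0.01 - rng.uniform(0.0, 0.6)} for g in truth + decoys]
    rows += [{"gene": g, "score": rng.uniform(-0.009, 0.0)} for g in rest]
    return pd.DataFrame(rows)


def simulate_dose_matrix(cfg: DoseMatrixSimConfig) -> pd.DataFrame:
    """Observed viability grid (%) under Loewe additivity plus an interaction offset.

    Monotherapy margins follow the 4PL curves exactly (plus noise); every
    combination cell is the Loewe-expected viability minus
    ``interaction_offset`` percentage points (positive offset = extra
    killing), plus Gaussian noise, clipped to [0, 110] %.
    """
    rng = np.random.default_rng(cfg.seed)
    doses_a = np.asarray(cfg.dose_grid_a, dtype=float)
    doses_b = np.asarray(cfg.dose_grid_b, dtype=float)
    grid = np.empty((doses_a.size, doses_b.size))
    for i, da in enumerate(doses_a):
        for j, db in enumerate(doses_b):
            expected = pharmacology.loewe_expected(cfg.fit_a, cfg.fit_b, da, db)
            value = 100.0 * expected
            if da > 0 and db > 0:
                value -= cfg.interaction_offset
            grid[i, j] = value
    if cfg.noise_sd > 0:
        grid = grid + rng.normal(0.0, cfg.noise_sd, size=grid.shape)
    grid = np.clip(grid, 0.0, 110.0)
    return pd.DataFrame(grid, index=doses_a, columns=doses_b)


def simulate_survival(cfg: SurvivalSimConfig) -> pd.DataFrame:
    """Cohort table (id, time, event, expression, component).

    Expression is a two-component Gaussian mixture; event times are
    exponential with the baseline hazard multiplied by ``hazard_ratio`` for
    the high-expression component.  A ``censor_rate`` fraction of subjects
    (Bernoulli) is censored at a uniform fraction of their event time.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    component = rng.random(n) < cfg.mixture_weight  # True = high component
    means = np.where(component, cfg.mixture_means[1], cfg.mixture_means[0])
    sds = np.where(component, cfg.mixture_sds[1], cfg.mixture_sds[0])
    expression = rng.normal(means, sds)
    hazard = cfg.baseline_hazard * np.where(component, cfg.hazard_ratio, 1.0)
    event_time = rng.exponential(1.0 / hazard)
    censored = rng.random(n) < cfg.censor_rate
    u = rng.random(n)
    time = np.where(censored, event_time * u, event_time)
    time = np.maximum(time, 1e-9)
    return pd.DataFrame({
        "id": [f"P{i:04d}" for i in range(n)],
        "time": time,
        "event": ~censored,
        "expression": expression,
        "component": np.where(component, "high", "low"),
    })
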