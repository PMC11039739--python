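"""Dose-response fitting and Loewe-additivity synergy scoring.

Viability is expressed as a fraction of the vehicle (DMSO) control, so a
monotherapy curve runs from ``top`` (~1 at dose 0) down to ``bottom``.  The
combination null model is Loewe additivity: the expected response ``y`` at a
dose pair (dA, dB) solves

    dA / DA(y) + dB / DB(y) = 1

where ``D(y)`` is the inverse of the fitted monotherapy curve.  Synergy is
quantified in viability percentage points as expected-minus-observed, so
positive scores mean more killing than the additive expectation.  The overall
score over the combination cells is classified with the conventional bands:
> 10 synergistic, between -10 and 10 additive, < -10 antagonistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "FourPL",
    "ViabilitySeries",
    "DoseResponseFit",
    "SynergyMap",
    "normalize_viability",
    "fit_dose_response",
    "loewe_expected",
    "synergy_map",
]

# clamp for inverse-curve evaluation, keeps D(y) finite at the asymptotes
_EPS = 1e-6


@dataclass(frozen=True)
class FourPL:
    """Four-parameter logistic curve f(d) = bottom + (top-bottom)/(1+(d/ed50)^hill).

    ``hill > 0`` gives a decreasing viability curve: f(0) = top, f(inf) = bottom.
    ``ed50`` is the dose of half-maximal effect, in the same units as the doses.
    """

    top: float
    bottom: float
    ed50: float
    hill: float

    def __post_init__(self) -> None:
        if self.ed50 <= 0:
            raise ValueError(f"ed50 must be positive, got {self.ed50}")
        if self.bottom > self.top:
            raise ValueError("bottom must not exceed top")

    def __call__(self, dose):
        dose = np.asarray(dose, dtype=float)
        with np.errstate(divide="ignore"):
            ratio = np.where(dose > 0, (dose / self.ed50) ** self.hill, 0.0)
        return self.bottom + (self.top - self.bottom) / (1.0 + ratio)

    def inverse(self, y: float) -> float:
        """Dose producing response ``y``; y is clamped into (bottom, top)."""
        span = self.top - self.bottom
        lo = self.bottom + _EPS * span
        hi = self.top - _EPS * span
        y = min(max(y, lo), hi)
        return self.ed50 * ((self.top - y) / (y - self.bottom)) ** (1.0 / self.hill)


@dataclass
class ViabilitySeries:
    """Dose ladder with replicate raw signal and vehicle-normalized fractions."""

    doses: np.ndarray  # includes 0 = vehicle
    raw: pd.DataFrame  # rows = doses, columns = replicates
    viability: pd.DataFrame  # same shape, fraction of vehicle mean

    def mean_viability(self) -> pd.Series:
        return self.viability.mean(axis=1)


@dataclass
class DoseResponseFit:
    top: float
    bottom: float
    ed50: float
    hill: float
    residual_ss: float
    converged: bool
    message: str = ""

    @property
    def curve(self) -> FourPL:
        return FourPL(self.top, self.bottom, self.ed50, self.hill)

    def __call__(self, dose):
        return self.curve(dose)


@dataclass
class SynergyMap:
    scores: pd.DataFrame  # per-cell Loewe score, percentage points
    overall: float
    classification: str
    n_cells: int
    flagged_cells: list = field(default_factory=list)


def normalize_viability(raw: pd.DataFrame, doses=None, vehicle_dose: float = 0.0) -> ViabilitySeries:
    """Normalize raw signal (rows = doses, columns = replicates) to the vehicle mean.

    The vehicle row is identified by ``vehicle_dose`` in the index (or in
    ``doses`` if the index is not numeric).
    """
    if doses is None:
        doses = np.asarray(raw.index, dtype=float)
    else:
        doses = np.asarray(doses, dtype=float)
        raw = raw.set_axis(doses, axis=0)
    if vehicle_dose not in doses:
        raise ValueError(f"vehicle dose {vehicle_dose} not present in dose ladder")
    vehicle_mean = raw.loc[vehicle_dose].to_numpy(dtype=float).mean()
    if vehicle_mean <= 0:
        raise ValueError(f"vehicle mean signal must be positive, got {vehicle_mean}")
    viability = raw.astype(float) / vehicle_mean
    return ViabilitySeries(doses=doses, raw=raw, viability=viability)


def _fit_once(doses, response, p0, bounds):
    popt, _ = optimize.curve_fit(
        lambda d, top, bottom, log_ed50, hill: bottom
        + (top - bottom) / (1.0 + (d / np.exp(log_ed50)) ** hill),
        doses,
        response,
        p0=p0,
        bounds=bounds,
        maxfev=10000,
    )
    top, bottom, log_ed50, hill = popt
    fit = FourPL(top, bottom, float(np.exp(log_ed50)), hill)
    rss = float(np.sum((fit(doses) - response) ** 2))
    return fit, rss


def fit_dose_response(series: ViabilitySeries | None = None, *, doses=None,
                      viability=None, flat_tol: float = 0.05) -> DoseResponseFit:
    """Least-squares 4PL fit of mean viability over the dose ladder.

    Replicates are averaged before fitting.  Multi-start over a coarse grid of
    ED50 and Hill-slope initial values; the best residual wins.  A response
    whose dynamic range is below ``flat_tol`` is flagged non-determined rather
    than fitted.
    """
    if series is not None:
        doses = series.doses
        response = series.mean_viability().to_numpy(dtype=float)
    else:
        doses = np.asarray(doses, dtype=float)
        response = np.asarray(viability, dtype=float)
    nonzero = doses > 0
    if np.unique(doses[nonzero]).size < 4:
        raise ValueError("need at least 4 distinct nonzero doses for a 4PL fit")
    if response.max() - response.min() < flat_tol:
        return DoseResponseFit(
            top=float(response.mean()), bottom=float(response.mean()),
            ed50=float("nan"), hill=float("nan"), residual_ss=0.0,
            converged=False, message="flat response; ED50 not determined",
        )

    span = response.max() - response.min()
    lo, hi = doses[nonzero].min(), doses[nonzero].max()
    bounds = (
        [response.min() - span, response.min() - span, np.log(lo / 100.0), 0.05],
        [response.max() + span, response.max() + span, np.log(hi * 100.0), 10.0],
    )
    ed50_grid = np.exp(np.linspace(np.log(lo), np.log(hi), 5))
    best = None
    for ed50_0 in ed50_grid:
        for hill_0 in (0.5, 1.0, 2.0, 4.0):
            p0 = [response.max(), response.min(), np.log(ed50_0), hill_0]
            try:
                fit, rss = _fit_once(doses, response, p0, bounds)
            except (RuntimeError, ValueError):
                continue
            if best is None or rss < best[1]:
                best = (fit, rss)
    if best is None:
        return DoseResponseFit(
            top=float("nan"), bottom=float("nan"), ed50=float("nan"),
            hill=float("nan"), residual_ss=float("nan"), converged=False,
            message="4PL optimisation failed to converge from all starts",
        )
    fit, rss = best
    return DoseResponseFit(
        top=fit.top, bottom=fit.bottom, ed50=fit.ed50, hill=fit.hill,
        residual_ss=rss, converged=True,
    )


def loewe_expected(fit_a: FourPL | DoseResponseFit, fit_b: FourPL | DoseResponseFit,
                   dose_a: float, dose_b: float) -> float:
    """Loewe-additive expected viability fraction at a dose pair.

    Solves dA/DA(y) + dB/DB(y) = 1 by bracketed root-finding on the interval of
    responses both curves can produce.  Degenerate cases: a zero dose of one
    drug reduces to the other's monotherapy; identical curves satisfy the sham
    combination axiom y = f(dA + dB) automatically.
    """
    if isinstance(fit_a, DoseResponseFit):
        fit_a = fit_a.curve
    if isinstance(fit_b, DoseResponseFit):
        fit_b = fit_b.curve
    if dose_a < 0 or dose_b < 0:
        raise ValueError("doses must be non-negative")
    if dose_a == 0 and dose_b == 0:
        return float(fit_a(0.0))
    if dose_b == 0:
        return float(fit_a(dose_a))
    if dose_a == 0:
        return float(fit_b(dose_b))

    lo = max(fit_a.bottom, fit_b.bottom)
    hi = min(fit_a.top, fit_b.top)
    span = hi - lo
    if span <= 0:
        raise ValueError("monotherapy curves share no response range")
    y_lo, y_hi = lo + _EPS * span, hi - _EPS * span

    def g(y: float) -> float:
        return dose_a / fit_a.inverse(y) + dose_b / fit_b.inverse(y) - 1.0

    # g is increasing in y (less effect => smaller equivalent doses)
    if g(y_lo) >= 0:  # combination stronger than either curve can represent
        return float(y_lo)
    if g(y_hi) <= 0:
        return float(y_hi)
    return float(optimize.brentq(g, y_lo, y_hi, xtol=1e-10))


def synergy_map(matrix: pd.DataFrame, fit_a: FourPL | DoseResponseFit | None = None,
                fit_b: FourPL | DoseResponseFit | None = None) -> SynergyMap:
    """Score a dose-combination matrix against the Loewe expectation.

    ``matrix`` holds observed viability in percent, indexed by drug-A doses
    (rows) and drug-B doses (columns), with the monotherapies in the zero
    row/column.  Missing monotherapy fits are refit from the matrix margins.
    Per-cell score = 100 * expected_fraction - observed_percent; the overall
    score is the mean over cells where both doses are positive.
    """
    doses_a = np.asarray(matrix.index, dtype=float)
    doses_b = np.asarray(matrix.columns, dtype=float)
    if 0.0 not in doses_a or 0.0 not in doses_b:
        raise ValueError("dose matrix must include zero-dose monotherapy margins")
    if fit_a is None:
        fit_a = fit_dose_response(doses=doses_a, viability=matrix.loc[:, 0.0].to_numpy(float) / 100.0)
    if fit_b is None:
        fit_b = fit_dose_response(doses=doses_b, viability=matrix.loc[0.0, :].to_numpy(float) / 100.0)

    scores = pd.DataFrame(np.nan, index=matrix.index, columns=matrix.columns)
    flagged = []
    vals = []
    for da in doses_a:
        for db in doses_b:
            obs = matrix.loc[da, db]
            if pd.isna(obs):
                flagged.append((da, db))
                continue
            expected = loewe_expected(fit_a, fit_b, da, db)
            score = 100.0 * expected - float(obs)
            scores.loc[da, db] = score
            if da > 0 and db > 0:
                vals.append(score)
    if not vals:
        raise ValueError("no combination cells (both doses > 0) to score")
    overall = float(np.mean(vals))
    if overall > 10.0:
        classification = "synergistic"
    elif overall < -10.0:
        classification = "antagonistic"
    else:
        classification = "additive"
    if flagged:
        warnings.warn(f"{len(flagged)} missing cells excluded from the overall score")
    return SynergyMap(scores=scores, overall=overall, classification=classification,
                      n_cells=len(vals), flagged_cells=flagged)
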