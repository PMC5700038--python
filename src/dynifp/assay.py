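"""Receptor-assay mathematics.

Dual-luciferase normalization, Hill dose–response fitting, threshold-
concentration extraction (the ligand concentration producing 10 % of the
10 µM forskolin signalling output), E_max relative to wild type at the
highest applicable odorant concentration (250 µM), the four-way mutant
phenotype classification, and competitive-inhibition curve summarization
with log-linear IC50 interpolation.

Responses are handled as dimensionless fractions internally; percentages
appear only at I/O boundaries. Concentrations are µM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "LuciferaseWell",
    "DosePoint",
    "HillFit",
    "MutantClass",
    "CompetitionPoint",
    "CompetitionSummary",
    "HillFitError",
    "IC50NotReached",
    "normalize_luciferase",
    "hill_response",
    "fit_hill",
    "threshold_concentration",
    "relative_emax",
    "classify_mutant",
    "competition_summary",
]

MUTANT_CLASSES = ("hyperactive", "unaffected", "affected", "inactive", "unclassified")

#: Hill-coefficient bounds used during fitting.
HILL_N_BOUNDS = (0.3, 10.0)


class HillFitError(RuntimeError):
    """Hill fit failed to converge; carries per-start diagnostics."""


class IC50NotReached(ValueError):
    """No competition point at or below 50 % relative response."""


@dataclass(frozen=True)
class LuciferaseWell:
    """Raw firefly/Renilla luminescence counts for one well."""

    firefly: float
    renilla: float
    condition: str = ""

    def __post_init__(self):
        if self.renilla <= 0:
            raise ValueError("Renilla counts must be positive")

    @property
    def ratio(self) -> float:
        return self.firefly / self.renilla


def normalize_luciferase(well: LuciferaseWell, lowest_ratio: float,
                         highest_ratio: float) -> float:
    """Plate normalization (ratio − lowest) / (highest − lowest).

    The lowest/highest ratios come from the plate's negative (0.1 % DMSO)
    and positive (10 µM forskolin) controls. Values outside [0, 1] are
    reported unclipped.
    """
    if highest_ratio <= lowest_ratio:
        raise ValueError("highest_ratio must exceed lowest_ratio")
    return (well.ratio - lowest_ratio) / (highest_ratio - lowest_ratio)


@dataclass(frozen=True)
class DosePoint:
    """One (concentration, normalized response) point."""

    concentration: float  # µM
    normalized_response: float
    sem: float | None = None

    def __post_init__(self):
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill curve: baseline + amplitude · cⁿ / (ec50ⁿ + cⁿ)."""

    baseline: float
    amplitude: float
    ec50: float
    hill_n: float
    residual_norm: float

    def __post_init__(self):
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")
        if self.hill_n <= 0:
            raise ValueError("hill_n must be positive")

    def response(self, concentration) -> np.ndarray | float:
        return hill_response(concentration, self.baseline, self.amplitude,
                             self.ec50, self.hill_n)


def hill_response(c, baseline: float, amplitude: float, ec50: float,
                  hill_n: float):
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore"):
        val = baseline + amplitude * c ** hill_n / (ec50 ** hill_n + c ** hill_n)
    return float(val) if val.ndim == 0 else val


def fit_hill(points: Sequence[DosePoint]) -> HillFit:
    """Least-squares Hill fit with three documented starts.

    Starts: ec50 at the geometric mean of the positive concentrations and at
    the concentrations bracketing the half-rise, each with n = 1; bounds
    n ∈ [0.3, 10], ec50 within a 100-fold margin of the tested range. The
    best of the converged starts (smallest residual norm) is returned, so
    the fit is deterministic. All-equal responses give a zero-amplitude fit.
    """
    if len(points) < 4:
        raise ValueError("Hill fit needs at least 4 dose points")
    c = np.array([p.concentration for p in points], dtype=float)
    y = np.array([p.normalized_response for p in points], dtype=float)
    if np.ptp(y) == 0:
        pos = c[c > 0]
        mid = float(np.exp(np.mean(np.log(pos)))) if len(pos) else 1.0
        return HillFit(baseline=float(y[0]), amplitude=0.0, ec50=mid,
                       hill_n=1.0, residual_norm=0.0)

    pos = c[c > 0]
    if len(pos) == 0:
        raise ValueError("at least one positive concentration required")
    c_lo, c_hi = pos.min(), pos.max()
    geo_mid = float(np.exp(np.mean(np.log(pos))))
    half = y.min() + 0.5 * np.ptp(y)
    above = c[y >= half]
    half_rise = float(above[above > 0].min()) if np.any(above > 0) else geo_mid
    starts = [
        (y.min(), np.ptp(y), geo_mid, 1.0),
        (y.min(), np.ptp(y), half_rise, 1.0),
        (y.min(), np.ptp(y), geo_mid, 2.0),
    ]
    lb = [-np.inf, -np.inf, c_lo / 100.0, HILL_N_BOUNDS[0]]
    ub = [np.inf, np.inf, c_hi * 100.0, HILL_N_BOUNDS[1]]

    def resid(theta):
        return hill_response(c, *theta) - y

    best = None
    diagnostics = []
    for x0 in starts:
        x0 = np.clip(np.asarray(x0, dtype=float), lb, ub)
        try:
            sol = least_squares(resid, x0, bounds=(lb, ub), method="trf")
        except Exception as exc:  # pragma: no cover - scipy internal failure
            diagnostics.append(f"start {x0}: {exc}")
            continue
        if not sol.success:
            diagnostics.append(f"start {x0}: {sol.message}")
            continue
        norm = float(np.linalg.norm(sol.fun))
        if best is None or norm < best[0] - 1e-12:
            best = (norm, sol.x)
    if best is None:
        raise HillFitError("no start converged: " + "; ".join(diagnostics))
    norm, (b, a, ec50, n) = best
    return HillFit(baseline=float(b), amplitude=float(a), ec50=float(ec50),
                   hill_n=float(n), residual_norm=norm)


def threshold_concentration(fit: HillFit, forskolin_response: float = 1.0,
                            threshold_fraction: float = 0.10) -> float:
    """Concentration at which the fitted curve reaches 10 % of the forskolin
    (positive-control) response; the experimentally reported "threshold".

    The target response must lie strictly between the curve's baseline and
    plateau; otherwise the threshold is beyond the tested concentrations.
    """
    target = threshold_fraction * forskolin_response
    lo = min(fit.baseline, fit.baseline + fit.amplitude)
    hi = max(fit.baseline, fit.baseline + fit.amplitude)
    if not (lo < target < hi):
        raise ValueError("threshold beyond tested concentrations")
    # analytic inverse of the Hill curve
    f = (target - fit.baseline) / fit.amplitude
    return float(fit.ec50 * (f / (1.0 - f)) ** (1.0 / fit.hill_n))


def relative_emax(mutant_response_at_250: float,
                  wt_response_at_250: float) -> float:
    """Mutant response at 250 µM as a percentage of wild type."""
    if wt_response_at_250 <= 0:
        raise ValueError("wild-type response must be positive")
    return 100.0 * mutant_response_at_250 / wt_response_at_250


@dataclass(frozen=True)
class MutantClass:
    """Phenotype class with the margins that produced it."""

    label: str
    threshold_uM: float
    emax_percent: float

    def __post_init__(self):
        if self.label not in MUTANT_CLASSES:
            raise ValueError(f"unknown class {self.label!r}")


def classify_mutant(threshold_uM: float | None, emax_percent: float) -> MutantClass:
    """Four-way phenotype classification.

    hyperactive: E_max > 110 % of WT (any threshold);
    unaffected:  threshold 140–170 µM and E_max 80–110 %;
    affected:    threshold (170, 210] µM and E_max [40, 80) %;
    inactive:    threshold > 210 µM and E_max < 40 %.
    A threshold of ``None`` ("not reached") is treated as > 210 µM.
    Combinations matching no bin are returned as "unclassified" with both
    margins preserved for reporting.
    """
    t = float("inf") if threshold_uM is None else float(threshold_uM)
    e = float(emax_percent)
    if not np.isfinite(e):
        raise ValueError("emax must be finite")
    if e > 110:
        label = "hyperactive"
    elif t > 210 and e < 40:
        label = "inactive"
    elif 170 < t <= 210 and 40 <= e < 80:
        label = "affected"
    elif 140 <= t <= 170 and 80 <= e <= 110:
        label = "unaffected"
    else:
        label = "unclassified"
    return MutantClass(label=label, threshold_uM=t, emax_percent=e)


@dataclass(frozen=True)
class CompetitionPoint:
    """Relative response at one antagonist concentration (fixed agonist)."""

    antagonist_conc: float  # µM
    agonist_conc: float  # µM
    relative_response: float  # fraction of the no-antagonist response

    def __post_init__(self):
        if not 0 <= self.relative_response <= 1:
            raise ValueError("relative response must be in [0, 1]")
        if self.antagonist_conc < 0 or self.agonist_conc < 0:
            raise ValueError("concentrations must be non-negative")


@dataclass(frozen=True)
class CompetitionSummary:
    """Interpolated IC50 and monotonicity diagnostics."""

    ic50_uM: float
    exact_point: bool
    agonist_conc: float
    non_monotone_segments: tuple[tuple[float, float], ...]


def competition_summary(points: Sequence[CompetitionPoint]) -> CompetitionSummary:
    """Summarize an inhibition curve.

    The IC50 is the antagonist concentration giving 50 % relative response:
    an exact data point at 0.5 is preferred; otherwise the two bracketing
    points are interpolated log-linearly in concentration. Point order does
    not matter. Rising (non-monotone) segments are flagged.
    """
    if len(points) < 2:
        raise ValueError("at least two competition points required")
    pts = sorted(points, key=lambda p: p.antagonist_conc)
    agonist = pts[0].agonist_conc
    non_mono = tuple(
        (a.antagonist_conc, b.antagonist_conc)
        for a, b in zip(pts, pts[1:])
        if b.relative_response > a.relative_response
    )
    for p in pts:
        if p.relative_response == 0.5:
            return CompetitionSummary(ic50_uM=p.antagonist_conc, exact_point=True,
                                      agonist_conc=agonist,
                                      non_monotone_segments=non_mono)
    if all(p.relative_response > 0.5 for p in pts):
        raise IC50NotReached("all responses above 50%: IC50 not reached")
    for a, b in zip(pts, pts[1:]):
        if a.relative_response > 0.5 > b.relative_response:
            if a.antagonist_conc <= 0:
                ic50 = b.antagonist_conc
            else:
                la, lb = np.log(a.antagonist_conc), np.log(b.antagonist_conc)
                frac = (a.relative_response - 0.5) / (a.relative_response - b.relative_response)
                ic50 = float(np.exp(la + frac * (lb - la)))
            return CompetitionSummary(ic50_uM=ic50, exact_point=False,
                                      agonist_conc=agonist,
                                      non_monotone_segments=non_mono)
    raise IC50NotReached("no bracketing pair around 50% found")
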