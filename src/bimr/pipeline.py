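"""End-to-end bidirectional MR orchestration and reporting.

A *direction* is one exposure-outcome pair analysed with one exposure study
and one outcome study: orient -> significance filter -> LD clump ->
harmonize -> IVW / MR-Egger / weighted median -> heterogeneity, Egger
intercept, I^2_GX -> Cook's-distance outlier rerun.  ``run_bidirectional``
assembles both directions over a grid of trait pairs, computes the total
test count and attaches Bonferroni-adjusted significance thresholds.

Log-scale outcomes are reported as percent differences: a coefficient b on
100 x ln(outcome) corresponds to a 100 (exp(b/100) - 1) percent change.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .diagnostics import cooks_outliers, rerun_without
from .estimators import MRFit, egger, ivw, usable, weighted_median
from .exceptions import DataError, DomainError
from .instruments import (
    DEFAULT_CLUMP_R2,
    DEFAULT_CLUMP_WINDOW_BP,
    GENOME_WIDE_P,
    select_instruments,
)
from .summary_model import (
    HarmonizedInstrument,
    LDPair,
    VariantAssociation,
    harmonize,
    orient_to_trait_increasing,
)

__all__ = [
    "DirectionResult",
    "AnalysisReport",
    "standardize_exposure",
    "observational_association",
    "percent_difference",
    "bonferroni_threshold",
    "run_direction",
    "run_bidirectional",
]


def standardize_exposure(values: np.ndarray) -> np.ndarray:
    """Rescale so a 1-unit change is a 1-SD change (population SD, mean 0)."""
    v = np.asarray(values, dtype=float)
    sd = v.std()  # population convention (divide by n)
    if sd == 0:
        raise DomainError("exposure has zero variance; cannot standardize")
    return (v - v.mean()) / sd


def observational_association(
    outcome: np.ndarray,
    exposure: np.ndarray,
    covariates: np.ndarray | None = None,
    log_outcome: bool = False,
):
    """Observational linear regression, with and without confounder adjustment.

    Returns ``(unadjusted, adjusted)`` dicts of estimate / se / ci_low /
    ci_high / pvalue (adjusted is ``None`` when no covariates are given).
    With ``log_outcome`` the outcome is natural-log transformed first; if it
    contains zeros, ln(y + 1) is used and the offset recorded in the result.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    log_offset = 0.0
    if log_outcome:
        if np.any(y < 0):
            raise DataError("log transform requested but outcome has negative values")
        if np.any(y == 0):
            log_offset = 1.0
        y = np.log(y + log_offset)

    def _ols(design: np.ndarray) -> dict:
        n, p = design.shape
        if n <= p + 2:
            raise DataError(f"too few complete cases: n={n} for {p} parameters")
        res = sm.OLS(y, design).fit()
        if res.df_resid <= 0 or np.linalg.matrix_rank(design) < p:
            raise DataError("rank-deficient design: collinear covariate columns")
        ci = res.conf_int()[1]
        return {
            "estimate": float(res.params[1]),
            "se": float(res.bse[1]),
            "ci_low": float(ci[0]),
            "ci_high": float(ci[1]),
            "pvalue": float(res.pvalues[1]),
            "log_outcome": log_outcome,
            "log_offset": log_offset,
        }

    ones = np.ones_like(x)
    unadjusted = _ols(np.column_stack([ones, x]))
    adjusted = None
    if covariates is not None and np.size(covariates):
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        adjusted = _ols(np.column_stack([ones, x, c]))
    return unadjusted, adjusted


def percent_difference(beta_ln_x100: float) -> float:
    """Percent change implied by a coefficient reported in 100 x ln units."""
    return float(100.0 * (np.exp(beta_ln_x100 / 100.0) - 1.0))


def bonferroni_threshold(level: float, n_tests: int) -> float:
    """Bonferroni-adjusted significance threshold: level / n_tests."""
    if not (0 < level < 1):
        raise DomainError(f"level must lie in (0, 1), got {level}")
    if n_tests < 1:
        raise DomainError(f"n_tests must be >= 1, got {n_tests}")
    return level / n_tests


@dataclass
class DirectionResult:
    """Results for one exposure-outcome pair in one direction."""

    exposure_name: str
    outcome_name: str
    direction: str  # "X->Y" or "Y->X"
    estimable: bool
    reason: str | None = None
    n_snps: int = 0
    instrument_variants: list[str] = field(default_factory=list)
    fits: dict = field(default_factory=dict)  # method -> MRFit (or None)
    outliers: dict = field(default_factory=dict)
    outlier_rerun: dict = field(default_factory=dict)
    notes: dict = field(default_factory=dict)


@dataclass
class AnalysisReport:
    """Bidirectional results with multiplicity-adjusted thresholds."""

    directions: list[DirectionResult]
    n_tests: int
    bonferroni_05: float
    bonferroni_01: float
    notes: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d in self.directions:
            base = {
                "exposure": d.exposure_name,
                "outcome": d.outcome_name,
                "direction": d.direction,
                "n_snps": d.n_snps,
            }
            if not d.estimable:
                rows.append({**base, "method": "none", "reason": d.reason})
                continue
            for method, fit in d.fits.items():
                if fit is None:
                    rows.append({**base, "method": method, "reason": "not estimable"})
                    continue
                rows.append(
                    {
                        **base,
                        "method": method,
                        "estimate": fit.estimate,
                        "se": fit.se,
                        "ci_low": fit.ci_low,
                        "ci_high": fit.ci_high,
                        "pvalue": fit.pvalue,
                        "Q": fit.Q,
                        "I2": fit.I2,
                        "intercept": fit.intercept,
                        "intercept_pvalue": fit.intercept_pvalue,
                        "IGX2": fit.IGX2,
                    }
                )
        return pd.DataFrame(rows)

    def to_json(self, path=None) -> str:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if hasattr(o, "__dataclass_fields__"):
                return asdict(o)
            return str(o)

        payload = json.dumps(asdict(self), default=_default, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def run_direction(
    exposure_name: str,
    outcome_name: str,
    exposure_stats: Sequence[VariantAssociation],
    outcome_stats: Sequence[VariantAssociation],
    direction: str = "X->Y",
    ld: Iterable[LDPair] | None = None,
    p_threshold: float = GENOME_WIDE_P,
    r2_threshold: float = DEFAULT_CLUMP_R2,
    window_bp: int = DEFAULT_CLUMP_WINDOW_BP,
    wme_seed: int | None = 0,
    cooks_threshold: float | None = None,
) -> DirectionResult:
    """One MR direction: select instruments, harmonize, fit the suite, diagnose."""
    result = DirectionResult(
        exposure_name=exposure_name, outcome_name=outcome_name, direction=direction, estimable=False
    )
    oriented = orient_to_trait_increasing(exposure_stats)
    selected, meta = select_instruments(
        exposure_name, oriented, ld, p_threshold, r2_threshold, window_bp
    )
    if not selected:
        result.reason = "no genome-wide-significant instruments"
        return result
    harmonized = harmonize(selected, outcome_stats)
    kept = usable(harmonized)
    n_dropped = len(harmonized) - len(kept)
    if n_dropped:
        result.notes["harmonization_dropped"] = n_dropped
    if len(kept) < 2:
        result.reason = f"only {len(kept)} harmonized instrument(s); need >= 2"
        result.n_snps = len(kept)
        return result

    result.estimable = True
    result.n_snps = len(kept)
    result.instrument_variants = [h.variant_id for h in kept]
    result.fits["IVW"] = ivw(kept)
    for name, fn in (
        ("Egger", egger),
        ("WME", lambda k: weighted_median(k, seed=wme_seed)),
    ):
        try:
            result.fits[name] = fn(kept)
        except DomainError as exc:
            result.fits[name] = None
            result.notes[f"{name}_unavailable"] = str(exc)

    try:
        report = cooks_outliers(kept, model="IVW", threshold_rule=cooks_threshold)
        result.outliers = {
            "threshold": report.threshold,
            "flagged": report.flagged,
            "cooks_distance": report.cooks_distance,
            "funnel_points": report.funnel_points,
        }
        if report.flagged and len(kept) - len(report.flagged) >= 2:
            result.outlier_rerun = rerun_without(kept, report.flagged, wme_seed=wme_seed)
    except DomainError as exc:
        result.notes["outliers_unavailable"] = str(exc)
    return result


def run_bidirectional(
    forward: Sequence[tuple],
    reverse: Sequence[tuple],
    level: float = 0.05,
    **direction_kwargs,
) -> AnalysisReport:
    """Run every configured pair in both directions and assemble the report.

    ``forward`` and ``reverse`` are sequences of
    ``(exposure_name, outcome_name, exposure_stats, outcome_stats)`` tuples;
    the total test count is the number of pairs across both directions and
    sets the Bonferroni thresholds.  Every pair yields a populated row or an
    explicit not-estimable reason — the grid is always complete.
    """
    directions: list[DirectionResult] = []
    for tag, pairs in (("X->Y", forward), ("Y->X", reverse)):
        for exposure_name, outcome_name, exp_stats, out_stats in pairs:
            directions.append(
                run_direction(
                    exposure_name, outcome_name, exp_stats, out_stats,
                    direction=tag, **direction_kwargs,
                )
            )
    n_tests = len(directions)
    return AnalysisReport(
        directions=directions,
        n_tests=n_tests,
        bonferroni_05=bonferroni_threshold(level, n_tests),
        bonferroni_01=bonferroni_threshold(0.01, n_tests),
    )
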