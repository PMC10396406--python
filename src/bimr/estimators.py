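"""Two-sample Mendelian randomization estimators.

Given J harmonized instruments with SNP-exposure betas beta_Xj (se_Xj) and
SNP-outcome betas beta_Yj (se_Yj), the suite comprises:

* the per-SNP Wald ratio beta_Yj / beta_Xj with first-order delta SE;
* the inverse-variance weighted (IVW) estimate — weighted least squares of
  beta_Y on beta_X through the origin with weights 1/se_Yj^2 — under a
  multiplicative random-effects model: the fixed-effect SE is inflated by
  phi = max(1, sqrt(Q / (J - 1))) where Q is Cochran's heterogeneity
  statistic;
* MR-Egger: the same weighted regression with an unconstrained intercept;
  a non-zero intercept indicates unbalanced horizontal pleiotropy, and the
  I^2_GX statistic quantifies the regression-dilution (NOME violation) bias
  affecting the Egger slope;
* the weighted median of the Wald ratios, consistent while less than half of
  the instrument weight comes from invalid variants, with a parametric
  bootstrap SE.

Inference uses normal quantiles throughout (configurable at the call sites
that assemble confidence intervals).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import DomainError
from .summary_model import HarmonizedInstrument

__all__ = [
    "MRFit",
    "wald_ratio",
    "ivw",
    "egger",
    "igx2",
    "weighted_median",
    "heterogeneity",
    "usable",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass
class MRFit:
    """One estimator's output on one instrument set."""

    method: str  # IVW | Egger | WME | Wald
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    Q: float | None = None
    I2: float | None = None
    re_scale_phi: float | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pvalue: float | None = None
    IGX2: float | None = None
    notes: dict = field(default_factory=dict)


def usable(instruments: Sequence[HarmonizedInstrument]) -> list[HarmonizedInstrument]:
    """Instruments that survived harmonization (status kept or flipped)."""
    return [h for h in instruments if h.status in ("kept", "flipped")]


def _arrays(instruments: Sequence[HarmonizedInstrument]):
    kept = usable(instruments)
    bx = np.array([h.beta_exposure for h in kept], dtype=float)
    by = np.array([h.beta_outcome for h in kept], dtype=float)
    sx = np.array([h.se_exposure for h in kept], dtype=float)
    sy = np.array([h.se_outcome for h in kept], dtype=float)
    return kept, bx, by, sx, sy


def _normal_p(z: float) -> float:
    return float(2 * stats.norm.sf(abs(z)))


def _fit(method, est, se, n_snps, **extra) -> MRFit:
    z = est / se if se > 0 else math.inf * np.sign(est)
    return MRFit(
        method=method,
        estimate=float(est),
        se=float(se),
        ci_low=float(est - _Z95 * se),
        ci_high=float(est + _Z95 * se),
        pvalue=_normal_p(z) if se > 0 else 0.0,
        n_snps=n_snps,
        **extra,
    )


def wald_ratio(h: HarmonizedInstrument) -> MRFit:
    """Single-SNP causal estimate: the Wald ratio with delta-method SE."""
    if not abs(h.beta_exposure) > 0:
        raise DomainError(
            f"{h.variant_id}: zero exposure beta, Wald ratio undefined"
        )
    if h.beta_exposure < 0:
        raise DomainError(
            f"{h.variant_id}: negative exposure beta; orient the exposure study "
            "to trait-increasing alleles first (orient_to_trait_increasing)"
        )
    est = h.beta_outcome / h.beta_exposure
    se = h.se_outcome / abs(h.beta_exposure)
    return _fit("Wald", est, se, 1)


def heterogeneity(
    instruments: Sequence[HarmonizedInstrument], theta: float
) -> tuple[float, float]:
    """Cochran's Q and I^2 for SNP-specific estimates around a pooled ``theta``.

    Q = sum_j w_j (beta_Yj - theta beta_Xj)^2 with w_j = 1/se_Yj^2;
    I^2 = max(0, (Q - (J - 1)) / Q).
    """
    _, bx, by, _, sy = _arrays(instruments)
    j = bx.size
    if j < 2:
        raise DomainError(f"heterogeneity needs at least 2 instruments, got {j}")
    w = 1.0 / sy**2
    q = float(np.sum(w * (by - theta * bx) ** 2))
    i2 = max(0.0, (q - (j - 1)) / q) if q > 0 else 0.0
    return q, i2


def ivw(instruments: Sequence[HarmonizedInstrument]) -> MRFit:
    """Inverse-variance weighted estimate with multiplicative random effects.

    Weighted least squares of beta_Y on beta_X through the origin with
    weights 1/se_Y^2; algebraically the inverse-variance weighted mean of the
    Wald ratios.  The reported SE is the fixed-effect SE scaled by
    phi = max(1, sqrt(Q/(J-1))), so heterogeneity widens but never narrows
    the interval.
    """
    kept, bx, by, _, sy = _arrays(instruments)
    j = bx.size
    if j < 2:
        raise DomainError(
            f"IVW needs at least 2 instruments, got {j}; use wald_ratio for a single SNP"
        )
    w = 1.0 / sy**2
    sxx = float(np.sum(w * bx * bx))
    theta = float(np.sum(w * bx * by)) / sxx
    se_fixed = sxx ** -0.5
    q = float(np.sum(w * (by - theta * bx) ** 2))
    phi = max(1.0, math.sqrt(q / (j - 1)))
    i2 = max(0.0, (q - (j - 1)) / q) if q > 0 else 0.0
    return _fit(
        "IVW", theta, phi * se_fixed, j, Q=q, I2=i2, re_scale_phi=phi
    )


def egger(instruments: Sequence[HarmonizedInstrument]) -> MRFit:
    """MR-Egger regression: weighted fit of beta_Y on beta_X with intercept.

    Rows with a negative exposure beta are sign-flipped (both betas) so every
    instrument refers to the trait-increasing allele, which the Egger model
    requires.  The intercept estimates average directional pleiotropy; both
    SEs carry the multiplicative random-effects scale phi computed from the
    intercept-model Q with J - 2 degrees of freedom.
    """
    kept, bx, by, sx, sy = _arrays(instruments)
    j = bx.size
    if j < 3:
        raise DomainError(f"MR-Egger needs at least 3 instruments, got {j}")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2
    sw = float(np.sum(w))
    xbar = float(np.sum(w * bx)) / sw
    ybar = float(np.sum(w * by)) / sw
    sxx = float(np.sum(w * (bx - xbar) ** 2))
    if sxx == 0:
        raise DomainError("exposure betas are all identical; Egger slope undefined")
    slope = float(np.sum(w * (bx - xbar) * (by - ybar))) / sxx
    intercept = ybar - slope * xbar
    resid = by - intercept - slope * bx
    q = float(np.sum(w * resid**2))
    phi = max(1.0, math.sqrt(q / (j - 2)))
    se_slope = phi / math.sqrt(sxx)
    se_intercept = phi * math.sqrt(1.0 / sw + xbar**2 / sxx)
    i2 = max(0.0, (q - (j - 2)) / q) if q > 0 else 0.0
    fit = _fit(
        "Egger",
        slope,
        se_slope,
        j,
        Q=q,
        I2=i2,
        re_scale_phi=phi,
        intercept=float(intercept),
        intercept_se=float(se_intercept),
        intercept_pvalue=_normal_p(intercept / se_intercept),
    )
    if np.all(sx > 0):
        fit.IGX2 = igx2(instruments)
    return fit


def igx2(instruments: Sequence[HarmonizedInstrument]) -> float:
    """I^2_GX: regression-dilution statistic for MR-Egger.

    The weighted spread of the SNP-exposure betas relative to their standard
    errors: Q_GX = sum_j v_j (beta_Xj - mean)^2 with v_j = 1/se_Xj^2 and the
    v-weighted mean; I^2_GX = max(0, (Q_GX - (J-1))/Q_GX).  Values near 1
    indicate negligible attenuation of the Egger slope.
    """
    _, bx, _, sx, _ = _arrays(instruments)
    j = bx.size
    if j < 2:
        raise DomainError(f"I2_GX needs at least 2 instruments, got {j}")
    if np.any(~np.isfinite(sx)) or np.any(sx <= 0):
        raise DomainError("missing or non-positive se_exposure")
    v = 1.0 / sx**2
    mean = float(np.sum(v * bx)) / float(np.sum(v))
    q_gx = float(np.sum(v * (bx - mean) ** 2))
    return max(0.0, (q_gx - (j - 1)) / q_gx) if q_gx > 0 else 0.0


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median via linear interpolation of the standardized CDF.

    With values ordered ascending and weights normalized to sum 1, the
    standardized cumulative weight is s_j = cum(w)_j - w_j/2; the estimate
    interpolates the ordered values at s = 0.5.
    """
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - w / 2
    return float(np.interp(0.5, s, v))


def weighted_median(
    instruments: Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int | None = 0,
) -> MRFit:
    """Weighted median estimator with parametric-bootstrap SE.

    Per-SNP Wald ratios are weighted by 1/ratio_se^2.  The SE resamples
    beta_X and beta_Y from normal distributions centred at the observed betas
    with their reported SEs, recomputes the weighted median ``n_boot`` times
    and takes the standard deviation.  Instruments are sorted by variant_id
    before sampling, so the result does not depend on input order.
    """
    kept = sorted(usable(instruments), key=lambda h: h.variant_id)
    j = len(kept)
    if j < 3:
        raise DomainError(f"weighted median needs at least 3 instruments, got {j}")
    bx = np.array([h.beta_exposure for h in kept])
    by = np.array([h.beta_outcome for h in kept])
    sx = np.array([h.se_exposure for h in kept])
    sy = np.array([h.se_outcome for h in kept])
    if np.any(bx == 0):
        raise DomainError("zero exposure beta: Wald ratio undefined")
    ratios = by / bx
    w = (bx / sy) ** 2
    est = _weighted_median(ratios, w)

    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, j))
    by_b = rng.normal(by, sy, size=(n_boot, j))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios_b = by_b / bx_b
        w_b = (bx_b / sy) ** 2
    boot = np.empty(n_boot)
    for i in range(n_boot):
        boot[i] = _weighted_median(ratios_b[i], w_b[i])
    se = float(np.std(boot, ddof=1))
    q, i2 = heterogeneity(kept, est)
    return _fit("WME", est, se, j, Q=q, I2=i2)
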