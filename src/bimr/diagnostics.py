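"""Sensitivity machinery for the MR pipeline.

Covers four batteries: funnel data and Cook's-distance influence diagnostics
on the weighted regression underlying IVW or Egger; re-running the estimator
suite with flagged variants excluded; an analytic approximation to the bias
induced by sample overlap between the instrument-discovery and analysis
cohorts (winner's curse); and the split-sample strategy in which SNP-exposure
and SNP-outcome associations come from disjoint random halves of one cohort,
with the two directed estimates pooled by fixed-effect meta-analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .exceptions import DataError, DomainError
from .estimators import MRFit, egger, ivw, usable, weighted_median
from .summary_model import HarmonizedInstrument

__all__ = [
    "OutlierReport",
    "OverlapBias",
    "MetaResult",
    "cooks_outliers",
    "rerun_without",
    "overlap_bias",
    "split_indices",
    "split_sample_mr",
    "meta_fixed",
]


@dataclass
class OutlierReport:
    """Cook's distances, flagged variants and funnel-plot coordinates."""

    cooks_distance: dict[str, float]
    threshold: float
    flagged: list[str]
    funnel_points: list[tuple[str, float, float]]  # (variant_id, ratio, precision)


@dataclass
class OverlapBias:
    """Expected weak-instrument bias under sample overlap, and its type-1 impact."""

    overlap_fraction: float
    mean_F: float
    confounded_assoc: float
    se_mr: float
    expected_bias: float
    type1_error: float


@dataclass
class MetaResult:
    """Fixed-effect inverse-variance pooling of two estimates."""

    estimate_a: float
    se_a: float
    estimate_b: float
    se_b: float
    pooled_estimate: float
    pooled_se: float


def cooks_outliers(
    instruments: Sequence[HarmonizedInstrument],
    model: str = "IVW",
    threshold_rule: float | None = None,
) -> OutlierReport:
    """Cook's distance for every instrument in the weighted MR regression.

    ``model="IVW"`` uses the no-intercept regression of beta_Y on beta_X
    (p = 1 parameter); ``model="Egger"`` includes the intercept (p = 2).
    Weights are 1/se_Y^2.  The default threshold is 4/J.  Funnel points
    (Wald ratio, precision = 1/ratio_se) are always returned.
    """
    kept = usable(instruments)
    j = len(kept)
    if model not in ("IVW", "Egger"):
        raise DomainError(f"model must be IVW or Egger, got {model!r}")
    p = 1 if model == "IVW" else 2
    if j < p + 2:
        raise DomainError(f"Cook's distance for {model} needs at least {p + 2} instruments, got {j}")
    bx = np.array([h.beta_exposure for h in kept])
    by = np.array([h.beta_outcome for h in kept])
    sy = np.array([h.se_outcome for h in kept])
    sw = 1.0 / sy  # sqrt of the weights
    X = bx[:, None] if p == 1 else np.column_stack([np.ones(j), bx])
    Xw = X * sw[:, None]
    yw = by * sw
    xtx_inv = np.linalg.inv(Xw.T @ Xw)
    beta = xtx_inv @ (Xw.T @ yw)
    h_lev = np.einsum("ij,jk,ik->i", Xw, xtx_inv, Xw)
    resid = yw - Xw @ beta
    s2 = float(resid @ resid) / (j - p)
    if s2 == 0:
        d = np.zeros(j)
    else:
        d = resid**2 * h_lev / (p * s2 * (1 - h_lev) ** 2)
    threshold = 4.0 / j if threshold_rule is None else float(threshold_rule)
    ids = [h.variant_id for h in kept]
    flagged = [ids[i] for i in range(j) if d[i] > threshold]
    funnel = [
        (h.variant_id, h.ratio, 1.0 / h.ratio_se)
        for h in kept
        if np.isfinite(h.ratio_se) and h.ratio_se > 0
    ]
    return OutlierReport(
        cooks_distance=dict(zip(ids, d.tolist())),
        threshold=threshold,
        flagged=flagged,
        funnel_points=funnel,
    )


def rerun_without(
    instruments: Sequence[HarmonizedInstrument],
    excluded: Sequence[str],
    wme_seed: int | None = 0,
) -> dict[str, MRFit | None]:
    """Re-run the estimator suite with the listed variants excluded.

    Returns a dict with keys IVW/Egger/WME; an estimator whose minimum
    instrument count is no longer met maps to ``None`` with the reason stored
    in the surviving fits' notes.
    """
    kept_ids = {h.variant_id for h in usable(instruments)}
    unknown = set(excluded) - kept_ids
    if unknown:
        raise DomainError(f"excluded variants not in instrument set: {sorted(unknown)}")
    reduced = [h for h in instruments if h.variant_id not in set(excluded)]
    j = len(usable(reduced))
    if j < 2:
        raise DomainError(
            f"excluding {len(set(excluded))} variants leaves {j} instruments; IVW needs 2"
        )
    out: dict[str, MRFit | None] = {}
    out["IVW"] = ivw(reduced)
    out["IVW"].notes["sensitivity"] = f"excluded {sorted(set(excluded))}"
    for name, fn in (
        ("Egger", egger),
        ("WME", lambda r: weighted_median(r, seed=wme_seed)),
    ):
        try:
            fit = fn(reduced)
            fit.notes["sensitivity"] = f"excluded {sorted(set(excluded))}"
            out[name] = fit
        except DomainError:
            out[name] = None
    return out


def overlap_bias(
    o: float,
    mean_F: float,
    b_conf: float,
    se_mr: float,
    alpha: float = 0.05,
) -> OverlapBias:
    """Expected bias from overlap between discovery and analysis samples.

    The standard weak-instrument approximation: with overlap fraction ``o``,
    mean instrument F statistic ``mean_F`` and confounded observational
    association ``b_conf``, the MR estimate is pulled toward the confounded
    association by roughly ``o * b_conf / mean_F``.  The induced type-1 error
    of a nominal-``alpha`` two-sided test is
    P(|Z + bias/se_mr| > z_{1-alpha/2}) for standard-normal Z.
    """
    if not (0 <= o <= 1):
        raise DomainError(f"overlap fraction must lie in [0, 1], got {o}")
    if not mean_F > 0:
        raise DomainError(f"mean F must be positive, got {mean_F}")
    if not se_mr > 0:
        raise DomainError(f"se_mr must be positive, got {se_mr}")
    bias = o * b_conf / mean_F
    b = bias / se_mr
    z = stats.norm.ppf(1 - alpha / 2)
    type1 = float(stats.norm.cdf(-z - b) + stats.norm.sf(z - b))
    return OverlapBias(
        overlap_fraction=o,
        mean_F=mean_F,
        confounded_assoc=b_conf,
        se_mr=se_mr,
        expected_bias=bias,
        type1_error=type1,
    )


def split_indices(n: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Random split of ``range(n)`` into halves A (size ceil(n/2)) and B.

    Disjoint, exhaustive and deterministic given the seed; indices are
    returned sorted within each half.
    """
    if n < 2:
        raise DomainError(f"need at least 2 individuals to split, got {n}")
    perm = np.random.default_rng(seed).permutation(n)
    n_a = (n + 1) // 2
    return np.sort(perm[:n_a]), np.sort(perm[n_a:])


def meta_fixed(est_a: float, se_a: float, est_b: float, se_b: float) -> MetaResult:
    """Fixed-effect inverse-variance meta-analysis of two estimates."""
    if se_a <= 0 or se_b <= 0:
        raise DomainError("standard errors must be positive")
    wa, wb = 1.0 / se_a**2, 1.0 / se_b**2
    pooled = (wa * est_a + wb * est_b) / (wa + wb)
    pooled_se = (wa + wb) ** -0.5
    return MetaResult(est_a, se_a, est_b, se_b, pooled, pooled_se)


def _assoc_scan(y: np.ndarray, g: np.ndarray, covariates: np.ndarray | None):
    """Per-SNP simple linear regression of trait on dosage (plus covariates).

    Covariates are projected out of both trait and dosages (Frisch-Waugh),
    then the marginal slope, SE and two-sided t p-value are computed in
    closed form for every SNP at once.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    n = y.shape[0]
    df = n - 2
    if covariates is not None and np.size(covariates):
        c = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
        coef, *_ = np.linalg.lstsq(c, np.column_stack([y[:, None], g]), rcond=None)
        fitted = c @ coef
        y = y - fitted[:, 0]
        g = g - fitted[:, 1:]
        df = n - 2 - (c.shape[1] - 1)
    yc = y - y.mean()
    gc = g - g.mean(axis=0)
    sgg = (gc**2).sum(axis=0)
    syy = float(yc @ yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (gc.T @ yc) / sgg
        sse = np.maximum(syy - beta**2 * sgg, 0.0)
        se = np.sqrt(sse / df / sgg)
        t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df=df)
    return beta, se, np.clip(p, np.finfo(float).tiny, 1.0), sgg > 0


def split_sample_mr(
    individual_data,
    instrument: Sequence[str],
    estimator_config: Mapping | None = None,
    seed: int = 0,
) -> tuple[MRFit, MRFit, MetaResult]:
    """Split-sample MR: SNP-X from one half, SNP-Y from the other, both ways.

    ``individual_data`` is a cohort with ``exposure``, ``outcome``,
    ``genotypes`` (n x J) and ``variant_ids`` attributes (the synthetic
    module's ``CohortData``) or an equivalent mapping.  Per-SNP associations
    are estimated by simple linear regression separately in random halves A
    and B (adjusted for the cohort's covariates when present); the IVW
    estimate of A-exposure on B-outcome and its mirror are pooled by
    fixed-effect meta-analysis.
    """
    cfg = dict(estimator_config or {})
    data = individual_data
    try:
        x = np.asarray(data.exposure, dtype=float)
        y = np.asarray(data.outcome, dtype=float)
        g_all = np.asarray(data.genotypes, dtype=float)
        ids_all = list(data.variant_ids)
        cov = getattr(data, "covariates", None)
    except AttributeError as exc:
        raise DataError(f"individual_data lacks a required field: {exc}") from exc
    col = {v: i for i, v in enumerate(ids_all)}
    missing = [v for v in instrument if v not in col]
    if missing:
        raise DataError(f"instrument variants absent from genotype data: {missing}")
    g = g_all[:, [col[v] for v in instrument]]
    cov = np.asarray(cov, dtype=float) if cov is not None and np.size(cov) else None

    idx_a, idx_b = split_indices(len(x), seed)
    halves = {}
    for name, idx in (("A", idx_a), ("B", idx_b)):
        cov_h = cov[idx] if cov is not None else None
        bx, sx, _, okx = _assoc_scan(x[idx], g[idx], cov_h)
        by, sy, _, oky = _assoc_scan(y[idx], g[idx], cov_h)
        halves[name] = (bx, sx, by, sy, okx & oky)

    def _direction(exp_half: str, out_half: str) -> MRFit:
        bx, sx, _, _, ok1 = halves[exp_half]
        _, _, by, sy, ok2 = halves[out_half]
        ok = ok1 & ok2 & (bx != 0)
        hs = [
            HarmonizedInstrument(
                variant_id=instrument[i],
                beta_exposure=float(bx[i]),
                se_exposure=float(sx[i]),
                beta_outcome=float(by[i]),
                se_outcome=float(sy[i]),
                eaf_exposure=None,
                eaf_outcome=None,
                ratio=float(by[i] / bx[i]),
                ratio_se=float(sy[i] / abs(bx[i])),
                status="kept",
            )
            for i in range(len(instrument))
            if ok[i]
        ]
        fit = ivw(hs)
        fit.notes["direction"] = f"exposure from {exp_half}, outcome from {out_half}"
        return fit

    fit_ab = _direction("A", "B")
    fit_ba = _direction("B", "A")
    meta = meta_fixed(fit_ab.estimate, fit_ab.se, fit_ba.estimate, fit_ba.se)
    return fit_ab, fit_ba, meta
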