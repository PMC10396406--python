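"""Genetic instrument construction.

Filters SNP-trait associations at genome-wide significance, prunes them to
near-independence by greedy LD clumping (keep the most significant SNP, drop
correlated neighbours within a window), and quantifies instrument strength
via the multi-SNP F statistic and variance explained.  A confounder screen
tests every (SNP, confounder) pair and flags instruments failing a
Benjamini-Hochberg false-discovery-rate correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import DataError, DomainError
from .summary_model import LDPair, VariantAssociation

__all__ = [
    "InstrumentSet",
    "filter_genome_wide",
    "clump",
    "instrument_strength",
    "score_r2",
    "confounder_screen",
    "select_instruments",
]

GENOME_WIDE_P = 5e-8
DEFAULT_CLUMP_R2 = 0.1
DEFAULT_CLUMP_WINDOW_BP = 250_000


@dataclass
class InstrumentSet:
    """A selected instrument: variant list plus selection and strength metadata."""

    exposure_name: str
    variants: list[str]
    selection_params: tuple[float, float, int]  # (p_threshold, r2_threshold, window_bp)
    f_statistic: float | None = None
    variance_explained: float | None = None

    @property
    def n_snps(self) -> int:
        return len(self.variants)


def filter_genome_wide(
    records: Iterable[VariantAssociation], p_threshold: float = GENOME_WIDE_P
) -> list[VariantAssociation]:
    """Keep associations with p strictly below the genome-wide threshold."""
    return [r for r in records if r.pvalue < p_threshold]


def _ld_lookup(ld: Iterable[LDPair] | None) -> dict[frozenset, float]:
    table: dict[frozenset, float] = {}
    for pair in ld or ():
        key = frozenset((pair.variant_a, pair.variant_b))
        table[key] = max(pair.r2, table.get(key, 0.0))
    return table


def clump(
    records: Sequence[VariantAssociation],
    ld: Iterable[LDPair] | None = None,
    r2_threshold: float = DEFAULT_CLUMP_R2,
    window_bp: int = DEFAULT_CLUMP_WINDOW_BP,
) -> list[VariantAssociation]:
    """Greedy LD clumping.

    Repeatedly keeps the remaining variant with the smallest p-value (ties:
    ascending position, then variant_id) and discards every remaining variant
    on the same chromosome within +/- ``window_bp`` whose r^2 with it exceeds
    ``r2_threshold`` (strict).  An absent LD pair is treated as r^2 = 0.
    Returns the kept set in genomic order.
    """
    for r in records:
        if r.position is None:
            raise DataError(f"{r.variant_id}: missing position, required for clumping")
    table = _ld_lookup(ld)
    remaining = sorted(records, key=lambda r: (r.pvalue, r.position, r.variant_id))
    kept: list[VariantAssociation] = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        survivors = []
        for r in remaining:
            if (
                r.chromosome == best.chromosome
                and abs(r.position - best.position) <= window_bp
                and table.get(frozenset((r.variant_id, best.variant_id)), 0.0) > r2_threshold
            ):
                continue
            survivors.append(r)
        remaining = survivors
    return sorted(kept, key=lambda r: (r.chromosome, r.position, r.variant_id))


def instrument_strength(genotype_score_r2: float, n: int, k: int) -> tuple[float, float]:
    """Multi-SNP instrument F statistic and variance explained.

    F = R^2 (n - k - 1) / (k (1 - R^2)) for an instrument of ``k`` SNPs
    evaluated on ``n`` individuals; returns ``(F, R^2)``.
    """
    r2 = float(genotype_score_r2)
    if not (0 <= r2 < 1):
        raise DomainError(f"variance explained must lie in [0, 1), got {r2}")
    if k < 1 or n <= k + 1:
        raise DomainError(f"need n > k + 1 >= 2, got n={n}, k={k}")
    f = r2 * (n - k - 1) / (k * (1 - r2))
    return f, r2


def score_r2(
    phenotype: np.ndarray, genotypes: np.ndarray, weights: np.ndarray
) -> float:
    """Variance in a phenotype explained by a weighted allele score.

    The score for individual i is sum_j w_j g_ij; returns the squared Pearson
    correlation between phenotype and score.
    """
    y = np.asarray(phenotype, dtype=float)
    g = np.asarray(genotypes, dtype=float)
    w = np.asarray(weights, dtype=float)
    if y.ndim != 1 or g.shape[0] != y.shape[0] or g.shape[1] != w.shape[0]:
        raise DomainError("incompatible shapes for phenotype/genotypes/weights")
    if y.shape[0] <= 2:
        raise DomainError("need more than 2 individuals")
    score = g @ w
    if np.std(score) == 0:
        raise DomainError("weighted allele score has zero variance")
    r = np.corrcoef(y, score)[0, 1]
    return float(r * r)


def _pair_pvalues(genotypes: np.ndarray, confounders: pd.DataFrame) -> pd.DataFrame:
    """p-value of the marginal association of each SNP with each confounder.

    Continuous confounders use the simple-linear-regression slope t test;
    binary (0/1) confounders use the logistic score test, which needs no
    iterative fit.
    """
    g = np.asarray(genotypes, dtype=float)
    n, k = g.shape
    gc = g - g.mean(axis=0)
    sgg = (gc**2).sum(axis=0)
    if np.any(sgg == 0):
        j = int(np.flatnonzero(sgg == 0)[0])
        raise DataError(f"monomorphic genotype column {j}: no variance")
    out = {}
    for name in confounders.columns:
        c = np.asarray(confounders[name], dtype=float)
        if np.all(c == c[0]):
            raise DomainError(f"constant confounder column {name!r}")
        uniq = np.unique(c)
        if uniq.size == 2 and set(uniq) <= {0.0, 1.0}:
            # logistic score test of H0: no SNP effect, intercept-only null
            p0 = c.mean()
            u = gc.T @ (c - p0)
            var = p0 * (1 - p0) * sgg
            z = u / np.sqrt(var)
            out[name] = 2 * stats.norm.sf(np.abs(z))
        else:
            cc = c - c.mean()
            scc = (cc**2).sum()
            beta = (gc.T @ cc) / sgg
            sse = scc - beta**2 * sgg
            se = np.sqrt(np.maximum(sse, 0.0) / (n - 2) / sgg)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(se > 0, beta / se, np.inf)
            out[name] = 2 * stats.t.sf(np.abs(t), df=n - 2)
    return pd.DataFrame(out)


def confounder_screen(
    instrument: Sequence[VariantAssociation] | Sequence[str],
    confounders: pd.DataFrame | np.ndarray,
    genotypes: np.ndarray,
    fdr_q: float = 0.05,
) -> tuple[list[str], pd.DataFrame]:
    """Screen instrument SNPs for association with measured confounders.

    One marginal test per (SNP, confounder) pair; Benjamini-Hochberg applied
    jointly across all pairs at level ``fdr_q``.  A variant is flagged when
    any of its pairs is rejected.  Returns ``(flagged_variant_ids, qvalues)``
    where ``qvalues`` is a variants x confounders table of BH-adjusted
    p-values.
    """
    ids = [v.variant_id if isinstance(v, VariantAssociation) else str(v) for v in instrument]
    conf = confounders if isinstance(confounders, pd.DataFrame) else pd.DataFrame(
        np.asarray(confounders), columns=[f"confounder_{i}" for i in range(np.atleast_2d(confounders).shape[1])]
    )
    g = np.asarray(genotypes, dtype=float)
    if g.shape[1] != len(ids):
        raise DataError(
            f"genotype matrix has {g.shape[1]} columns but {len(ids)} instrument variants"
        )
    pvals = _pair_pvalues(g, conf)
    flat = pvals.to_numpy().ravel()
    reject, qflat, _, _ = multipletests(flat, alpha=fdr_q, method="fdr_bh")
    qvalues = pd.DataFrame(
        qflat.reshape(pvals.shape), index=ids, columns=pvals.columns
    )
    rejected = reject.reshape(pvals.shape)
    flagged = [ids[i] for i in range(len(ids)) if rejected[i].any()]
    return flagged, qvalues


def select_instruments(
    exposure_name: str,
    records: Sequence[VariantAssociation],
    ld: Iterable[LDPair] | None = None,
    p_threshold: float = GENOME_WIDE_P,
    r2_threshold: float = DEFAULT_CLUMP_R2,
    window_bp: int = DEFAULT_CLUMP_WINDOW_BP,
) -> tuple[list[VariantAssociation], InstrumentSet]:
    """Significance filter followed by LD clumping; returns kept records and metadata."""
    significant = filter_genome_wide(records, p_threshold)
    kept = clump(significant, ld, r2_threshold, window_bp)
    meta = InstrumentSet(
        exposure_name=exposure_name,
        variants=[r.variant_id for r in kept],
        selection_params=(p_threshold, r2_threshold, window_bp),
    )
    return kept, meta
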