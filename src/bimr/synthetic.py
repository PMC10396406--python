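"""Synthetic two-cohort GWAS generator with known ground truth.

The generative model mirrors the structural assumptions of a pseudo
two-sample bidirectional MR study:

    U  =  N(0, 1)  +  sum_c  b_c G_c            (confounder, optionally genetic)
    X  =  sum_j gamma_j G_j  +  q_U U  +  eps_X  (exposure)
    Y  =  theta X  +  sum_j alpha_j G_j  +  sum_m delta_m G_m  +  r_U U  +  eps_Y

with eps terms standard normal.  G_j are exposure-instrument SNPs (dosages
Binomial(2, MAF_j)), alpha_j direct (pleiotropic) SNP-outcome effects drawn
under a balanced / directional / correlated regime, and G_m a disjoint set of
SNPs acting directly on the outcome — the instruments for the reverse MR
direction.  LD blocks are induced by copying a block-anchor genotype with
probability sqrt(r^2), which yields pairwise genotype correlation sqrt(r^2)
and hence r^2 as targeted (block members share the anchor's MAF).  Two
cohorts of configurable size may share their first floor(o * n) individuals,
emulating sample overlap between instrument discovery and outcome analysis.

Positively skewed outcome traits are produced by exponentiating the linear
predictor (log-normal) or by a Poisson draw with log link (count trait with a
floor at zero), so the pipeline's log-transform and percent-difference
reporting paths can be exercised end to end.

Every draw comes from one seeded generator: each function is a pure function
of (config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import ConfigurationError
from .summary_model import VariantAssociation

__all__ = [
    "SimulationConfig",
    "VariantPanel",
    "CohortData",
    "simulate_cohorts",
    "gwas",
    "make_two_sample_dataset",
]

# Ordered, non-identical allele pairs; palindromic = {A,T} or {C,G}.
_ALL_PAIRS = [
    (a, b) for a in "ACGT" for b in "ACGT" if a != b
]
_NON_PALINDROMIC_PAIRS = [
    (a, b) for (a, b) in _ALL_PAIRS if {a, b} not in ({"A", "T"}, {"C", "G"})
]


@dataclass
class SimulationConfig:
    """Full parameterization of the generative model.

    Defaults describe a realistic well-powered two-sample setting: 50
    instrument SNPs with common allele frequencies, two cohorts of 20 000,
    no overlap, a causal effect of 0.2 SD outcome per SD exposure, per-SNP
    exposure effects of mean 0.1 and sd 0.05 (so instruments are strong but
    heterogeneous in strength), moderate confounding, and no pleiotropy.
    """

    n_snps: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_exposure_cohort: int = 20_000
    n_outcome_cohort: int = 20_000
    overlap_fraction: float = 0.0
    causal_effect: float = 0.2
    gamma_dist: tuple[float, float] = (0.1, 0.05)
    pleiotropy_mode: str = "none"  # none | balanced | directional | correlated
    alpha_params: tuple[float, float, float] = (0.0, 0.01, 0.0)  # (mean, sd, rho with gamma)
    pleiotropy_fraction: float = 1.0  # fraction of instrument SNPs receiving alpha
    confounder_effects: tuple[float, float] = (0.3, 0.3)  # (q_U on X, r_U on Y)
    n_confounder_snps: int = 0
    confounder_snp_effect: float = 0.15
    n_outcome_snps: int = 0  # SNPs acting directly on Y: reverse-direction instruments
    delta_dist: tuple[float, float] = (0.1, 0.05)
    ld_blocks: Sequence[tuple[int, float]] = field(default_factory=tuple)  # (size, r2)
    outcome_transform: str = "identity"  # identity | log_normal_skew | poisson_count
    pc_covariates: int = 0
    pc_effect: float = 0.05
    allow_palindromic: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_fraction <= 1):
            raise ConfigurationError("overlap_fraction must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.pleiotropy_mode not in ("none", "balanced", "directional", "correlated"):
            raise ConfigurationError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if abs(self.alpha_params[2]) > 1:
            raise ConfigurationError("pleiotropy-gamma correlation must lie in [-1, 1]")
        if not (0 <= self.pleiotropy_fraction <= 1):
            raise ConfigurationError("pleiotropy_fraction must lie in [0, 1]")
        total = self.n_snps
        for size, r2 in self.ld_blocks:
            if not (0 <= r2 < 1):
                raise ConfigurationError("within-block r2 must lie in [0, 1)")
            if size < 1:
                raise ConfigurationError("LD block size must be >= 1")
            total -= size
        if total < 0:
            raise ConfigurationError("LD blocks cover more SNPs than n_snps")
        if self.outcome_transform not in ("identity", "log_normal_skew", "poisson_count"):
            raise ConfigurationError(f"unknown outcome_transform {self.outcome_transform!r}")


@dataclass
class VariantPanel:
    """Static variant metadata shared by both cohorts."""

    variant_ids: list[str]
    chromosome: list[str]
    position: list[int]
    effect_allele: list[str]
    other_allele: list[str]
    maf: np.ndarray
    role: list[str]  # exposure | outcome | confounder


@dataclass
class CohortData:
    """Individual-level data for one cohort."""

    ids: list[str]
    genotypes: np.ndarray  # n x J dosages in {0, 1, 2}
    exposure: np.ndarray
    outcome: np.ndarray
    confounder: np.ndarray
    covariates: np.ndarray  # n x pc_covariates (possibly 0 columns)
    panel: VariantPanel

    @property
    def variant_ids(self) -> list[str]:
        return self.panel.variant_ids

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]


def _build_panel(config: SimulationConfig, rng: np.random.Generator) -> tuple[VariantPanel, np.ndarray, dict]:
    """Variant metadata, per-SNP MAFs and LD-copy assignments."""
    j_exp = config.n_snps
    j_out = config.n_outcome_snps
    j_conf = config.n_confounder_snps
    j_all = j_exp + j_out + j_conf
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=j_all)

    # LD blocks consume exposure SNPs in order; members share the anchor MAF.
    anchor = np.arange(j_all)
    copy_prob = np.zeros(j_all)
    pos_cursor = 0
    positions = np.empty(j_all, dtype=int)
    i = 0
    for size, r2 in config.ld_blocks:
        a = i
        for m in range(size):
            anchor[i] = a
            copy_prob[i] = 0.0 if i == a else np.sqrt(r2)
            maf[i] = maf[a]
            positions[i] = pos_cursor + 1 + m * 10_000  # within the clumping window
            i += 1
        pos_cursor += 1_000_000
    while i < j_all:
        positions[i] = pos_cursor + 1
        pos_cursor += 1_000_000
        i += 1

    pairs = _ALL_PAIRS if config.allow_palindromic else _NON_PALINDROMIC_PAIRS
    idx = rng.integers(0, len(pairs), size=j_all)
    roles = ["exposure"] * j_exp + ["outcome"] * j_out + ["confounder"] * j_conf
    panel = VariantPanel(
        variant_ids=[f"rs{i + 1}" for i in range(j_all)],
        chromosome=["1"] * j_all,
        position=positions.tolist(),
        effect_allele=[pairs[i][0] for i in idx],
        other_allele=[pairs[i][1] for i in idx],
        maf=maf,
        role=roles,
    )
    return panel, maf, {"anchor": anchor, "copy_prob": copy_prob}


def _draw_genotypes(
    rng: np.random.Generator, n: int, maf: np.ndarray, ld: dict
) -> np.ndarray:
    g = rng.binomial(2, maf, size=(n, maf.size)).astype(np.int8)
    anchor, copy_prob = ld["anchor"], ld["copy_prob"]
    for j in np.flatnonzero(copy_prob > 0):
        mask = rng.random(n) < copy_prob[j]
        g[mask, j] = g[mask, anchor[j]]
    return g


def _draw_effects(config: SimulationConfig, rng: np.random.Generator):
    """Per-SNP effects and validity labels."""
    j = config.n_snps
    g_mean, g_sd = config.gamma_dist
    gamma = rng.normal(g_mean, g_sd, size=j)
    mu_a, sd_a, rho = config.alpha_params
    alpha = np.zeros(j)
    n_invalid = int(round(config.pleiotropy_fraction * j))
    invalid = np.zeros(j, dtype=bool)
    if config.pleiotropy_mode != "none" and n_invalid > 0:
        which = rng.choice(j, size=n_invalid, replace=False)
        invalid[which] = True
        if config.pleiotropy_mode == "balanced":
            alpha[which] = rng.normal(0.0, sd_a, size=n_invalid)
        elif config.pleiotropy_mode == "directional":
            alpha[which] = rng.normal(mu_a, sd_a, size=n_invalid)
        else:  # correlated: alpha tracks gamma, violating InSIDE
            z = rng.normal(size=n_invalid)
            g_std = (gamma[which] - g_mean) / g_sd if g_sd > 0 else np.zeros(n_invalid)
            alpha[which] = mu_a + sd_a * (rho * g_std + np.sqrt(max(0.0, 1 - rho**2)) * z)
    d_mean, d_sd = config.delta_dist
    delta = rng.normal(d_mean, d_sd, size=config.n_outcome_snps)
    b_conf = np.full(config.n_confounder_snps, config.confounder_snp_effect)
    return gamma, alpha, delta, b_conf, invalid


def simulate_cohorts(config: SimulationConfig) -> tuple[CohortData, CohortData]:
    """Draw an exposure cohort and an outcome cohort from the model.

    With overlap fraction o the first floor(o * min(n)) individuals are
    shared between the cohorts (identical genotypes and traits).
    """
    rng = np.random.default_rng(config.seed)
    panel, maf, ld = _build_panel(config, rng)
    gamma, alpha, delta, b_conf, invalid = _draw_effects(config, rng)

    n_e, n_o = config.n_exposure_cohort, config.n_outcome_cohort
    m = int(np.floor(config.overlap_fraction * min(n_e, n_o)))
    n_pool = n_e + n_o - m

    g = _draw_genotypes(rng, n_pool, maf, ld)
    gf = g.astype(float)
    j_exp = config.n_snps
    j_out = config.n_outcome_snps
    g_exp = gf[:, :j_exp]
    g_out = gf[:, j_exp : j_exp + j_out]
    g_conf = gf[:, j_exp + j_out :]

    u = rng.normal(size=n_pool)
    if b_conf.size:
        u = u + g_conf @ b_conf
    q_u, r_u = config.confounder_effects
    pcs = rng.normal(size=(n_pool, config.pc_covariates))
    pc_shift = pcs.sum(axis=1) * config.pc_effect if config.pc_covariates else 0.0

    x = g_exp @ gamma + q_u * u + rng.normal(size=n_pool) + pc_shift
    lin_y = config.causal_effect * x + g_exp @ alpha + r_u * u + pc_shift
    if j_out:
        lin_y = lin_y + g_out @ delta
    if config.outcome_transform == "identity":
        y = lin_y + rng.normal(size=n_pool)
    elif config.outcome_transform == "log_normal_skew":
        y = np.exp(lin_y + rng.normal(size=n_pool))
    else:  # poisson_count: log link, floor at zero
        rate = np.exp(np.clip(lin_y, None, 10.0))
        y = rng.poisson(rate).astype(float)

    ids = [f"id{i + 1}" for i in range(n_pool)]

    def _cohort(rows: np.ndarray) -> CohortData:
        return CohortData(
            ids=[ids[i] for i in rows],
            genotypes=g[rows],
            exposure=x[rows],
            outcome=y[rows],
            confounder=u[rows],
            covariates=pcs[rows],
            panel=panel,
        )

    rows_e = np.arange(n_e)
    rows_o = np.concatenate([np.arange(m), np.arange(n_e, n_e + n_o - m)])
    cohort_e, cohort_o = _cohort(rows_e), _cohort(rows_o)
    truth = {
        "theta": config.causal_effect,
        "gamma": gamma,
        "alpha": alpha,
        "delta": delta,
        "confounder_snp_effects": b_conf,
        "invalid": invalid,
        "overlap_fraction": config.overlap_fraction,
        "n_shared": m,
        "panel": panel,
    }
    cohort_e.truth = truth  # type: ignore[attr-defined]
    cohort_o.truth = truth  # type: ignore[attr-defined]
    return cohort_e, cohort_o


def gwas(
    cohort: CohortData, trait: str = "exposure", covariate_adjust: bool = False
) -> list[VariantAssociation]:
    """Per-SNP linear-regression scan of a trait on allele dosage.

    ``covariate_adjust`` projects the cohort's simulated principal components
    out of both trait and dosages first.  Monomorphic SNPs (undefined SE)
    are dropped; a single warning reports how many.
    """
    if trait not in ("exposure", "outcome"):
        raise ConfigurationError(f"trait must be exposure or outcome, got {trait!r}")
    from .diagnostics import _assoc_scan

    y = cohort.exposure if trait == "exposure" else cohort.outcome
    cov = cohort.covariates if (covariate_adjust and cohort.covariates.size) else None
    beta, se, p, ok = _assoc_scan(np.asarray(y, dtype=float), cohort.genotypes, cov)
    eaf = cohort.genotypes.mean(axis=0) / 2.0
    panel = cohort.panel
    n = cohort.n
    records = []
    n_dropped = 0
    for j in range(len(panel.variant_ids)):
        if not ok[j] or not np.isfinite(se[j]) or se[j] <= 0:
            n_dropped += 1
            continue
        records.append(
            VariantAssociation(
                variant_id=panel.variant_ids[j],
                chromosome=panel.chromosome[j],
                position=panel.position[j],
                effect_allele=panel.effect_allele[j],
                other_allele=panel.other_allele[j],
                eaf=float(eaf[j]),
                beta=float(beta[j]),
                se=float(se[j]),
                pvalue=float(p[j]),
                n=n,
            )
        )
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} monomorphic SNP(s) from the scan", stacklevel=2)
    return records


def make_two_sample_dataset(
    config: SimulationConfig, covariate_adjust: bool = False
) -> tuple[list[VariantAssociation], list[VariantAssociation], dict]:
    """Exposure-study and outcome-study summary statistics plus ground truth.

    The exposure scan runs in cohort 1 on the exposure trait; the outcome
    scan runs in cohort 2 on the outcome trait.  The truth record carries
    theta, per-SNP gamma/alpha/delta, validity labels, the overlap fraction
    and the variant panel — the reference surface for every recovery test.
    """
    cohort_e, cohort_o = simulate_cohorts(config)
    exp_stats = gwas(cohort_e, "exposure", covariate_adjust)
    out_stats = gwas(cohort_o, "outcome", covariate_adjust)
    return exp_stats, out_stats, cohort_e.truth  # type: ignore[attr-defined]
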