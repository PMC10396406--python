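import numpy as np
import pytest

from bimr import (
    HarmonizedInstrument,
    SimulationConfig,
    VariantAssociation,
    harmonize,
    make_two_sample_dataset,
    orient_to_trait_increasing,
    usable,
)


def make_variant(
    variant_id="rs1",
    chromosome="1",
    position=1000,
    effect_allele="A",
    other_allele="G",
    eaf=0.3,
    beta=0.1,
    se=0.01,
    pvalue=1e-9,
    n=10000,
):
    return VariantAssociation(
        variant_id, chromosome, position, effect_allele, other_allele, eaf, beta, se, pvalue, n
    )


def make_instrument(variant_id="rs1", bx=0.1, by=0.02, sx=0.005, sy=0.01, status="kept"):
    return HarmonizedInstrument(
        variant_id=variant_id,
        beta_exposure=bx,
        se_exposure=sx,
        beta_outcome=by,
        se_outcome=sy,
        eaf_exposure=0.3,
        eaf_outcome=0.3,
        ratio=by / bx if bx else float("nan"),
        ratio_se=sy / abs(bx) if bx else float("nan"),
        status=status,
    )


def simulated_instruments(seed, **config_overrides):
    """Harmonized instruments for the full known-valid SNP panel plus truth."""
    cfg = SimulationConfig(seed=seed, **config_overrides)
    exp_stats, out_stats, truth = make_two_sample_dataset(cfg)
    roles = truth["panel"].role
    keep_ids = {v for v, r in zip(truth["panel"].variant_ids, roles) if r == "exposure"}
    exp_stats = [r for r in exp_stats if r.variant_id in keep_ids]
    out_stats = [r for r in out_stats if r.variant_id in keep_ids]
    kept = usable(harmonize(orient_to_trait_increasing(exp_stats), out_stats))
    return kept, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


def random_instruments(rng, j=10, theta=0.2):
    """Random well-behaved instruments for algebraic property checks."""
    bx = rng.uniform(0.05, 0.3, j)
    sy = rng.uniform(0.005, 0.03, j)
    by = theta * bx + rng.normal(0, sy)
    sx = rng.uniform(0.002, 0.01, j)
    return [
        make_instrument(f"rs{i + 1}", bx[i], by[i], sx[i], sy[i]) for i in range(j)
    ]
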