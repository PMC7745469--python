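import numpy as np
import pytest

from mrmediate import HarmonizedSet, SummaryAssociation


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_harmonized_set(rng, j, slope=0.2, exposure_noise=True):
    """A random pre-aligned set with heteroscedastic outcome SEs."""
    bx = rng.normal(0.05, 0.02, j)
    bx = np.where(np.abs(bx) < 1e-3, 1e-3, bx)
    sx = rng.uniform(0.002, 0.01, j) if exposure_noise else np.full(j, 1e-6)
    sy = rng.uniform(0.01, 0.05, j)
    by = slope * bx + rng.normal(0, sy)
    return HarmonizedSet.from_arrays(bx, sx, by, sy)


def make_assoc(
    variant_id,
    beta=0.05,
    se=0.005,
    pval=1e-10,
    ea="A",
    oa="G",
    eaf=0.3,
    n=500_000,
    trait="trait",
):
    return SummaryAssociation(
        variant_id=variant_id,
        effect_allele=ea,
        other_allele=oa,
        beta=beta,
        se=se,
        pval=pval,
        n=n,
        trait_id=trait,
        eaf=eaf,
    )
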