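import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mrtools.harmonize import HarmonizedPair
from mrtools.sumstats import VariantAssociation

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_pair(vid, bx, sy, by, sx=0.01, p_out=0.5):
    """HarmonizedPair with only the estimator-relevant fields filled."""
    return HarmonizedPair(
        variant_id=vid,
        beta_exposure=bx,
        se_exposure=sx,
        beta_outcome=by,
        se_outcome=sy,
        p_outcome=p_out,
    )


def make_assoc(vid, ea="A", oa="G", beta=0.1, se=0.01, p=1e-10, chrom="1", pos=None, eaf=0.3, n=None):
    return VariantAssociation(
        variant_id=vid, chrom=chrom, pos=pos, effect_allele=ea, other_allele=oa,
        eaf=eaf, beta=beta, se=se, pvalue=p, n=n,
    )


@pytest.fixture
def ivw_toy_pairs():
    """Three-variant toy with equal weights 100 and ratios 0.2, 0.25, 0.2."""
    return [
        make_pair("rs1", 0.10, 0.010, 0.020),
        make_pair("rs2", 0.20, 0.020, 0.050),
        make_pair("rs3", 0.15, 0.015, 0.030),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
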