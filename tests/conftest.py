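import numpy as np
import pytest

from targetmr import SummaryPanel, SummaryStatRecord, make_ld_ar1


def record(
    snp_id="rs1",
    pos=100,
    beta=0.1,
    se=0.02,
    pval=None,
    eaf=0.3,
    ea="A",
    oa="G",
    n=10_000,
    trait_type="quantitative",
    chrom="1",
):
    """Build a record with a z-consistent p-value unless one is given."""
    from scipy.stats import norm

    if pval is None:
        pval = max(2 * norm.sf(abs(beta / se)), 1e-300)
    return SummaryStatRecord(
        snp_id=snp_id, chrom=chrom, pos=pos, effect_allele=ea, other_allele=oa,
        eaf=eaf, beta=beta, se=se, pval=pval, n=n, trait_type=trait_type,
        case_fraction=0.5 if trait_type == "case_control" else None,
    )


@pytest.fixture
def three_snp_panel():
    return SummaryPanel(
        trait_name="GENE1",
        tissue="cerebellum",
        panel_kind="eqtl",
        records=[
            record("rs1", pos=100, beta=0.30, se=0.05, eaf=0.25),
            record("rs2", pos=200, beta=0.10, se=0.05, eaf=0.40, ea="C", oa="T"),
            record("rs3", pos=300, beta=-0.02, se=0.05, eaf=None, ea="G", oa="A"),
        ],
    )


@pytest.fixture
def ar1_ld():
    return make_ld_ar1(5, 0.9)


def random_correlation(m, rng):
    """A random valid correlation matrix via a Wishart-style construction."""
    a = rng.standard_normal((m, m + 2))
    s = a @ a.T + 0.1 * np.eye(m)
    d = np.sqrt(np.diag(s))
    return s / np.outer(d, d)
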