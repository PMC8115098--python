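"""Shared fixtures: hand-built instrument sets and simulated datasets."""
from __future__ import annotations

import pytest

from mrkit import instruments, synthetic
from mrkit.types import HarmonizedInstrument, VariantAssociation


def make_variant(
    snp_id="rs1",
    chrom="1",
    pos=1000,
    effect_allele="A",
    other_allele="G",
    eaf=0.3,
    beta=0.1,
    se=0.02,
    pvalue=None,
    n=100_000.0,
) -> VariantAssociation:
    """A valid record; p-value derived from beta/se unless given."""
    from scipy import stats

    if pvalue is None:
        pvalue = float(2 * stats.norm.sf(abs(beta) / se))
    return VariantAssociation(
        snp_id=snp_id, chrom=chrom, pos=pos, effect_allele=effect_allele,
        other_allele=other_allele, eaf=eaf, beta=beta, se=se, pvalue=pvalue, n=n,
    )


def make_h(
    beta_exp, beta_out, se_out, se_exp=1e-6, snp_id=None, **kw
) -> HarmonizedInstrument:
    return HarmonizedInstrument(
        snp_id=snp_id or f"rs{abs(hash((beta_exp, beta_out, se_out))) % 10**6}",
        beta_exp=beta_exp, se_exp=se_exp, beta_out=beta_out, se_out=se_out,
        eaf_exp=0.3, eaf_out=0.3, action_taken="aligned",
        pvalue_exp=kw.get("pvalue_exp"), pvalue_out=kw.get("pvalue_out"),
        n_exp=kw.get("n_exp", 100_000.0), n_out=kw.get("n_out", 100_000.0),
    )


@pytest.fixture
def three_iv_oracle():
    """The hand-computable set: weights {1,1,4}, ratios {2,1,1}."""
    return [
        make_h(1.0, 2.0, 1.0, snp_id="s1"),
        make_h(1.0, 1.0, 1.0, snp_id="s2"),
        make_h(2.0, 2.0, 1.0, snp_id="s3"),
    ]


def true_iv_harmonized(truth: synthetic.SimTruth):
    """Harmonized set over the generator's known instruments (no selection)."""
    ds = synthetic.simulate_iv_dataset(truth)
    iv_ids = set(ds.iv_ids)
    ivset = [r for r in ds.exposure if r.snp_id in iv_ids]
    return instruments.usable(instruments.harmonize(ivset, ds.outcome))


@pytest.fixture
def default_dataset():
    return synthetic.simulate_iv_dataset(synthetic.SimTruth(seed=3))
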