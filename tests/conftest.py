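import numpy as np
import pandas as pd
import pytest

from mrscreen.sumstats import CANONICAL_COLUMNS, SummaryStats, harmonized_from_arrays


def make_sumstats(rows, trait_id="trait", default_n=None):
    """Build a SummaryStats from a list of dicts with canonical keys."""
    df = pd.DataFrame(rows)
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return SummaryStats(trait_id=trait_id, table=df[CANONICAL_COLUMNS], default_n=default_n)


def variant(vid, chrom="1", pos=1000, ea="A", oa="G", eaf=0.3, beta=0.05,
            se=0.008, pvalue=1e-8, n=26333):
    return dict(variant_id=vid, chromosome=chrom, position=pos, effect_allele=ea,
                other_allele=oa, eaf=eaf, beta=beta, se=se, pvalue=pvalue, n=n)


@pytest.fixture
def toy_harmonized():
    """Builder for a HarmonizedSet straight from effect arrays."""
    return harmonized_from_arrays


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
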