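import numpy as np
import pandas as pd
import pytest

from mrtarget.harmonization import InstrumentSet
from mrtarget.summary_io import SummaryStatTable

RECORD_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
]


def make_table(rows, name="trait", kind="quantitative", units="mmHg"):
    """Build a SummaryStatTable from plain row tuples."""
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return SummaryStatTable(trait_name=name, trait_kind=kind, trait_units=units,
                            records=df)


def random_correlation(rng, m, n_obs=25):
    """A random full-rank correlation matrix (sample correlation of MVN data)."""
    x = rng.standard_normal((n_obs, m))
    r = np.corrcoef(x.T)
    np.fill_diagonal(r, 1.0)
    return r


def random_instrument_set(rng, m=None, outcome_kind="binary"):
    """A random, well-conditioned instrument set for algebraic checks."""
    if m is None:
        m = int(rng.integers(2, 11))
    return InstrumentSet(
        variant_ids=[f"rs{i}" for i in range(m)],
        gamma=rng.normal(0.0, 0.05, m),
        sigma_x=rng.uniform(0.002, 0.01, m),
        Gamma=rng.normal(0.0, 0.02, m),
        sigma_y=rng.uniform(0.005, 0.03, m),
        rho=random_correlation(rng, m),
        outcome_kind=outcome_kind,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230951)
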