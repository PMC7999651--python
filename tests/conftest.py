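import numpy as np
import pandas as pd
import pytest

from statinpgx import pgx
from statinpgx.config import default_config


@pytest.fixture(scope="session")
def defs():
    return pgx.load_definitions()


@pytest.fixture(scope="session")
def small_config():
    """A 40-subject cohort keeping the five-arm trial structure."""
    return default_config(seed=11, n_subjects=40)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    from statinpgx.cohort import simulate_cohort

    return simulate_cohort(small_config)


def make_calls(genotype_by_rsid, defs, subject_id="S1"):
    """Long genotype table for one subject from {rsid: n_alt_copies}.

    Variants not named are homozygous reference.
    """
    rows = []
    for row in defs.panel.itertuples():
        n = genotype_by_rsid.get(row.rsid, 0)
        alleles = [row.alt] * n + [row.ref] * (2 - n)
        rows.append({"subject_id": subject_id, "gene": row.gene,
                     "rsid": row.rsid, "allele1": alleles[0],
                     "allele2": alleles[1]})
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
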