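import numpy as np
import pandas as pd
import pytest

from rrlpopgen import build_cohort, call_population
from rrlpopgen.core import CallSet


@pytest.fixture(scope="session")
def cohort():
    """Small deterministic two-population cohort used across modules."""
    return build_cohort(n_snps=60, chrom_len=400_000, seed=11)


@pytest.fixture(scope="session")
def callsets(cohort):
    hard = call_population(cohort.counts, "hard_filter")
    lik = call_population(cohort.counts, "likelihood", label="likelihood")
    return hard, lik


def make_callset(label, gt, individuals=None, pos=None, chrom="chr1", dp=None):
    """Hand-built CallSet from a genotype matrix (sites x individuals)."""
    gt = np.asarray(gt, dtype=np.int8)
    n_sites, n_inds = gt.shape
    individuals = individuals or [f"I{j}" for j in range(n_inds)]
    pos = pos if pos is not None else 100 * np.arange(1, n_sites + 1)
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "ref": "A", "alt": "G"}
    )
    return CallSet(label=label, sites=sites, individuals=list(individuals), gt=gt,
                   dp=None if dp is None else np.asarray(dp))
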