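import numpy as np
import pytest

from lemnapop import CohortSpec, simulate_cohort
from lemnapop.variants import VariantTable


@pytest.fixture(scope="session")
def small_cohort():
    """A small mixed-species cohort used by several integration tests."""
    spec = CohortSpec(
        n_pops_sp1=3, n_pops_sp2=2, samples_per_pop=3, n_sites=800, seed=1
    )
    table, truth = simulate_cohort(spec)
    return spec, table, truth


def make_table(gt, qual=None, dp=None, ad_ref=None, ad_alt=None, samples=None,
               subgenome=None):
    """Build a VariantTable from a genotype matrix with sensible fillers."""
    gt = np.asarray(gt, dtype=np.int8)
    n_sites, n_samples = gt.shape
    if samples is None:
        samples = [f"S{i + 1}" for i in range(n_samples)]
    if dp is None:
        dp = np.full(gt.shape, 30, dtype=np.int32)
    if ad_alt is None:
        ad_alt = (np.maximum(gt, 0) * dp // 2).astype(np.int32)
    if ad_ref is None:
        ad_ref = (dp - ad_alt).astype(np.int32)
    if qual is None:
        qual = np.full(n_sites, 60.0)
    return VariantTable(
        samples=list(samples),
        contig=np.asarray(["chr1"] * n_sites, dtype=object),
        pos=np.arange(1, n_sites + 1) * 10,
        ref=np.asarray(["A"] * n_sites, dtype=object),
        alt=np.asarray(["T"] * n_sites, dtype=object),
        qual=np.asarray(qual, dtype=float),
        gt=gt,
        ad_ref=np.asarray(ad_ref, dtype=np.int32),
        ad_alt=np.asarray(ad_alt, dtype=np.int32),
        dp=np.asarray(dp, dtype=np.int32),
        contig_subgenome={"chr1": subgenome} if subgenome else {},
    )
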