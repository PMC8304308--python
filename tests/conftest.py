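import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cross():
    """A small simulated cross with a strong causal locus, shared read-only."""
    import qtlbsa as q

    cfg = q.CrossConfig(
        n_individuals=100,
        bulk_size=15,
        n_sites=200,
        chrom_length_bp=2_000_000,
        causal_pos_bp=1_000_000,
        noise_sd=1.0,
        seed=11,
    )
    pop = q.simulate_f2(cfg)
    e_idx, l_idx = q.make_bulks(pop, cfg.bulk_size)
    sites = q.sample_depths(pop, e_idx, l_idx)
    return cfg, pop, e_idx, l_idx, sites


def make_site(
    chrom="chr1",
    pos=100,
    ref="A",
    alt="G",
    p1_gt="ref_hom",
    p2_gt="alt_hom",
    e_ref=10,
    e_alt=10,
    l_ref=10,
    l_alt=10,
    **extra,
):
    row = dict(
        chrom=chrom, pos=pos, ref=ref, alt=alt, p1_gt=p1_gt, p2_gt=p2_gt,
        e_ref=e_ref, e_alt=e_alt, l_ref=l_ref, l_alt=l_alt,
    )
    row.update(extra)
    return row


@pytest.fixture
def site_table_factory():
    def factory(rows):
        return pd.DataFrame([make_site(**r) for r in rows])

    return factory
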