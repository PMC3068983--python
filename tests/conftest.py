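import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

from tfret.intervals_io import (  # noqa: E402
    CEBPA,
    PPARG,
    AnalysisConfig,
    BindingSite,
    GenomicInterval,
)
from tfret.synthetic_data import SimConfig, generate_fixture  # noqa: E402


def make_site(chrom, start, end, factor=CEBPA, species="mouse", site_id=None, tags=0):
    if site_id is None:
        site_id = f"{factor}_{chrom}_{start}_{end}"
    return BindingSite(site_id, GenomicInterval(chrom, start, end), factor, species, tags)


@pytest.fixture(scope="session")
def cfg():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """A small but complete synthetic fixture shared by pipeline-level tests."""
    outdir = tmp_path_factory.mktemp("fixture")
    sim = SimConfig(seed=11, n_chroms=2, chrom_len=1_000_000, n_sites=300, n_genes=80)
    truth = generate_fixture(sim, outdir)
    return outdir, sim, truth


def random_sites(rng, n, factor, species, chrom="chr1", span=100_000, wmin=50, wmax=500):
    sites = []
    for i in range(n):
        start = int(rng.integers(0, span))
        width = int(rng.integers(wmin, wmax))
        sites.append(
            BindingSite(
                f"{species[0]}{factor[0]}{i}",
                GenomicInterval(chrom, start, start + width),
                factor,
                species,
            )
        )
    return sites
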