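import numpy as np
import pytest

from locusdissect.simulate import LocusSpec, make_ld, simulate_locus


@pytest.fixture(scope="session")
def shared_causal_locus():
    """AR(1) locus where a GWAS and an eQTL trait share one causal variant."""
    spec = LocusSpec(
        n_variants=100,
        block_sizes=[100],
        rho=0.95,
        causal_effects={"gwas": [(50, 0.05)], "eqtl": [(50, 0.05)]},
        sample_sizes={"gwas": 50_000, "eqtl": 50_000},
        seed=11,
    )
    return simulate_locus(spec)


@pytest.fixture(scope="session")
def distinct_causal_locus():
    """Two independent LD blocks with the two traits' causals in different
    blocks (cross-block r^2 = 0)."""
    spec = LocusSpec(
        n_variants=100,
        block_sizes=[50, 50],
        rho=0.95,
        causal_effects={"gwas": [(25, 0.05)], "eqtl": [(75, 0.05)]},
        sample_sizes={"gwas": 50_000, "eqtl": 50_000},
        seed=11,
    )
    return simulate_locus(spec)


@pytest.fixture()
def small_ld():
    spec = LocusSpec(n_variants=20, block_sizes=[20], rho=0.9, seed=3)
    return make_ld(spec)


def two_sided_normal_p(z):
    from scipy.stats import norm

    return 2 * norm.sf(np.abs(z))
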