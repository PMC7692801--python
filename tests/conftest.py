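import numpy as np
import pytest

from hrepml import (
    CovariateTable,
    GenotypeTable,
    ScanContext,
    SimulationConfig,
    compute_kinship,
    default_qtns,
    fit_null,
    rotate,
    spectral_decompose,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def make_genotypes(rng, n=40, m=60):
    """Small random 0/1/2 genotype table (outbred coding for variety)."""
    calls = rng.integers(0, 3, size=(m, n)).astype(float)
    chrom = np.repeat(np.arange(1, 6), int(np.ceil(m / 5)))[:m]
    pos = (np.arange(m) + 1) * 100
    return GenotypeTable(chrom, pos, calls)


def make_context(rng, n=40, m=60, h2_poly=0.0):
    """Genotypes, phenotype and a ready ScanContext for REML tests."""
    G = make_genotypes(rng, n=n, m=m)
    K = compute_kinship(G)
    basis = spectral_decompose(K)
    y = rng.normal(10.0, 1.0, size=n)
    if h2_poly > 0:
        z = rng.standard_normal(n)
        u = basis.eigenvectors @ (np.sqrt(basis.eigenvalues) * z)
        y = y + np.sqrt(h2_poly) * u / max(u.std(), 1e-12)
    F = CovariateTable(np.column_stack([np.ones(n), rng.normal(size=n)]))
    rotate(y, F.design, basis)
    null = fit_null(basis.rotated_phenotype, basis.rotated_covariates, basis.eigenvalues)
    ctx = ScanContext(basis=basis, null=null)
    return G, y, F, ctx


def tiny_sim_config(**overrides):
    defaults = dict(
        n_individuals=100,
        n_markers=300,
        qtns=default_qtns(300),
        n_replicates=2,
        seed=7,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)
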