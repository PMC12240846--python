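import numpy as np
import pytest

from hsqtl import simdata, varcomp
from hsqtl.scan import LocoWorkspace


@pytest.fixture(scope="session")
def small_cohort():
    """300 animals x ~1000 SNPs on 4 chromosomes with one strong planted QTL."""
    cfg = simdata.SimConfig(
        seed=11,
        n_individuals=300,
        chrom_lengths=[(str(c + 1), 25_000_000) for c in range(4)],
        snp_density=10,
        qtl_specs=[simdata.PlantedQtl("1", 12_000_000, 0.15)],
        h2_poly=0.2,
        traits=["consumption", "break_point"],
    )
    G, pheno, truth = simdata.simulate_cohort(cfg)
    return cfg, G, pheno, truth


@pytest.fixture(scope="session")
def small_loco(small_cohort):
    _, G, _, _ = small_cohort
    loco = varcomp.compute_loco_grms(G)
    return loco, LocoWorkspace(G, loco)


def planted_partition_graph(n, K, p_in, p_out, seed):
    """Symmetric binary adjacency with block-dependent edge probabilities."""
    rng = np.random.default_rng(seed)
    z = np.repeat(np.arange(K), n // K)
    A = np.zeros((n, n), dtype=np.int8)
    iu = np.triu_indices(n, 1)
    p = np.where(z[iu[0]] == z[iu[1]], p_in, p_out)
    A[iu] = rng.random(iu[0].size) < p
    return z, A + A.T
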