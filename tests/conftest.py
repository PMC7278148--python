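import numpy as np
import pytest

from txdiv import simulate


@pytest.fixture(scope="session")
def small_config():
    """Compact two-subspecies panel used across tests."""
    return simulate.SimulationConfig(
        n_accessions_per_pop=(15, 18),
        n_snps=4000,
        n_genes=80,
        chromosome_lengths={"chr1": 3_000_000, "chr2": 3_000_000},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    dataset, archs = simulate.simulate_dataset(small_config)
    return dataset, archs


def hudson_fst(dosages, mask_a, mask_b):
    """Brute-force Hudson Fst estimator (ratio of averages) from haploid
    dosages; the independent oracle for divergence recovery."""
    def freq_n(rows):
        sub = dosages[rows]
        n = (~np.isnan(sub)).sum(axis=0)
        p = np.nansum(sub, axis=0) / np.maximum(n, 1)
        return p, n

    p1, n1 = freq_n(np.flatnonzero(mask_a))
    p2, n2 = freq_n(np.flatnonzero(mask_b))
    ok = (n1 >= 2) & (n2 >= 2)
    p1, p2, n1, n2 = p1[ok], p2[ok], n1[ok], n2[ok]
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num.sum() / den.sum()


def toy_genotypes(dosages):
    """GenotypeTable from a raw dosage matrix (test helper)."""
    import pandas as pd
    from txdiv.dataio import GenotypeTable

    dosages = np.asarray(dosages, dtype=float)
    n_acc, m = dosages.shape
    snps = pd.DataFrame({
        "snp_id": [f"s{j}" for j in range(m)],
        "chrom": "chr1",
        "pos": np.arange(1, m + 1) * 100,
        "ref": "A", "alt": "G",
    })
    return GenotypeTable([f"a{i}" for i in range(n_acc)], snps, dosages)
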