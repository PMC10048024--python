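import numpy as np
import pytest

from equindel.loci import GenotypeMatrix, VariantLocus
from equindel.simulate import SimulationConfig, simulate_population

FAIL_FRACTIONS = {
    "DP": 0.05,
    "QUAL": 0.03,
    "LOWQUAL": 0.03,
    "QD": 0.02,
    "MQ0": 0.02,
    "HRun": 0.02,
    "SB": 0.02,
}


@pytest.fixture(scope="session")
def sim_population():
    """Mid-size synthetic population with injected signatures and filter
    violations; 101 samples, a little missingness on ordinary loci."""
    cfg = SimulationConfig(
        n_samples=101,
        n_diallelic=2000,
        n_multiallelic=250,
        n_artifact_allhet=30,
        n_all_alt_hom=12,
        missing_rate=0.02,
        filter_fail_fractions=FAIL_FRACTIONS,
        seed=20230303,
    )
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """Small population written to disk (per-sample VCFs, known sets)."""
    cfg = SimulationConfig(
        n_samples=20,
        n_diallelic=400,
        n_multiallelic=50,
        n_artifact_allhet=10,
        n_all_alt_hom=5,
        seed=97,
    )
    outdir = tmp_path_factory.mktemp("bundle")
    return simulate_population(cfg, outdir=str(outdir))


def make_matrix(genotypes, locus=None, info=None):
    """Single-locus matrix from a list of (a, b) allele pairs."""
    locus = locus or VariantLocus("1", 1000, "A", ("AT",))
    calls = np.array([sorted(g) for g in genotypes], dtype=np.int16).reshape(-1, 1, 2).transpose(1, 0, 2)
    samples = [f"S{i}" for i in range(len(genotypes))]
    return GenotypeMatrix([locus], samples, calls, [dict(info or {})])
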