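import numpy as np
import pytest

from drysweep.genio import PanelMap, VariantTable


def make_vt(genotypes, pos=None, chrom="chr1", ref=None, alt=None,
            samples=None, phased=True) -> VariantTable:
    """Build a small VariantTable from a list of per-site genotype lists.

    genotypes: [[(a, b), ...] per site]; -1 codes a missing allele.
    """
    n_sites = len(genotypes)
    n_samples = len(genotypes[0]) if n_sites else 0
    if pos is None:
        pos = list(range(1, n_sites + 1))
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    g = np.array(genotypes, dtype=np.int8).reshape(n_sites, n_samples, 2)
    return VariantTable(
        chrom=np.full(n_sites, chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.array(ref if ref is not None else ["A"] * n_sites, dtype=object),
        alt=np.array(alt if alt is not None else ["G"] * n_sites, dtype=object),
        genotypes=g,
        samples=list(samples),
        phased=phased,
    )


@pytest.fixture
def two_breed_panel():
    """Four samples split over two breeds in distinct groups."""
    return PanelMap(
        {"s0": "X", "s1": "X", "s2": "Y", "s3": "Y"},
        {"X": "sudanese_zebu", "Y": "gir"},
    )


@pytest.fixture(scope="session")
def small_sweep_cohort():
    """One-chromosome cohort with a single implanted Sudanese sweep (seeded).

    Shared across modules that need a realistic signal without re-simulating.
    """
    from drysweep import simdata

    params = simdata.SimulationParams(
        n_chromosomes=1, chrom_length=4_000_000, seed=11,
        sweeps=[simdata.SweepSpec("chr1", 2_000_000, 250_000,
                                  frozenset({"GAS", "ARY", "BTN", "KEN", "BAG"}),
                                  0.95)],
    )
    return simdata.simulate_cohort(params)
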