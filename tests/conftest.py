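import numpy as np
import pytest

from popmosaic import simdata as sim
from popmosaic.genotypes import GenotypeMatrix


def make_genotypes(dosage, pos=None, chrom=None, ref=None, alt=None, pops=None,
                   depth=None, qual=None):
    """Small GenotypeMatrix from raw arrays with sensible defaults."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, s = dosage.shape
    return GenotypeMatrix(
        samples=[f"S{i}" for i in range(n)],
        chrom=np.asarray(chrom if chrom is not None else ["1"] * s, dtype=object),
        pos=np.asarray(pos if pos is not None else np.arange(1, s + 1) * 1000),
        ref=np.asarray(ref if ref is not None else ["A"] * s, dtype=object),
        alt=np.asarray(alt if alt is not None else ["G"] * s, dtype=object),
        dosage=dosage,
        depth=None if depth is None else np.asarray(depth),
        qual=None if qual is None else np.asarray(qual),
        populations=None if pops is None else np.asarray(pops, dtype=object),
    )


@pytest.fixture(scope="session")
def three_source_freqs():
    return sim.sample_source_frequencies(
        20_000, [0.15, 0.05, 0.05], seed=11, labels=["EUR", "GOG", "ANG"]
    )


@pytest.fixture(scope="session")
def admixed_cohort(three_source_freqs):
    specs = [
        sim.AdmixtureSpec("EUR", [1, 0, 0], 8),
        sim.AdmixtureSpec("GOG", [0, 1, 0], 8),
        sim.AdmixtureSpec("ANG", [0, 0, 1], 8),
        sim.AdmixtureSpec("CRE", [0.10, 0.55, 0.35], 8),
    ]
    return sim.simulate_admixed_genotypes(three_source_freqs, specs, seed=12)
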