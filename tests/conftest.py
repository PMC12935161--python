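import numpy as np
import pytest

import isokit as ik


def random_transcript(rng: np.random.Generator, max_exons: int = 6):
    """A random valid transcript for coordinate property tests."""
    n_ex = int(rng.integers(1, max_exons + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    pos = int(rng.integers(0, 1000))
    exons = []
    for _ in range(n_ex):
        length = int(rng.integers(1, 300))
        exons.append(ik.GenomicInterval("chrR", pos, pos + length, strand))
        pos += length + int(rng.integers(1, 500))
    return ik.Transcript(f"tx{rng.integers(1e9)}", "gene", exons=exons)


def per_base_table(tx):
    """Brute-force genomic<->transcript lookup: list of genomic positions in
    transcript order, built base by base."""
    exons = tx.exons if tx.strand == "+" else list(reversed(tx.exons))
    bases = []
    for e in exons:
        rng_ = range(e.start, e.end) if tx.strand == "+" else range(e.end - 1, e.start - 1, -1)
        bases.extend(rng_)
    return bases


@pytest.fixture(scope="session")
def sim_dataset():
    """A moderate synthetic dataset shared by read-only tests."""
    cfg = ik.SimulationConfig(seed=42, n_genes=30)
    genome, models, truth = ik.simulate_annotation(cfg)
    return cfg, genome, models, truth


@pytest.fixture(scope="session")
def toy():
    return ik.make_toy_locus()
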