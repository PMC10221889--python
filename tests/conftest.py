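import numpy as np
import pandas as pd
import pytest

from sixma.io_formats import GeneModel, GenomeSequence, MethylationSiteSet


def make_sites(rows, mod_type="6mA"):
    """rows: iterable of (chrom, pos, strand[, context, coverage])."""
    full = []
    for r in rows:
        chrom, pos, strand = r[0], r[1], r[2]
        context = r[3] if len(r) > 3 else ("NA" if mod_type == "6mA" else "CG")
        cov = r[4] if len(r) > 4 else 20
        full.append((chrom, pos, strand, mod_type, context, cov))
    df = pd.DataFrame(
        full, columns=["chrom", "pos", "strand", "mod_type", "context", "coverage"]
    )
    return MethylationSiteSet(df)


def random_genome(rng, lengths, p=(0.305, 0.195, 0.195, 0.305)):
    chroms = {}
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for name, L in lengths.items():
        codes = rng.choice(4, size=L, p=list(p))
        chroms[name] = bases[codes].tobytes().decode()
    return GenomeSequence(chroms)


@pytest.fixture(scope="session")
def tiny_genome():
    rng = np.random.default_rng(11)
    return random_genome(rng, {"chr1": 10_000, "chr2": 8_000})


@pytest.fixture(scope="session")
def tiny_genes():
    return [
        GeneModel("gA", "chr1", "+", 3000, 5000, [(3000, 3600), (4200, 5000)], 1400),
        GeneModel("gB", "chr1", "-", 6500, 8000, [(6500, 8000)], 1500),
        GeneModel("gC", "chr2", "+", 1000, 2200, [(1000, 1400), (1800, 2200)], 800),
    ]


@pytest.fixture(scope="session")
def small_simulation():
    """A full synthetic dataset shared by slower integration tests."""
    from sixma.synthetic_data import SimulationConfig, simulate_all

    cfg = SimulationConfig(
        seed=7, n_chromosomes=1, chromosome_length=400_000, n_genes=60
    )
    return simulate_all(cfg)
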