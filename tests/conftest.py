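import numpy as np
import pandas as pd
import pytest

from chromcouple.formats import CountTable, GenomicInterval, GeneRecord, NarrowPeak


SAMPLES = [f"{pop}_rep{r}" for pop in "AB" for r in (1, 2, 3)]
GROUPS = {s: s.split("_")[0] for s in SAMPLES}


def make_count_table(matrix, feature_ids=None, samples=None, groups=None):
    matrix = np.asarray(matrix)
    if feature_ids is None:
        feature_ids = [f"g{i:04d}" for i in range(matrix.shape[0])]
    if samples is None:
        samples = SAMPLES[: matrix.shape[1]]
    if groups is None:
        groups = {s: s.split("_")[0] for s in samples}
    return CountTable(
        pd.DataFrame(matrix, index=feature_ids, columns=samples), groups
    )


def nb_counts(rng, mu, dispersion, size=None):
    """NB draws with mean mu and variance mu + dispersion * mu^2."""
    if dispersion < 1e-8:
        return rng.poisson(mu, size=size)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + np.asarray(mu)), size=size)


def random_sequence(rng, length, gc=0.45):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[rng.choice(4, size=length, p=p)].tobytes().decode()


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_peaks():
    def peak(chrom, start, end, name="p", summit=None):
        width = end - start
        return NarrowPeak(
            GenomicInterval(chrom, start, end),
            name=name,
            summit_offset=width // 2 if summit is None else summit,
        )

    return peak


@pytest.fixture
def gene_factory():
    def gene(gene_id, chrom, start, end, strand="+"):
        return GeneRecord(gene_id, GenomicInterval(chrom, start, end, strand))

    return gene
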