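import numpy as np
import pytest

from strpop.io import AUTOSOMAL, X, GenotypeTable, LocusDef, Sample


@pytest.fixture
def mini_autosomal_table():
    """Two samples at one autosomal locus: 15/16 and 15/15."""
    panel = [LocusDef("vWA", AUTOSOMAL)]
    samples = [Sample("s1", "M", "pop"), Sample("s2", "F", "pop")]
    calls = {("s1", "vWA"): ("15", "16"), ("s2", "vWA"): ("15", "15")}
    return GenotypeTable(samples, calls, panel)


@pytest.fixture
def mini_x_table():
    """One male and one female at an X locus."""
    panel = [LocusDef("DXS10135", X)]
    samples = [Sample("m1", "M", "pop"), Sample("f1", "F", "pop")]
    calls = {("m1", "DXS10135"): ("15",), ("f1", "DXS10135"): ("15", "16")}
    return GenotypeTable(samples, calls, panel)


def hwe_genotypes(rng: np.random.Generator, freqs, n: int):
    """Diploid genotypes sampled under HWE from a frequency vector."""
    p = np.asarray(freqs, dtype=float)
    labels = [str(8 + j) for j in range(len(p))]
    draws = rng.choice(len(p), size=(n, 2), p=p)
    return [(labels[min(a, b)], labels[max(a, b)]) for a, b in draws]
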