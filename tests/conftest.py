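import numpy as np
import pandas as pd
import pytest

from aflpop.io import BandMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_bands():
    """2 samples x 3 markers with one missing cell."""
    return BandMatrix(
        ["s1", "s2"], ["m1", "m2", "m3"],
        np.array([[1, 0, -1], [1, 1, 0]], dtype=np.int8))


@pytest.fixture
def toy_samples():
    """16 samples in 2 sites x 2 habitats, 4 per cell, on a small grid."""
    rows = []
    k = 0
    for site in ("A", "B"):
        for hab in ("bottomland", "hilltop"):
            for i in range(4):
                rows.append((f"{site}{hab[0]}{i}", site, hab,
                             10.0 * k + i, 5.0 * i, 20.0 + 10 * (hab == "hilltop")))
            k += 1
    return pd.DataFrame(rows, columns=["sample_id", "site", "habitat",
                                       "x", "y", "elevation"])


@pytest.fixture
def toy_env():
    return pd.DataFrame({
        "site": ["A", "A", "B", "B"],
        "habitat": ["bottomland", "hilltop"] * 2,
        "soil_type": ["hygromorphic", "ferralitic"] * 2,
        "waterlog": [2, 0, 1, 0],
        "drought": [0, 2, 1, 3],
    })


def random_bands(rng, n_samples, n_loci, p_lo=0.2, p_hi=0.8, fis=-0.14,
                 prefix="s"):
    """Panmictic dominant phenotypes at uniform allele frequencies."""
    from aflpop.outliers import _phenotype_absent_prob
    p0 = rng.uniform(p_lo, p_hi, n_loci)
    absent = _phenotype_absent_prob(p0, fis)
    vals = (rng.random((n_samples, n_loci)) >= absent).astype(np.int8)
    return BandMatrix([f"{prefix}{i}" for i in range(n_samples)],
                      [f"L{j:03d}" for j in range(n_loci)], vals)


def single_site_table(bands, rng, extent=200.0):
    return pd.DataFrame({
        "sample_id": bands.sample_ids,
        "site": "S", "habitat": "h",
        "x": rng.uniform(0, extent, bands.n_samples),
        "y": rng.uniform(0, extent, bands.n_samples),
        "elevation": 0.0,
    })
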