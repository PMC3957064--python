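import numpy as np
import pytest

from vtet.io import IntensityMatrix, Phenotype, ProbeMap


@pytest.fixture
def rng():
    return np.random.default_rng(20140318)


@pytest.fixture
def toy_probes():
    return ProbeMap(
        np.array(["p1", "p2", "p3"], dtype=object),
        np.array(["1", "1", "1"], dtype=object),
        np.array([100, 200, 300]),
    )


def make_noise_matrix(n_subjects, T, rng, normalized=True, with_baf=False):
    """i.i.d. standard-normal LRR, optional uninformative BAF."""
    probes = ProbeMap(
        np.array([f"p{t}" for t in range(T)], dtype=object),
        np.array(["1"] * T, dtype=object),
        np.arange(1, T + 1) * 10,
    )
    baf = (
        rng.choice([0.0, 1.0], size=(n_subjects, T))
        if with_baf
        else np.full((n_subjects, T), np.nan)
    )
    return IntensityMatrix(
        [f"s{i}" for i in range(n_subjects)],
        probes,
        rng.standard_normal((n_subjects, T)),
        baf,
        normalized=normalized,
    )


@pytest.fixture
def noise_matrix(rng):
    return make_noise_matrix(50, 20, rng)


@pytest.fixture
def balanced_phenotype():
    def _make(m, n):
        sid = np.array(
            [f"s{i}" for i in range(m + n)], dtype=object
        )
        lab = np.array(["case"] * m + ["control"] * n, dtype=object)
        return Phenotype(sid, lab)

    return _make
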