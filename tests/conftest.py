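import numpy as np
import pandas as pd
import pytest

from lmaland.core_data import AlterationMatrix
from lmaland.landscape import Landscape


def make_landscape(
    k: int = 5,
    seed: int = 0,
    e_min: float = 0.3,
    e_spread: float = 0.5,
    tumour_type: str = "SIM",
) -> Landscape:
    """A synthetic landscape with lognormal SA, uniform SS and a symmetric
    positive epistasis matrix (E >= e_min); deterministic given the seed."""
    rng = np.random.default_rng(seed)
    drivers = [f"D{i:02d}_mut" for i in range(k)]
    sa = {d: float(rng.lognormal(0.5, 0.8)) for d in drivers}
    ss = {d: float(rng.uniform(0.5, 1.5)) for d in drivers}
    raw = np.exp(rng.normal(0.0, e_spread, size=(k, k)))
    e = np.maximum(np.sqrt(raw * raw.T), e_min)
    np.fill_diagonal(e, np.nan)
    freqs = {d: float(f) for d, f in zip(drivers, np.linspace(0.6, 0.1, k))}
    return Landscape(
        tumour_type=tumour_type,
        drivers=drivers,
        sa=sa,
        ss=ss,
        epistasis=pd.DataFrame(e, index=drivers, columns=drivers),
        frequencies=freqs,
    )


def make_uniform_landscape(k: int, sa: float = 1.0, ss: float = 1.0, e: float = 1.0) -> Landscape:
    """All drivers identical, all interactions equal: closed forms apply."""
    drivers = [f"D{i:02d}_mut" for i in range(k)]
    em = np.full((k, k), float(e))
    np.fill_diagonal(em, np.nan)
    return Landscape(
        tumour_type="UNIFORM",
        drivers=drivers,
        sa={d: float(sa) for d in drivers},
        ss={d: float(ss) for d in drivers},
        epistasis=pd.DataFrame(em, index=drivers, columns=drivers),
        frequencies={d: float(f) for d, f in zip(drivers, np.linspace(0.9, 0.1, k))},
    )


def random_binary_matrix(n_samples: int, n_alts: int, seed: int, p: float = 0.5,
                         min_load: int = 1) -> AlterationMatrix:
    rng = np.random.default_rng(seed)
    x = (rng.random((n_samples, n_alts)) < p).astype(np.int8)
    for i in range(n_samples):  # keep every sample and column non-degenerate
        while x[i].sum() < min_load:
            x[i, rng.integers(n_alts)] = 1
    for j in range(n_alts):
        if x[:, j].sum() == 0:
            x[rng.integers(n_samples), j] = 1
    df = pd.DataFrame(
        x,
        index=[f"S{i:03d}" for i in range(n_samples)],
        columns=[f"D{j:02d}_mut" for j in range(n_alts)],
    )
    return AlterationMatrix(df)


@pytest.fixture
def landscape_factory():
    return make_landscape


@pytest.fixture
def uniform_landscape_factory():
    return make_uniform_landscape
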