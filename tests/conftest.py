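import numpy as np
import pytest

from redqueen.model import (FitnessSpec, ModelParams, PopulationState,
                            UniformHotspots)
from redqueen.simulate import SimulationConfig, TrajectoryRecord


def make_population(x, theta, Ne=1000):
    """Population with prescribed frequencies and activities (uniform model).

    Frequencies are converted to integer copy counts, so entries of ``x``
    must be multiples of 1/(2*Ne).
    """
    x = np.asarray(x, dtype=float)
    counts = np.rint(x * 2 * Ne).astype(np.int64)
    assert counts.sum() == 2 * Ne, "x must be resolvable into 2*Ne copies"
    theta = np.asarray(theta, dtype=float)
    return PopulationState(Ne=Ne, ids=np.arange(len(x), dtype=np.int64),
                           counts=counts, dose=-np.log(theta),
                           model=UniformHotspots())


def make_synthetic_trajectory(sample_ids, sample_x, stride=1, Ne=1000,
                              dose=None):
    """TrajectoryRecord built directly from per-sample allele tables."""
    import pandas as pd
    params = ModelParams(Ne=Ne, u=1e-6, v=1e-7, g=1e-2,
                         fitness=FitnessSpec("power", 0.01))
    config = SimulationConfig(params=params, seed=0, record_stride=stride)
    n = len(sample_ids)
    gens = np.arange(n) * stride
    sample_ids = [np.asarray(i, dtype=np.int64) for i in sample_ids]
    sample_x = [np.asarray(x, dtype=float) for x in sample_x]
    if dose is None:
        dose = [np.zeros_like(x) for x in sample_x]
    rows = []
    for t, x in zip(gens, sample_x):
        hom = float(x @ x)
        rows.append({"generation": t, "D": 1.0 / hom, "R": 1.0, "H": 1.0,
                     "hom": hom, "K": len(x)})
    return TrajectoryRecord(config=config, burnin=0, generations=gens,
                            sample_ids=sample_ids, sample_x=sample_x,
                            sample_dose=dose, summaries=pd.DataFrame(rows))


@pytest.fixture
def power_fitness():
    return FitnessSpec("power", 1.0)


@pytest.fixture
def central_params():
    """Central parameter values of the phase-diagram scans."""
    return ModelParams(Ne=100_000, u=1e-6, v=1e-7, g=1e-2,
                       fitness=FitnessSpec("power", 0.01))
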