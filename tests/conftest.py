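import numpy as np
import pytest

from velogrn import TimeSeriesDataset
from velogrn.coupling import Coupling, CouplingSet


def make_dataset(m=4, ns=(5, 5, 5), seed=0, transformed=False, times=None):
    """Small random dataset for unit tests."""
    rng = np.random.default_rng(seed)
    N = len(ns)
    expression = [rng.poisson(5.0, size=(m, n)).astype(float) for n in ns]
    return TimeSeriesDataset(
        gene_names=[f"g{i}" for i in range(m)],
        time_points=np.arange(N, dtype=float) if times is None else np.asarray(times, float),
        expression=expression,
        cell_ids=[[f"t{k}_c{j}" for j in range(n)] for k, n in enumerate(ns)],
        transformed=transformed,
    )


def identity_couplings(ds):
    """Exact identity-matching couplings (permutation/n) for a dataset with
    equal cohort sizes."""
    out = []
    for k in range(ds.n_timepoints - 1):
        n = ds.expression[k].shape[1]
        assert ds.expression[k + 1].shape[1] == n
        out.append(
            Coupling(
                T=np.eye(n) / n,
                p=np.full(n, 1 / n),
                q=np.full(n, 1 / n),
                source_time=float(ds.time_points[k]),
                target_time=float(ds.time_points[k + 1]),
            )
        )
    return CouplingSet(out)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
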