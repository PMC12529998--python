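import numpy as np
import pytest

from ginet.dataset import GIDataset
from ginet.graph_io import Network
from ginet.netfeatures import CORE5, build_pair_features
from ginet.synthetic import BenchmarkConfig, generate_benchmark


@pytest.fixture
def path4() -> Network:
    return Network.from_edges([("A", "B"), ("B", "C"), ("C", "D")])


@pytest.fixture
def k4() -> Network:
    return Network.from_edges(
        [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"), ("C", "D")]
    )


@pytest.fixture
def two_triangles() -> Network:
    return Network.from_edges(
        [("A", "B"), ("B", "C"), ("C", "A"), ("X", "Y"), ("Y", "Z"), ("Z", "X")]
    )


@pytest.fixture(scope="session")
def benchmark():
    """Default synthetic benchmark at seed 1 (the study conditions)."""
    return generate_benchmark(BenchmarkConfig(seed=1))


@pytest.fixture(scope="session")
def benchmark_features(benchmark):
    """Full 18-feature table for every planted pair of the default benchmark."""
    return build_pair_features(
        benchmark.network,
        list(map(tuple, benchmark.pairs[["gene_a", "gene_b"]].to_numpy())),
        seed=1,
    )


@pytest.fixture(scope="session")
def benchmark_labeled(benchmark, benchmark_features):
    """Labeled pair table joined with its features (label + 18 columns)."""
    return benchmark.pairs.merge(benchmark_features, on=["gene_a", "gene_b"])


@pytest.fixture(scope="session")
def benchmark_dataset(benchmark, benchmark_features) -> GIDataset:
    return GIDataset.from_features(benchmark.pairs, benchmark_features)


@pytest.fixture(scope="session")
def benchmark_core5(benchmark_dataset) -> GIDataset:
    return benchmark_dataset.select_features(list(CORE5))


@pytest.fixture(scope="session")
def separable_dataset() -> GIDataset:
    """Well-separated 3-class Gaussian features keyed by dummy gene pairs."""
    import pandas as pd

    rng = np.random.default_rng(42)
    rows = []
    centers = {"SL": (0.0, 0.0), "SV": (6.0, 0.0), "NOT": (0.0, 6.0)}
    i = 0
    for label, (cx, cy) in centers.items():
        for _ in range(100):
            rows.append(
                {
                    "gene_a": f"A{i}",
                    "gene_b": f"B{i}",
                    "label": label,
                    "f1": rng.normal(cx, 0.5),
                    "f2": rng.normal(cy, 0.5),
                }
            )
            i += 1
    return GIDataset(pd.DataFrame(rows))
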