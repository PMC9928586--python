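import numpy as np
import pandas as pd
import pytest

from lungmap import SpotMatrix


@pytest.fixture
def toy_spot_matrix() -> SpotMatrix:
    """3 spots x 2 genes with simple coordinates."""
    return SpotMatrix(
        counts=np.array([[5, 0], [2, 3], [0, 0]]),
        spot_ids=np.array(["s1", "s2", "s3"], dtype=object),
        gene_ids=np.array(["GA", "GB"], dtype=object),
        coords=np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]]),
    )


def random_spot_matrix(rng: np.random.Generator, n_spots: int = 50,
                       n_genes: int = 40, lam: float = 10.0) -> SpotMatrix:
    """Poisson-count matrix sized so QC thresholds actually bite."""
    counts = rng.poisson(lam, size=(n_spots, n_genes))
    # sparsify so gene detection and per-spot gene counts vary
    counts[rng.random((n_spots, n_genes)) < 0.4] = 0
    return SpotMatrix(
        counts=counts,
        spot_ids=np.array([f"s{i}" for i in range(n_spots)], dtype=object),
        gene_ids=np.array([f"g{j}" for j in range(n_genes)], dtype=object),
        coords=rng.uniform(0, 1000, size=(n_spots, 2)),
    )


def qc_oracle(counts: np.ndarray, min_umi: int, min_genes: int,
              min_spots_per_gene: int) -> tuple[list[int], list[int]]:
    """Brute-force loop restatement of the spot-then-gene QC filter."""
    spots = []
    for i in range(counts.shape[0]):
        total = 0
        detected = 0
        for j in range(counts.shape[1]):
            total += counts[i, j]
            if counts[i, j] > 0:
                detected += 1
        if total >= min_umi and detected >= min_genes:
            spots.append(i)
    genes = []
    for j in range(counts.shape[1]):
        n_det = sum(1 for i in spots if counts[i, j] > 0)
        if n_det >= min_spots_per_gene:
            genes.append(j)
    return spots, genes
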