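import numpy as np
import pytest

from richnet import FCMatrix, load_region_table


@pytest.fixture(scope="session")
def default_table():
    return load_region_table()


@pytest.fixture
def toy_table(tmp_path):
    """Six-region table with two rich-club members over three subnetworks."""
    path = tmp_path / "regions.tsv"
    path.write_text(
        "index\tname\tsubnetwork\trich_club\n"
        "1\tA\tSN\t1\n2\tB\tSN\t1\n3\tC\tDMN\t0\n"
        "4\tD\tDMN\t0\n5\tE\tFPN\t0\n6\tF\tFPN\t0\n"
    )
    return path


def random_fc(rng, n=12, density=0.4) -> FCMatrix:
    mask = np.triu(rng.random((n, n)) < density, 1)
    w = np.zeros((n, n))
    w[mask] = rng.uniform(0.05, 0.95, size=int(mask.sum()))
    return FCMatrix(w=w + w.T)


@pytest.fixture
def rng():
    return np.random.default_rng(20230907)
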