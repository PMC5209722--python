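import numpy as np
import pytest

import lncwalk as lw


def random_network(rng: np.random.Generator, max_per_layer: int = 10,
                   density: float = 0.35) -> lw.CompositeNetwork:
    """A random valid composite network (independent of the synthetic module)."""
    ng, nph, nl = (int(v) for v in rng.integers(1, max_per_layer + 1, size=3))

    def sym(n: int) -> np.ndarray:
        A = rng.random((n, n)) * (rng.random((n, n)) < density)
        A = np.triu(A, 1)
        return A + A.T

    def cross(a: int, b: int) -> np.ndarray:
        return rng.random((a, b)) * (rng.random((a, b)) < density)

    net = lw.CompositeNetwork(
        [f"g{i:03d}" for i in range(ng)],
        [f"p{i:03d}" for i in range(nph)],
        [f"l{i:03d}" for i in range(nl)],
        sym(ng), sym(nph), sym(nl),
        cross(ng, nph), cross(ng, nl), cross(nph, nl),
    )
    net.validate()
    return net


def random_jumps(rng: np.random.Generator) -> lw.JumpParams:
    while True:
        x, y, z = rng.random(3) * 0.6
        try:
            return lw.JumpParams(x, y, z)
        except ValueError:  # pairwise sum cap
            continue


@pytest.fixture(scope="session")
def t1_network() -> lw.CompositeNetwork:
    """Tiny worked-example network: 2 genes, 1 phenotype, 1 lncRNA, 4 edges."""
    tables = {
        "gene-gene": lw.EdgeTable.from_records(
            "gene-gene", [("g1", "g2", 1.0, "experimental")]),
        "gene-phenotype": lw.EdgeTable.from_records(
            "gene-phenotype", [("g1", "p1", 1.0, "experimental")]),
        "gene-lncrna": lw.EdgeTable.from_records(
            "gene-lncrna", [("g2", "l1", 0.5, "predicted")]),
        "phenotype-lncrna": lw.EdgeTable.from_records(
            "phenotype-lncrna", [("p1", "l1", 1.0, "experimental")]),
    }
    return lw.build_composite(tables)


@pytest.fixture(scope="session")
def default_fixture():
    """The standard planted benchmark (generator seed 42)."""
    return lw.generate_network(lw.SynthConfig())


@pytest.fixture(scope="session")
def default_loocv(default_fixture):
    net, catalog, _ = default_fixture
    return lw.loocv(net, catalog)
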