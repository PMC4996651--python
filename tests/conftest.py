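import numpy as np
import pandas as pd
import pytest

from lgatlas import lineage, simulate


@pytest.fixture(scope="session")
def atlas_tree():
    return simulate.default_atlas_tree()


@pytest.fixture(scope="session")
def toy():
    """Deterministic toy annotation fixture with its hand-built truth table."""
    return simulate.make_toy_annotation(seed=0)


@pytest.fixture(scope="session")
def toy_dir(toy, tmp_path_factory):
    d = tmp_path_factory.mktemp("toy")
    toy.write(d)
    return d


@pytest.fixture(scope="session")
def small_expression():
    """10 samples x 40 genes random matrix plus a matching balanced tree."""
    rng = np.random.default_rng(42)
    samples = [f"s{i}" for i in range(10)]
    genes = [f"g{i}" for i in range(40)]
    norm = pd.DataFrame(rng.uniform(1, 100, size=(40, 10)), index=genes, columns=samples)
    tree = lineage.parse_newick("((s0,s1),(s2,s3),((s4,s5),(s6,s7)),(s8,s9));")
    return norm, tree
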