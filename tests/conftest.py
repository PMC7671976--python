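import numpy as np
import pytest

import deraml as d
from deraml.variants import AMINO_ACIDS, PointMutation, Variant


def random_variant(graph, rng, n_mutations=None):
    """A random variant with 1-3 mutations at distinct graph positions."""
    k = int(n_mutations if n_mutations is not None else rng.integers(1, 4))
    positions = rng.choice(graph.positions, size=k, replace=False)
    muts = []
    for p in positions:
        wt = graph.amino_acid_at(int(p))
        alternatives = [a for a in AMINO_ACIDS if a != wt]
        muts.append(PointMutation(int(p), wt, str(rng.choice(alternatives))))
    return Variant(muts)


def random_variant_set(graph, n, rng, include_wt=False):
    out = [Variant(())] if include_wt else []
    seen = {str(v) for v in out}
    while len(out) < n:
        v = random_variant(graph, rng)
        if str(v) not in seen:
            seen.add(str(v))
            out.append(v)
    return out


@pytest.fixture(scope="session")
def small_graph():
    return d.generate_toy_structure(30, seed=3)


@pytest.fixture(scope="session")
def medium_graph():
    return d.generate_toy_structure(60, seed=3)


@pytest.fixture(scope="session")
def models():
    return d.load_substitution_models()


@pytest.fixture(scope="session")
def small_bank(small_graph):
    return d.KernelBank.default(small_graph)
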