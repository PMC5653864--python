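import numpy as np
import pytest

from paleotempo import CharacterMatrix, TimeTree, Timescale


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def toy_matrix():
    """3 taxa x 4 characters with one MISSING cell."""
    return CharacterMatrix(
        taxon_labels=["A", "B", "C"],
        state_symbols=[["0", "1"], ["0", "1"], ["0", "1", "2"], ["0", "1"]],
        codes=np.array([[0, 1, -1, 0], [1, 0, 2, 0], [0, 0, 1, 1]]),
    )


@pytest.fixture
def cherry_tree():
    """Two tips at 0 Ma joined at 10 Ma: ((A:10,B:10) at age 10)."""
    return TimeTree(
        parent=np.array([-1, 0, 0]),
        age=np.array([10.0, 0.0, 0.0]),
        labels=[None, "A", "B"],
    )


@pytest.fixture
def four_tip_tree():
    """Balanced 4-tip tree, root 20 Ma, internal nodes 12 and 8 Ma."""
    return TimeTree(
        parent=np.array([-1, 0, 0, 1, 1, 2, 2]),
        age=np.array([20.0, 12.0, 8.0, 0.0, 2.0, 0.0, 3.0]),
        labels=[None, None, None, "A", "B", "C", "D"],
    )


def random_matrix(rng, n_taxa, n_char, p_miss=0.2, max_states=4) -> CharacterMatrix:
    syms, codes = [], np.zeros((n_taxa, n_char), dtype=np.int64)
    for k in range(n_char):
        ks = int(rng.integers(2, max_states + 1))
        syms.append([str(i) for i in range(ks)])
        codes[:, k] = rng.integers(0, ks, size=n_taxa)
        miss = rng.random(n_taxa) < p_miss
        codes[miss, k] = -1
    return CharacterMatrix(
        taxon_labels=[f"t{i}" for i in range(n_taxa)],
        state_symbols=syms,
        codes=codes,
    )


def random_time_tree(rng, n_tips, span=100.0) -> TimeTree:
    """Random binary topology with ages drawn to respect monotonicity."""
    # coalescent-style: start with tips at random young ages, merge upward
    age = list(rng.uniform(0.0, 0.25 * span, size=n_tips))
    nodes = list(range(n_tips))
    parent = {i: -1 for i in nodes}
    labels = {i: f"t{i+1}" for i in nodes}
    nxt = n_tips
    current = max(age)
    active = nodes[:]
    while len(active) > 1:
        current += rng.uniform(0.05 * span, 0.2 * span)
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        parent[nxt] = -1
        age.append(current)
        labels[nxt] = None
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    n = len(age)
    return TimeTree(
        parent=np.array([parent[i] for i in range(n)]),
        age=np.array(age),
        labels=[labels[i] for i in range(n)],
    )
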