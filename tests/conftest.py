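import itertools

import pytest
from hypothesis import settings

from mitoarch import fixtures as fx
from mitoarch.simulate import GeneratorSpec, generate_record

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def chefuensis():
    """Shallow-water snailfish record (WYANC cluster, 37 genes)."""
    return fx.chefuensis_record()


@pytest.fixture(scope="session")
def tanakae():
    """Deep-water snailfish record (WNCYAA cluster, 38 genes)."""
    return fx.tanakae_record()


@pytest.fixture(scope="session")
def synthetic_wncyaa():
    """One sequenced synthetic genome with a rearranged cluster + ledger."""
    return generate_record(GeneratorSpec(seed=11, cluster_pattern="WNCYAA"))


@pytest.fixture(scope="session")
def study_tree_and_maps():
    return fx.liparidae_newick(), fx.pattern_map(), fx.depth_map()


# ---------------------------------------------------------------------------
# independent oracles shared across test modules
# ---------------------------------------------------------------------------


def brute_force_parsimony(tree, chars) -> int:
    """Minimum state changes by exhaustive internal-node labeling."""
    internals = [n for n in tree.postorder_node_iter() if n.child_nodes()]
    states = sorted(set(chars.values()))
    best = None
    for combo in itertools.product(states, repeat=len(internals)):
        lab = dict(zip(internals, combo))
        cost = 0
        for n in tree.postorder_node_iter():
            for ch in n.child_nodes():
                s_ch = lab[ch] if ch.child_nodes() else chars[ch.taxon.label]
                if lab[n] != s_ch:
                    cost += 1
        best = cost if best is None else min(best, cost)
    return best


def tdrl_successor_states(state: tuple) -> set:
    """All orders reachable in exactly one duplication-loss round, by raw
    subset enumeration (no embedding machinery)."""
    out = set()
    n = len(state)
    alphabet = set(state)
    for i in range(1, n + 1):
        for j in range(i, n + 1):
            post = state[:j] + state[i - 1:j] + state[j:]
            m = len(post)
            for mask in range(1 << m):
                kept = tuple(post[k] for k in range(m) if mask >> k & 1)
                if set(kept) == alphabet:
                    out.add(kept)
    return out


def tdrl_min_rounds_oracle(source, target, max_rounds) -> int | None:
    """Minimum TDRL rounds by breadth-first state enumeration."""
    source, target = tuple(source), tuple(target)
    level = {source}
    if target in level:
        return 0
    for r in range(1, max_rounds + 1):
        level = set().union(*(tdrl_successor_states(s) for s in level))
        if target in level:
            return r
    return None
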