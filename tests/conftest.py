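import numpy as np
import pytest

from phyloshift import asr, core_io, synth


@pytest.fixture(scope="session")
def lg_model():
    """21-state LG+gap model, 1 gamma category (cheap default for tests)."""
    return asr.SubstitutionModel.empirical("LG", alpha=1.0, n_categories=1)


@pytest.fixture(scope="session")
def lg_gamma_model():
    return asr.SubstitutionModel.empirical("LG", alpha=0.7, n_categories=2)


@pytest.fixture()
def four_leaf_tree():
    return core_io.read_tree(
        "((a:0.15,b:0.25)0.9:0.1,(c:0.3,d:0.2)0.8:0.35);")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def brute_force_marginals(msa, tree, model):
    """Independent oracle: exhaustive enumeration of all internal-state
    assignments, per site, mixed over gamma categories.

    Returns dict node_id -> (n_sites, n_states) posterior array.  Only
    feasible for <= 5 leaves and <= 3 sites.
    """
    import itertools

    internal = [n for n in tree.internal_nodes()]
    leaves = tree.leaves()
    n_states = model.n_states
    n_sites = msa.length
    post = {n.id: np.zeros((n_sites, n_states)) for n in internal}
    for site in range(n_sites):
        total = 0.0
        accum = {n.id: np.zeros(n_states) for n in internal}
        for rate in model.category_rates:
            P = {
                n.id: model.transition_matrix(n.length * rate)
                for n in tree.preorder() if n.parent is not None
            }
            leaf_vec = {
                leaf.id: model.encode(msa.sequence(leaf.label))[site]
                for leaf in leaves
            }
            for assignment in itertools.product(range(n_states),
                                                repeat=len(internal)):
                states = dict(zip((n.id for n in internal), assignment))
                prob = model.frequencies[states[tree.root.id]]
                for node in tree.preorder():
                    if node.parent is None:
                        continue
                    parent_state = states[node.parent.id]
                    if node.is_leaf:
                        prob *= float(
                            P[node.id][parent_state] @ leaf_vec[node.id])
                    else:
                        prob *= P[node.id][parent_state, states[node.id]]
                total += prob
                for node in internal:
                    accum[node.id][states[node.id]] += prob
        for node in internal:
            post[node.id][site] = accum[node.id] / total
    return post
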