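import numpy as np
import pytest

from sleepgraph import factor, graph, pcr, synthetic


def small_spec(seed: int = 7, effect_size: float = 0.5, n: int = 150) -> synthetic.CohortSpec:
    """Desk-scale study conditions reused across tests: 5 sites, 30 nodes,
    3 networks of 10."""
    return synthetic.CohortSpec(
        n_participants=n,
        n_sites=5,
        n_nodes=30,
        community_sizes=(10, 10, 10),
        effect_size=effect_size,
        seed=seed,
    )


@pytest.fixture(scope="session")
def planted_cohort():
    return synthetic.generate_cohort(small_spec())


@pytest.fixture(scope="session")
def planted_pipeline(planted_cohort):
    """Features, scored phenotypes, covariates and target of the planted cohort."""
    coh = planted_cohort
    X = graph.build_feature_matrix([m.weights for m in coh.connectomes], coh.communities)
    pheno, fmodel = factor.add_sleep_scores(coh.phenotypes)
    y = pheno["sleep_deficit"].to_numpy(dtype=float)
    C, _ = pcr.covariate_design(pheno)
    return {
        "cohort": coh,
        "X": X,
        "pheno": pheno,
        "factor_model": fmodel,
        "y": y,
        "C": C,
        "sites": pheno["site"].to_numpy(),
    }


def random_signed_graph(rng: np.random.Generator, n_nodes: int, n_networks: int):
    """Random symmetric signed weighted graph with a random community map."""
    w = rng.uniform(-1, 1, size=(n_nodes, n_nodes))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    labels = [f"c{j}" for j in range(n_networks)]
    node_labels = [labels[j] for j in range(n_networks)]  # every network nonempty
    node_labels += [labels[rng.integers(n_networks)] for _ in range(n_nodes - n_networks)]
    rng.shuffle(node_labels)
    # reshuffle until all networks present (shuffle preserves multiset, so always true)
    return w, graph.CommunityAssignment(tuple(node_labels), tuple(labels))


def naive_mdp_pcp(w: np.ndarray, comm: graph.CommunityAssignment):
    """Double-loop oracle for MDP/PCP on a positive-thresholded graph."""
    n = w.shape[0]
    wp = np.where(w > 0, w, 0.0).copy()
    np.fill_diagonal(wp, 0.0)
    labels = list(comm.node_to_network)
    mdp = np.zeros(n)
    pcp = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j and labels[j] == labels[i]:
                mdp[i] += wp[i, j]
        k_i = sum(wp[i, j] for j in range(n) if j != i)
        if k_i > 0:
            acc = 0.0
            for s in comm.networks:
                kappa = sum(wp[i, j] for j in range(n) if j != i and labels[j] == s)
                acc += (kappa / k_i) ** 2
            pcp[i] = 1.0 - acc
    return mdp, pcp
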