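import numpy as np
import pytest
from hypothesis import settings

from aimpanel.hierarchy import HierarchyConfig, reference_config
from aimpanel.simulate import simulate_dataset

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def balanced_tree(n_sub: int = 2, n_pools: int = 1):
    """4 lineages x n_sub subspecies x n_pools pools, fully balanced."""
    return {
        L: {f"{L}_sub{i}": [f"{L}_sub{i}_p{j}" for j in range(1, n_pools + 1)]
            for i in range(1, n_sub + 1)}
        for L in "ACMO"
    }


@pytest.fixture(scope="session")
def small_sim():
    """A modest 4-lineage / 8-subspecies / 8-pool dataset with genotypes."""
    cfg = HierarchyConfig(
        tree=balanced_tree(),
        n_snps=600,
        n_individuals_per_pool=40,
        null_allele_rate=0.05,
        quotas={"global": 60},
    )
    return cfg, simulate_dataset(cfg, seed=1234)


@pytest.fixture(scope="session")
def reference_sim_20k():
    """The 22-pool / 14-subspecies / 4-lineage reference design at 20k SNPs.

    Used for the panel quota arithmetic; only one individual per pool is
    simulated since genotypes are not needed at this scale.
    """
    cfg = reference_config(n_snps=20000, n_individuals_per_pool=1)
    return cfg, simulate_dataset(cfg, seed=20260101)


@pytest.fixture(scope="session")
def classified_sim():
    """Reference-shaped simulation with a trained classifier and held-out
    probabilities, shared by classification and reporting tests."""
    import aimpanel as ap

    cfg = reference_config(
        n_snps=4000, n_individuals_per_pool=25,
        quotas={"global": 100, "M": 60, "O": 100, "C": 200},
    )
    data = simulate_dataset(cfg, seed=42)
    pca = ap.hierarchical_pca_select(data.pool_table, cfg)
    fst = ap.select_fst_panel(data.pool_table, k_loose=5, k_stringent=15,
                              exclude=set(pca.snps))
    panel = ap.merge_panels(pca, fst)
    gm = data.genotypes.subset_snps(panel.snps)
    train_ids, test_ids = ap.split_reference(gm.samples, 0.7, seed=42)
    train, test = gm.subset_samples(train_ids), gm.subset_samples(test_ids)
    model = ap.fit(
        ap.default_candidates(42)["linear_svc"],
        ap.one_hot_encode(train), train.label_series("subspecies"),
        seed=42, name="linear_svc",
    )
    probs = ap.predict_probabilities(model, ap.one_hot_encode(test))
    return {
        "config": cfg, "data": data, "panel": panel, "model": model,
        "train": train, "test": test, "probs": probs,
        "y_test": test.label_series("subspecies"),
    }
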