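import numpy as np
import pytest

import erpsem


@pytest.fixture(scope="session")
def small_space():
    """300-word embedding space with planted factors (the standard fixture)."""
    space, truth = erpsem.generate_embeddings(300, 50, 8, 4.0, seed=1)
    return space, truth


@pytest.fixture(scope="session")
def noiseless_erp(small_space):
    """Noiseless ERPs: effect confined to 300-500 ms, factors 1-3 planted."""
    space, truth = small_space
    truth = erpsem.GroundTruth(
        factor_loadings=truth.factor_loadings,
        loading_directions=truth.loading_directions,
        seed=truth.seed,
    )
    erpsem.plant_forward_model(truth, 28, noise_sd=0.0)
    erp = erpsem.generate_erp(space, truth, 28)
    return erp, truth


@pytest.fixture(scope="session")
def noisy_erp(small_space):
    """Default-noise ERPs on the standard fixture."""
    space, truth = small_space
    truth = erpsem.GroundTruth(
        factor_loadings=truth.factor_loadings,
        loading_directions=truth.loading_directions,
        seed=truth.seed,
    )
    erpsem.plant_forward_model(truth, 28)
    erp = erpsem.generate_erp(space, truth, 28)
    return erp, truth


@pytest.fixture(scope="session")
def folds_300(small_space):
    space, _ = small_space
    return erpsem.make_folds(space.words, 10, seed=1)


@pytest.fixture(scope="session")
def components_300(small_space):
    space, _ = small_space
    return erpsem.kernel_pca(erpsem.cosine_kernel(space), 8)


def exact_signed_rank_p(diffs: np.ndarray) -> float:
    """Brute-force two-sided signed-rank p: enumerate all 2^n sign patterns."""
    from scipy.stats import rankdata

    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    patterns = (np.arange(2**n)[:, None] >> np.arange(n)) & 1  # 2^n x n of {0,1}
    w_all = patterns @ ranks
    p_le = np.mean(w_all <= w_obs + 1e-12)
    p_ge = np.mean(w_all >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


def exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Brute-force two-sided rank-sum p: enumerate all C(n, m) label splits."""
    from itertools import combinations

    from scipy.stats import rankdata

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    r_obs = ranks[: a.size].sum()
    mean_r = a.size * (pooled.size + 1) / 2.0
    stats = np.array(
        [ranks[list(c)].sum() for c in combinations(range(pooled.size), a.size)]
    )
    # two-sided by distance of the rank sum from its null mean
    p = np.mean(np.abs(stats - mean_r) >= abs(r_obs - mean_r) - 1e-12)
    return min(1.0, float(p))
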