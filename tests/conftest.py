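import numpy as np
import pytest

from rhm import QtlEffect, SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 300-individual, 2-chromosome dataset with two planted pleiotropic QTL.

    Small enough for dense REML everywhere, large enough that the planted
    signals are visible to the scan.
    """
    qtl = [QtlEffect(1, 40_000_000, (0.40, 0.30, 0.0)),
           QtlEffect(2, 60_000_000, (0.0, 0.20, -0.30))]
    cfg = SimConfig(n_founders=100, n_generations=3, n_offspring_per_mating=2,
                    n_chromosomes=2, n_snps_per_chrom=120, qtl_spec=qtl,
                    seed=11)
    ped, gm, mmap, pheno, truth = simulate_dataset(cfg)
    return {"config": cfg, "pedigree": ped, "genotypes": gm, "map": mmap,
            "phenotypes": pheno, "truth": truth}


def naive_restricted_loglik(y, X, Ks, theta):
    """Dense textbook evaluation of the restricted log-likelihood (test oracle).

    Builds the full covariance, inverts it explicitly, and assembles
    -0.5 [ log|V| + log|X'V^-1 X| + (y-Xb)'V^-1(y-Xb) + (n-p) log 2 pi ].
    Kept deliberately naive and independent of the package's evaluation path.
    """
    y = np.asarray(y, float)
    n = y.size
    p = X.shape[1]
    V = theta[-1] * np.eye(n)
    for t, K in zip(theta[:-1], Ks):
        V = V + t * K
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    quad = float(r @ Vi @ r)
    s1, ld_V = np.linalg.slogdet(V)
    s2, ld_X = np.linalg.slogdet(XtViX)
    assert s1 > 0 and s2 > 0
    return -0.5 * (ld_V + ld_X + quad + (n - p) * np.log(2 * np.pi))


@pytest.fixture(scope="session")
def toy_psd_matrices():
    """Five fixed small PSD matrices with matching response vectors."""
    instances = []
    for i, (n, seed) in enumerate([(8, 101), (10, 102), (12, 103),
                                   (9, 104), (11, 105)]):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((n, n))
        K = A @ A.T / n
        L = np.linalg.cholesky(K + 1e-9 * np.eye(n))
        y = L @ rng.standard_normal(n) + 0.8 * rng.standard_normal(n)
        instances.append((y, K))
    return instances
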