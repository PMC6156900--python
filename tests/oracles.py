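"""Independent oracles used by the tests.

These deliberately avoid the package's computational paths: gene dropping
estimates expected allele sharing by Monte-Carlo transmission of founder
alleles, and the dense restricted log-likelihood works with full n x n
matrices, explicit solves and slogdets.
"""

from __future__ import annotations

import numpy as np

from famassoc.pedigree import Individual, Pedigree


def gene_drop_relationship(ped: Pedigree, n_loci: int, rng: np.random.Generator):
    """Monte-Carlo estimate of K = 2*Phi by dropping founder alleles.

    Every individual carries two allele labels per locus; founders (and
    unobserved parent slots) get globally unique labels, children inherit
    one random allele from each parent independently per locus.  The
    per-locus kinship between i and j is the fraction of the four
    allele-pair comparisons that are identical by descent.

    Returns ``(K_hat, K_se)`` aligned to ``ped.ids`` — the estimate and its
    Monte-Carlo standard error (zero for structurally constant pairs).
    """
    topo = ped.topological_order()
    ids = ped.ids
    n = len(ids)
    alleles: dict[str, np.ndarray] = {}
    next_label = 0
    for iid in topo:
        ind = ped[iid]
        pair = np.empty((n_loci, 2), dtype=np.int64)
        for slot, parent in enumerate((ind.father_id, ind.mother_id)):
            if parent is None:
                # a missing parent contributes two unique founder alleles,
                # transmitted at random per locus
                choice = rng.integers(2, size=n_loci)
                pair[:, slot] = next_label + choice
                next_label += 2
            else:
                pa = alleles[parent]
                choice = rng.integers(2, size=n_loci)
                pair[:, slot] = pa[np.arange(n_loci), choice]
        alleles[iid] = pair
    k_hat = np.zeros((n, n))
    k_se = np.zeros((n, n))
    for i in range(n):
        ai = alleles[ids[i]]
        for j in range(i, n):
            aj = alleles[ids[j]]
            if i == j:
                # phi_ii = (1 + P(two alleles of i are IBD)) / 2 per locus
                phi = 0.5 * (1.0 + (ai[:, 0] == ai[:, 1]).astype(float))
            else:
                phi = 0.25 * (
                    (ai[:, 0] == aj[:, 0]).astype(float)
                    + (ai[:, 0] == aj[:, 1])
                    + (ai[:, 1] == aj[:, 0])
                    + (ai[:, 1] == aj[:, 1])
                )
            k_hat[i, j] = k_hat[j, i] = 2.0 * phi.mean()
            k_se[i, j] = k_se[j, i] = 2.0 * phi.std(ddof=1) / np.sqrt(n_loci)
    return k_hat, k_se


def random_pedigree(rng: np.random.Generator, max_members: int = 10) -> Pedigree:
    """A random acyclic single-family pedigree with 2-4 founders and random
    two-parent matings drawn from already-created members."""
    n_founders = int(rng.integers(2, 5))
    members = [Individual(f"I{i}", "FAM") for i in range(n_founders)]
    total = int(rng.integers(n_founders + 1, max_members + 1))
    while len(members) < total:
        i, j = rng.choice(len(members), size=2, replace=False)
        members.append(
            Individual(
                f"I{len(members)}",
                "FAM",
                father_id=members[int(i)].individual_id,
                mother_id=members[int(j)].individual_id,
            )
        )
    return Pedigree(members)


def dense_restricted_loglik(y, X, K, sigma2_mu, sigma2_eps):
    """Textbook residual-contrast restricted log-likelihood, dense route."""
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    V = sigma2_mu * np.asarray(K, float) + sigma2_eps * np.eye(n)
    Vi = np.linalg.inv(V)
    A = X.T @ Vi @ X
    beta = np.linalg.solve(A, X.T @ Vi @ y)
    r = y - X @ beta
    _, logdet_v = np.linalg.slogdet(V)
    _, logdet_a = np.linalg.slogdet(A)
    _, logdet_x = np.linalg.slogdet(X.T @ X)
    return -0.5 * (
        (n - p) * np.log(2.0 * np.pi)
        + logdet_v
        + logdet_a
        - logdet_x
        + float(r @ Vi @ r)
    )


def dense_reml_grid(y, X, K, log_lambda_grid):
    """Grid-search REML oracle maximizing the profiled dense restricted
    likelihood over lambda = sigma2_mu / sigma2_eps; returns (s2_mu, s2_eps)."""
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    K = np.asarray(K, float)
    best = (-np.inf, 0.0, 0.0)
    for g in log_lambda_grid:
        lam = float(np.exp(g))
        H = lam * K + np.eye(n)
        Hi = np.linalg.inv(H)
        A = X.T @ Hi @ X
        beta = np.linalg.solve(A, X.T @ Hi @ y)
        r = y - X @ beta
        s2 = float(r @ Hi @ r) / (n - p)
        ll = dense_restricted_loglik(y, X, K, lam * s2, s2)
        if ll > best[0]:
            best = (ll, lam * s2, s2)
    return best[1], best[2]
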