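"""Independent numerical oracles used by the test suite.

Each oracle computes a quantity by brute force — Monte-Carlo
integration, exhaustive enumeration, dense linear algebra — without
touching the code path it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import logsumexp


def mc_log_marginal(
    y: np.ndarray,
    X: np.ndarray,
    c: float,
    n_samples: int = 10**7,
    seed: int = 123,
    chunk: int = 10**6,
) -> float:
    """Monte-Carlo estimate of the log marginal likelihood.

    Integrates  N(y; a + X b, s2 I) * N(b; 0, c*s2*(Xc'Xc)^-1) * (1/s2)
    over (a, b, s2) by importance sampling: (a, b) from wide Gaussians
    around the least-squares fit, log s2 from a Gaussian.  X holds the
    g-prior regressors (self-lag + candidates), no intercept column;
    the prior scatter matrix uses the mean-centred X.
    """
    rng = np.random.default_rng(seed)
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    A = Xc.T @ Xc
    _, logdetA = np.linalg.slogdet(A)
    Xfull = np.column_stack([np.ones(n), X])
    coef, *_ = np.linalg.lstsq(Xfull, y, rcond=None)
    resid = y - Xfull @ coef
    s2_hat = float(resid @ resid) / max(n - p - 1, 1)
    scale = 6.0 * np.sqrt(s2_hat * np.diag(np.linalg.inv(Xfull.T @ Xfull)))
    logs2_mu, logs2_sd = np.log(s2_hat), 1.5

    chunks = []
    done = 0
    while done < n_samples:
        m = min(chunk, n_samples - done)
        theta = coef + rng.standard_normal((m, p + 1)) * scale
        logs2 = logs2_mu + rng.standard_normal(m) * logs2_sd
        s2 = np.exp(logs2)
        r = y[None, :] - theta @ Xfull.T
        loglik = -0.5 * n * np.log(2 * np.pi * s2) - 0.5 * np.sum(r * r, axis=1) / s2
        b = theta[:, 1:]
        quad = np.einsum("ij,jk,ik->i", b, A, b)
        logprior_b = (
            -0.5 * p * np.log(2 * np.pi * c * s2) + 0.5 * logdetA - 0.5 * quad / (c * s2)
        )
        logprior_s2 = -logs2
        logq = (
            -0.5 * np.sum(((theta - coef) / scale) ** 2, axis=1)
            - np.sum(np.log(scale))
            - 0.5 * (p + 1) * np.log(2 * np.pi)
            - 0.5 * ((logs2 - logs2_mu) / logs2_sd) ** 2
            - np.log(logs2_sd)
            - 0.5 * np.log(2 * np.pi)
            - logs2  # density over s2, not log s2
        )
        chunks.append(logsumexp(loglik + logprior_b + logprior_s2 - logq))
        done += m
    return float(logsumexp(chunks) - np.log(n_samples))


def enumerate_edge_posteriors(design, prior_fn, g, accepted_subsets):
    """Edge posteriors by independent re-scoring of given subsets.

    Re-fits every subset with plain numpy least squares, recomputes the
    g-prior marginal from its closed form written out locally, and sums
    posterior mass per regulator, normalizing over the provided subsets
    only.  Kept deliberately separate from the scoring module.
    """
    from scipy.special import gammaln

    y = design.y
    n = y.shape[0]
    tss = float(np.sum((y - y.mean()) ** 2))
    log_posts = []
    for subset in accepted_subsets:
        X = np.column_stack(
            [design.X_base]
            + [design.X_candidates[:, design.candidate_ids.index(s)] for s in subset]
        )
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sse = max(float(resid @ resid), 1e-12 * float(y @ y))
        p = len(subset) + 1
        q = (g / (1 + g)) * sse + (1 / (1 + g)) * tss
        lml = (
            gammaln((n - 1) / 2)
            - ((n - 1) / 2) * np.log(np.pi)
            - 0.5 * np.log(n)
            - (p / 2) * np.log1p(g)
            - ((n - 1) / 2) * np.log(q)
        )
        log_posts.append(lml + prior_fn(subset))
    log_posts = np.asarray(log_posts)
    nc = logsumexp(log_posts)
    posteriors = {}
    for rid in design.candidate_ids:
        mass = [lp for lp, s in zip(log_posts, accepted_subsets) if rid in s]
        posteriors[rid] = float(np.exp(logsumexp(mass) - nc)) if mass else 0.0
    return posteriors


def brute_force_betweenness(nodes, edges):
    """Unnormalized directed betweenness by exhaustive path enumeration."""
    adj = {u: [] for u in nodes}
    for u, v in edges:
        adj[u].append(v)

    def all_shortest_paths(s, t):
        # BFS layer by layer, collecting every shortest path
        if s == t:
            return []
        paths, frontier, best = [], [[s]], None
        while frontier and best is None:
            nxt = []
            for path in frontier:
                for w in adj[path[-1]]:
                    if w in path:
                        continue
                    if w == t:
                        paths.append(path + [w])
                    else:
                        nxt.append(path + [w])
            if paths:
                best = len(paths[0])
            frontier = nxt
        return paths

    b = {u: 0.0 for u in nodes}
    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            paths = all_shortest_paths(s, t)
            if not paths:
                continue
            for path in paths:
                for mid in path[1:-1]:
                    b[mid] += 1.0 / len(paths)
    return b


def dense_pagerank(nodes, edges, damping=0.85):
    """PageRank by dense eigen-solve of the Google matrix."""
    n = len(nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    M = np.zeros((n, n))
    for u, v in edges:
        M[idx[v], idx[u]] = 1.0
    col = M.sum(axis=0)
    for j in range(n):
        if col[j] > 0:
            M[:, j] /= col[j]
        else:
            M[:, j] = 1.0 / n  # dangling mass spread uniformly
    G = damping * M + (1 - damping) / n * np.ones((n, n))
    w, V = np.linalg.eig(G)
    k = int(np.argmax(w.real))
    v = np.abs(V[:, k].real)
    v /= v.sum()
    return {u: float(v[idx[u]]) for u in nodes}


def prefix_aupr(ranked_labels):
    """Area under the PR curve by stepping through every rank prefix.

    ``ranked_labels``: booleans in descending-score order, no ties.
    Builds the full precision/recall sequence one prefix at a time and
    sums trapezoids over consecutive recall-advancing prefixes; the
    first advance contributes a rectangle (precision is undefined at
    the empty prefix).
    """
    n_pos = sum(ranked_labels)
    precisions, recalls = [], []
    tp = 0
    for k, lab in enumerate(ranked_labels, start=1):
        tp += int(lab)
        precisions.append(tp / k)
        recalls.append(tp / n_pos)
    area = 0.0
    prev_p, prev_r = None, 0.0
    for p, r in zip(precisions, recalls):
        if r > prev_r:
            area += (r - prev_r) * (p if prev_p is None else 0.5 * (prev_p + p))
        prev_p, prev_r = p, r
    return float(area)
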