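"""Independent oracle implementations used by the test suite.

Each oracle is deliberately written from the textbook definition, not by
calling the package code paths it checks.
"""

from __future__ import annotations

import numpy as np


def gene_dropping_relationship(entries, pair_list, n_rep=200_000, seed=0):
    """Monte-Carlo numerator relationships by simulated allele transmission.

    ``entries``: list of (genotype, parent1|None, parent2|None) in an order
    where parents precede offspring. Every founder gets two unique alleles;
    each offspring inherits one random allele from each parent (both from
    the single parent under selfing). The numerator relationship A_ij is
    twice the coancestry: 2 * P(random allele of i IBD to random allele of
    j), estimated over replicates; A_ii = 2 * (0.5 * (1 + P(i's two alleles
    IBD))).
    """
    rng = np.random.default_rng(seed)
    names = [g for g, _, _ in entries]
    idx = {g: k for k, g in enumerate(names)}
    n = len(names)
    allele = np.zeros((n_rep, n, 2), dtype=np.int64)
    counter = 0
    for k, (g, p1, p2) in enumerate(entries):
        if p1 is None and p2 is None:
            allele[:, k, 0] = 2 * counter
            allele[:, k, 1] = 2 * counter + 1
            counter += 1
        else:
            for slot, p in enumerate((p1, p2)):
                src = idx[p] if p is not None else None
                if src is None:
                    allele[:, k, slot] = 2 * counter
                    counter += 1
                else:
                    pick = rng.integers(0, 2, size=n_rep)
                    allele[:, k, slot] = allele[np.arange(n_rep), src, pick]
    out = {}
    for (gi, gj) in pair_list:
        i, j = idx[gi], idx[gj]
        if i == j:
            # A_ii = 1 + F_i with F_i = P(the two alleles of i are IBD)
            f_self = np.mean(allele[:, i, 0] == allele[:, i, 1])
            out[(gi, gj)] = 1.0 + f_self
        else:
            # A_ij = 2 * coancestry, averaged over the 4 allele pairings
            eq = (allele[:, i, :, None] == allele[:, j, None, :])
            out[(gi, gj)] = 2.0 * eq.mean()
    return out


def nipals_pls2(X, Y, n_components, tol=1e-13, max_iter=10_000):
    """Textbook NIPALS PLS2 with mean-centering, unit-norm x-weights.

    Returns dict with W (P,K), T (M,K), P_load (P,K), Q (I,K), x_mean,
    y_mean, and a ``project`` function applying the deflation sequence to a
    new centered x-row.
    """
    X = np.asarray(X, dtype=float).copy()
    Y = np.asarray(Y, dtype=float).copy()
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean
    M, P = Xc.shape
    K = n_components
    W = np.zeros((P, K))
    T = np.zeros((M, K))
    Pl = np.zeros((P, K))
    Q = np.zeros((Y.shape[1], K))
    for k in range(K):
        u = Yc[:, np.argmax(np.var(Yc, axis=0))].copy()
        w_old = None
        for _ in range(max_iter):
            w = Xc.T @ u
            w = w / np.linalg.norm(w)
            t = Xc @ w
            q = Yc.T @ t / (t @ t)
            u = Yc @ q / (q @ q)
            if w_old is not None and np.linalg.norm(w - w_old) < tol:
                break
            w_old = w
        t = Xc @ w
        p = Xc.T @ t / (t @ t)
        q = Yc.T @ t / (t @ t)
        Xc = Xc - np.outer(t, p)
        Yc = Yc - np.outer(t, q)
        W[:, k], T[:, k], Pl[:, k], Q[:, k] = w, t, p, q

    def project(x_row):
        x = np.asarray(x_row, dtype=float) - x_mean
        scores = np.zeros(K)
        for k in range(K):
            scores[k] = x @ W[:, k]
            x = x - scores[k] * Pl[:, k]
        return scores

    return {"W": W, "T": T, "P": Pl, "Q": Q, "x_mean": x_mean,
            "y_mean": y_mean, "project": project}


def msepd_triple_loop(observed, predicted):
    """Brute-force MSEPD: explicit sums over locations and ordered pairs.

    ``observed``/``predicted``: dicts location -> vector, aligned.
    """
    locs = sorted(observed)
    M = len(locs)
    I = len(next(iter(observed.values())))
    total = 0.0
    for loc in locs:
        ybar = observed[loc]
        z = predicted[loc]
        for i in range(I):
            for ip in range(I):
                if ip == i:
                    continue
                total += ((ybar[i] - ybar[ip]) - (z[i] - z[ip])) ** 2
    return total / (M * I * (I - 1))


def spearman_tied_ranks(x, y):
    """Spearman rho via average ranks and the Pearson formula on ranks."""
    def ranks(v):
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v), dtype=float)
        r[order] = np.arange(1, len(v) + 1)
        for val in np.unique(v):
            mask = v == val
            r[mask] = r[mask].mean()
        return r

    rx, ry = ranks(np.asarray(x)), ranks(np.asarray(y))
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def dense_gls_means(trial_df, varcomps):
    """Adjusted means and their covariance by explicit dense-V GLS.

    Builds V = Zh Zh' s2h + Zr Zr' s2r + Zc Zc' s2c + I s2e from the plot
    table and returns ((X'V^-1 X)^-1 X'V^-1 y, (X'V^-1 X)^-1) under the
    cell-means genotype design.
    """
    import pandas as pd

    df = trial_df.dropna(subset=["yield_value"]).reset_index(drop=True)
    genotypes = sorted(df["genotype"].unique())
    n = len(df)

    def inc(keys):
        levels = sorted(set(keys))
        Z = np.zeros((n, len(levels)))
        for r, k in enumerate(keys):
            Z[r, levels.index(k)] = 1.0
        return Z

    X = inc(list(df["genotype"]))[:, [sorted(set(df["genotype"])).index(g)
                                      for g in genotypes]]
    Zh = inc(list(df["replicate"]))
    Zr = inc(list(zip(df["replicate"], df["row"])))
    Zc = inc(list(zip(df["replicate"], df["column"])))
    s2h, s2r, s2c, s2e = varcomps
    V = s2h * Zh @ Zh.T + s2r * Zr @ Zr.T + s2c * Zc @ Zc.T + s2e * np.eye(n)
    Vi = np.linalg.inv(V)
    C = np.linalg.inv(X.T @ Vi @ X)
    means = C @ X.T @ Vi @ df["yield_value"].to_numpy(dtype=float)
    return genotypes, means, C


def henderson_mme_blups(y, X, Z, G_full, R_diag):
    """Solve Henderson's mixed-model equations assembled densely."""
    Rinv = np.diag(1.0 / R_diag)
    C11 = X.T @ Rinv @ X
    C12 = X.T @ Rinv @ Z
    C22 = Z.T @ Rinv @ Z + np.linalg.inv(G_full)
    lhs = np.block([[C11, C12], [C12.T, C22]])
    rhs = np.concatenate([X.T @ Rinv @ y, Z.T @ Rinv @ y])
    sol = np.linalg.solve(lhs, rhs)
    p = X.shape[1]
    return sol[:p], sol[p:]
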