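"""Independent brute-force oracles the implementation is checked against.

Each oracle takes a different computational route from the code under test:
the ANOVA oracle builds an explicit sum-to-zero effect-coded design matrix
and measures each term's sum of squares as an RSS difference between nested
least-squares fits; the letter-display oracle enumerates maximal cliques of
the non-significance graph; the OLS oracle solves the normal equations
directly; the selection oracle scores every marginality-respecting submodel.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
from scipy import stats


def _effect_columns(levels: int, idx: np.ndarray) -> np.ndarray:
    """Sum-to-zero (deviation) coding: levels-1 columns."""
    cols = np.zeros((len(idx), levels - 1))
    for j in range(levels - 1):
        cols[idx == j, j] = 1.0
        cols[idx == levels - 1, j] = -1.0
    return cols


def anova_oracle(cube: np.ndarray) -> dict:
    """Term SS for a balanced (a, b, c, n) cube via nested least squares."""
    a, b, c, n = cube.shape
    ia, ib, ic = np.meshgrid(np.arange(a), np.arange(b), np.arange(c),
                             indexing="ij")
    ia = np.repeat(ia.ravel(), n)
    ib = np.repeat(ib.ravel(), n)
    ic = np.repeat(ic.ravel(), n)
    y = cube.reshape(-1)

    A = _effect_columns(a, ia)
    B = _effect_columns(b, ib)
    C = _effect_columns(c, ic)

    def interact(u, v):
        return np.concatenate(
            [u[:, [i]] * v[:, [j]] for i in range(u.shape[1])
             for j in range(v.shape[1])],
            axis=1,
        )

    blocks = {
        "T": A,
        "RH": B,
        "D": C,
        "T:RH": interact(A, B),
        "T:D": interact(A, C),
        "RH:D": interact(B, C),
        "T:RH:D": interact(interact(A, B), C),
    }

    def rss(names):
        X = np.concatenate(
            [np.ones((len(y), 1))] + [blocks[t] for t in names], axis=1
        )
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    all_terms = list(blocks)
    full = rss(all_terms)
    ss = {t: rss([u for u in all_terms if u != t]) - full for t in all_terms}
    ss["residual"] = full
    return ss


def cld_oracle(nonsig: np.ndarray) -> set[frozenset]:
    """Letter classes = maximal cliques of the non-significance graph."""
    g = nx.Graph()
    k = nonsig.shape[0]
    g.add_nodes_from(range(k))
    for i in range(k):
        for j in range(i + 1, k):
            if nonsig[i, j]:
                g.add_edge(i, j)
    return {frozenset(c) for c in nx.find_cliques(g)}


def ols_oracle(X: np.ndarray, y: np.ndarray) -> dict:
    """Normal-equations least squares with classical standard errors."""
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    n, p = X.shape
    rss = float(resid @ resid)
    sigma2 = rss / (n - p)
    se = np.sqrt(np.diag(np.linalg.inv(xtx)) * sigma2)
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), n - p)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1 - rss / tss
    return {
        "beta": beta, "se": se, "t": tvals, "p": pvals,
        "rss": rss, "r_squared": r2,
        "adj_r_squared": 1 - (1 - r2) * (n - 1) / (n - p),
    }


def aic_oracle(n: int, rss: float, n_params: int) -> float:
    return n * np.log(rss / n) + 2 * (n_params + 1)


def marginality_ok(subset: set, contains: dict) -> bool:
    for term in subset:
        if not set(contains.get(term, ())) <= subset:
            return False
    return True


def exhaustive_selection(
    design, full_terms, forced, contains, fit_fn
) -> tuple:
    """Minimum-AIC model over all marginality-respecting submodels."""
    full_terms = tuple(full_terms)
    best_terms, best_aic = None, np.inf
    optional = [t for t in full_terms if t not in forced]
    for r in range(len(optional) + 1):
        for drop in itertools.combinations(optional, r):
            keep = tuple(t for t in full_terms if t not in drop)
            if not marginality_ok(set(keep), contains):
                continue
            fit = fit_fn(design, keep)
            if fit.aic < best_aic:
                best_aic, best_terms = fit.aic, keep
    return best_terms, best_aic
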