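"""Independent brute-force oracles, kept free of the package's own code paths.

Each function recomputes a statistic from first principles (explicit
matrix inverses, hand rank assignment, direct sum-of-squares formulas)
so that agreement with the package is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np


def blomberg_k_dense(V: np.ndarray, x: np.ndarray) -> float:
    """K via an explicit dense inverse of V (no factorization reuse)."""
    V = np.asarray(V, float)
    x = np.asarray(x, float)
    n = x.size
    Vi = np.linalg.inv(V)
    one = np.ones(n)
    a = (one @ Vi @ x) / (one @ Vi @ one)
    r = x - a
    mse0 = (r @ r) / (n - 1)
    mse = (r @ Vi @ r) / (n - 1)
    expected = (np.trace(V) - n / (one @ Vi @ one)) / (n - 1)
    return float((mse0 / mse) / expected)


def vcv_bruteforce(tree) -> tuple[list[str], np.ndarray]:
    """Shared root-to-MRCA path lengths by exhaustive ancestor-chain walks."""
    leaves = sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)
    labels = [l.taxon.label for l in leaves]

    def chain(node):
        out = []
        while node is not None:
            out.append(node)
            node = node.parent_node
        return out[::-1]  # root .. node

    def depth_to(node):
        total = 0.0
        while node.parent_node is not None:
            total += node.edge.length or 0.0
            node = node.parent_node
        return total

    n = len(leaves)
    V = np.zeros((n, n))
    chains = [chain(l) for l in leaves]
    for i in range(n):
        V[i, i] = depth_to(leaves[i])
        for j in range(i + 1, n):
            shared = [a for a, b in zip(chains[i], chains[j]) if a is b]
            V[i, j] = V[j, i] = depth_to(shared[-1])
    return labels, V


def patristic_bruteforce(tree) -> tuple[list[str], np.ndarray]:
    """Tip-to-tip path sums: depth_i + depth_j - 2 * depth(MRCA)."""
    labels, V = vcv_bruteforce(tree)
    d = V.diagonal()[:, None] + V.diagonal()[None, :] - 2 * V
    return labels, d


def euclidean_bruteforce(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, float)
    n = A.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d[i, j] = np.sqrt(sum((A[i, k] - A[j, k]) ** 2 for k in range(A.shape[1])))
    return d


def tied_ranks(values) -> np.ndarray:
    """Average ranks assigned by explicit position enumeration."""
    values = np.asarray(values, float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(values.size)
    i = 0
    while i < values.size:
        j = i
        while j + 1 < values.size and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0  # positions are 1-based
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_bruteforce(x, y) -> float:
    rx, ry = tied_ranks(x), tied_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def kruskal_bruteforce(groups: dict) -> float:
    """Tie-corrected H from hand-assigned joint ranks."""
    samples = [np.asarray(v, float) for v in groups.values()]
    pooled = np.concatenate(samples)
    ranks = tied_ranks(pooled)
    n_total = pooled.size
    h = 0.0
    start = 0
    for s in samples:
        r = ranks[start : start + s.size]
        h += s.size * (r.mean() - (n_total + 1) / 2.0) ** 2
        start += s.size
    h *= 12.0 / (n_total * (n_total + 1))
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - sum(c**3 - c for c in counts) / (n_total**3 - n_total)
    return float(h / correction)


def anova_bruteforce(groups: dict) -> float:
    """One-way F from direct between/within sum-of-squares."""
    samples = [np.asarray(v, float) for v in groups.values()]
    grand = np.concatenate(samples).mean()
    ss_between = sum(s.size * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df1 = len(samples) - 1
    df2 = sum(s.size for s in samples) - len(samples)
    return float((ss_between / df1) / (ss_within / df2))


def regression_anova_bruteforce(y, X) -> dict:
    """Partial SS and F per predictor via explicit normal-equation refits."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, k = X.shape

    def sse(design):
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        r = y - design @ beta
        return float(r @ r)

    full = np.hstack([np.ones((n, 1)), X])
    sse_full = sse(full)
    dfe = n - k - 1
    mse = sse_full / dfe
    out = {"error_SS": sse_full, "error_df": dfe}
    sst = float(((y - y.mean()) ** 2).sum())
    out["model_SS"] = sst - sse_full
    out["model_F"] = (out["model_SS"] / k) / mse
    for j in range(k):
        reduced = np.delete(full, j + 1, axis=1)
        ss = sse(reduced) - sse_full
        out[f"x{j}_SS"] = ss
        out[f"x{j}_F"] = ss / mse
    return out


def linreg_bruteforce(x, y) -> tuple[float, float]:
    """Slope and intercept from the covariance/variance closed form."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
    return float(slope), float(y.mean() - slope * x.mean())
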