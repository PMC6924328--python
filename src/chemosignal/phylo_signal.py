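"""Blomberg's K phylogenetic signal, permutation test, and K comparison.

Blomberg's K asks whether a continuous trait measured at the tips of a
tree is more (K > 1) or less (K < 1) similar among relatives than a
Brownian-motion process along the tree's branches would produce (K = 1).
With V the tree-implied covariance of the tips (shared root-to-node path
lengths), n tips, trait vector x and phylogenetic (GLS) mean
a = (1' V^-1 x) / (1' V^-1 1):

    MSE0 = (x - a)'(x - a) / (n - 1)          # ordinary mean square
    MSE  = (x - a)' V^-1 (x - a) / (n - 1)    # phylogenetic mean square
    K    = (MSE0 / MSE) / [(tr(V) - n / (1' V^-1 1)) / (n - 1)]

The observed ratio is scaled by its Brownian expectation, making K
invariant to affine transforms of the trait and to rescaling all branch
lengths by a positive constant.

Significance is assessed by permuting trait values across tips: the
p-value is (1 + #{K_perm >= K_obs}) / (n_perm + 1).

:func:`compare_k` contrasts the signal a trait carries on two candidate
trees (here: a chemotaxonomic dendrogram vs a genetic phylogram) by a
within-species nonparametric bootstrap of the replicate observations:
each iteration resamples replicates with replacement within species,
recomputes species means, and recomputes K on both trees; the
distribution of Delta-K = K_a - K_b gives a percentile interval and a
two-sided p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .trees import DistanceMatrix, clamp_negative_branch_lengths, patristic_distances

__all__ = [
    "PhyloCovariance",
    "SignalResult",
    "KComparison",
    "tree_vcv",
    "blomberg_k",
    "blomberg_k_test",
    "compare_k",
]


@dataclass(frozen=True)
class PhyloCovariance:
    """Tree-implied covariance of tip values (shared path lengths from the root)."""

    labels: tuple[str, ...]
    V: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        V = np.asarray(self.V, dtype=float)
        object.__setattr__(self, "V", V)
        n = len(self.labels)
        if V.shape != (n, n):
            raise ValueError(f"V shape {V.shape} does not match {n} labels")
        if not np.allclose(V, V.T, rtol=1e-8, atol=1e-12):
            raise ValueError("V must be symmetric")

    @property
    def n(self) -> int:
        return len(self.labels)


def tree_vcv(tree: dendropy.Tree, rooting: str = "basal") -> PhyloCovariance:
    """Tip variance-covariance matrix implied by a tree.

    ``V[i, j]`` is the path length from the root to the most recent
    common ancestor of tips i and j; the diagonal holds root-to-tip
    depths. Negative branch lengths (raw NJ estimates) are clamped via
    :func:`~chemosignal.trees.clamp_negative_branch_lengths` first.

    Parameters
    ----------
    tree:
        Tree with >= 3 tips. An unrooted NJ tree is used with its basal
        trifurcation as the root (``rooting="basal"``, the default);
        ``rooting="midpoint"`` reroots at the midpoint of the longest
        tip-to-tip path first.
    """
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(tips) < 3:
        raise ValueError(f"tree_vcv requires >= 3 tips, got {len(tips)}")
    work = clamp_negative_branch_lengths(tree)
    if rooting == "midpoint":
        work.reroot_at_midpoint(update_bipartitions=False)
    elif rooting != "basal":
        raise ValueError(f"rooting must be 'basal' or 'midpoint', got {rooting!r}")

    labels = sorted(leaf.taxon.label for leaf in work.leaf_node_iter())
    index = {label: i for i, label in enumerate(labels)}
    n = len(labels)
    V = np.zeros((n, n))
    depth: dict[dendropy.Node, float] = {}
    for node in work.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            depth[node] = 0.0
        else:
            depth[node] = depth[parent] + (node.edge.length or 0.0)
        if node.is_leaf():
            i = index[node.taxon.label]
            V[i, i] = depth[node]
    # off-diagonals: MRCA depth = depth of deepest node whose clade holds both tips
    for node in work.postorder_internal_node_iter():
        children = node.child_nodes()
        clades = [
            [index[leaf.taxon.label] for leaf in child.leaf_iter()]
            for child in children
        ]
        for a in range(len(clades)):
            for b in range(a + 1, len(clades)):
                for i in clades[a]:
                    for j in clades[b]:
                        V[i, j] = V[j, i] = depth[node]
    if np.allclose(V, 0.0):
        raise ValueError("zero-length tree: V is singular (all shared paths are 0)")
    return PhyloCovariance(tuple(labels), V)


class _KEngine:
    """Cached factorization of V for repeated K evaluations on one tree."""

    def __init__(self, vcv: PhyloCovariance):
        self.labels = vcv.labels
        self.n = vcv.n
        try:
            self._factor = cho_factor(vcv.V)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "singular or non-positive-definite V (duplicate zero-length tips?)"
            ) from exc
        ones = np.ones(self.n)
        self._Vinv_ones = cho_solve(self._factor, ones)
        self._ones_Vinv_ones = float(ones @ self._Vinv_ones)
        expected_num = float(np.trace(vcv.V)) - self.n / self._ones_Vinv_ones
        self.expected_ratio = expected_num / (self.n - 1)
        if self.expected_ratio <= 0:
            raise ValueError("degenerate tree: Brownian expected ratio is not positive")

    def k_batch(self, X: np.ndarray) -> np.ndarray:
        """K for each column of X (shape n x m), aligned to ``self.labels``."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != self.n:
            X = X.T
        S = cho_solve(self._factor, X)  # V^-1 X
        a = (np.ones(self.n) @ S) / self._ones_Vinv_ones  # GLS mean per column
        R = X - a  # residuals
        VinvR = S - np.outer(self._Vinv_ones, a)
        mse0 = np.einsum("ij,ij->j", R, R)
        mse = np.einsum("ij,ij->j", R, VinvR)
        if np.any(mse0 <= 0):
            raise ValueError("zero trait variance: constant trait has no signal")
        return (mse0 / mse) / self.expected_ratio


def _align_trait(x, labels: tuple[str, ...]) -> np.ndarray:
    """Order a trait vector (Series/dict) to match VCV labels, with checks."""
    if isinstance(x, pd.Series):
        x = x.astype(float)
    elif isinstance(x, dict):
        x = pd.Series(x, dtype=float)
    else:
        raise TypeError("trait must be a pandas Series or dict keyed by tip label")
    x.index = x.index.map(lambda s: str(s).strip())
    missing = [l for l in labels if l not in x.index]
    extra = [l for l in x.index if l not in labels]
    if missing or extra:
        raise ValueError(
            f"trait/tip label mismatch; tips without trait: {missing}; "
            f"trait labels not on tree: {extra}"
        )
    values = x.reindex(list(labels)).to_numpy()
    if not np.isfinite(values).all():
        raise ValueError("trait contains non-finite values")
    return values


def blomberg_k(
    tree: dendropy.Tree | PhyloCovariance,
    x: pd.Series | dict,
    rooting: str = "basal",
) -> float:
    """Blomberg's K for trait ``x`` (indexed by tip label) on ``tree``."""
    vcv = tree if isinstance(tree, PhyloCovariance) else tree_vcv(tree, rooting)
    engine = _KEngine(vcv)
    return float(engine.k_batch(_align_trait(x, vcv.labels)[:, None])[0])


@dataclass(frozen=True)
class SignalResult:
    """Observed K with its permutation test."""

    K: float
    p: float
    n_perm: int
    seed: int | None
    tree_id: str | None = None
    trait_id: str | None = None

    def as_dict(self) -> dict:
        return {
            "K": self.K,
            "p": self.p,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "tree_id": self.tree_id,
            "trait_id": self.trait_id,
        }


def blomberg_k_test(
    tree: dendropy.Tree | PhyloCovariance,
    x: pd.Series | dict,
    n_perm: int = 999,
    seed: int | None = None,
    rooting: str = "basal",
    tree_id: str | None = None,
    trait_id: str | None = None,
) -> SignalResult:
    """Permutation test for phylogenetic signal.

    Trait values are shuffled across tips uniformly at random ``n_perm``
    times; p = (1 + #{K_perm >= K_obs}) / (n_perm + 1), so the smallest
    attainable p is 1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    vcv = tree if isinstance(tree, PhyloCovariance) else tree_vcv(tree, rooting)
    engine = _KEngine(vcv)
    values = _align_trait(x, vcv.labels)
    k_obs = float(engine.k_batch(values[:, None])[0])
    rng = np.random.default_rng(seed)
    perms = np.empty((vcv.n, n_perm))
    for m in range(n_perm):
        perms[:, m] = rng.permutation(values)
    k_perm = engine.k_batch(perms)
    p = (1.0 + np.count_nonzero(k_perm >= k_obs)) / (n_perm + 1.0)
    return SignalResult(K=k_obs, p=float(p), n_perm=n_perm, seed=seed,
                        tree_id=tree_id, trait_id=trait_id)


@dataclass(frozen=True)
class KComparison:
    """Bootstrap comparison of K between two trees for the same trait."""

    K_a: float
    K_b: float
    delta_samples: np.ndarray = field(repr=False)
    ci95: tuple[float, float]
    ci95_percentile: tuple[float, float]
    p_two_sided: float
    seed: int | None
    scheme: str = "within-species nonparametric bootstrap of replicates"

    @property
    def delta(self) -> float:
        return self.K_a - self.K_b

    def as_dict(self) -> dict:
        return {
            "K_a": self.K_a,
            "K_b": self.K_b,
            "delta": self.delta,
            "ci95": list(self.ci95),
            "ci95_percentile": list(self.ci95_percentile),
            "p_two_sided": self.p_two_sided,
            "iterations": int(self.delta_samples.size),
            "seed": self.seed,
            "scheme": self.scheme,
        }


def compare_k(
    tree_a: dendropy.Tree | PhyloCovariance,
    tree_b: dendropy.Tree | PhyloCovariance,
    replicates: pd.DataFrame,
    b: int = 1000,
    seed: int | None = None,
    species_col: str = "species",
    value_col: str = "measure",
    rooting: str = "basal",
) -> KComparison:
    """Resampling comparison of Blomberg's K between two candidate trees.

    ``replicates`` holds per-individual observations (>= 2 per species).
    Each of the ``b`` iterations resamples observations with replacement
    within every species, recomputes species means, and recomputes K on
    both trees; Delta-K = K_a - K_b. The two-sided p-value is
    2 * min(frac Delta <= 0, frac Delta >= 0), floored at 1/b.

    Resampled means carry extra within-species noise, which attenuates
    both K values, so the bootstrap Delta-K distribution is neither
    centred on the observed Delta-K nor symmetric (K is a nonnegative
    ratio statistic, hence right-skewed). ``ci95`` is therefore the
    bias-corrected (BC) percentile interval: with z0 the normal quantile
    of the fraction of bootstrap deltas below the observed delta, the
    interval endpoints are the bootstrap quantiles at
    Phi(2*z0 -/+ 1.96). Acceleration is omitted because the natural
    jackknife (delete one species) would change the tree's tip set and
    with it the statistic's definition. ``ci95_percentile`` keeps the
    raw percentile interval.
    """
    if b < 1:
        raise ValueError(f"iteration count must be >= 1, got {b}")
    vcv_a = tree_a if isinstance(tree_a, PhyloCovariance) else tree_vcv(tree_a, rooting)
    vcv_b = tree_b if isinstance(tree_b, PhyloCovariance) else tree_vcv(tree_b, rooting)
    if set(vcv_a.labels) != set(vcv_b.labels):
        only_a = sorted(set(vcv_a.labels) - set(vcv_b.labels))
        only_b = sorted(set(vcv_b.labels) - set(vcv_a.labels))
        raise ValueError(
            f"trees disagree on species: only in first {only_a}; only in second {only_b}"
        )
    groups = {
        str(sp).strip(): sub[value_col].to_numpy(dtype=float)
        for sp, sub in replicates.groupby(species_col, sort=False)
    }
    missing = [l for l in vcv_a.labels if l not in groups]
    if missing:
        raise ValueError(f"species on trees but missing from replicates: {missing}")
    thin = [sp for sp in vcv_a.labels if groups[sp].size < 2]
    if thin:
        raise ValueError(f"species with < 2 replicate observations: {thin}")

    labels = vcv_a.labels
    engine_a = _KEngine(vcv_a)
    engine_b = _KEngine(vcv_b)
    means = pd.Series({sp: groups[sp].mean() for sp in labels})
    k_a = float(engine_a.k_batch(_align_trait(means, labels)[:, None])[0])
    k_b = float(engine_b.k_batch(_align_trait(means, vcv_b.labels)[:, None])[0])

    rng = np.random.default_rng(seed)
    boot_a = np.empty((len(labels), b))
    for i, sp in enumerate(labels):
        obs = groups[sp]
        idx = rng.integers(0, obs.size, size=(b, obs.size))
        boot_a[i] = obs[idx].mean(axis=1)
    # same resampled means, row order adapted to each tree's label order
    order_b = [labels.index(l) for l in vcv_b.labels]
    delta = engine_a.k_batch(boot_a) - engine_b.k_batch(boot_a[order_b])
    q_lo, q_hi = np.percentile(delta, [2.5, 97.5])
    delta_obs = k_a - k_b
    ci_bc = _bias_corrected_interval(delta, delta_obs)
    frac_le = np.mean(delta <= 0)
    frac_ge = np.mean(delta >= 0)
    p = max(1.0 / b, 2.0 * min(frac_le, frac_ge))
    return KComparison(
        K_a=k_a,
        K_b=k_b,
        delta_samples=delta,
        ci95=ci_bc,
        ci95_percentile=(float(q_lo), float(q_hi)),
        p_two_sided=float(min(1.0, p)),
        seed=seed,
    )


def _bias_corrected_interval(
    samples: np.ndarray, observed: float, alpha: float = 0.05
) -> tuple[float, float]:
    """BC bootstrap interval (Efron's bias-corrected percentile, a = 0)."""
    from scipy.stats import norm

    frac_below = np.mean(samples < observed)
    if frac_below <= 0.0 or frac_below >= 1.0:
        # observed outside the bootstrap support: fall back to percentiles
        lo, hi = np.percentile(samples, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        return float(lo), float(hi)
    z0 = norm.ppf(frac_below)
    z = norm.ppf(1 - alpha / 2)
    lo_q = 100 * norm.cdf(2 * z0 - z)
    hi_q = 100 * norm.cdf(2 * z0 + z)
    lo, hi = np.percentile(samples, [lo_q, hi_q])
    return float(lo), float(hi)
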