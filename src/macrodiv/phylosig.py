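"""Pagel's lambda phylogenetic signal of model residuals on a family-level
phylogeny.

Under Brownian motion the covariance between two tips is proportional to
their shared branch length from the root.  Pagel's lambda multiplies the
off-diagonal entries of that covariance, so lambda = 0 is phylogenetic
independence and lambda = 1 full Brownian covariance.  The statistic is
estimated by maximum likelihood of a multivariate normal with mean and scale
profiled out, and tested against lambda = 0 with a likelihood-ratio
chi-square (df = 1).

The tree is family-level while residuals are species-level; they are joined
either by averaging residuals within a family (default) or by expanding each
family tip into a star polytomy of its species.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import dendropy
import numpy as np
from scipy import optimize, stats

__all__ = ["LambdaFit", "read_newick", "tree_vcv", "map_values_to_tree", "fit_lambda"]


@dataclass
class LambdaFit:
    """Maximum-likelihood Pagel's lambda with its likelihood-ratio test."""

    lam: float
    lambda_max: float
    loglik_at_lambda: float
    loglik_at_zero: float
    p_value: float
    sigma2: float
    mu: float


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a Newick tree; every non-root edge must carry a branch length and
    tip labels must be unique."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate tip labels: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dup}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("tree has edges without branch lengths")
        if edge.length < 0:
            raise ValueError("negative branch length")
    return tree


def tree_vcv(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance matrix: C[i,j] = shared path length from
    the root to tips i and j."""
    leaves = list(tree.leaf_node_iter())
    labels = [leaf.taxon.label for leaf in leaves]
    # depth of every node from the root
    depth = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_tree(tree)
    n = len(leaves)
    C = np.zeros((n, n))
    for i in range(n):
        C[i, i] = depth[leaves[i]]
        for j in range(i + 1, n):
            dij = pdm.patristic_distance(leaves[i].taxon, leaves[j].taxon)
            C[i, j] = C[j, i] = 0.5 * (depth[leaves[i]] + depth[leaves[j]] - dij)
    return C, labels


def map_values_to_tree(
    values: Sequence[float],
    family_labels: Sequence[str],
    tree: dendropy.Tree,
    mode: Literal["family_mean", "star_expand"] = "family_mean",
    epsilon: float = 1e-6,
) -> tuple[np.ndarray, dendropy.Tree, list[str]]:
    """Attach species-level values to a family-level tree.

    ``family_mean``: one value per family tip, the mean of its species;
    families with no species are pruned with a warning.  ``star_expand``:
    each family tip becomes a star polytomy of its species with tiny branch
    ``epsilon``, keeping one value per species.
    Returns (tip values, working tree, tip labels in value order).
    """
    import warnings

    values = np.asarray(values, float)
    family_labels = [str(f) for f in family_labels]
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = sorted(set(family_labels) - tips)
    if missing:
        raise ValueError(f"family labels absent from tree: {missing}")
    tree = tree.clone(depth=1)
    by_family: dict[str, list[int]] = {}
    for i, f in enumerate(family_labels):
        by_family.setdefault(f, []).append(i)
    empty = sorted(tips - set(by_family))
    if empty:
        warnings.warn(f"tips with no species dropped: {empty}")
        tree.retain_taxa_with_labels(list(by_family))
    if mode == "family_mean":
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        vals = np.array([values[by_family[l]].mean() for l in labels])
        return vals, tree, labels
    if mode == "star_expand":
        tns = tree.taxon_namespace
        out_labels: list[str] = []
        out_vals: list[float] = []
        for leaf in list(tree.leaf_node_iter()):
            fam = leaf.taxon.label
            members = by_family[fam]
            leaf.taxon = None
            for i in members:
                sp_label = f"{fam}__sp{i}"
                taxon = tns.new_taxon(sp_label)
                child = dendropy.Node(taxon=taxon, edge_length=epsilon)
                leaf.add_child(child)
                out_labels.append(sp_label)
                out_vals.append(values[i])
        return np.asarray(out_vals), tree, out_labels
    raise ValueError(f"unknown mode {mode!r}")


def _profile_loglik(y: np.ndarray, C: np.ndarray) -> tuple[float, float, float]:
    """MVN log-likelihood with mean and scale profiled out analytically."""
    n = y.size
    L = np.linalg.cholesky(C)
    ones = np.ones(n)
    sol_y = np.linalg.solve(L, y)
    sol_1 = np.linalg.solve(L, ones)
    mu = float(sol_1 @ sol_y / (sol_1 @ sol_1))
    r = sol_y - mu * sol_1
    sigma2 = float(r @ r) / n
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return ll, mu, sigma2


def _lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    out = lam * C
    np.fill_diagonal(out, np.diag(C))
    return out


def _lambda_max(C: np.ndarray, cap: float = 5.0) -> float:
    """Largest lambda keeping C(lambda) positive definite (>= 1 for
    ultrametric trees), found by bisection."""
    def pd(lam):
        try:
            np.linalg.cholesky(_lambda_cov(C, lam))
            return True
        except np.linalg.LinAlgError:
            return False

    if not pd(1.0):
        hi_ok = 1.0
        while hi_ok > 1e-6 and not pd(hi_ok):
            hi_ok /= 2
        lo, hi = hi_ok, 1.0
    else:
        lo = 1.0
        hi = cap
        if pd(hi):
            return hi
    for _ in range(60):
        mid = (lo + hi) / 2
        if pd(mid):
            lo = mid
        else:
            hi = mid
    return lo


def fit_lambda(tip_values: Sequence[float], tree_or_cov, chi2_boundary_halved: bool = False) -> LambdaFit:
    """Maximum-likelihood Pagel's lambda.

    ``tree_or_cov`` is a dendropy tree (tips in the order of ``tip_values``
    as returned by :func:`map_values_to_tree`) or a precomputed Brownian
    covariance matrix.  The p-value is a likelihood-ratio chi-square with
    df = 1 against lambda = 0 (optionally halved to account for the boundary;
    the plain chi-square convention is the default and is recorded in the
    field ``p_value``).
    """
    y = np.asarray(tip_values, float)
    if y.size < 4:
        raise ValueError("need at least 4 tips")
    if isinstance(tree_or_cov, dendropy.Tree):
        C, _ = tree_vcv(tree_or_cov)
    else:
        C = np.asarray(tree_or_cov, float)
    if C.shape != (y.size, y.size):
        raise ValueError("covariance/tip-value size mismatch")
    if np.any(np.diag(C) <= 0):
        raise ValueError("tree has zero-depth tips; covariance singular")
    lam_max = _lambda_max(C)

    def nll(lam):
        try:
            ll, _, _ = _profile_loglik(y, _lambda_cov(C, lam))
        except np.linalg.LinAlgError:
            return np.inf
        return -ll

    res = optimize.minimize_scalar(nll, bounds=(0.0, lam_max), method="bounded",
                                   options={"xatol": 1e-10})
    # guard against local optima at the grid points the optimizer may skip
    candidates = [(float(res.x), -res.fun)]
    for lam in (0.0, min(1.0, lam_max), lam_max):
        candidates.append((lam, -nll(lam)))
    lam_hat, ll_hat = max(candidates, key=lambda t: t[1])
    ll0 = -nll(0.0)
    ll_hat = max(ll_hat, ll0)
    lr = max(0.0, 2.0 * (ll_hat - ll0))
    p = float(stats.chi2.sf(lr, df=1))
    if chi2_boundary_halved:
        p = p / 2 if lr > 0 else 1.0
    _, mu, sigma2 = _profile_loglik(y, _lambda_cov(C, lam_hat))
    return LambdaFit(
        lam=float(lam_hat),
        lambda_max=float(lam_max),
        loglik_at_lambda=float(ll_hat),
        loglik_at_zero=float(ll0),
        p_value=min(p, 1.0),
        sigma2=float(sigma2),
        mu=float(mu),
    )
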