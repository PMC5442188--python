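"""Phylogenetic composition versus fitness.

Consortia are presence/absence sets of tree tips, so community distance is
the *unweighted UniFrac*: the fraction of branch length leading exclusively
to tips of one of the two communities, among all branch length leading to
tips of either. The association between the resulting distance matrix and a
per-consortium fitness covariate is tested with a PERMANOVA-style
permutation test (the `adonis` model with a single continuous term):
Gower-center the squared distances, project onto the centered covariate,
and compare the observed pseudo-F against covariate permutations.

An auxiliary reading — the maximum pairwise patristic distance among a
consortium's members, regressed on fitness — is also provided.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from .plate_io import Consortium

logger = logging.getLogger(__name__)


class PhyloError(ValueError):
    """Invalid tree, consortium/tip mismatch, or ill-posed test input."""


class StrainTree:
    """Rooted tree with branch lengths whose tips are strain IDs.

    UniFrac needs a root; an input tree that looks unrooted (basal polytomy)
    is used as rooted at that basal node, with a logged notice — the same
    convention the classic UniFrac tooling applies to unrooted trees. Edge
    tip-sets are cached so pairwise UniFrac over thousands of consortium
    pairs stays cheap.
    """

    def __init__(self, tree: dendropy.Tree) -> None:
        self._tree = tree
        if len(tree.seed_node.child_nodes()) > 2:
            logger.info("input tree appears unrooted (basal polytomy); treating the basal node as the root")
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise PhyloError("tree has duplicate tip labels")
        self.tips: frozenset[str] = frozenset(labels)
        self._edges: list[tuple[float, frozenset[str]]] = []
        below: dict[dendropy.Node, frozenset[str]] = {}
        total = 0.0
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                tip_set = frozenset([node.taxon.label])
            else:
                tip_set = frozenset().union(*(below[c] for c in node.child_nodes()))
            below[node] = tip_set
            if node.parent_node is None:
                continue
            length = node.edge.length
            if length is None:
                length = 0.0
            if length < 0:
                raise PhyloError(f"negative branch length {length} above {sorted(tip_set)[:3]}")
            total += length
            if length > 0:
                self._edges.append((float(length), tip_set))
        if total <= 0:
            raise PhyloError("tree has zero total branch length")

    @classmethod
    def from_newick(cls, source: str | Path) -> "StrainTree":
        """Parse a newick file path or literal newick string."""
        text = None
        path = Path(source) if not str(source).lstrip().startswith("(") else None
        if path is not None and path.exists():
            text = path.read_text()
        else:
            text = str(source)
        tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
        return cls(tree)

    def max_patristic(self, members: Iterable[str]) -> float:
        """Maximum pairwise tip-to-tip path length among the given members."""
        members = sorted(set(members))
        self._check_members(members)
        if len(members) < 2:
            return 0.0
        pdm = getattr(self, "_pdm", None)
        if pdm is None:
            pdm = self._tree.phylogenetic_distance_matrix()
            self._pdm = pdm
            self._taxa = {t.label: t for t in self._tree.taxon_namespace}
        return max(
            float(pdm.patristic_distance(self._taxa[a], self._taxa[b]))
            for a, b in itertools.combinations(members, 2)
        )

    def _check_members(self, members: Iterable[str]) -> None:
        missing = sorted(set(members) - self.tips)
        if missing:
            raise PhyloError(f"consortium member(s) not found among tree tips: {missing}")


def _as_members(consortium: Consortium | Iterable[str]) -> frozenset[str]:
    if isinstance(consortium, Consortium):
        return consortium.members
    members = frozenset(str(m) for m in consortium)
    if not members:
        raise PhyloError("consortium must be non-empty")
    return members


def unweighted_unifrac(tree: StrainTree, a: Consortium | Iterable[str], b: Consortium | Iterable[str]) -> float:
    """Unweighted UniFrac distance between two strain sets on ``tree``.

    Branch length unique to one community divided by branch length leading
    to either community; identical communities give 0, communities sharing
    no branches give 1.
    """
    A = _as_members(a)
    B = _as_members(b)
    tree._check_members(A | B)
    unique = 0.0
    observed = 0.0
    for length, tips in tree._edges:
        in_a = not tips.isdisjoint(A)
        in_b = not tips.isdisjoint(B)
        if in_a or in_b:
            observed += length
            if in_a != in_b:
                unique += length
    return unique / observed if observed > 0 else 0.0


def unifrac_matrix(tree: StrainTree, consortia: Sequence[Consortium]) -> DistanceMatrix:
    """Symmetric UniFrac distance matrix over consortia, ordered by canonical ID."""
    ordered = sorted(consortia, key=lambda c: c.canonical_id)
    ids = [c.canonical_id for c in ordered]
    if len(set(ids)) != len(ids):
        raise PhyloError("duplicate consortia in distance-matrix request")
    n = len(ordered)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = unweighted_unifrac(tree, ordered[i], ordered[j])
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids)


@dataclass
class AdonisResult:
    pseudo_f: float
    r2: float
    p: float
    n_perm: int
    seed: int | None
    exact: bool = False


def _gower_center(d_squared: np.ndarray) -> np.ndarray:
    n = d_squared.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return -0.5 * j @ d_squared @ j


def adonis(
    dm: DistanceMatrix | np.ndarray,
    covariate,
    n_perm: int | str = 999,
    seed: int | None = None,
) -> AdonisResult:
    """Permutation test of a distance matrix against one continuous covariate.

    With G the Gower-centered -D^2/2 matrix and x the centered covariate,
    SS_model = x'Gx / x'x (the one-dimensional hat-matrix projection),
    pseudo-F = SS_model / (SS_resid / (n - 2)), R^2 = SS_model / SS_total.
    The p value is ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)`` over seeded
    covariate permutations; ``n_perm="all"`` enumerates every permutation
    (small n only) and reports the exact tail fraction.
    """
    if isinstance(dm, DistanceMatrix):
        data = dm.data
        ids = list(dm.ids)
    else:
        data = np.asarray(dm, dtype=float)
        ids = None
        if data.ndim != 2 or data.shape[0] != data.shape[1]:
            raise PhyloError("distance matrix must be square")
        if not np.allclose(data, data.T):
            raise PhyloError("distance matrix must be symmetric")
        if not np.allclose(np.diag(data), 0.0):
            raise PhyloError("distance matrix must have a zero diagonal")
    n = data.shape[0]
    if isinstance(covariate, pd.Series) and ids is not None:
        covariate = covariate.reindex(ids)
        if covariate.isna().any():
            raise PhyloError("covariate missing for some distance-matrix IDs")
    x = np.asarray(covariate, dtype=float)
    if x.shape != (n,):
        raise PhyloError(f"covariate length {x.shape} does not match matrix dimension {n}")
    if np.ptp(x) == 0:
        raise PhyloError("covariate is constant; adonis model is ill-posed")
    if n < 3:
        raise PhyloError("need at least 3 observations")

    g = _gower_center(data**2)
    ss_total = float(np.trace(g))
    xc = x - x.mean()
    denom = float(xc @ xc)

    def pseudo_f(ss_model):
        # residual can hit exact zero when the distances are a function of the
        # covariate itself; the statistic is then infinite, not an error
        ss_resid = np.asarray(ss_total - ss_model, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(ss_resid > 0, ss_model / (ss_resid / (n - 2)), np.inf)

    ss_obs = float(xc @ g @ xc) / denom
    f_obs = pseudo_f(ss_obs)
    r2 = ss_obs / ss_total if ss_total != 0 else float("nan")

    if n_perm == "all":
        perms = np.array(list(itertools.permutations(range(n))))
        xp = xc[perms]  # (n!, n)
        ss_perm = np.einsum("ij,jk,ik->i", xp, g, xp) / denom
        f_perm = pseudo_f(ss_perm)
        p = float(np.mean(f_perm >= f_obs))
        return AdonisResult(float(f_obs), float(r2), p, len(perms), seed, exact=True)

    n_perm = int(n_perm)
    if n_perm < 1:
        raise PhyloError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    xp = np.empty((n_perm, n))
    for i in range(n_perm):
        xp[i] = rng.permutation(xc)
    ss_perm = np.einsum("ij,jk,ik->i", xp, g, xp) / denom
    f_perm = pseudo_f(ss_perm)
    p = (1 + int(np.sum(f_perm >= f_obs))) / (1 + n_perm)
    return AdonisResult(float(f_obs), float(r2), float(p), n_perm, seed, exact=False)


def patristic_fitness_regression(
    tree: StrainTree,
    consortia: Sequence[Consortium],
    fitness,
) -> pd.Series:
    """OLS of per-consortium maximum patristic distance on fitness.

    The auxiliary "maximum phylogeny distance" reading: monocultures have
    distance 0. Returns slope, intercept, r2, p, n.
    """
    ordered = sorted(consortia, key=lambda c: c.canonical_id)
    dmax = np.array([tree.max_patristic(c.members) for c in ordered])
    if isinstance(fitness, pd.Series):
        fitness = fitness.reindex([c.canonical_id for c in ordered])
        if fitness.isna().any():
            raise PhyloError("fitness missing for some consortia")
    y = np.asarray(fitness, dtype=float)
    if y.shape != dmax.shape:
        raise PhyloError("fitness length does not match consortium list")
    fit = stats.linregress(y, dmax)
    return pd.Series(
        {
            "slope": fit.slope,
            "intercept": fit.intercept,
            "r2": fit.rvalue**2,
            "p": fit.pvalue,
            "n": len(y),
        }
    )
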