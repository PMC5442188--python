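"""Unweighted UniFrac and the adonis permutation test."""

from __future__ import annotations

import io
import itertools

import numpy as np
import pandas as pd
import pytest

from microsocial.phylo import (
    AdonisResult,
    PhyloError,
    StrainTree,
    adonis,
    patristic_fitness_regression,
    unifrac_matrix,
    unweighted_unifrac,
)
from microsocial.plate_io import Consortium


def two_tip_tree():
    return StrainTree.from_newick("(X:1,Y:1);")


def star4_tree():
    # basal polytomy -> midpoint-rooted with a notice; equal unit branches
    return StrainTree.from_newick("(A:1,B:1,C:1,D:1);")


def test_unifrac_hand_cases():
    tree = two_tip_tree()
    assert unweighted_unifrac(tree, {"X"}, {"X"}) == pytest.approx(0.0)
    assert unweighted_unifrac(tree, {"X"}, {"Y"}) == pytest.approx(1.0)
    assert unweighted_unifrac(tree, {"X"}, {"X", "Y"}) == pytest.approx(0.5)


def test_unifrac_star_tree_values():
    tree = star4_tree()
    assert unweighted_unifrac(tree, {"A"}, {"B"}) == pytest.approx(1.0)
    # shared branch A, unique branches B and C among observed {A, B, C}
    assert unweighted_unifrac(tree, {"A", "B"}, {"A", "C"}) == pytest.approx(2.0 / 3.0)


def test_unifrac_unknown_member_is_named():
    with pytest.raises(PhyloError, match="ZZ"):
        unweighted_unifrac(two_tip_tree(), {"X"}, {"ZZ"})


def test_unifrac_matrix_consistent_with_pairwise():
    tree = star4_tree()
    consortia = [Consortium(frozenset(m)) for m in ({"A"}, {"A", "B"}, {"C", "D"})]
    dm = unifrac_matrix(tree, consortia)
    assert list(dm.ids) == sorted(c.canonical_id for c in consortia)
    assert np.allclose(dm.data, dm.data.T)
    assert np.allclose(np.diag(dm.data), 0.0)
    lookup = {c.canonical_id: c for c in consortia}
    for i, j in itertools.combinations(range(3), 2):
        expected = unweighted_unifrac(tree, lookup[dm.ids[i]], lookup[dm.ids[j]])
        assert dm.data[i, j] == pytest.approx(expected)


def random_tree_newick(rng: np.random.Generator, labels: list[str]) -> str:
    """Random rooted binary topology with uniform random branch lengths."""

    def build(tips: list[str]) -> str:
        if len(tips) == 1:
            return f"{tips[0]}:{rng.uniform(0.05, 1.0):.6f}"
        k = int(rng.integers(1, len(tips)))
        return f"({build(tips[:k])},{build(tips[k:])}):{rng.uniform(0.05, 1.0):.6f}"

    mixed = list(labels)
    rng.shuffle(mixed)
    return f"({build(mixed[: len(mixed) // 2])},{build(mixed[len(mixed) // 2 :])});"


def test_unifrac_agrees_with_reference_implementation():
    """Cross-check against scikit-bio's unweighted UniFrac on random instances."""
    from skbio import TreeNode
    from skbio.diversity.beta import unweighted_unifrac as skbio_unifrac

    rng = np.random.default_rng(17)
    for _ in range(50):
        n = int(rng.integers(4, 10))
        labels = [f"T{i}" for i in range(n)]
        newick = random_tree_newick(rng, labels)
        tree = StrainTree.from_newick(newick)
        sk_tree = TreeNode.read(io.StringIO(newick))
        a = set(rng.choice(labels, size=rng.integers(1, n), replace=False))
        b = set(rng.choice(labels, size=rng.integers(1, n), replace=False))
        mine = unweighted_unifrac(tree, a, b)
        ref = skbio_unifrac(
            [int(t in a) for t in labels], [int(t in b) for t in labels], taxa=labels, tree=sk_tree
        )
        assert mine == pytest.approx(float(ref), abs=1e-10)


def test_unifrac_properties_on_random_instances():
    rng = np.random.default_rng(23)
    for _ in range(200):
        n = int(rng.integers(3, 8))
        labels = [f"T{i}" for i in range(n)]
        tree = StrainTree.from_newick(random_tree_newick(rng, labels))
        a = set(rng.choice(labels, size=rng.integers(1, n), replace=False))
        b = set(rng.choice(labels, size=rng.integers(1, n), replace=False))
        d_ab = unweighted_unifrac(tree, a, b)
        assert 0.0 <= d_ab <= 1.0
        assert d_ab == pytest.approx(unweighted_unifrac(tree, b, a))  # symmetry
        assert unweighted_unifrac(tree, a, a) == 0.0


def test_tree_validation():
    with pytest.raises(PhyloError, match="negative"):
        StrainTree.from_newick("(X:-1,Y:1);")
    with pytest.raises(PhyloError, match="zero total"):
        StrainTree.from_newick("(X:0,Y:0);")


# ---------------------------------------------------------------------------
# adonis


def gower_f_oracle(d: np.ndarray, x: np.ndarray) -> float:
    """Independent pseudo-F computation used to cross-check adonis."""
    n = len(x)
    j = np.eye(n) - 1.0 / n
    g = -0.5 * j @ (d**2) @ j
    xc = x - x.mean()
    ss_model = xc @ g @ xc / (xc @ xc)
    ss_total = np.trace(g)
    return ss_model / ((ss_total - ss_model) / (n - 2))


def exhaustive_p_oracle(d: np.ndarray, x: np.ndarray) -> float:
    f_obs = gower_f_oracle(d, x)
    fs = [gower_f_oracle(d, x[list(perm)]) for perm in itertools.permutations(range(len(x)))]
    return float(np.mean(np.array(fs) >= f_obs))


def random_distance_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    pts = rng.standard_normal((n, 3))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, 0.0)
    return d


def test_adonis_exact_matches_exhaustive_oracle():
    rng = np.random.default_rng(31)
    d = random_distance_matrix(rng, 4)
    x = rng.standard_normal(4)
    result = adonis(d, x, n_perm="all")
    assert result.exact and result.n_perm == 24
    assert result.p == pytest.approx(exhaustive_p_oracle(d, x), abs=1e-12)
    assert result.pseudo_f == pytest.approx(gower_f_oracle(d, x), rel=1e-12)


def test_adonis_monte_carlo_matches_exact_tail():
    rng = np.random.default_rng(37)
    d = random_distance_matrix(rng, 5)
    x = rng.standard_normal(5)
    p_exact = adonis(d, x, n_perm="all").p
    p_mc = adonis(d, x, n_perm=4999, seed=3).p
    se = np.sqrt(p_exact * (1 - p_exact) / 5000)
    assert abs(p_mc - p_exact) < 4 * se + 1e-4


def test_adonis_r2_invariant_to_affine_covariate_transform():
    rng = np.random.default_rng(41)
    d = random_distance_matrix(rng, 12)
    x = rng.standard_normal(12)
    a = adonis(d, x, n_perm=199, seed=9)
    b = adonis(d, 2.5 * x - 7.0, n_perm=199, seed=9)
    assert a.r2 == pytest.approx(b.r2, rel=1e-12)
    assert a.pseudo_f == pytest.approx(b.pseudo_f, rel=1e-12)
    assert a.p == b.p


def test_adonis_invariant_to_consistent_relabeling():
    rng = np.random.default_rng(43)
    d = random_distance_matrix(rng, 6)
    x = rng.standard_normal(6)
    perm = rng.permutation(6)
    a = adonis(d, x, n_perm="all")
    b = adonis(d[np.ix_(perm, perm)], x[perm], n_perm="all")
    assert a.pseudo_f == pytest.approx(b.pseudo_f, rel=1e-10)
    assert a.p == pytest.approx(b.p, abs=1e-12)


def test_adonis_detects_covariate_built_into_distances():
    rng = np.random.default_rng(47)
    x = rng.standard_normal(8)
    d = np.abs(x[:, None] - x[None, :])
    result = adonis(d, x, n_perm="all")
    assert result.r2 > 0.5
    # reversal symmetry of |f_i - f_j| makes 2 of 8! permutations tie the max
    assert result.p <= 4 / result.n_perm


def test_adonis_input_validation():
    d = random_distance_matrix(np.random.default_rng(53), 5)
    with pytest.raises(PhyloError, match="constant"):
        adonis(d, np.ones(5), n_perm=99, seed=1)
    with pytest.raises(PhyloError, match="symmetric"):
        adonis(np.arange(25.0).reshape(5, 5), np.arange(5.0), n_perm=99, seed=1)
    with pytest.raises(PhyloError, match="length"):
        adonis(d, np.arange(4.0), n_perm=99, seed=1)


def test_max_patristic_and_regression(strain_tree):
    assert strain_tree.max_patristic({"MS2"}) == 0.0
    # MS2 and SH7 are sisters: 0.04 + 0.035
    assert strain_tree.max_patristic({"MS2", "SH7"}) == pytest.approx(0.075)
    consortia = [Consortium(frozenset(m)) for m in ({"MS2"}, {"MS2", "SH7"}, {"A5", "MS2"}, {"A5", "A6"})]
    fitness = pd.Series([3.0, 4.0, 2.0, 1.0], index=[c.canonical_id for c in consortia])
    reg = patristic_fitness_regression(strain_tree, consortia, fitness)
    assert 0.0 <= reg["r2"] <= 1.0
    assert reg["n"] == 4
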