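"""OU machinery: skimming, design matrices, fitting, shift detection."""

import math

import numpy as np
import pandas as pd
import pytest

from exprevo import synth
from exprevo._trees import Node, Tree
from exprevo.oushifts import (OrganOUParams, ShiftSearchConfig, TreeArrays,
                              consensus, detect_shifts, fit_null, max_shifts,
                              ou_design, skim_tree)
from exprevo.synth import ORGANS


def _star(lengths):
    root = Node("r")
    root.age = max(lengths)
    for i, ln in enumerate(lengths):
        c = root.add_child(Node(f"t{i}"))
        c.length = ln
        c.age = root.age - ln
    return Tree(root)


# ---------------------------------------------------------------------------
# skimming
# ---------------------------------------------------------------------------

def test_skim_collapses_identical_tips_to_single_tip(species6):
    tree, _ = synth.simulate_gene_family(species6,
                                         synth.FamilySimParams(seed=0))
    row = np.array([1.0, 2, 3, 4, 5, 6])
    traits = pd.DataFrame([row] * len(tree.leaves()),
                          index=tree.leaf_names(), columns=list(ORGANS))
    sk = skim_tree(tree, traits)
    assert len(sk.tree.leaves()) == 1
    assert np.allclose(sk.values.iloc[0], row)
    assert sorted(sk.collapse_map[sk.tree.leaf_names()[0]]) == \
        sorted(tree.leaf_names())


def test_skim_star_clade_mean_is_arithmetic_mean():
    tree = _star([10.0, 10.0, 10.0])
    tree.set_lengths_from_ages()
    rng = np.random.default_rng(0)
    base = np.array([1.0, 2, 3, 4, 5, 6])
    rows = {f"t{i}": base + rng.normal(0, 1e-4, 6) for i in range(3)}
    traits = pd.DataFrame(rows).T
    traits.columns = list(ORGANS)
    sk = skim_tree(tree, traits)
    assert len(sk.tree.leaves()) == 1
    assert np.allclose(sk.values.iloc[0], traits.mean(axis=0), atol=1e-9)


def test_skim_two_tip_clade_uses_gls_weights():
    """Lengths 1 and 3: BM mean = (3 x1 + x2) / 4."""
    root = Node("r")
    root.age = 3.0
    a = root.add_child(Node("a")); a.length = 1.0; a.age = 2.0
    b = root.add_child(Node("b")); b.length = 3.0; b.age = 0.0
    tree = Tree(root)
    x1 = np.array([1.0, 2, 3, 4, 5, 6])
    x2 = x1 * 1.0001          # correlation ~1, different values
    traits = pd.DataFrame([x1, x2], index=["a", "b"], columns=list(ORGANS))
    from exprevo.oushifts import _bm_phylo_mean
    mean = _bm_phylo_mean(root, traits)
    assert np.allclose(mean, (3 * x1 + x2) / 4, rtol=1e-6)


def test_skim_zero_variance_tips():
    tree = _star([5.0, 5.0])
    tree.set_lengths_from_ages()
    traits = pd.DataFrame([[2.0] * 6, [2.0] * 6], index=["t0", "t1"],
                          columns=list(ORGANS))
    sk = skim_tree(tree, traits)   # equal constant vectors: corr treated as 1
    assert len(sk.tree.leaves()) == 1
    traits2 = pd.DataFrame([[2.0] * 6, [3.0] * 6], index=["t0", "t1"],
                           columns=list(ORGANS))
    sk2 = skim_tree(tree, traits2)  # unequal constants: corr treated as 0
    assert len(sk2.tree.leaves()) == 2


# ---------------------------------------------------------------------------
# shift cap
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n,expected", [(4, 2), (9, 4), (16, 8), (100, 50),
                                        (250, 100), (400, 100),
                                        (40000, 200)])
def test_max_shifts_formula(n, expected):
    assert max_shifts(n) == expected


def test_max_shifts_override_and_floor():
    assert max_shifts(2382, cap_override=10) == 10
    with pytest.raises(ValueError):
        max_shifts(3)


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def test_ou_design_matches_path_integration_oracle(species6):
    """V and X reproduced by numerically integrating the OU kernel
    along root-to-tip paths."""
    from scipy.integrate import quad
    sp = species6.tree()
    sp.label_internals(prefix="n", overwrite=True)
    arr = TreeArrays(sp)
    alpha = 0.1
    X, V = ou_design(arr, alpha)
    T = arr.T
    tips = arr.tips
    for i in range(arr.n):
        for j in range(arr.n):
            if i == j:
                t_share = T
            else:
                t_share = T - sp.mrca([tips[i].name, tips[j].name]).age
            # cov = int_0^{t_share} e^{-a (t_i - s)} e^{-a (t_j - s)} ds
            f = lambda s: math.exp(-alpha * (T - s)) ** 2 \
                if i == j else \
                math.exp(-alpha * (T - s)) * math.exp(-alpha * (T - s))
            val, _ = quad(lambda s: math.exp(-alpha * ((T - s) + (T - s))),
                          0.0, t_share, epsabs=1e-13, epsrel=1e-13)
            # tips at age 0: path times are T - s on both sides beyond MRCA
            d_ij = 2.0 * (T - t_share) if i != j else 0.0
            expected = math.exp(-alpha * 0.0) * val if i == j else \
                math.exp(0.0) * val
            # general form: e^{-a d_ij} int_0^{t_share} e^{-2a(t_share-s)} ds
            val2, _ = quad(lambda s: math.exp(-2 * alpha * (t_share - s)),
                           0.0, t_share, epsabs=1e-13, epsrel=1e-13)
            expected = math.exp(-alpha * d_ij) * val2
            assert V[i, j] == pytest.approx(expected, abs=1e-10)
    # X column: alpha int_{t_start}^{T} e^{-alpha (T - s)} ds per descendant
    for bi, br in enumerate(arr.branches):
        t_start = T - br.parent.age
        val, _ = quad(lambda s: alpha * math.exp(-alpha * (T - s)),
                      t_start, T, epsabs=1e-13, epsrel=1e-13)
        desc = {l.name for l in Tree(br).leaves()}
        for ti, tip in enumerate(tips):
            expected = val if tip.name in desc else 0.0
            assert X[ti, 1 + bi] == pytest.approx(expected, abs=1e-10)


def test_ou_design_brownian_limit(species6):
    sp = species6.tree()
    arr = TreeArrays(sp)
    _, V = ou_design(arr, 1e-8)
    rel = np.abs(V - arr.t_mrca) / np.maximum(arr.t_mrca, 1e-12)
    assert rel.max() < 1e-4


def test_ou_design_saturation_for_large_alpha(species6):
    sp = species6.tree()
    arr = TreeArrays(sp)
    X, _ = ou_design(arr, 5.0)    # alpha T = 2000
    for bi in range(len(arr.branches)):
        col = X[:, 1 + bi]
        mask = arr.desc[bi]
        assert np.allclose(col[mask], 1.0, atol=1e-12)
        assert np.allclose(col[~mask], 0.0)


def test_ou_design_rejects_nonpositive_alpha(species6):
    arr = TreeArrays(species6.tree())
    with pytest.raises(ValueError):
        ou_design(arr, 0.0)


# ---------------------------------------------------------------------------
# null fitting
# ---------------------------------------------------------------------------

def test_fit_null_gamma_identity_and_loglik(species8):
    tree, _ = synth.simulate_gene_family(species8,
                                         synth.FamilySimParams(seed=0))
    traits, _ = synth.simulate_ou_expression(
        tree, synth.ExprSimParams(seed=1, shift_prob={"S": 0, "D": 0, "R": 0}))
    params = fit_null(tree, traits)
    for organ, p in params.items():
        assert p.gamma == p.sigma2 / (2 * p.alpha)
        assert np.isfinite(p.loglik)


def test_fit_null_flags_degenerate_traits(species6):
    tree, _ = synth.simulate_gene_family(species6,
                                         synth.FamilySimParams(seed=0))
    traits = pd.DataFrame(np.full((len(tree.leaves()), 6), 2.5),
                          index=tree.leaf_names(), columns=list(ORGANS))
    params = fit_null(tree, traits)
    assert all(p.sigma2 <= 1e-12 for p in params.values())


def test_gamma_identity_enforced():
    with pytest.raises(ValueError):
        OrganOUParams(alpha=-1.0, sigma2=1.0, theta0=0.0)
    p = OrganOUParams(alpha=0.04, sigma2=0.8, theta0=0.0)
    assert p.gamma == pytest.approx(10.0)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def test_constant_traits_give_zero_shifts(species8):
    tree, _ = synth.simulate_gene_family(species8,
                                         synth.FamilySimParams(seed=0))
    traits = pd.DataFrame(np.full((len(tree.leaves()), 6), 3.0),
                          index=tree.leaf_names(), columns=list(ORGANS))
    model = detect_shifts(tree, traits, ShiftSearchConfig(n_lambda=10))
    assert model.shift_branches == []
    assert np.allclose(model.optima[tree.root.name], 3.0)


def test_detection_recovers_large_planted_shift():
    sp = synth.SpeciesTreeSpec.random(24, 400.0, seed=19)
    tree = sp.tree()
    tree.label_internals(prefix="n", overwrite=True)
    for leaf in tree.leaves():
        leaf.species = leaf.name
    ep = synth.ExprSimParams(seed=3, shift_prob={"S": 0, "D": 0, "R": 0})
    traits, _ = synth.simulate_ou_expression(tree, ep)
    eligible = [e for e in tree.edges() if not e.is_leaf
                and 3 <= len(Tree(e).leaves()) <= 10]
    target = max(eligible, key=lambda e: e.parent.age - e.age)
    gamma = ep.sigma2_k / (2 * ep.alpha_k)
    delta = 5.0 * np.sqrt(gamma)
    w = 1 - np.exp(-ep.alpha_k * target.parent.age)
    desc = [l.name for l in Tree(target).leaves()]
    traits.loc[desc] += delta * w
    model = detect_shifts(tree, traits, ShiftSearchConfig(n_lambda=30))
    assert target.name in model.shift_branches
    # selected model beats the single-regime model in likelihood
    null = fit_null(tree, traits)
    assert model.loglik >= sum(p.loglik for p in null.values()) - 1e-6
    # emitted optima follow theta0 + accumulated deltas
    row = model.deltas.loc[target.name].to_numpy()
    assert np.allclose(model.optima[target.name],
                       model.optima[target.parent.name] + row)


def test_detection_invariant_to_organ_relabeling(species8):
    tree, _ = synth.simulate_gene_family(species8,
                                         synth.FamilySimParams(seed=0))
    ep = synth.ExprSimParams(seed=5, shift_prob={"S": 0, "D": 0, "R": 0})
    traits, _ = synth.simulate_ou_expression(tree, ep)
    target = max((e for e in tree.edges() if not e.is_leaf),
                 key=lambda e: len(Tree(e).leaves()))
    gamma = ep.sigma2_k / (2 * ep.alpha_k)
    desc = [l.name for l in Tree(target).leaves()]
    traits.loc[desc] += 5.0 * np.sqrt(gamma)
    m1 = detect_shifts(tree, traits, ShiftSearchConfig(n_lambda=20))
    perm = ["testis", "brain", "liver", "heart", "ovary", "kidney"]
    permuted = traits[perm]
    permuted.columns = list(ORGANS)
    m2 = detect_shifts(tree, permuted, ShiftSearchConfig(n_lambda=20))
    assert m1.shift_branches == m2.shift_branches
    if m1.shift_branches:
        d1 = m1.deltas.to_numpy()
        d2 = m2.deltas.rename(columns=dict(zip(ORGANS, perm)))[list(ORGANS)]
        assert np.allclose(d1, d2.to_numpy(), atol=1e-6)


def test_detection_reproducible(species8):
    tree, _ = synth.simulate_gene_family(species8,
                                         synth.FamilySimParams(seed=0))
    traits, _ = synth.simulate_ou_expression(tree,
                                             synth.ExprSimParams(seed=9))
    cfg = ShiftSearchConfig(n_lambda=15)
    m1 = detect_shifts(tree, traits, cfg)
    m2 = detect_shifts(tree, traits, cfg)
    assert m1.shift_branches == m2.shift_branches
    assert m1.aicc == m2.aicc


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def _fake_model(tree, shifts):
    from exprevo.oushifts import RegimeModel
    optima = {n.name: np.zeros(6) for n in tree.preorder()}
    params = {o: OrganOUParams(0.1, 1.0, 0.0) for o in ORGANS}
    return RegimeModel(shift_branches=list(shifts), organ_params=params,
                       deltas=pd.DataFrame(np.zeros((len(shifts), 6)),
                                           index=list(shifts),
                                           columns=list(ORGANS)),
                       optima=optima, loglik=0.0, aicc=0.0,
                       n_params=18, n_tips=len(tree.leaves()))


def test_consensus_set_algebra(species6):
    tree, _ = synth.simulate_gene_family(species6,
                                         synth.FamilySimParams(seed=0))
    b = [e.name for e in tree.edges()][:3]
    same, venn = consensus(_fake_model(tree, b), _fake_model(tree, b))
    assert same == sorted(b) and venn["both"] == 3
    empty, _ = consensus(_fake_model(tree, b[:1]), _fake_model(tree, b[2:3]))
    assert empty == []
    mid, venn = consensus(_fake_model(tree, b[:2]), _fake_model(tree, b[1:]))
    assert mid == [b[1]] and venn == {"a_only": 1, "b_only": 1, "both": 1}
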