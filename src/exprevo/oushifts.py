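"""Multi-optima Ornstein-Uhlenbeck regime-shift detection on dated gene
trees.

Expression in the six organs is modelled as a multivariate OU process
with organ-specific alpha and sigma^2 shared across the tree; only the
optima shift, jointly in the same branches for all organs.  Candidate
shift configurations are screened by a group lasso over branch
indicator columns (the six organs' optimum changes of one branch form a
group), scored by AICc after an unpenalised GLS refit with re-optimised
alpha, and pruned by a backward pass.  Large trees are first skimmed by
collapsing clades whose tips have near-identical expression
(min pairwise Pearson r > 0.99), replacing each clade by its
Brownian-motion phylogenetic mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize_scalar

from ._trees import Node, Tree
from .synth import ORGANS

__all__ = [
    "OrganOUParams", "RegimeModel", "SkimmedTree", "ShiftSearchConfig",
    "TreeArrays", "skim_tree", "max_shifts", "ou_design", "fit_null",
    "detect_shifts", "consensus",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class OrganOUParams:
    alpha: float
    sigma2: float
    theta0: float
    loglik: float = np.nan
    at_bound: bool = False    # alpha hit the top of the search grid

    def __post_init__(self):
        if self.alpha <= 0 or self.sigma2 <= 0:
            raise ValueError("alpha and sigma2 must be positive")

    @property
    def gamma(self) -> float:
        """Stationary variance sigma^2 / (2 alpha)."""
        return self.sigma2 / (2.0 * self.alpha)


@dataclass
class RegimeModel:
    shift_branches: list[str]
    organ_params: dict[str, OrganOUParams]      # organ -> params
    deltas: pd.DataFrame                        # shifts x organs
    optima: dict[str, np.ndarray]               # node -> 6-vector theta
    loglik: float
    aicc: float
    n_params: int
    n_tips: int

    @property
    def gamma(self) -> dict[str, float]:
        return {k: p.gamma for k, p in self.organ_params.items()}


@dataclass
class SkimmedTree:
    tree: Tree
    collapse_map: dict[str, list[str]]
    values: pd.DataFrame                        # new tips x organs


@dataclass
class ShiftSearchConfig:
    corr_threshold: float = 0.99
    n_lambda: int = 50
    lambda_min_ratio: float = 1e-3
    alpha_grid_size: int = 32
    half_life_range: tuple[float, float] = (1e-3, 10.0)  # x tree depth
    cap_override: Optional[int] = None
    # model-space correction: each shift's position is selected among B
    # candidate branches, which costs 2 ln B on the AICc scale (an MDL /
    # uniform-model-prior argument); without it the search over ~2N
    # branch positions is anti-conservative.  Set False for the plain
    # parameter-count AICc.
    position_penalty: bool = True
    seed: int = 0


# ---------------------------------------------------------------------------
# tree skimming
# ---------------------------------------------------------------------------

def _pair_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa < 1e-12 or sb < 1e-12:
        return 1.0 if np.allclose(a, b, atol=1e-12) else 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _bm_phylo_mean(clade: Node, traits: pd.DataFrame) -> np.ndarray:
    """GLS estimate of the clade root state under Brownian motion."""
    sub = Tree(clade)
    leaves = sub.leaves()
    depths = sub.depths()
    n = len(leaves)
    anc: list[dict[int, float]] = []
    for leaf in leaves:
        chain, node = {}, leaf
        while node is not None:
            chain[id(node)] = depths[id(node)]
            node = node.parent if node is not clade else None
        anc.append(chain)
    V = np.zeros((n, n))
    for i in range(n):
        V[i, i] = depths[id(leaves[i])]
        for j in range(i + 1, n):
            shared = [d for nid, d in anc[i].items() if nid in anc[j]]
            V[i, j] = V[j, i] = max(shared) if shared else 0.0
    V = V + 1e-10 * max(V.max(), 1.0) * np.eye(n)
    Y = traits.loc[[l.name for l in leaves]].to_numpy(dtype=float)
    c, low = cho_factor(V, lower=True)
    ones = np.ones(n)
    w = cho_solve((c, low), ones)
    return (w @ Y) / (w @ ones)


def skim_tree(tree: Tree, traits: pd.DataFrame,
              corr_threshold: float = 0.99) -> SkimmedTree:
    """Collapse maximal clades whose tips have min pairwise Pearson
    correlation above the threshold; collapsed-tip values are the BM
    phylogenetic means of the clade."""
    if len(tree.leaves()) < 1:
        raise ValueError("empty tree")
    work = tree.copy()
    values: dict[str, np.ndarray] = {}
    collapse_map: dict[str, list[str]] = {}

    def _uniform(node: Node) -> bool:
        tips = [l.name for l in Tree(node).leaves()]
        if len(tips) < 2:
            return False
        arr = traits.loc[tips].to_numpy(dtype=float)
        for i in range(len(tips)):
            for j in range(i + 1, len(tips)):
                if _pair_corr(arr[i], arr[j]) <= corr_threshold:
                    return False
        return True

    def _descend(node: Node) -> None:
        if node.is_leaf:
            values[node.name] = traits.loc[node.name].to_numpy(dtype=float)
            collapse_map[node.name] = [node.name]
            return
        if _uniform(node):
            tips = [l.name for l in Tree(node).leaves()]
            mean = _bm_phylo_mean(node, traits)
            node.children = []
            node.age = 0.0
            if node.parent is not None:
                node.length = node.parent.age
            name = node.name or "clade"
            node.name = name
            values[name] = mean
            collapse_map[name] = tips
            return
        for c in list(node.children):
            _descend(c)

    _descend(work.root)
    vals = pd.DataFrame.from_dict(values, orient="index",
                                  columns=list(traits.columns))
    vals = vals.loc[work.leaf_names()]
    return SkimmedTree(work, collapse_map, vals)


def max_shifts(n_tips: int, cap_override: Optional[int] = None) -> int:
    """Upper limit on the number of regime shifts:
    floor(max[min(N/2, 100), sqrt(N)])."""
    if cap_override is not None:
        return int(cap_override)
    if n_tips < 4:
        raise ValueError("need >= 4 tips")
    return int(math.floor(max(min(n_tips / 2.0, 100.0), math.sqrt(n_tips))))


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

class TreeArrays:
    """Index structure of a dated ultrametric tree for OU algebra."""

    def __init__(self, tree: Tree):
        if not tree.is_ultrametric(tol=1e-4):
            raise ValueError("OU fitting requires an ultrametric, dated tree")
        if tree.root.age is None:
            tree.set_ages_from_lengths()
        self.tree = tree
        self.tips = tree.leaves()
        self.tip_names = [t.name for t in self.tips]
        self.n = len(self.tips)
        self.T = float(tree.root.age)
        # candidate branches: every branch (child labels), root excluded
        self.branches = tree.edges()
        self.branch_names = [b.name for b in self.branches]
        tip_idx = {id(t): i for i, t in enumerate(self.tips)}
        # descendant tip masks and MRCA ages
        self.desc = np.zeros((len(self.branches), self.n), dtype=bool)
        below: dict[int, list[int]] = {}
        self.mrca_age = np.zeros((self.n, self.n))
        for node in tree.postorder():
            if node.is_leaf:
                below[id(node)] = [tip_idx[id(node)]]
                self.mrca_age[below[id(node)][0], below[id(node)][0]] = 0.0
            else:
                kids = [below[id(c)] for c in node.children]
                for a in range(len(kids)):
                    for b in range(a + 1, len(kids)):
                        for i in kids[a]:
                            for j in kids[b]:
                                self.mrca_age[i, j] = node.age
                                self.mrca_age[j, i] = node.age
                below[id(node)] = [i for k in kids for i in k]
        for bi, br in enumerate(self.branches):
            self.desc[bi, below[id(br)]] = True
        self.parent_age = np.array([b.parent.age for b in self.branches])
        # root-to-mrca times and patristic distances between tips
        self.t_mrca = self.T - self.mrca_age
        self.d_pat = 2.0 * self.mrca_age
        np.fill_diagonal(self.d_pat, 0.0)
        np.fill_diagonal(self.t_mrca, self.T)


def ou_design(arr: TreeArrays, alpha: float,
              branch_subset: Optional[Sequence[int]] = None
              ) -> tuple[np.ndarray, np.ndarray]:
    """Expectation design X and covariance V (sigma^2 factored out).

    V_ij = (1/2a) e^{-a d_ij} (1 - e^{-2a t_ij}) with t_ij the
    root-to-MRCA time and d_ij the patristic distance; X has a column of
    ones plus, per candidate branch, the indicator of descent scaled by
    1 - e^{-a (T - t_start)} with the shift placed at the branch start.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    V = (1.0 / (2.0 * alpha)) * np.exp(-alpha * arr.d_pat) \
        * (-np.expm1(-2.0 * alpha * arr.t_mrca))
    idx = range(len(arr.branches)) if branch_subset is None else branch_subset
    cols = [np.ones(arr.n)]
    for bi in idx:
        cols.append(arr.desc[bi] * (-np.expm1(-alpha * arr.parent_age[bi])))
    X = np.column_stack(cols)
    return X, V


# ---------------------------------------------------------------------------
# null model fitting
# ---------------------------------------------------------------------------

def _gls_profile(arr: TreeArrays, alpha: float, y: np.ndarray,
                 M: Optional[np.ndarray] = None
                 ) -> tuple[float, np.ndarray, float]:
    """Profile log-likelihood at fixed alpha; M defaults to intercept-only.

    Returns (loglik, beta_hat, sigma2_hat)."""
    n = arr.n
    _, V = ou_design(arr, alpha, branch_subset=[])
    if M is None:
        M = np.ones((n, 1))
    L = cholesky(V + 1e-12 * np.eye(n), lower=True)
    yt = solve_triangular(L, y, lower=True)
    Mt = solve_triangular(L, M, lower=True)
    beta, *_ = np.linalg.lstsq(Mt, yt, rcond=None)
    resid = yt - Mt @ beta
    rss = float(resid @ resid)
    sigma2 = max(rss / n, 1e-12)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    ll = -0.5 * n * math.log(2.0 * math.pi * sigma2) - 0.5 * logdet - 0.5 * n
    return ll, beta, sigma2


def _alpha_grid(arr: TreeArrays, cfg: ShiftSearchConfig) -> np.ndarray:
    """Log-spaced alphas spanning half-lives from 0.1% to 1000% of depth."""
    lo_hl, hi_hl = cfg.half_life_range
    a_hi = math.log(2.0) / (lo_hl * arr.T)
    a_lo = math.log(2.0) / (hi_hl * arr.T)
    return np.geomspace(a_lo, a_hi, cfg.alpha_grid_size)


def _fit_alpha(arr: TreeArrays, y: np.ndarray, cfg: ShiftSearchConfig,
               M_builder=None) -> tuple[float, float, np.ndarray, float, bool]:
    """Maximise the profile likelihood over alpha (grid + local refine).

    M_builder(alpha) -> design matrix; default intercept-only.
    Returns (alpha, loglik, beta, sigma2, at_bound)."""
    grid = _alpha_grid(arr, cfg)

    def nll(log_a):
        a = math.exp(log_a)
        M = M_builder(a) if M_builder else None
        return -_gls_profile(arr, a, y, M)[0]

    vals = [nll(math.log(a)) for a in grid]
    k = int(np.argmin(vals))
    lo = math.log(grid[max(k - 1, 0)])
    hi = math.log(grid[min(k + 1, len(grid) - 1)])
    res = minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-4})
    best_log_a = res.x if res.fun <= vals[k] else math.log(grid[k])
    alpha = math.exp(best_log_a)
    M = M_builder(alpha) if M_builder else None
    ll, beta, sigma2 = _gls_profile(arr, alpha, y, M)
    at_bound = k >= len(grid) - 1
    return alpha, ll, beta, sigma2, at_bound


def fit_null(tree: Tree, traits: pd.DataFrame,
             config: Optional[ShiftSearchConfig] = None
             ) -> dict[str, OrganOUParams]:
    """Per-organ single-regime OU fit (alpha, sigma2, theta0)."""
    cfg = config or ShiftSearchConfig()
    arr = tree if isinstance(tree, TreeArrays) else TreeArrays(tree)
    out: dict[str, OrganOUParams] = {}
    for organ in traits.columns:
        y = traits.loc[arr.tip_names, organ].to_numpy(dtype=float)
        if np.ptp(y) < 1e-12:
            out[organ] = OrganOUParams(alpha=1.0 / arr.T, sigma2=1e-12,
                                       theta0=float(y[0]), loglik=np.inf)
            continue
        alpha, ll, beta, sigma2, at_bound = _fit_alpha(arr, y, cfg)
        out[organ] = OrganOUParams(alpha=alpha, sigma2=sigma2,
                                   theta0=float(beta[0]), loglik=ll,
                                   at_bound=at_bound)
    return out


# ---------------------------------------------------------------------------
# group lasso over branch groups
# ---------------------------------------------------------------------------

def _gl_cd_kernel(G, q, a, a_mean, lambdas, tol_scale, max_iter, stop_size):
    """Gram-based block coordinate descent over the lambda path.

    Group b is zeroed when ||c_b|| <= lambda; otherwise the group norm
    solves the fixed point n = ||c / (a + lambda/n)||."""
    n_lam = lambdas.shape[0]
    K, P = q.shape
    beta = np.zeros((K, P))
    out = np.zeros((n_lam, K, P))
    c = np.zeros(K)
    for li in range(n_lam):
        lam = lambdas[li]
        for _ in range(max_iter):
            delta = 0.0
            for b in range(P):
                nonzero = False
                for k in range(K):
                    s = q[k, b] + a[k, b] * beta[k, b]
                    for p in range(P):
                        s -= G[k, b, p] * beta[k, p]
                    c[k] = s
                    if beta[k, b] != 0.0:
                        nonzero = True
                if b == 0:
                    for k in range(K):
                        new = c[k] / a[k, b]
                        d = abs(new - beta[k, b])
                        if d > delta:
                            delta = d
                        beta[k, b] = new
                    continue
                cn = 0.0
                for k in range(K):
                    cn += c[k] * c[k]
                cn = math.sqrt(cn)
                if cn <= lam or cn < 1e-14:
                    if nonzero:
                        for k in range(K):
                            if abs(beta[k, b]) > delta:
                                delta = abs(beta[k, b])
                            beta[k, b] = 0.0
                    continue
                nn = (cn - lam) / max(a_mean[b], 1e-12)
                if nn < 1e-12:
                    nn = 1e-12
                for _ in range(20):
                    s2 = 0.0
                    for k in range(K):
                        v = c[k] / (a[k, b] + lam / nn)
                        s2 += v * v
                    nn_new = math.sqrt(s2)
                    if abs(nn_new - nn) < 1e-9 * max(nn, 1.0):
                        nn = nn_new
                        break
                    nn = max(nn_new, 1e-12)
                for k in range(K):
                    new = c[k] / (a[k, b] + lam / nn)
                    d = abs(new - beta[k, b])
                    if d > delta:
                        delta = d
                    beta[k, b] = new
            if delta < tol_scale:
                break
        out[li] = beta
        n_active = 0
        for b in range(1, P):
            for k in range(K):
                if beta[k, b] != 0.0:
                    n_active += 1
                    break
        if n_active > stop_size:
            for lj in range(li + 1, n_lam):
                out[lj] = beta
            break
    return out


try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit
    _gl_cd = _njit(cache=True)(_gl_cd_kernel)
except Exception:  # numba unavailable: pure-python fallback
    _gl_cd = _gl_cd_kernel


def _group_lasso_path(Xs: list[np.ndarray], ys: list[np.ndarray],
                      lambdas: np.ndarray, tol: float = 1e-3,
                      max_iter: int = 60,
                      stop_size: Optional[int] = None) -> list[np.ndarray]:
    """Block coordinate descent; column 0 of each X is the unpenalised
    intercept, remaining columns are grouped across the K responses.

    Returns per-lambda coefficient arrays of shape (K, 1 + B).  The
    path stops early once the active set exceeds `stop_size` groups
    (the remaining, smaller lambdas could only grow it further)."""
    X = np.stack(Xs)                       # K x n x (1+B)
    Y = np.stack(ys)                       # K x n
    G = np.einsum("knp,knq->kpq", X, X)
    q = np.einsum("knp,kn->kp", X, Y)
    a = np.einsum("kpp->kp", G).copy()
    a_mean = a.mean(axis=0)
    scale = max(float(np.sqrt((Y * Y).sum() / Y.size)), 1e-8)
    if stop_size is None:
        stop_size = X.shape[2]
    out = _gl_cd(G, q, a, a_mean, np.asarray(lambdas, dtype=float),
                 tol * scale, max_iter, stop_size)
    return [out[i] for i in range(out.shape[0])]


# ---------------------------------------------------------------------------
# shift detection
# ---------------------------------------------------------------------------

class _FitCache:
    """Grid-cached whitened designs for fast support refits.

    For every grid alpha, caches the Cholesky factor of V, its
    log-determinant, the whitened full design [1 | all branch columns]
    and the whitened responses; a support refit then only slices
    columns and solves a small least-squares problem.  Alpha is
    re-optimised per support over a neighbourhood of grid points around
    each organ's null-fit optimum.
    """

    def __init__(self, arr: TreeArrays, traits: pd.DataFrame,
                 cfg: ShiftSearchConfig, neighbourhood: int = 100):
        self.arr = arr
        self.cfg = cfg
        self.organs = list(traits.columns)
        self.grid = _alpha_grid(arr, cfg)
        self.nbh = neighbourhood
        self.Y = {o: traits.loc[arr.tip_names, o].to_numpy(dtype=float)
                  for o in self.organs}
        self.logdet = np.empty(len(self.grid))
        self.W: list[np.ndarray] = []       # per grid alpha: L^-1 [1|X]
        self.yt: list[dict] = []            # per grid alpha: organ -> L^-1 y
        eye = np.eye(arr.n) * 1e-12
        for gi, a in enumerate(self.grid):
            X, V = ou_design(arr, a)
            L = cholesky(V + eye, lower=True)
            self.logdet[gi] = 2.0 * float(np.sum(np.log(np.diag(L))))
            self.W.append(solve_triangular(L, X, lower=True))
            self.yt.append({o: solve_triangular(L, self.Y[o], lower=True)
                            for o in self.organs})
        self.center = {o: None for o in self.organs}  # grid idx of null optimum

    def _ll_at(self, gi: int, organ: str, cols: np.ndarray
               ) -> tuple[float, np.ndarray, float]:
        n = self.arr.n
        Mt = self.W[gi][:, cols]
        yt = self.yt[gi][organ]
        beta, *_ = np.linalg.lstsq(Mt, yt, rcond=None)
        rss = float(np.sum((yt - Mt @ beta) ** 2))
        sigma2 = max(rss / n, 1e-12)
        ll = (-0.5 * n * math.log(2.0 * math.pi * sigma2)
              - 0.5 * self.logdet[gi] - 0.5 * n)
        return ll, beta, sigma2

    def set_centers(self, null_params: dict[str, OrganOUParams]) -> None:
        for o, p in null_params.items():
            self.center[o] = int(np.argmin(np.abs(np.log(self.grid)
                                                  - math.log(p.alpha))))

    def refit(self, support: Sequence[int]
              ) -> tuple[float, float, dict, np.ndarray, np.ndarray]:
        """Returns (aicc, loglik, organ_params, theta0, deltas)."""
        support = sorted(support)
        cols = np.concatenate([[0], 1 + np.asarray(support, dtype=int)]) \
            if support else np.array([0])
        K = len(self.organs)
        params: dict[str, OrganOUParams] = {}
        total_ll = 0.0
        theta0 = np.zeros(K)
        deltas = np.zeros((len(support), K))
        for ki, organ in enumerate(self.organs):
            y = self.Y[organ]
            if np.ptp(y) < 1e-12:
                params[organ] = OrganOUParams(alpha=1.0 / self.arr.T,
                                              sigma2=1e-12, theta0=float(y[0]))
                theta0[ki] = float(y[0])
                continue
            c = self.center[organ]
            idxs = (range(len(self.grid)) if c is None else
                    range(max(c - self.nbh, 0),
                          min(c + self.nbh + 1, len(self.grid))))
            best = None
            for gi in idxs:
                ll, beta, sigma2 = self._ll_at(gi, organ, cols)
                if best is None or ll > best[0]:
                    best = (ll, beta, sigma2, gi)
            ll, beta, sigma2, gi = best
            params[organ] = OrganOUParams(
                alpha=float(self.grid[gi]), sigma2=max(sigma2, 1e-12),
                theta0=float(beta[0]), loglik=ll,
                at_bound=gi >= len(self.grid) - 1)
            theta0[ki] = float(beta[0])
            if len(support):
                deltas[:, ki] = beta[1:]
            total_ll += ll
        p = 3 * K + K * len(support)
        n = K * self.arr.n
        if n - p - 1 <= 0:
            return np.inf, total_ll, params, theta0, deltas
        aicc = -2.0 * total_ll + 2.0 * p + 2.0 * p * (p + 1) / (n - p - 1)
        if self.cfg.position_penalty:
            B = max(len(self.arr.branches), 2)
            aicc += 2.0 * len(support) * math.log(B)
        return aicc, total_ll, params, theta0, deltas


def _refit_support(arr: TreeArrays, traits: pd.DataFrame,
                   support: Sequence[int], cfg: ShiftSearchConfig
                   ) -> tuple[float, float, dict, np.ndarray, np.ndarray]:
    """Standalone unpenalised GLS refit (used for degenerate inputs)."""
    cache = _FitCache(arr, traits, cfg)
    return cache.refit(support)


def detect_shifts(tree: Tree, traits: pd.DataFrame,
                  config: Optional[ShiftSearchConfig] = None) -> RegimeModel:
    """Group-lasso screening + AICc selection of regime shifts.

    Pipeline: per-organ null fit for initial alpha; whitening by the
    Cholesky inverse of each organ's covariance; group lasso along a
    geometric lambda path tying the organs' branch coefficients; AICc
    refits for every distinct support within the shift cap; backward
    elimination to an AICc fixpoint.
    """
    cfg = config or ShiftSearchConfig()
    arr = TreeArrays(tree)
    cap = max_shifts(arr.n, cfg.cap_override)
    organs = list(traits.columns)
    traits = traits.loc[arr.tip_names]

    constant = all(np.ptp(traits[o].to_numpy()) < 1e-12 for o in organs)
    if constant:
        aicc, ll, params, theta0, deltas = _refit_support(arr, traits, [], cfg)
        return _emit(arr, [], params, theta0, np.zeros((0, len(organs))),
                     ll, aicc, organs)

    cache = _FitCache(arr, traits, cfg)
    null_params = fit_null(arr, traits, cfg)
    cache.set_centers(null_params)

    # whiten per organ at the null alphas (nearest cached grid point)
    Xs, ys = [], []
    for organ in organs:
        gi = cache.center[organ]
        s = math.sqrt(max(null_params[organ].sigma2, 1e-12))
        Xs.append(cache.W[gi] / s)
        ys.append(cache.yt[gi][organ] / s)

    # lambda path from the null-support lambda_max
    c0 = []
    for b in range(len(arr.branches)):
        cb = []
        for k, organ in enumerate(organs):
            x0 = Xs[k][:, 0]
            r = ys[k] - x0 * (x0 @ ys[k]) / (x0 @ x0)
            cb.append(Xs[k][:, 1 + b] @ r)
        c0.append(np.linalg.norm(cb))
    lam_max = max(max(c0), 1e-8)
    lambdas = np.geomspace(lam_max * 0.999, lam_max * cfg.lambda_min_ratio,
                           cfg.n_lambda)

    path = _group_lasso_path(Xs, ys, lambdas, stop_size=cap + 3)
    supports: list[tuple[int, ...]] = [()]
    seen = {()}
    truncated = False
    for beta in path:
        norms = np.linalg.norm(beta[:, 1:], axis=0)
        sup = tuple(np.nonzero(norms > 1e-8)[0])
        if len(sup) > cap:
            order = np.argsort(norms[list(sup)])[::-1][:cap]
            sup = tuple(sorted(np.asarray(sup)[order]))
            truncated = True
        if sup not in seen:
            seen.add(sup)
            supports.append(sup)
    if truncated:
        import warnings
        warnings.warn("shift cap reached along the lasso path; support "
                      "truncated by group norm")

    best = None
    for sup in supports:
        aicc, ll, params, theta0, deltas = cache.refit(list(sup))
        key = (aicc, len(sup), tuple(arr.branch_names[i] for i in sup))
        if best is None or key < best[0]:
            best = (key, sup, aicc, ll, params, theta0, deltas)

    # backward pass
    _, sup, aicc, ll, params, theta0, deltas = best
    sup = list(sup)
    improved = True
    while improved and sup:
        improved = False
        options = []
        for drop in sup:
            cand = [b for b in sup if b != drop]
            a2, l2, p2, t2, d2 = cache.refit(cand)
            options.append((a2, cand, l2, p2, t2, d2))
        options.sort(key=lambda o: (o[0], len(o[1])))
        if options and options[0][0] <= aicc:
            aicc, sup, ll, params, theta0, deltas = (
                options[0][0], options[0][1], options[0][2],
                options[0][3], options[0][4], options[0][5])
            improved = True

    return _emit(arr, sorted(sup), params, theta0, deltas, ll, aicc, organs)


def _emit(arr: TreeArrays, support: list[int], params, theta0, deltas,
          ll: float, aicc: float, organs: list[str]) -> RegimeModel:
    support = sorted(support)                 # rows of `deltas` follow this
    raw_names = [arr.branch_names[i] for i in support]
    order = list(np.argsort(raw_names))
    names = [raw_names[i] for i in order]
    deltas = deltas[order] if len(support) else deltas
    ddf = pd.DataFrame(deltas, index=names, columns=organs)
    # per-node optima: theta0 plus deltas of shifts on the root path
    shift_set = {name: deltas[i] for i, name in enumerate(names)}
    optima: dict[str, np.ndarray] = {arr.tree.root.name: theta0.copy()}
    for node in arr.tree.preorder():
        if node.parent is None:
            continue
        theta = optima[node.parent.name].copy()
        if node.name in shift_set:
            theta = theta + shift_set[node.name]
        optima[node.name] = theta
    K = len(organs)
    n_params = 3 * K + K * len(support)
    return RegimeModel(shift_branches=names, organ_params=params,
                       deltas=ddf, optima=optima, loglik=ll, aicc=aicc,
                       n_params=n_params, n_tips=arr.n)


def consensus(model_a: RegimeModel, model_b: RegimeModel
              ) -> tuple[list[str], dict[str, int]]:
    """Shift branches detected in both models, with Venn counts.

    Branch ids are original child-node labels, so models fitted on
    differently skimmed versions of the same tree remain comparable: a
    shift on a branch the other metric collapsed away cannot be
    consistent and drops out of the intersection."""
    if not set(model_a.optima) & set(model_b.optima):
        raise ValueError("models come from different trees (no shared nodes)")
    sa, sb = set(model_a.shift_branches), set(model_b.shift_branches)
    both = sorted(sa & sb)
    venn = {"a_only": len(sa - sb), "b_only": len(sb - sa), "both": len(both)}
    return both, venn
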