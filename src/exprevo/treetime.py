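"""Gene-tree rooting, node classification and divergence dating.

Nodes are classified speciation/duplication by species overlap; rooting
candidates are scored by duplication-loss reconciliation against the
dated species tree (dup cost 1.5, loss cost 1.0 by default) alongside
midpoint and minimal-ancestor-deviation candidates.  Dating maps
speciation nodes onto species-tree ages (fixed constraints), brackets
duplication nodes between their nearest ancestral and descendant
speciation ages (root fallback 1105 MY, the animal-fungi split), and
estimates the remaining ages by constrained weighted least squares under
a clock with a configurable number of rate categories.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from ._trees import Node, Tree

__all__ = [
    "RootingConfig", "TimeConstraints", "DatingReport",
    "classify_species_overlap", "root_tree", "build_constraints", "date_tree",
]

ROOT_UPPER_DEFAULT = 1105.0  # MY


@dataclass
class RootingConfig:
    dup_score: float = 1.5
    loss_score: float = 1.0

    def __post_init__(self):
        if self.dup_score <= 0 or self.loss_score <= 0:
            raise ValueError("costs must be > 0")


@dataclass
class TimeConstraints:
    fixed: dict[str, float] = field(default_factory=dict)
    bounded: dict[str, tuple[float, float]] = field(default_factory=dict)
    root_upper_default: float = ROOT_UPPER_DEFAULT
    species_root_age: float = ROOT_UPPER_DEFAULT
    infeasible: list[str] = field(default_factory=list)


@dataclass
class DatingReport:
    relaxation_steps: int = 0
    dropped_bounds: bool = False
    objective: float = 0.0
    rates: dict[str, float] = field(default_factory=dict)
    messages: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# species-overlap classification and reconciliation
# ---------------------------------------------------------------------------

def _species_map(gene_tree: Tree, sp_tree: Tree) -> dict[int, Node]:
    """LCA mapping: each gene node -> species-tree MRCA of its species set."""
    sp_sets = gene_tree.species_sets()
    cache: dict[frozenset, Node] = {}
    out: dict[int, Node] = {}
    for node in gene_tree.preorder():
        key = sp_sets[id(node)]
        if key not in cache:
            cache[key] = sp_tree.mrca(key) if len(key) > 1 else sp_tree.find(next(iter(key)))
        out[id(node)] = cache[key]
    return out


def classify_species_overlap(gene_tree: Tree, sp_tree: Optional[Tree] = None
                             ) -> dict[str, str]:
    """'D' where the two child subtrees share species, else 'S'.

    Annotates each node's ``event``; with a species tree given, S nodes
    additionally get their species-tree mapping in ``extra['sp_map']``.
    """
    sp_sets = gene_tree.species_sets()
    events: dict[str, str] = {}
    for node in gene_tree.internals():
        if len(node.children) != 2:
            raise ValueError(f"non-binary node {node.name!r}")
        left, right = (sp_sets[id(c)] for c in node.children)
        ev = "D" if left & right else "S"
        node.event = ev
        events[node.name] = ev
        if ev == "S" and sp_tree is not None:
            node.extra["sp_map"] = sp_tree.mrca(sp_sets[id(node)]).name
    return events


def _dl_counts(gene_tree: Tree, sp_tree: Tree) -> tuple[int, int]:
    """Duplication and loss counts of the LCA reconciliation."""
    smap = _species_map(gene_tree, sp_tree)
    depth: dict[int, int] = {id(sp_tree.root): 0}
    for n in sp_tree.preorder():
        if n.parent is not None:
            depth[id(n)] = depth[id(n.parent)] + 1
    dups = losses = 0
    for u in gene_tree.internals():
        is_dup = any(smap[id(u)] is smap[id(v)] for v in u.children)
        if is_dup:
            dups += 1
        for v in u.children:
            k = depth[id(smap[id(v)])] - depth[id(smap[id(u)])]
            losses += max(k - 1 + (1 if is_dup else 0), 0)
    return dups, losses


# ---------------------------------------------------------------------------
# rooting
# ---------------------------------------------------------------------------

def _bipartition(node: Node, all_tips: frozenset) -> frozenset:
    side = frozenset(leaf.name for leaf in Tree(node).leaves()) \
        if node.children else frozenset([node.name])
    other = all_tips - side
    return min(side, other, key=lambda s: tuple(sorted(s)))


def _pairwise_tip_distances(tree: Tree) -> dict[tuple[str, str], float]:
    depths = tree.depths()
    anc: dict[str, list[Node]] = {}
    for leaf in tree.leaves():
        chain, n = [], leaf
        while n is not None:
            chain.append(n)
            n = n.parent
        anc[leaf.name] = chain
    dist = {}
    leaves = tree.leaves()
    for a, b in itertools.combinations(leaves, 2):
        seen = {id(n) for n in anc[a.name]}
        m = next(n for n in anc[b.name] if id(n) in seen)
        d = depths[id(a)] + depths[id(b)] - 2 * depths[id(m)]
        dist[(a.name, b.name)] = dist[(b.name, a.name)] = d
    return dist


def _mad_deviation(rooted: Tree, dist: dict) -> float:
    """Root-mean-square relative deviation of midpoint positions."""
    depths = rooted.depths()
    anc: dict[str, dict[int, Node]] = {}
    for leaf in rooted.leaves():
        chain, n = {}, leaf
        while n is not None:
            chain[id(n)] = n
            n = n.parent
        anc[leaf.name] = chain
    devs = []
    for a, b in itertools.combinations(rooted.leaves(), 2):
        m = a
        while id(m) not in anc[b.name]:
            m = m.parent
        d_ab = dist[(a.name, b.name)]
        if d_ab <= 0:
            continue
        r = abs(2.0 * (depths[id(a)] - depths[id(m)]) / d_ab - 1.0)
        devs.append(r * r)
    return float(np.sqrt(np.mean(devs))) if devs else 0.0


def root_tree(tree: Tree, sp_tree: Tree,
              config: Optional[RootingConfig] = None
              ) -> tuple[Tree, "object"]:
    """Try every branch as the root; combine duplication-loss, midpoint
    and minimal-ancestor-deviation signals.

    The duplication-loss-minimal candidate set is authoritative: the MAD
    root is used if it lies in that set, else the midpoint root, else
    the DL-minimal candidate topologically nearest the MAD root (ties:
    lexicographically smallest bipartition).  Returns the rooted tree
    and a per-candidate score table (pandas DataFrame).
    """
    import pandas as pd
    config = config or RootingConfig()
    if len(tree.leaves()) < 3:
        raise ValueError("rooting needs >= 3 tips")
    work = tree.copy()
    all_tips = frozenset(work.leaf_names())
    dist = _pairwise_tip_distances(work)

    edges = work.edges()
    rows = []
    rooted_cache: dict[frozenset, tuple[Node, Tree, float]] = {}
    for child in edges:
        bip = _bipartition(child, all_tips)
        if bip in rooted_cache:
            continue
        cand = work.reroot_on_edge(child, 0.5)
        for n in cand.preorder():
            if n.is_leaf:
                n.species = n.species or _strip_copy(n.name)
        d, l = _dl_counts(cand, sp_tree)
        # MAD: optimal root position on this branch, then RMS deviation
        mad_x, mad_score = _mad_on_edge(work, child, dist, all_tips)
        rooted_cache[bip] = (child, cand, mad_x)
        rows.append({"bipartition": tuple(sorted(bip)), "dups": d,
                     "losses": l,
                     "dl_score": config.dup_score * d + config.loss_score * l,
                     "mad": mad_score})
    table = pd.DataFrame(rows)

    # midpoint candidate
    mp_child, mp_fraction = _midpoint_edge(work, dist)
    mp_bip = tuple(sorted(_bipartition(mp_child, all_tips)))
    # MAD candidate = edge with smallest deviation
    mad_idx = int(table["mad"].idxmin())
    mad_bip = table.loc[mad_idx, "bipartition"]

    min_score = table["dl_score"].min()
    dl_set = set(table.loc[table["dl_score"] == min_score, "bipartition"])
    if mad_bip in dl_set:
        chosen = mad_bip
    elif mp_bip in dl_set:
        chosen = mp_bip
    else:
        mad_child = rooted_cache[frozenset(mad_bip)][0]
        best = sorted(dl_set, key=lambda b: (
            _topo_distance(work, rooted_cache[frozenset(b)][0], mad_child), b))
        chosen = best[0]

    child, _, mad_x = rooted_cache[frozenset(chosen)]
    if chosen == mad_bip:
        frac = mad_x
    elif chosen == mp_bip:
        frac = mp_fraction
    else:
        frac = 0.5
    final = work.reroot_on_edge(child, frac)
    final.label_internals(prefix="n", overwrite=True)
    table["chosen"] = [tuple(b) == chosen for b in table["bipartition"]]
    table["midpoint"] = [tuple(b) == mp_bip for b in table["bipartition"]]
    table["mad_root"] = [tuple(b) == mad_bip for b in table["bipartition"]]
    return final, table


def _strip_copy(name: str) -> str:
    return name.rsplit("_g", 1)[0] if "_g" in name else name


def _mad_on_edge(tree: Tree, child: Node, dist: dict, all_tips: frozenset
                 ) -> tuple[float, float]:
    side = frozenset(leaf.name for leaf in Tree(child).leaves()) \
        if child.children else frozenset([child.name])
    length = child.length
    # distances from tips in `side` up to the child end of the branch
    sub_depths = Tree(child).depths()
    t_child = {leaf.name: sub_depths[id(leaf)] for leaf in Tree(child).leaves()}
    num = den = 0.0
    for a in side:
        for b in all_tips - side:
            d_ab = dist[(a, b)]
            if d_ab <= 0:
                continue
            u = 2.0 / d_ab
            num += u * (1.0 - u * t_child[a])
            den += u * u
    x = min(max(num / den, 0.0), length) if den > 0 else 0.5 * length
    frac = x / length if length > 0 else 0.5
    rooted = tree.reroot_on_edge(child, frac)
    return frac, _mad_deviation(rooted, dist)


def _midpoint_edge(tree: Tree, dist: dict) -> tuple[Node, float]:
    (a, b), d_max = max(((p, d) for p, d in dist.items()), key=lambda kv: kv[1])
    na, nb = tree.find(a), tree.find(b)
    depths = tree.depths()
    chain_a, n = [], na
    while n is not None:
        chain_a.append(n)
        n = n.parent
    ids_a = {id(x) for x in chain_a}
    m, n = None, nb
    while n is not None:
        if id(n) in ids_a:
            m = n
            break
        n = n.parent
    # walk from a toward the MRCA, then down toward b, finding the halfway point
    half = d_max / 2.0
    path = []
    n = na
    while n is not m:
        path.append(n)          # branches on the a-side, child end first
        n = n.parent
    b_side = []
    n = nb
    while n is not m:
        b_side.append(n)
        n = n.parent
    path.extend(reversed(b_side))
    walked = 0.0
    for node in path:
        nxt = walked + node.length
        if nxt >= half - 1e-12:
            on_a_side = id(node) in {id(x) for x in chain_a}
            within = half - walked
            frac = (within / node.length) if node.length > 0 else 0.5
            if not on_a_side:
                frac = 1.0 - frac
            return node, min(max(frac, 0.0), 1.0)
        walked = nxt
    return path[-1], 0.5


def _topo_distance(tree: Tree, n1: Node, n2: Node) -> int:
    chain, n = {}, n1
    i = 0
    while n is not None:
        chain[id(n)] = i
        n = n.parent
        i += 1
    n, j = n2, 0
    while id(n) not in chain:
        n = n.parent
        j += 1
    return chain[id(n)] + j


# ---------------------------------------------------------------------------
# time constraints
# ---------------------------------------------------------------------------

def build_constraints(gene_tree: Tree, sp_tree: Tree,
                      events: dict[str, str],
                      root_upper_default: float = ROOT_UPPER_DEFAULT
                      ) -> TimeConstraints:
    """Fix speciation nodes to species-tree ages; bracket duplication
    nodes between nearest descendant and ancestral speciation ages."""
    sp_sets = gene_tree.species_sets()
    tc = TimeConstraints(root_upper_default=root_upper_default,
                         species_root_age=sp_tree.root.age or root_upper_default)
    for node in gene_tree.internals():
        if events[node.name] == "S":
            tc.fixed[node.name] = float(sp_tree.mrca(sp_sets[id(node)]).age)

    def _nearest_desc_s(node: Node) -> float:
        best = 0.0
        for c in node.children:
            if c.is_leaf:
                continue
            if events[c.name] == "S":
                best = max(best, tc.fixed[c.name])
            else:
                best = max(best, _nearest_desc_s(c))
        return best

    for node in gene_tree.internals():
        if events[node.name] == "S":
            continue
        lower = _nearest_desc_s(node)
        upper = root_upper_default
        anc = node.parent
        while anc is not None:
            if events.get(anc.name) == "S":
                upper = tc.fixed[anc.name]
                break
            anc = anc.parent
        tc.bounded[node.name] = (lower, upper)
        if lower >= upper:
            tc.infeasible.append(node.name)
    return tc


# ---------------------------------------------------------------------------
# dating by constrained weighted least squares
# ---------------------------------------------------------------------------

def _assign_categories(edges: list[Node], k: int,
                       depths: dict[int, float]) -> list[int]:
    if k <= 1:
        return [0] * len(edges)
    mid = np.array([depths[id(e.parent)] + e.length / 2 for e in edges])
    qs = np.quantile(mid, np.linspace(0, 1, k + 1)[1:-1]) if len(mid) else []
    return list(np.searchsorted(qs, mid))


def date_tree(gene_tree: Tree, constraints: TimeConstraints,
              rate_categories: int = 1, smoothing: float = 1.0,
              eps: float = 1e-6, max_relax: int = 5
              ) -> tuple[Tree, DatingReport]:
    """Estimate node ages under the clock model.

    Minimises sum_b (l_b - r_{c(b)} t_b)^2 / max(l_b, eps) over free node
    ages and per-category rates (plus a smoothing penalty on rate
    variation across categories), subject to fixed speciation ages,
    duplication brackets and parent-older-than-child ordering.  When the
    constraint set is infeasible, duplication brackets are widened by
    10% of the species-tree root age per step (at most `max_relax`
    steps) and finally dropped.
    """
    report = DatingReport()
    tree = gene_tree.copy()
    step = 0.10 * constraints.species_root_age

    for attempt in range(max_relax + 2):
        widen = attempt * step
        drop = attempt > max_relax
        bounded = {} if drop else {
            k: (max(lo - widen, 0.0), hi + widen)
            for k, (lo, hi) in constraints.bounded.items()}
        ok, msg = _try_date(tree, constraints.fixed, bounded,
                            rate_categories, smoothing, eps, report)
        if ok:
            report.relaxation_steps = attempt
            report.dropped_bounds = drop
            if attempt:
                report.messages.append(
                    f"relaxation ladder: {attempt} step(s)"
                    + (", bounds dropped" if drop else ""))
            tree.set_lengths_from_ages()
            return tree, report
        report.messages.append(f"attempt {attempt}: {msg}")
    raise RuntimeError("dating infeasible after full relaxation: "
                       + "; ".join(report.messages[-3:]))


def _try_date(tree: Tree, fixed: dict[str, float],
              bounded: dict[str, tuple[float, float]],
              rate_categories: int, smoothing: float, eps: float,
              report: DatingReport) -> tuple[bool, str]:
    nodes = list(tree.preorder())
    internals = [n for n in nodes if not n.is_leaf]
    free = [n for n in internals if n.name not in fixed]
    for leaf in tree.leaves():
        leaf.age = 0.0
    for n in internals:
        if n.name in fixed:
            n.age = fixed[n.name]

    # initial feasible ages, postorder
    min_gap = 1e-4
    for n in reversed(nodes):
        if n.is_leaf or n.name in fixed:
            continue
        lo_kids = max((c.age for c in n.children), default=0.0)
        lo, hi = bounded.get(n.name, (0.0, np.inf))
        n.age = max(lo_kids + min_gap, lo + min_gap / 2)
        if n.age > hi + 1e-9:
            if lo_kids + min_gap > hi + 1e-9:
                return False, f"node {n.name}: children older than upper bound"
            n.age = min(max(lo_kids + min_gap, lo), hi)
    for n in nodes:  # parents must exceed children even with fixed ages
        if n.parent is not None and n.parent.age <= n.age:
            if n.parent.name in fixed and (n.name in fixed or n.is_leaf):
                return False, f"fixed ages conflict at {n.name}"
            if n.parent.name not in fixed:
                n.parent.age = n.age + min_gap

    edges = [n for n in nodes if n.parent is not None]
    lengths = np.array([e.length for e in edges])
    weights = np.maximum(lengths, eps)
    depths = tree.depths()
    cats = _assign_categories(edges, rate_categories, depths)
    ncat = max(cats) + 1 if edges else 1

    if not free:
        rates = {}
        for e, c in zip(edges, cats):
            t = e.parent.age - e.age
            rates[e.name] = e.length / t if t > 0 else 0.0
        report.rates = rates
        report.objective = 0.0
        return True, ""

    idx = {id(n): i for i, n in enumerate(free)}
    x0 = np.array([n.age for n in free])

    def ages_of(x):
        a = {}
        for n in nodes:
            if n.is_leaf:
                a[id(n)] = 0.0
            elif n.name in fixed:
                a[id(n)] = fixed[n.name]
            else:
                a[id(n)] = x[idx[id(n)]]
        return a

    def durations(x):
        a = ages_of(x)
        return np.array([a[id(e.parent)] - a[id(e)] for e in edges])

    def objective(x):
        t = np.maximum(durations(x), 1e-9)
        f = 0.0
        r_by_cat = np.zeros(ncat)
        for c in range(ncat):
            m = np.array([ci == c for ci in cats])
            if not m.any():
                continue
            num = np.sum(lengths[m] * t[m] / weights[m])
            den = np.sum(t[m] ** 2 / weights[m])
            r = num / den if den > 0 else 0.0
            r_by_cat[c] = r
            f += np.sum((lengths[m] - r * t[m]) ** 2 / weights[m])
        if ncat > 1 and smoothing > 0:
            f += smoothing * np.sum((r_by_cat - r_by_cat.mean()) ** 2)
        return f

    cons = []
    for e in edges:
        pi = idx.get(id(e.parent))
        ci = idx.get(id(e))
        if pi is None and ci is None:
            continue
        def _make(pi=pi, ci=ci, p=e.parent, c=e):
            def g(x):
                pa = x[pi] if pi is not None else (fixed.get(p.name, 0.0))
                ca = x[ci] if ci is not None else (
                    0.0 if c.is_leaf else fixed.get(c.name, 0.0))
                return pa - ca - 1e-6
            return g
        cons.append({"type": "ineq", "fun": _make()})
    bnds = []
    for n in free:
        lo, hi = bounded.get(n.name, (0.0, None))
        bnds.append((lo, hi))

    res = minimize(objective, x0, method="SLSQP", bounds=bnds,
                   constraints=cons,
                   options={"maxiter": 500, "ftol": 1e-12})
    x = res.x
    # accept near-feasible solutions; clamp tiny violations into bounds
    for n in free:
        lo, hi = bounded.get(n.name, (0.0, np.inf))
        hi = np.inf if hi is None else hi
        n.age = float(min(max(x[idx[id(n)]], lo), hi))
    bad = [e.name for e in edges if e.parent.age < (0.0 if e.is_leaf else e.age) - 1e-6
           or e.parent.age - e.age < -1e-6]
    if bad:
        return False, f"ordering violated at {bad[:3]}"
    report.objective = float(objective(np.array([n.age for n in free])))
    a = {id(n): n.age for n in nodes}
    report.rates = {}
    t = np.maximum(np.array([a[id(e.parent)] - a[id(e)] for e in edges]), 1e-12)
    for c in range(ncat):
        m = np.array([ci == c for ci in cats])
        num = np.sum(lengths[m] * t[m] / weights[m])
        den = np.sum(t[m] ** 2 / weights[m])
        r = num / den if den > 0 else 0.0
        for e, mi in zip(edges, m):
            if mi:
                report.rates[e.name] = float(r)
    return True, ""
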