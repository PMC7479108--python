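"""Branch categories (speciation / duplication / retrotransposition) and
ancestral discrete-character inference.

Intron presence is collapsed to a binary character and chromosomal
location to {autosome, X, Y}; marginal ancestral posteriors come from
the pruning algorithm under asymmetric continuous-time rate matrices
(intron loss 1e-3, gain 1e-4, translocation 1e-3 per gene per MY) with
a stationary root prior.  A duplication-descended branch is re-labelled
R when its maximum-posterior intron state flips from intron-containing
to intronless across the branch with both posteriors above 0.5; the
sister (original) copy stays D.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.linalg import expm

from ._trees import Node, Tree

__all__ = [
    "DiscreteCharModel", "BranchAnnotation", "intron_model",
    "chromosome_model", "ancestral_binary", "ancestral_discrete",
    "classify_branches", "sample_histories",
]

INTRON_STATES = ("intronless", "intron_containing")
CHROM_STATES = ("A", "X", "Y")


@dataclass
class DiscreteCharModel:
    states: tuple[str, ...]
    rate_matrix: np.ndarray     # per MY; rows sum to 0
    root_prior: Optional[np.ndarray] = None   # None -> stationary

    def __post_init__(self):
        Q = np.asarray(self.rate_matrix, dtype=float)
        if Q.shape != (len(self.states), len(self.states)):
            raise ValueError("rate matrix shape mismatch")
        off = Q.copy()
        np.fill_diagonal(off, 0.0)
        if (off < 0).any():
            raise ValueError("off-diagonal rates must be >= 0")
        if not np.allclose(Q.sum(axis=1), 0.0, atol=1e-12):
            raise ValueError("rate matrix rows must sum to 0")
        self.rate_matrix = Q

    def stationary(self) -> np.ndarray:
        Q = self.rate_matrix
        A = np.vstack([Q.T, np.ones(len(self.states))])
        b = np.zeros(len(self.states) + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()

    def prior(self) -> np.ndarray:
        return self.stationary() if self.root_prior is None else self.root_prior


def intron_model(loss_rate: float = 1e-3, gain_rate: float = 1e-4
                 ) -> DiscreteCharModel:
    """Binary intron character; state order (intronless, containing)."""
    Q = np.array([[-gain_rate, gain_rate],
                  [loss_rate, -loss_rate]])
    return DiscreteCharModel(INTRON_STATES, Q)


def chromosome_model(translocation_rate: float = 1e-3) -> DiscreteCharModel:
    r = translocation_rate
    Q = np.full((3, 3), r)
    np.fill_diagonal(Q, -2.0 * r)
    return DiscreteCharModel(CHROM_STATES, Q)


@dataclass
class BranchAnnotation:
    category: str                       # S | D | R
    translocation: bool = False
    missing_chromosome: bool = False


# ---------------------------------------------------------------------------
# pruning-algorithm marginal posteriors
# ---------------------------------------------------------------------------

def _transition(model: DiscreteCharModel, t: float) -> np.ndarray:
    return expm(model.rate_matrix * max(t, 1e-9))


def ancestral_discrete(tree: Tree, tip_states: dict[str, Optional[str]],
                       model: DiscreteCharModel) -> pd.DataFrame:
    """Marginal posterior state probabilities at every node.

    Missing tip states (None or absent) are marginalised.  Branch
    durations come from node ages (dated tree)."""
    k = len(model.states)
    sidx = {s: i for i, s in enumerate(model.states)}
    pri = model.prior()

    P: dict[int, np.ndarray] = {}
    for node in tree.preorder():
        if node.parent is not None:
            t = node.parent.age - node.age
            P[id(node)] = _transition(model, t)

    down: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            state = tip_states.get(node.name)
            vec = np.ones(k) if state is None else np.eye(k)[sidx[state]]
            down[id(node)] = vec
        else:
            vec = np.ones(k)
            for c in node.children:
                vec = vec * (P[id(c)] @ down[id(c)])
            down[id(node)] = vec

    up: dict[int, np.ndarray] = {id(tree.root): pri.copy()}
    for node in tree.preorder():
        for c in node.children:
            sib = np.ones(k)
            for w in node.children:
                if w is not c:
                    sib = sib * (P[id(w)] @ down[id(w)])
            up[id(c)] = (up[id(node)] * sib) @ P[id(c)]

    rows = {}
    for node in tree.preorder():
        post = up[id(node)] * down[id(node)]
        total = post.sum()
        rows[node.name] = post / total if total > 0 else pri
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(model.states))


def ancestral_binary(tree: Tree, tip_states: dict[str, Optional[int]],
                     model: Optional[DiscreteCharModel] = None
                     ) -> pd.DataFrame:
    """Intron-state posteriors from binary tip data (0 = intronless,
    or raw intron counts which are collapsed to presence/absence)."""
    model = model or intron_model()
    conv = {}
    for name, v in tip_states.items():
        if v is None:
            conv[name] = None
        else:
            conv[name] = INTRON_STATES[0] if int(v) == 0 else INTRON_STATES[1]
    return ancestral_discrete(tree, conv, model)


def sample_histories(tree: Tree, tip_states: dict[str, Optional[str]],
                     model: DiscreteCharModel, n_maps: int = 100,
                     seed: int = 0) -> pd.DataFrame:
    """Joint node-state realisations (stochastic mapping at node
    resolution); returns per-branch transition frequencies."""
    rng = np.random.default_rng(seed)
    k = len(model.states)
    sidx = {s: i for i, s in enumerate(model.states)}
    pri = model.prior()
    P, down = {}, {}
    for node in tree.preorder():
        if node.parent is not None:
            P[id(node)] = _transition(model, node.parent.age - node.age)
    for node in tree.postorder():
        if node.is_leaf:
            state = tip_states.get(node.name)
            down[id(node)] = (np.ones(k) if state is None
                              else np.eye(k)[sidx[state]])
        else:
            vec = np.ones(k)
            for c in node.children:
                vec = vec * (P[id(c)] @ down[id(c)])
            down[id(node)] = vec

    counts = {n.name: 0 for n in tree.edges()}
    for _ in range(n_maps):
        root_p = pri * down[id(tree.root)]
        root_p = root_p / root_p.sum()
        drawn = {id(tree.root): int(rng.choice(k, p=root_p))}
        for node in tree.preorder():
            for c in node.children:
                s = drawn[id(node)]
                p = P[id(c)][s] * down[id(c)]
                p = p / p.sum()
                drawn[id(c)] = int(rng.choice(k, p=p))
                if drawn[id(c)] != s:
                    counts[c.name] += 1
    return pd.DataFrame({"transition_freq":
                         {n: c / n_maps for n, c in counts.items()}})


# ---------------------------------------------------------------------------
# branch classification
# ---------------------------------------------------------------------------

def classify_branches(tree: Tree, events: dict[str, str],
                      intron_post: pd.DataFrame,
                      chrom_post: Optional[pd.DataFrame] = None,
                      posterior_cutoff: float = 0.5
                      ) -> dict[str, BranchAnnotation]:
    """Per-branch S/D/R category plus translocation flags.

    The branch above a node takes its parent's event; a D branch
    becomes R when the MAP intron state switches containing ->
    intronless across it with both endpoint posteriors above the
    cutoff.  If both children of a duplication node qualify, only the
    one with the stronger intronless posterior is R (the other is the
    original copy).
    """
    out: dict[str, BranchAnnotation] = {}
    p_less = intron_post[INTRON_STATES[0]]

    def _retro_score(parent: Node, child: Node) -> float:
        pp = float(p_less[parent.name])
        pc = float(p_less[child.name])
        if (1.0 - pp) > posterior_cutoff and pc > posterior_cutoff:
            return pc
        return -1.0

    for parent in tree.internals():
        ev = events.get(parent.name)
        if ev is None:
            raise ValueError(f"unclassified parent node {parent.name!r}")
        if ev == "S":
            cats = {c.name: "S" for c in parent.children}
        else:
            scores = {c.name: _retro_score(parent, c) for c in parent.children}
            best = max(scores, key=lambda n: scores[n])
            cats = {}
            for c in parent.children:
                cats[c.name] = ("R" if c.name == best and scores[best] > 0
                                else "D")
        for c in parent.children:
            ann = BranchAnnotation(category=cats[c.name])
            if chrom_post is not None:
                rowp = chrom_post.loc[parent.name]
                rowc = chrom_post.loc[c.name]
                if rowp.isna().any() or rowc.isna().any():
                    ann.missing_chromosome = True
                else:
                    ann.translocation = (rowp.idxmax() != rowc.idxmax())
            out[c.name] = ann
    return out
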