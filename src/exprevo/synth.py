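"""Truth-known synthetic data generators.

Three generators mirror the structure of the real inputs the pipeline
consumes:

* gene families evolving along a dated species tree by a branch-wise
  Gillespie process of duplication, loss and retrotransposition (a
  duplication whose new copy loses all introns and relocates);
* six-organ expression evolving on the gene tree under a multivariate
  Ornstein-Uhlenbeck process with regime shifts planted per branch
  category, the shifted organ drawn from a propensity matrix indexed by
  the current primary-expressed organ (PEO);
* per-sample expression tables with project-level batch effects,
  library-size scaling for the FPKM variant, and planted anomalous
  projects whose organ labels are permuted.

Everything is reproducible bit-exactly from the seeds carried in the
parameter objects.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._trees import Node, Tree, parse_newick, to_newick

ORGANS = ("brain", "heart", "kidney", "liver", "ovary", "testis")
CHROMOSOMES = ("A", "X", "Y")

__all__ = [
    "ORGANS", "CHROMOSOMES", "SpeciesTreeSpec", "FamilySimParams",
    "ExprSimParams", "SampleSimParams", "TruthRecord",
    "simulate_gene_family", "simulate_ou_expression", "simulate_samples",
    "simulate_omega", "subst_branch_lengths", "branch_category",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class SpeciesTreeSpec:
    """Dated, ultrametric species tree (ages in MY)."""
    newick_dated: str
    ages: dict[str, float]
    n_species: int

    def tree(self) -> Tree:
        t = parse_newick(self.newick_dated)
        t.set_ages_from_lengths()
        for node in t.preorder():
            if node.name in self.ages:
                node.age = self.ages[node.name]
        return t

    @classmethod
    def random(cls, n_species: int = 8, root_age: float = 400.0,
               seed: int = 0) -> "SpeciesTreeSpec":
        """Random ultrametric topology with child ages uniform in
        (0.35, 0.85) of the parent age."""
        rng = np.random.default_rng(seed)
        names = [f"sp{i + 1:02d}" for i in range(n_species)]

        def _build(tips: list[str], age: float) -> Node:
            if len(tips) == 1:
                n = Node(tips[0])
                n.age = 0.0
                return n
            cut = int(rng.integers(1, len(tips)))
            node = Node(None)
            node.age = age
            for part in (tips[:cut], tips[cut:]):
                child_age = 0.0 if len(part) == 1 else age * rng.uniform(0.35, 0.85)
                node.add_child(_build(part, child_age))
            return node

        root = _build(names, root_age)
        tree = Tree(root)
        tree.label_internals(prefix="s", overwrite=True)
        tree.set_lengths_from_ages()
        ages = {n.name: float(n.age) for n in tree.preorder()}
        return cls(newick_dated=to_newick(tree), ages=ages, n_species=n_species)


@dataclass
class FamilySimParams:
    dup_rate: float = 0.0        # events / gene lineage / MY
    loss_rate: float = 0.0
    retro_rate: float = 0.0
    seed: int = 0
    initial_introns: int = 8
    initial_chromosome: str = "A"

    def __post_init__(self):
        if min(self.dup_rate, self.loss_rate, self.retro_rate) < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class ExprSimParams:
    alpha_k: np.ndarray = field(default_factory=lambda: np.full(6, 0.05))
    sigma2_k: np.ndarray = field(default_factory=lambda: np.full(6, 0.3))
    theta0_k: np.ndarray = field(default_factory=lambda: np.array(
        [4.0, 3.0, 3.0, 3.0, 2.0, 2.0]))
    shift_prob: dict = field(default_factory=lambda: {"S": 0.02, "D": 0.09,
                                                      "R": 0.30})
    shift_size_sd: float = 4.0   # log2 units
    propensity: np.ndarray = field(default_factory=lambda: np.full((6, 6), 1 / 6))
    seed: int = 0
    root_stationary: bool = True

    def __post_init__(self):
        self.alpha_k = np.asarray(self.alpha_k, dtype=float)
        self.sigma2_k = np.asarray(self.sigma2_k, dtype=float)
        self.theta0_k = np.asarray(self.theta0_k, dtype=float)
        self.propensity = np.asarray(self.propensity, dtype=float)
        if np.any(self.alpha_k <= 0) or np.any(self.sigma2_k <= 0):
            raise ValueError("alpha_k and sigma2_k must be positive")
        if not np.allclose(self.propensity.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("propensity rows must sum to 1")
        if any(not 0 <= v <= 1 for v in self.shift_prob.values()):
            raise ValueError("shift probabilities must lie in [0, 1]")


@dataclass
class SampleSimParams:
    projects_per_organ: int = 3
    samples_per_project: int = 2
    project_effect_sd: float = 0.5   # log2 units
    noise_sd: float = 0.25           # log2 units
    libsize_lognormal_sd: float = 0.3
    n_anomalous_projects: int = 0
    seed: int = 0

    def __post_init__(self):
        if min(self.projects_per_organ, self.samples_per_project,
               self.n_anomalous_projects) < 0:
            raise ValueError("counts must be >= 0")


@dataclass
class TruthRecord:
    """Ground truth emitted alongside every synthetic object."""
    true_shift_branches: set = field(default_factory=set)
    true_deltas: dict = field(default_factory=dict)       # branch -> 6-vector
    true_events: dict = field(default_factory=dict)       # node -> S|D|R
    true_ages: dict = field(default_factory=dict)         # node -> MY
    true_anomalous_projects: set = field(default_factory=set)
    true_omega: dict = field(default_factory=dict)        # branch -> ratio
    extinct: bool = False
    extra: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def _conv(v):
            if isinstance(v, (set, frozenset)):
                return sorted(v)
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, dict):
                return {k: _conv(x) for k, x in v.items()}
            return v
        payload = {k: _conv(v) for k, v in dataclasses.asdict(self).items()}
        return json.dumps(payload, sort_keys=True)


# ---------------------------------------------------------------------------
# gene family simulation (branch-wise Gillespie along the species tree)
# ---------------------------------------------------------------------------

def branch_category(node: Node) -> Optional[str]:
    """Category of the branch above `node` from its parent's event.

    A retrotransposition node spawns one 'R' branch (the intronless,
    relocated copy) while its sister keeps category 'D'.
    """
    parent = node.parent
    if parent is None or parent.event is None:
        return None
    if parent.event == "R":
        return "R" if node.extra.get("retrocopy") else "D"
    return parent.event


def simulate_gene_family(species: SpeciesTreeSpec, params: FamilySimParams
                         ) -> tuple[Optional[Tree], TruthRecord]:
    """Evolve one gene family along the dated species tree.

    Returns ``(None, truth)`` with ``truth.extinct`` set when every copy
    is lost before the present.
    """
    rng = np.random.default_rng(params.seed)
    sp_tree = species.tree()
    total_rate = params.dup_rate + params.loss_rate + params.retro_rate

    def _evolve(sp_node: Node, age: float, introns: int, chrom: str
                ) -> Optional[Node]:
        """One gene lineage from `age` down the species branch into
        `sp_node`, then through its subtree."""
        t_end = sp_node.age
        while True:
            wait = rng.exponential(1.0 / total_rate) if total_rate > 0 else math.inf
            if age - wait <= t_end:
                break
            age -= wait
            u = rng.random() * total_rate
            if u < params.loss_rate:
                return None
            is_retro = u >= params.loss_rate + params.dup_rate
            node = Node(None)
            node.age = age
            node.event = "R" if is_retro else "D"
            if is_retro:
                new_chrom = CHROMOSOMES[int(rng.integers(len(CHROMOSOMES)))]
                c_new = _evolve(sp_node, age, 0, new_chrom)
            else:
                c_new = _evolve(sp_node, age, introns, chrom)
            c_old = _evolve(sp_node, age, introns, chrom)
            if is_retro and c_new is not None:
                c_new.extra["retrocopy"] = 1
            kids = [c for c in (c_old, c_new) if c is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]
            for c in kids:
                node.add_child(c)
            return node
        # arrived at the species node
        if sp_node.is_leaf:
            tip = Node(None)
            tip.age = 0.0
            tip.species = sp_node.name
            tip.extra["introns"] = introns
            tip.extra["chromosome"] = chrom
            return tip
        node = Node(None)
        node.age = sp_node.age
        node.event = "S"
        for sp_child in sp_node.children:
            c = _evolve(sp_child, sp_node.age, introns, chrom)
            if c is not None:
                node.add_child(c)
        if not node.children:
            return None
        if len(node.children) == 1:
            return node.children[0]
        return node

    root_age = sp_tree.root.age
    root = _evolve(sp_tree.root, root_age, params.initial_introns,
                   params.initial_chromosome)

    truth = TruthRecord()
    if root is None:
        truth.extinct = True
        return None, truth

    gene_tree = Tree(root)
    gene_tree.root.parent = None
    # name tips per species, then canonical internal labels
    per_species: dict[str, int] = {}
    for leaf in gene_tree.leaves():
        per_species[leaf.species] = per_species.get(leaf.species, 0) + 1
        leaf.name = f"{leaf.species}_g{per_species[leaf.species]}"
    gene_tree.label_internals(prefix="n", overwrite=True)
    gene_tree.set_lengths_from_ages()

    for node in gene_tree.preorder():
        truth.true_ages[node.name] = float(node.age)
        if node.event:
            truth.true_events[node.name] = node.event
    truth.extra["branch_categories"] = {
        n.name: branch_category(n) for n in gene_tree.edges()
        if branch_category(n) is not None}
    return gene_tree, truth


def subst_branch_lengths(tree: Tree, rate_mean: float = 1e-3,
                         rate_log_sd: float = 0.0, seed: int = 0) -> Tree:
    """Copy of a dated tree with branch lengths in substitutions/site:
    duration x per-branch lognormal rate (strict clock when log-sd 0)."""
    rng = np.random.default_rng(seed)
    out = tree.copy()
    for node in out.preorder():
        if node.parent is None:
            continue
        rate = rate_mean * math.exp(rng.normal(0.0, rate_log_sd)
                                    - 0.5 * rate_log_sd ** 2)
        node.length = (node.parent.age - node.age) * rate
    for node in out.preorder():
        node.age = None
    return out


# ---------------------------------------------------------------------------
# OU expression simulation
# ---------------------------------------------------------------------------

def _ou_step(x: np.ndarray, theta: np.ndarray, alpha: np.ndarray,
             sigma2: np.ndarray, t: float, rng) -> np.ndarray:
    """Exact OU transition over duration t, per organ."""
    decay = np.exp(-alpha * t)
    mean = theta + (x - theta) * decay
    var = np.where(alpha * t > 1e-10,
                   sigma2 * (-np.expm1(-2.0 * alpha * t)) / (2.0 * alpha),
                   sigma2 * t)
    return mean + rng.standard_normal(x.shape) * np.sqrt(var)


def simulate_ou_expression(tree: Tree, params: ExprSimParams
                           ) -> tuple[pd.DataFrame, TruthRecord]:
    """Six-organ log2 expression at the tips of a dated gene tree.

    Regime shifts are planted at branch starts with the per-category
    probabilities in `params.shift_prob`; the targeted organ is drawn
    from the propensity row of the regime's current PEO, receives a
    positive optimum jump of about `shift_size_sd`, and the remaining
    organs receive small N(0, (shift_size_sd/4)^2) perturbations so the
    shift is joint across organs.
    """
    if not tree.is_ultrametric(tol=1e-6):
        raise ValueError("OU simulation requires an ultrametric, dated tree")
    rng = np.random.default_rng(params.seed)
    alpha, sigma2 = params.alpha_k, params.sigma2_k
    gamma = sigma2 / (2.0 * alpha)
    truth = TruthRecord()

    theta_root = params.theta0_k.copy()
    if params.root_stationary:
        x_root = theta_root + rng.standard_normal(6) * np.sqrt(gamma)
    else:
        x_root = theta_root.copy()

    states: dict[int, np.ndarray] = {id(tree.root): x_root}
    optima: dict[int, np.ndarray] = {id(tree.root): theta_root}
    rows = {}
    for node in tree.preorder():
        if node.parent is None:
            continue
        theta = optima[id(node.parent)]
        cat = branch_category(node)
        p_shift = params.shift_prob.get(cat, 0.0) if cat else 0.0
        if p_shift > 0 and rng.random() < p_shift:
            peo = int(np.argmax(theta))
            target = int(rng.choice(6, p=params.propensity[peo]))
            delta = rng.normal(0.0, params.shift_size_sd / 4.0, size=6)
            delta[target] += abs(rng.normal(params.shift_size_sd,
                                            params.shift_size_sd / 4.0))
            theta = theta + delta
            truth.true_shift_branches.add(node.name)
            truth.true_deltas[node.name] = delta
        optima[id(node)] = theta
        duration = node.parent.age - node.age
        states[id(node)] = _ou_step(states[id(node.parent)], theta,
                                    alpha, sigma2, duration, rng)
        if node.is_leaf:
            rows[node.name] = states[id(node)]
        if node.event:
            truth.true_events[node.name] = node.event
        truth.true_ages[node.name] = float(node.age)
    traits = pd.DataFrame.from_dict(rows, orient="index", columns=list(ORGANS))
    traits = traits.loc[tree.leaf_names()]
    truth.extra["optima"] = {n.name: optima[id(n)] for n in tree.preorder()}
    return traits, truth


def simulate_omega(tree: Tree, shift_branches: set, seed: int = 0,
                   base: float = 0.12,
                   category_mult: Optional[dict] = None,
                   shift_mult: float = 1.5, log_sd: float = 0.4
                   ) -> dict[str, float]:
    """Per-branch dN/dS drawn lognormally around a category- and
    shift-dependent median (duplication/retro branches evolve faster,
    shifted branches faster still)."""
    rng = np.random.default_rng(seed)
    mult = category_mult or {"S": 1.0, "D": 2.2, "R": 2.6}
    out = {}
    for node in tree.edges():
        cat = branch_category(node) or "S"
        med = base * mult.get(cat, 1.0)
        if node.name in shift_branches:
            med *= shift_mult
        out[node.name] = float(med * math.exp(rng.normal(0.0, log_sd)))
    return out


# ---------------------------------------------------------------------------
# per-sample expression tables
# ---------------------------------------------------------------------------

def _unlog(x: np.ndarray) -> np.ndarray:
    return np.maximum(np.exp2(x) - 1.0, 0.0)


def simulate_samples(truth_means: pd.DataFrame, params: SampleSimParams,
                     species: str = "sp01"
                     ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, TruthRecord]:
    """Per-sample TPM and FPKM tables for one species.

    `truth_means` is genes x organs on the log2 scale.  Each project
    spans all six organs with `samples_per_project` samples per organ; a
    project contributes one N(0, project_effect_sd) offset per gene to
    all of its samples.  Anomalous projects keep their measured values
    but have their organ labels cyclically permuted in the metadata.
    """
    rng = np.random.default_rng(params.seed)
    genes = list(truth_means.index)
    organs = [o for o in ORGANS if o in truth_means.columns]
    n_proj = params.projects_per_organ
    if params.n_anomalous_projects > n_proj:
        raise ValueError("more anomalous projects than projects")
    projects = [f"PRJ{species}{i + 1:03d}" for i in range(n_proj)]
    anomalous = set(projects[:params.n_anomalous_projects])

    shifted = {organs[i]: organs[(i + 1) % len(organs)]
               for i in range(len(organs))}
    proj_effect = {p: rng.normal(0.0, params.project_effect_sd, len(genes))
                   for p in projects}

    cols_tpm, cols_fpkm, meta_rows = {}, {}, []
    for proj in projects:
        for organ in organs:
            for i in range(params.samples_per_project):
                sid = f"{species}.{proj}.{organ}.{i + 1}"
                logval = (truth_means[organ].to_numpy()
                          + proj_effect[proj]
                          + rng.normal(0.0, params.noise_sd, len(genes)))
                tpm = _unlog(logval)
                lib = math.exp(rng.normal(0.0, params.libsize_lognormal_sd))
                cols_tpm[sid] = tpm
                cols_fpkm[sid] = tpm * lib
                label = shifted[organ] if proj in anomalous else organ
                meta_rows.append({"sample_id": sid, "project_id": proj,
                                  "species": species, "organ": label})
    tpm_df = pd.DataFrame(cols_tpm, index=genes)
    fpkm_df = pd.DataFrame(cols_fpkm, index=genes)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    truth = TruthRecord(true_anomalous_projects=anomalous)
    truth.extra["organ_truth_means"] = truth_means
    return {"TPM": tpm_df, "FPKM": fpkm_df}, meta, truth
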