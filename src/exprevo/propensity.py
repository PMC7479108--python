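"""Per-shift expression metrics and downstream statistics.

For every consistently detected regime shift the module records the
ancestral and derived organ profiles (unlogged fitted optima), the
organ-specificity index tau, the expression complementarity TEC against
the sister lineage, the primary-expressed organ (PEO) before and after
the shift, and the branch and sister dN/dS.  Downstream statistics
cover per-category shift frequencies and per-MY rates, stationary
variance comparisons, 6x6 PEO transition matrices with
margin-preserving permutation nulls, bootstrap global polarity, and
omega-ratio comparisons and regressions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synth import ORGANS

__all__ = [
    "StatsConfig", "TransitionMatrix", "tau", "tec", "unlog",
    "build_shift_records", "shift_rates", "stationary_variance_compare",
    "transition_matrix", "permutation_enrichment", "polarity",
    "omega_analysis", "robustness_subsets",
]


@dataclass
class StatsConfig:
    n_perm: int = 10_000
    n_boot: int = 1_000
    seed: int = 0
    undiff_band: float = 0.05
    alpha_level: float = 0.05
    bh_adjust: bool = False

    def __post_init__(self):
        if self.n_perm < 1 or self.n_boot < 1:
            raise ValueError("n_perm and n_boot must be >= 1")


@dataclass
class TransitionMatrix:
    counts: pd.DataFrame        # 6x6, ancestral rows -> derived columns
    category: str = "all"

    def __post_init__(self):
        if not np.allclose(np.diag(self.counts.to_numpy()), 0):
            raise ValueError("diagonal must be zero (PEO-changing shifts only)")

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def unlog(x: np.ndarray) -> np.ndarray:
    """Inverse of the log2(x+1) transform, clamped at zero."""
    return np.maximum(np.exp2(np.asarray(x, dtype=float)) - 1.0, 0.0)


def tau(mu_unlogged: Sequence[float]) -> float:
    """Organ specificity: 0 uniform, 1 single-organ.

    tau = sum_i (1 - x_i / max) / (n - 1)."""
    x = np.asarray(mu_unlogged, dtype=float)
    if (x < 0).any():
        raise ValueError("tau needs nonnegative values")
    m = x.max()
    if m <= 0:
        raise ValueError("tau undefined for the all-zero vector")
    return float(np.sum(1.0 - x / m) / (len(x) - 1))


def tec(mu_a_unlogged: Sequence[float], mu_b_unlogged: Sequence[float]
        ) -> float:
    """Expression complementarity: 0 identical patterns, 1 mutually
    exclusive.  1 - sum_i min(p_i, q_i) on sum-normalised vectors."""
    a = np.asarray(mu_a_unlogged, dtype=float)
    b = np.asarray(mu_b_unlogged, dtype=float)
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("TEC undefined for zero-sum vectors")
    p, q = a / a.sum(), b / b.sum()
    return float(np.clip(1.0 - np.minimum(p, q).sum(), 0.0, 1.0))


def _peo(mu_unlogged: np.ndarray) -> Optional[str]:
    """Primary-expressed organ; None when the maximum is tied."""
    x = np.asarray(mu_unlogged, dtype=float)
    m = x.max()
    winners = np.nonzero(np.isclose(x, m, rtol=0, atol=1e-12))[0]
    if len(winners) != 1:
        return None
    return ORGANS[int(winners[0])]


# ---------------------------------------------------------------------------
# shift records
# ---------------------------------------------------------------------------

def build_shift_records(families: dict, omegas: Optional[pd.DataFrame] = None
                        ) -> pd.DataFrame:
    """One row per consistent regime shift.

    `families` maps family_id -> dict with keys:
      model        RegimeModel (fitted optima per node, log2 scale)
      tree         dated Tree the model was fitted on
      shifts       consensus shift branch ids (defaults to model's)
      categories   branch -> S|D|R
      support      optional branch -> bootstrap support
    `omegas` is an optional frame indexed by (family_id, branch) with an
    `omega` column.  Root-branch shifts (no parent regime) are skipped
    and counted in the `skipped_root` attribute of the result.
    """
    rows = []
    skipped_root = 0
    for fam, d in sorted(families.items()):
        model = d["model"]
        tree = d["tree"]
        shifts = d.get("shifts", model.shift_branches)
        cats = d.get("categories", {})
        supp = d.get("support", {})
        node_by_name = {n.name: n for n in tree.preorder()}
        shifted = set(shifts)
        for br in sorted(shifts):
            node = node_by_name[br]
            if node.parent is None:
                skipped_root += 1
                continue
            mu_anc_log = model.optima[node.parent.name]
            mu_der_log = model.optima[node.name]
            mu_anc, mu_der = unlog(mu_anc_log), unlog(mu_der_log)
            if mu_anc.max() <= 0 or mu_der.max() <= 0:
                continue
            sisters = [c for c in node.parent.children if c is not node]
            sister = sisters[0] if sisters else None
            sister_shifted = any(c.name in shifted for c in sisters)
            mu_sis = (unlog(model.optima[sister.name])
                      if sister is not None else mu_anc)
            rec = {
                "family_id": fam, "branch_id": br,
                "category": cats.get(br, "S"),
                "tau_anc": tau(mu_anc), "tau_der": tau(mu_der),
                "mu_max_anc": float(np.max(mu_anc_log)),
                "mu_max_der": float(np.max(mu_der_log)),
                "tec": tec(mu_der, mu_sis) if mu_sis.max() > 0 else np.nan,
                "peo_anc": _peo(mu_anc), "peo_der": _peo(mu_der),
                "sister_shifted": sister_shifted,
                "bootstrap_support": supp.get(br, np.nan),
            }
            rec["d_tau"] = rec["tau_der"] - rec["tau_anc"]
            rec["d_mu_max"] = rec["mu_max_der"] - rec["mu_max_anc"]
            if omegas is not None:
                try:
                    rec["omega_shift"] = float(omegas.loc[(fam, br), "omega"])
                except KeyError:
                    rec["omega_shift"] = np.nan
                if sister is not None:
                    try:
                        rec["omega_sister"] = float(
                            omegas.loc[(fam, sister.name), "omega"])
                    except KeyError:
                        rec["omega_sister"] = np.nan
                else:
                    rec["omega_sister"] = np.nan
            rec["peo_switch"] = (rec["peo_anc"] is not None
                                 and rec["peo_der"] is not None
                                 and rec["peo_anc"] != rec["peo_der"])
            rows.append(rec)
    out = pd.DataFrame(rows)
    out.attrs["skipped_root"] = skipped_root
    return out


# ---------------------------------------------------------------------------
# frequencies, rates, gamma comparisons
# ---------------------------------------------------------------------------

def shift_rates(records: pd.DataFrame, census: pd.DataFrame) -> pd.DataFrame:
    """Per-category shift frequency (per branch) and rate (per MY).

    `census` has one row per classified branch with columns `category`
    and `duration` (MY).  A chi-square test of shift/non-shift x
    category is attached via `.attrs`."""
    cats = sorted(census["category"].unique())
    n_shift = (records.groupby("category").size() if len(records)
               else pd.Series(dtype=int))
    rows = {}
    table = []
    for c in cats:
        nb = int((census["category"] == c).sum())
        dur = float(census.loc[census["category"] == c, "duration"].sum())
        ns = int(n_shift.get(c, 0))
        rows[c] = {"branches": nb, "shifts": ns,
                   "frequency": ns / nb if nb else np.nan,
                   "total_my": dur, "rate_per_my": ns / dur if dur > 0 else np.nan}
        table.append([ns, max(nb - ns, 0)])
    out = pd.DataFrame(rows).T
    if len(table) >= 2 and all(sum(r) > 0 for r in table):
        arr = np.array(table)
        if (arr.sum(axis=0) > 0).all():
            chi2, p, dof, _ = stats.chi2_contingency(arr)
            out.attrs["chi2"] = float(chi2)
            out.attrs["chi2_p"] = float(p)
            out.attrs["chi2_dof"] = int(dof)
    return out


def brunner_munzel(x: Sequence[float], y: Sequence[float],
                   min_n: int = 10, n_perm: int = 2000, seed: int = 0
                   ) -> dict:
    """Two-sided Brunner-Munzel test; exact-permutation fallback below
    `min_n` per side (flagged)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if min(len(x), len(y)) >= min_n:
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.brunnermunzel(x, y, alternative="two-sided")
        # relative effect P(X<Y)+0.5P(X=Y)
        ranks = stats.rankdata(np.concatenate([x, y]))
        p_hat = (ranks[len(x):].mean() - (len(y) + 1) / 2) / len(x)
        if np.isfinite(res.statistic) and np.isfinite(res.pvalue):
            return {"statistic": float(res.statistic),
                    "p": float(res.pvalue),
                    "relative_effect": float(p_hat), "fallback": False}
        # complete separation degenerates the t approximation
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    p_hat = (ranks[len(x):].mean() - (len(y) + 1) / 2) / len(x)
    obs = abs(p_hat - 0.5)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        r = stats.rankdata(perm)
        ph = (r[len(x):].mean() - (len(y) + 1) / 2) / len(x)
        hits += abs(ph - 0.5) >= obs - 1e-12
    return {"statistic": float(p_hat), "p": (hits + 1) / (n_perm + 1),
            "relative_effect": float(p_hat), "fallback": True}


def stationary_variance_compare(models: Sequence, organs=ORGANS,
                                reproductive=("ovary", "testis")) -> dict:
    """Tree-wise stationary variances gamma = sigma^2/(2 alpha);
    reproductive organs vs the rest, Brunner-Munzel."""
    if len(models) < 2:
        raise ValueError("need >= 2 fitted trees")
    gam = pd.DataFrame([{o: m.organ_params[o].gamma for o in organs}
                        for m in models])
    rep = gam[list(reproductive)].to_numpy().ravel()
    oth = gam[[o for o in organs if o not in reproductive]].to_numpy().ravel()
    test = brunner_munzel(oth, rep)
    return {"gamma": gam, "test": test,
            "median_reproductive": float(np.median(rep)),
            "median_other": float(np.median(oth))}


# ---------------------------------------------------------------------------
# PEO transition matrices
# ---------------------------------------------------------------------------

def transition_matrix(records: pd.DataFrame, category: str = "all"
                      ) -> TransitionMatrix:
    """Counts of PEO-switching shifts, ancestral organ -> derived organ."""
    sel = records[records["peo_switch"] == True]  # noqa: E712
    if category != "all":
        sel = sel[sel["category"] == category]
    counts = pd.DataFrame(0, index=list(ORGANS), columns=list(ORGANS))
    for _, r in sel.iterrows():
        counts.loc[r["peo_anc"], r["peo_der"]] += 1
    return TransitionMatrix(counts, category)


def compare_matrices(matrices: dict[str, TransitionMatrix]) -> dict:
    """Spearman correlations between off-diagonal count vectors of
    category pairs, plus a chi-square homogeneity test."""
    mask = ~np.eye(6, dtype=bool)
    flat = {k: m.counts.to_numpy()[mask] for k, m in matrices.items()}
    keys = sorted(flat)
    spearman = {}
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            rho, p = stats.spearmanr(flat[a], flat[b])
            spearman[(a, b)] = {"rho": float(rho), "p": float(p)}
    out = {"spearman": spearman}
    stack = np.array([flat[k] for k in keys])
    keep = stack.sum(axis=0) > 0
    if keep.sum() >= 2 and (stack.sum(axis=1) > 0).all():
        chi2, p, dof, _ = stats.chi2_contingency(stack[:, keep])
        out["chi2"] = {"chi2": float(chi2), "p": float(p), "dof": int(dof)}
    return out


def _null_transition_counts(matrix: TransitionMatrix, n_perm: int,
                            seed: int) -> np.ndarray:
    """Null per-cell counts (n_perm x 36) from shuffling the derived-PEO
    multiset against the fixed ancestral labels; identity pairings fall
    on diagonal cells, which downstream analyses ignore."""
    counts = matrix.counts.to_numpy()
    anc_idx, der_idx = [], []
    for i in range(6):
        for j in range(6):
            anc_idx += [i] * counts[i, j]
            der_idx += [j] * counts[i, j]
    anc = np.asarray(anc_idx)
    der = np.asarray(der_idx)
    if len(np.unique(anc)) < 2 or len(np.unique(der)) < 2:
        raise ValueError("degenerate margins; p-values undefined")
    rng = np.random.default_rng(seed)
    n = len(anc)
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    der_shuf = der[order]                        # n_perm x n
    cell = anc[None, :] * 6 + der_shuf
    flat = (np.arange(n_perm)[:, None] * 36 + cell).ravel()
    return np.bincount(flat, minlength=n_perm * 36).reshape(n_perm, 36)


def permutation_enrichment(matrix: TransitionMatrix,
                           config: Optional[StatsConfig] = None
                           ) -> pd.DataFrame:
    """Per-cell two-sided enrichment p-values under a null that shuffles
    the derived-PEO multiset against the ancestral labels (margins
    preserved); identity pairings in a draw are dropped from the null
    matrix.  p = 2 min(P(null>=obs), P(null<=obs)) with the +1
    correction, capped at 1; optional BH adjustment across the 30
    off-diagonal cells."""
    cfg = config or StatsConfig()
    if matrix.total < 1:
        raise ValueError("empty transition matrix")
    null = _null_transition_counts(matrix, cfg.n_perm, cfg.seed)
    obs = matrix.counts.to_numpy().ravel()
    n_perm = cfg.n_perm
    p = np.ones(36)
    for c in range(36):
        i, j = divmod(c, 6)
        if i == j:
            p[c] = np.nan
            continue
        ge = int(np.sum(null[:, c] >= obs[c]))
        le = int(np.sum(null[:, c] <= obs[c]))
        p[c] = min(2.0 * min(ge + 1, le + 1) / (n_perm + 1), 1.0)
    P = pd.DataFrame(p.reshape(6, 6), index=list(ORGANS),
                     columns=list(ORGANS))
    if cfg.bh_adjust:
        mask = ~np.eye(6, dtype=bool)
        vals = P.to_numpy()[mask]
        adj = _bh(vals)
        out = P.to_numpy().copy()
        out[mask] = adj
        P = pd.DataFrame(out, index=list(ORGANS), columns=list(ORGANS))
    return P


def _bh(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj


# ---------------------------------------------------------------------------
# global polarity
# ---------------------------------------------------------------------------

def polarity_value(counts: np.ndarray) -> float:
    """Scaled sum of differences between opposite PEO shifts:
    sum_{i<j} |N_ij - N_ji| / sum_{i != j} N_ij, in [0, 1]."""
    c = np.asarray(counts, dtype=float)
    total = c.sum() - np.trace(c)
    if total <= 0:
        raise ValueError("empty matrix: polarity undefined")
    num = 0.0
    for i in range(c.shape[0]):
        for j in range(i + 1, c.shape[0]):
            num += abs(c[i, j] - c[j, i])
    return float(num / total)


def polarity(matrix: TransitionMatrix, records: Optional[pd.DataFrame] = None,
             config: Optional[StatsConfig] = None) -> dict:
    """Observed polarity plus a bootstrap distribution obtained by
    resampling individual PEO-switching shift records."""
    cfg = config or StatsConfig()
    value = polarity_value(matrix.counts.to_numpy())
    boot = None
    if records is not None:
        sel = records[records["peo_switch"] == True]  # noqa: E712
        if matrix.category != "all":
            sel = sel[sel["category"] == matrix.category]
        anc = sel["peo_anc"].map({o: i for i, o in enumerate(ORGANS)}).to_numpy()
        der = sel["peo_der"].map({o: i for i, o in enumerate(ORGANS)}).to_numpy()
        rng = np.random.default_rng(cfg.seed)
        n = len(anc)
        boot = np.empty(cfg.n_boot)
        for b in range(cfg.n_boot):
            pick = rng.integers(0, n, n)
            c = np.zeros((6, 6))
            np.add.at(c, (anc[pick], der[pick]), 1)
            boot[b] = polarity_value(c)
    return {"polarity": value, "bootstrap": boot}


def polarity_compare(boot_a: np.ndarray, boot_b: np.ndarray) -> dict:
    """Two-sided Kolmogorov-Smirnov comparison of bootstrap polarity
    distributions of two branch categories."""
    D, p = stats.ks_2samp(boot_a, boot_b, alternative="two-sided")
    return {"D": float(D), "p": float(p)}


# ---------------------------------------------------------------------------
# omega analysis
# ---------------------------------------------------------------------------

def _regress(x: np.ndarray, y: np.ndarray) -> dict:
    if len(x) < 3:
        return {"n": int(len(x)), "slope": np.nan, "p": np.nan,
                "insufficient": True}
    res = stats.linregress(x, y)
    return {"n": int(len(x)), "slope": float(res.slope),
            "intercept": float(res.intercept), "p": float(res.pvalue),
            "insufficient": False}


def omega_analysis(records: pd.DataFrame,
                   config: Optional[StatsConfig] = None) -> dict:
    """dN/dS of shifted (+) vs sister (-) branches.

    Pairs with missing or nonpositive omega, or with a shifted sister,
    are excluded (counted).  Reports per-category Brunner-Munzel tests,
    the higher/undifferentiated/lower split of the omega ratio (the
    band applies to the raw ratio), and regressions of log2(w+/w-) on
    d_tau, d_mu_max (split by sign) and TEC."""
    cfg = config or StatsConfig()
    need = {"omega_shift", "omega_sister"}
    if not need <= set(records.columns):
        raise ValueError("records lack omega columns")
    ok = records[(records["omega_shift"] > 0)
                 & (records["omega_sister"] > 0)
                 & (~records["sister_shifted"])].copy()
    excluded = len(records) - len(ok)
    ok["log2_ratio"] = np.log2(ok["omega_shift"] / ok["omega_sister"])
    ratio = ok["omega_shift"] / ok["omega_sister"]
    cls = pd.Series(np.where(np.abs(ratio - 1.0) <= cfg.undiff_band,
                             "undifferentiated",
                             np.where(ratio > 1, "higher", "lower")),
                    index=ok.index)
    out = {"excluded_pairs": int(excluded),
           "classification": cls.value_counts().to_dict(),
           "classification_fraction":
               (cls.value_counts(normalize=True).to_dict() if len(cls) else {}),
           "bm_tests": {}, "regressions": {}}
    for cat, grp in ok.groupby("category"):
        out["bm_tests"][cat] = brunner_munzel(grp["omega_sister"],
                                              grp["omega_shift"])
    for cat, grp in ok.groupby("category"):
        reg = {}
        for var in ("d_tau", "d_mu_max"):
            for sign, sel in (("neg", grp[grp[var] < 0]),
                              ("pos", grp[grp[var] > 0])):
                reg[f"{var}_{sign}"] = _regress(sel[var].to_numpy(),
                                                sel["log2_ratio"].to_numpy())
        tt = grp.dropna(subset=["tec"])
        reg["tec"] = _regress(tt["tec"].to_numpy(),
                              tt["log2_ratio"].to_numpy())
        out["regressions"][cat] = reg
    return out


# ---------------------------------------------------------------------------
# robustness subsets
# ---------------------------------------------------------------------------

def robustness_subsets(records: pd.DataFrame, filters: dict,
                       config: Optional[StatsConfig] = None) -> dict:
    """Rerun the transition/permutation/polarity analyses on filtered
    subsets (e.g. tau > 0.5 or bootstrap support > 0.99) and report
    concordance of significant cells with the full analysis."""
    cfg = config or StatsConfig()
    sel = records
    if "min_tau" in filters:
        sel = sel[sel["tau_der"] > filters["min_tau"]]
    if "min_support" in filters:
        sel = sel[sel["bootstrap_support"] > filters["min_support"]]
    out = {"n_records": int(len(sel))}
    if sel.empty or not sel["peo_switch"].any():
        out["skipped"] = True
        return out
    out["skipped"] = False
    full_m = transition_matrix(records)
    sub_m = transition_matrix(sel)
    out["matrix"] = sub_m
    try:
        p_full = permutation_enrichment(full_m, cfg)
        p_sub = permutation_enrichment(sub_m, cfg)
        mask = ~np.eye(6, dtype=bool)
        sig_full = (p_full.to_numpy() < cfg.alpha_level) & mask
        sig_sub = (p_sub.to_numpy() < cfg.alpha_level) & mask
        denom = max(sig_full.sum(), 1)
        out["significant_full"] = int(sig_full.sum())
        out["significant_subset"] = int(sig_sub.sum())
        out["concordance"] = float((sig_full & sig_sub).sum() / denom)
        out["p_values"] = p_sub
    except ValueError as exc:
        out["enrichment_error"] = str(exc)
    out["polarity"] = polarity(sub_m, sel, cfg)["polarity"]
    return out
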