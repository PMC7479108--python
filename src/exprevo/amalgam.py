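"""Normalisation, curation and batch correction of heterogeneous
per-sample expression tables into per-species organ means.

The stages run in the order: TMM scaling of FPKM on single-copy
orthologs -> log2(x+1) -> iterative removal of anomalous projects by
leave-own-project-out organ correlations -> surrogate-variable style
batch correction with the organ design protected -> organ-wise means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .synth import ORGANS

__all__ = [
    "ExpressionTable", "CurationReport", "SvaModel",
    "tmm_factors", "apply_tmm", "log_transform", "iterative_removal",
    "sva_correct", "organ_means", "subsample_convergence",
]

_UNLOGGED = {"TPM", "FPKM", "TMM-FPKM"}


@dataclass
class ExpressionTable:
    """Genes x samples matrix with a metric tag updated by every transform."""
    values: pd.DataFrame
    metric: str = "TPM"

    def __post_init__(self):
        if self.values.isna().any().any():
            raise ValueError("expression table contains missing values")
        if self.metric in _UNLOGGED and (self.values.to_numpy() < 0).any():
            raise ValueError("unlogged expression values must be >= 0")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, keep: Iterable[str]) -> "ExpressionTable":
        keep = [s for s in self.samples if s in set(keep)]
        return ExpressionTable(self.values[keep], self.metric)


@dataclass
class CurationReport:
    iterations: list = field(default_factory=list)  # (project, [violators])
    kept_samples: set = field(default_factory=set)
    removed_projects: list = field(default_factory=list)
    skipped: bool = False
    reason: str = ""
    status: str = "ok"
    flags: list = field(default_factory=list)


@dataclass
class SvaModel:
    n_sv: int
    sv_matrix: np.ndarray          # samples x n_sv
    protected_design: np.ndarray   # samples x organs


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

def tmm_factors(fpkm: ExpressionTable | pd.DataFrame,
                single_copy_ids: Sequence[str],
                m_trim: float = 0.30, a_trim: float = 0.05,
                min_genes: int = 20) -> pd.Series:
    """Per-sample scaling factor from the weighted trimmed mean of
    M-values computed on the single-copy ortholog subset.

    The reference sample is the column whose 75th percentile is closest
    to the mean 75th percentile.  M values are trimmed by `m_trim` and A
    values by `a_trim` on each side; weights are the inverse asymptotic
    (delta-method) variance of M.  Factors are normalised to geometric
    mean 1; dividing a sample's values by its factor removes its
    composition/depth bias.
    """
    df = fpkm.values if isinstance(fpkm, ExpressionTable) else fpkm
    missing = set(single_copy_ids) - set(df.index)
    if missing:
        raise KeyError(f"single-copy ids absent from table: {sorted(missing)[:5]}")
    if df.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    sub = df.loc[list(single_copy_ids)]
    usable = (sub > 0).sum(axis=0)
    if int(usable.min()) < min_genes:
        raise ValueError(
            f"fewer than {min_genes} usable single-copy genes in some sample")

    q75 = sub.quantile(0.75)
    ref_col = (q75 - q75.mean()).abs().idxmin()
    ref = sub[ref_col].to_numpy(dtype=float)

    logf = {}
    for col in sub.columns:
        x = sub[col].to_numpy(dtype=float)
        ok = (x > 0) & (ref > 0)
        if ok.sum() < min_genes:
            raise ValueError(
                f"fewer than {min_genes} usable single-copy genes in {col}")
        xr, rr = x[ok], ref[ok]
        m = np.log2(xr / rr)
        a = 0.5 * np.log2(xr * rr)
        # delta-method weights treating values as Poisson intensities
        w = 1.0 / (1.0 / xr + 1.0 / rr)
        lo_m, hi_m = np.quantile(m, [m_trim, 1.0 - m_trim])
        lo_a, hi_a = np.quantile(a, [a_trim, 1.0 - a_trim])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not keep.any():
            keep = np.ones_like(m, dtype=bool)
        logf[col] = float(np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    fac = pd.Series(logf)
    fac -= fac.mean()           # geometric mean of 2**fac becomes 1
    return np.exp2(fac).reindex(df.columns)


def apply_tmm(fpkm: ExpressionTable, factors: pd.Series) -> ExpressionTable:
    out = fpkm.values.div(factors, axis=1)
    return ExpressionTable(out, "TMM-FPKM")


# ---------------------------------------------------------------------------
# log transform
# ---------------------------------------------------------------------------

def log_transform(table: ExpressionTable) -> ExpressionTable:
    """Elementwise log2(x + 1)."""
    if table.metric not in _UNLOGGED:
        raise ValueError(f"metric {table.metric!r} is already logged")
    if (table.values.to_numpy() < 0).any():
        raise ValueError("negative values cannot be log-transformed")
    return ExpressionTable(np.log2(table.values + 1.0), f"log-{table.metric}")


# ---------------------------------------------------------------------------
# iterative anomalous-project removal
# ---------------------------------------------------------------------------

def _violations(values: pd.DataFrame, meta: pd.DataFrame) -> list[str]:
    """Samples whose correlation to their own organ's leave-own-project-out
    mean is not strictly greater than to every other organ's."""
    organs = sorted(meta["organ"].unique())
    arr = values.to_numpy(dtype=float)
    cols = list(values.columns)
    col_idx = {c: i for i, c in enumerate(cols)}
    bad: list[str] = []
    for sid in cols:
        own_organ = meta.loc[sid, "organ"]
        own_project = meta.loc[sid, "project_id"]
        x = arr[:, col_idx[sid]]
        corr: dict[str, float] = {}
        for organ in organs:
            sel = meta.index[(meta["organ"] == organ)
                             & (meta["project_id"] != own_project)]
            sel = [s for s in sel if s in col_idx]
            if not sel:  # project is this organ's only source: leave-self-out
                sel = [s for s in meta.index[meta["organ"] == organ]
                       if s in col_idx and s != sid]
            if not sel:
                continue
            mean = arr[:, [col_idx[s] for s in sel]].mean(axis=1)
            with np.errstate(invalid="ignore"):
                r = np.corrcoef(x, mean)[0, 1]
            corr[organ] = -1.0 if np.isnan(r) else float(r)
        if own_organ not in corr:
            continue
        others = [v for o, v in corr.items() if o != own_organ]
        if others and corr[own_organ] <= max(others):
            bad.append(sid)
    return bad


def iterative_removal(table: ExpressionTable, meta: pd.DataFrame
                      ) -> CurationReport:
    """Repeatedly score samples against leave-own-project-out organ means
    and drop the worst-offending project until no violations remain.

    Per iteration exactly one project is removed: the one with the most
    violating samples (ties: higher violating fraction, then smaller
    project id).  Requires >= 2 projects; otherwise the curation is
    skipped and everything kept.
    """
    meta = meta.loc[[s for s in table.samples if s in meta.index]]
    report = CurationReport(kept_samples=set(table.samples))
    if meta["project_id"].nunique() < 2:
        report.skipped = True
        report.reason = "fewer than 2 projects; curation skipped"
        return report

    current = table.values
    cur_meta = meta
    while True:
        bad = _violations(current, cur_meta)
        if not bad:
            break
        counts = cur_meta.loc[bad, "project_id"].value_counts()
        sizes = cur_meta["project_id"].value_counts()
        best = sorted(counts.index,
                      key=lambda p: (-counts[p], -counts[p] / sizes[p], p))[0]
        victims = [s for s in bad if cur_meta.loc[s, "project_id"] == best]
        report.iterations.append((best, victims))
        report.removed_projects.append(best)
        keep = cur_meta.index[cur_meta["project_id"] != best]
        cur_meta = cur_meta.loc[keep]
        current = current[list(keep)]
        if cur_meta.empty:
            report.status = "warning"
            report.flags.append("all projects removed")
            break
    report.kept_samples = set(cur_meta.index)
    return report


# ---------------------------------------------------------------------------
# surrogate-variable correction (two-pass residual PCA, permutation-selected)
# ---------------------------------------------------------------------------

def _organ_design(meta: pd.DataFrame, samples: Sequence[str]) -> np.ndarray:
    organs = sorted(meta.loc[list(samples), "organ"].unique())
    d = np.zeros((len(samples), len(organs)))
    for i, s in enumerate(samples):
        d[i, organs.index(meta.loc[s, "organ"])] = 1.0
    return d


def sva_correct(table: ExpressionTable, meta: pd.DataFrame,
                n_perm: int = 20, alpha_level: float = 0.05,
                seed: int = 0, max_sv: Optional[int] = None
                ) -> tuple[ExpressionTable, SvaModel]:
    """Estimate hidden sample covariates from organ-model residuals and
    regress them out while protecting organ effects.

    The number of surrogate variables is chosen by permutation parallel
    analysis: residual singular values are kept while they exceed the
    (1 - alpha_level) quantile of singular values of row-permuted
    residuals (`n_perm` permutations).  Surrogates are the leading right
    singular vectors; removal fits genes on [organ design | SVs] jointly
    and subtracts only the SV contribution.
    """
    rng = np.random.default_rng(seed)
    samples = table.samples
    Y = table.values.to_numpy(dtype=float)           # genes x samples
    D = _organ_design(meta, samples)
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("organ design is rank deficient")
    hat = D @ np.linalg.pinv(D)
    R = Y - Y @ hat.T                                # residuals, genes x samples
    rank = min(R.shape) - D.shape[1]
    if max_sv is None:
        max_sv = max(rank, 0)

    # permutation parallel analysis on variance fractions: permuting each
    # gene's residuals across samples destroys shared structure while
    # preserving per-gene variance; compare the fraction of variance on
    # each leading direction, not raw singular values (raw values are
    # inflated in the observed matrix because residualisation confines
    # its variance to a rank-(n-k) subspace)
    sv = np.linalg.svd(R, compute_uv=False)
    frac = sv ** 2 / max(np.sum(sv ** 2), 1e-300)
    null = np.empty((n_perm, len(sv)))
    for p in range(n_perm):
        perm = np.empty_like(R)
        for g in range(R.shape[0]):
            perm[g] = R[g, rng.permutation(R.shape[1])]
        perm = perm - perm @ hat.T
        s = np.linalg.svd(perm, compute_uv=False)
        null[p] = s ** 2 / max(np.sum(s ** 2), 1e-300)
    thresh = np.quantile(null, 1.0 - alpha_level, axis=0)
    n_sv = 0
    for k in range(min(len(sv), max_sv)):
        if frac[k] > thresh[k]:
            n_sv += 1
        else:
            break

    if n_sv == 0:
        model = SvaModel(0, np.zeros((len(samples), 0)), D)
        return ExpressionTable(table.values.copy(), f"SVA-{table.metric}"), model

    _, _, vt = np.linalg.svd(R, full_matrices=False)
    SV = vt[:n_sv].T                                  # samples x n_sv
    # orthonormalise for the model contract
    SV, _ = np.linalg.qr(SV)
    X = np.hstack([D, SV])
    B = Y @ np.linalg.pinv(X).T                       # genes x (organs+n_sv)
    corrected = Y - B[:, D.shape[1]:] @ SV.T
    out = pd.DataFrame(corrected, index=table.genes, columns=samples)
    return (ExpressionTable(out, f"SVA-{table.metric}"),
            SvaModel(n_sv, SV, D))


# ---------------------------------------------------------------------------
# organ means and subsampling
# ---------------------------------------------------------------------------

def organ_means(table: ExpressionTable, meta: pd.DataFrame
                ) -> tuple[pd.DataFrame, list[str]]:
    """Arithmetic per-organ means of log-scale values for one species.

    Returns (genes x organs frame restricted to observed organs,
    list of missing organs)."""
    meta = meta.loc[[s for s in table.samples if s in meta.index]]
    cols = {}
    for organ in ORGANS:
        sel = meta.index[meta["organ"] == organ]
        if len(sel):
            cols[organ] = table.values[list(sel)].mean(axis=1)
    missing = [o for o in ORGANS if o not in cols]
    return pd.DataFrame(cols, index=table.genes), missing


def subsample_convergence(table: ExpressionTable, meta: pd.DataFrame,
                          gene: str, organ: str, k_range: Sequence[int],
                          max_subsets: int = 200, seed: int = 0
                          ) -> dict[int, np.ndarray]:
    """Distribution of the organ mean of `gene` over k-project subsets,
    for each k in `k_range` (k larger than the project count is skipped)."""
    from itertools import combinations
    rng = np.random.default_rng(seed)
    meta = meta.loc[[s for s in table.samples if s in meta.index]]
    sel = meta[meta["organ"] == organ]
    projects = sorted(sel["project_id"].unique())
    row = table.values.loc[gene]
    out: dict[int, np.ndarray] = {}
    for k in k_range:
        if k < 1 or k > len(projects):
            continue
        from math import comb
        if comb(len(projects), k) <= max_subsets:
            subsets = list(combinations(projects, k))
        else:
            subsets = [tuple(rng.choice(projects, size=k, replace=False))
                       for _ in range(max_subsets)]
        vals = []
        for sub in subsets:
            samples = sel.index[sel["project_id"].isin(sub)]
            vals.append(float(row[list(samples)].mean()))
        out[k] = np.asarray(vals)
    return out
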