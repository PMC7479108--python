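"""End-to-end orchestration on synthetic or file-based inputs.

The demo pipeline wires the stages in analysis order: simulate (or
load) -> amalgamate per species -> (optionally re-)date gene trees ->
detect OU regime shifts per expression metric -> consensus -> annotate
branches -> propensity statistics.  Failures are isolated per family;
a rerun with the same config and seed reproduces every output
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import os
import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import amalgam, annotate, oushifts, propensity, synth, treetime
from ._trees import Tree, parse_newick, to_newick

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline",
           "validate_inputs", "stage_seed"]


def stage_seed(global_seed: int, stage: str, item: str = "") -> int:
    """Deterministic per-stage, per-family seed below 2**31."""
    return zlib.crc32(f"{global_seed}:{stage}:{item}".encode()) & 0x7FFFFFFF


@dataclass
class PipelineConfig:
    outdir: str = "exprevo_run"
    seed: int = 0
    n_families: int = 40
    n_species: int = 12
    root_age: float = 400.0
    dup_rate: float = 0.002
    loss_rate: float = 0.001
    retro_rate: float = 0.0005
    shift_prob: dict = field(default_factory=lambda: {"S": 0.02, "D": 0.09,
                                                      "R": 0.30})
    shift_size_sd: float = 4.0
    propensity: Optional[list] = None
    projects_per_organ: int = 3
    samples_per_project: int = 2
    project_effect_sd: float = 0.4
    noise_sd: float = 0.25
    n_anomalous_projects: int = 0
    metrics: tuple = ("TPM", "FPKM")
    redate: bool = False
    n_perm: int = 2000
    n_boot: int = 500
    n_lambda: int = 30

    @classmethod
    def from_json(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunManifest:
    seed: int = 0
    stages: list = field(default_factory=list)
    families: dict = field(default_factory=dict)   # id -> status dict
    outputs: list = field(default_factory=list)

    @property
    def counts(self) -> dict:
        c = {"ok": 0, "skipped": 0, "error": 0}
        for d in self.families.values():
            c[d["status"]] += 1
        return c

    def to_json(self) -> str:
        return json.dumps({"seed": self.seed, "stages": self.stages,
                           "families": self.families,
                           "counts": self.counts,
                           "outputs": self.outputs}, sort_keys=True, indent=1)


def _gene_id(fam: str, tip: str) -> str:
    """Tip labels repeat across families; gene ids must not."""
    return f"{fam}:{tip}"


def _organ_truth_tables(fam_data: dict) -> dict[str, pd.DataFrame]:
    """Per-species genes x organs truth means pooled across families."""
    per_species: dict[str, dict[str, np.ndarray]] = {}
    for fam, d in fam_data.items():
        species_of = {l.name: l.species for l in d["tree"].leaves()}
        for tip, row in d["traits"].iterrows():
            sp = species_of[tip]
            per_species.setdefault(sp, {})[_gene_id(fam, tip)] = row.to_numpy()
    return {sp: pd.DataFrame.from_dict(genes, orient="index",
                                       columns=list(synth.ORGANS)).sort_index()
            for sp, genes in per_species.items()}


def run_pipeline(config: PipelineConfig) -> RunManifest:
    cfg = config
    manifest = RunManifest(seed=cfg.seed)
    os.makedirs(cfg.outdir, exist_ok=True)

    # ---- stage 1: synthetic families -----------------------------------
    sp_spec = synth.SpeciesTreeSpec.random(cfg.n_species, cfg.root_age,
                                           seed=stage_seed(cfg.seed, "sptree"))
    fam_data: dict[str, dict] = {}
    for i in range(cfg.n_families):
        fam = f"fam{i + 1:04d}"
        fp = synth.FamilySimParams(cfg.dup_rate, cfg.loss_rate, cfg.retro_rate,
                                   seed=stage_seed(cfg.seed, "family", fam))
        tree, truth = synth.simulate_gene_family(sp_spec, fp)
        if tree is None or len(tree.leaves()) < 4:
            manifest.families[fam] = {"status": "skipped",
                                      "reason": "extinct or <4 tips"}
            continue
        prop = (np.asarray(cfg.propensity, dtype=float)
                if cfg.propensity is not None else np.full((6, 6), 1 / 6))
        ep = synth.ExprSimParams(shift_prob=cfg.shift_prob,
                                 shift_size_sd=cfg.shift_size_sd,
                                 propensity=prop,
                                 seed=stage_seed(cfg.seed, "expr", fam))
        traits, etruth = synth.simulate_ou_expression(tree, ep)
        fam_data[fam] = {"tree": tree, "traits": traits, "truth": truth,
                         "expr_truth": etruth}
        manifest.families[fam] = {"status": "ok"}
    manifest.stages.append("simulate")

    # ---- stage 2: amalgamation per species ------------------------------
    sample_params = synth.SampleSimParams(
        projects_per_organ=cfg.projects_per_organ,
        samples_per_project=cfg.samples_per_project,
        project_effect_sd=cfg.project_effect_sd, noise_sd=cfg.noise_sd,
        n_anomalous_projects=cfg.n_anomalous_projects)
    truth_tables = _organ_truth_tables(fam_data)
    organ_mean_tables: dict[str, dict[str, pd.DataFrame]] = {m: {}
                                                             for m in cfg.metrics}
    single_copy: dict[str, list[str]] = {}
    for fam, d in fam_data.items():
        by_sp: dict[str, list[str]] = {}
        for leaf in d["tree"].leaves():
            by_sp.setdefault(leaf.species, []).append(leaf.name)
        if all(len(v) == 1 for v in by_sp.values()):
            for sp, names in by_sp.items():
                single_copy.setdefault(sp, []).append(_gene_id(fam, names[0]))

    for sp, truth_means in sorted(truth_tables.items()):
        sp_params = dataclasses.replace(
            sample_params, seed=stage_seed(cfg.seed, "samples", sp))
        tables, meta, struth = synth.simulate_samples(truth_means, sp_params,
                                                      species=sp)
        sc = single_copy.get(sp, [])
        if len(sc) < 20:
            sc = list(truth_means.index)
        for metric in cfg.metrics:
            tab = amalgam.ExpressionTable(tables[metric], metric)
            if metric == "FPKM":
                min_genes = min(20, max(2, len(sc) // 2))
                factors = amalgam.tmm_factors(tab, sc, min_genes=min_genes)
                tab = amalgam.apply_tmm(tab, factors)
            tab = amalgam.log_transform(tab)
            report = amalgam.iterative_removal(tab, meta)
            tab = tab.subset_samples(report.kept_samples)
            kept_meta = meta.loc[sorted(report.kept_samples)]
            if not tab.samples:
                continue
            tab, _ = amalgam.sva_correct(tab, kept_meta,
                                         seed=stage_seed(cfg.seed, "sva", sp))
            means, _missing = amalgam.organ_means(tab, kept_meta)
            organ_mean_tables[metric][sp] = means
    manifest.stages.append("amalgam")

    # ---- stage 3: dating (optional re-estimation) ------------------------
    sp_tree = sp_spec.tree()
    if cfg.redate:
        for fam, d in list(fam_data.items()):
            try:
                subst = synth.subst_branch_lengths(
                    d["tree"], rate_log_sd=0.0,
                    seed=stage_seed(cfg.seed, "subst", fam))
                events = treetime.classify_species_overlap(subst, sp_tree)
                tc = treetime.build_constraints(subst, sp_tree, events)
                dated, _rep = treetime.date_tree(subst, tc)
                d["tree"] = dated
            except Exception as exc:  # isolate failures per family
                manifest.families[fam] = {"status": "error",
                                          "reason": f"dating: {exc}"}
                del fam_data[fam]
        manifest.stages.append("date")

    # ---- stage 4: shift detection per metric + consensus -----------------
    results: dict[str, dict] = {}
    for fam, d in sorted(fam_data.items()):
        try:
            tree = d["tree"]
            models = {}
            for metric in cfg.metrics:
                rows = {}
                skip = False
                for leaf in tree.leaves():
                    tab = organ_mean_tables[metric].get(leaf.species)
                    gid = _gene_id(fam, leaf.name)
                    if tab is None or gid not in tab.index \
                            or len(tab.columns) < 6:
                        skip = True
                        break
                    rows[leaf.name] = tab.loc[gid, list(synth.ORGANS)]
                if skip:
                    raise RuntimeError(f"missing organ means for {metric}")
                traits = pd.DataFrame(rows).T
                traits.columns = list(synth.ORGANS)
                scfg = oushifts.ShiftSearchConfig(
                    n_lambda=cfg.n_lambda,
                    seed=stage_seed(cfg.seed, "shifts", fam))
                sk = oushifts.skim_tree(tree, traits)
                if len(sk.tree.leaves()) < 4:
                    raise RuntimeError("tree skimmed below 4 tips")
                models[metric] = oushifts.detect_shifts(sk.tree, sk.values,
                                                        scfg)
            if len(cfg.metrics) == 2:
                shifts, venn = oushifts.consensus(models[cfg.metrics[0]],
                                                  models[cfg.metrics[1]])
            else:
                shifts = models[cfg.metrics[0]].shift_branches
                venn = {}
            results[fam] = {"model": models[cfg.metrics[0]], "tree": tree,
                            "shifts": shifts, "venn": venn}
            manifest.families[fam]["venn"] = venn
        except Exception as exc:
            manifest.families[fam] = {"status": "error", "reason": str(exc)}
    manifest.stages.append("shifts")

    # ---- stage 5: annotation --------------------------------------------
    for fam, r in sorted(results.items()):
        tree = r["tree"]
        events = {n.name: n.event or "S" for n in tree.internals()}
        introns = {l.name: l.extra.get("introns") for l in tree.leaves()}
        chroms = {l.name: l.extra.get("chromosome") for l in tree.leaves()}
        ipost = annotate.ancestral_binary(tree, introns)
        cpost = annotate.ancestral_discrete(tree, chroms,
                                            annotate.chromosome_model())
        anns = annotate.classify_branches(tree, events, ipost, cpost)
        r["categories"] = {b: a.category for b, a in anns.items()}
        r["omega"] = synth.simulate_omega(
            tree, set(fam_data[fam]["expr_truth"].true_shift_branches),
            seed=stage_seed(cfg.seed, "omega", fam))
    manifest.stages.append("annotate")

    # ---- stage 6: propensity statistics ----------------------------------
    omega_rows = []
    for fam, r in results.items():
        for br, w in r["omega"].items():
            omega_rows.append({"family_id": fam, "branch": br, "omega": w})
    omegas = (pd.DataFrame(omega_rows).set_index(["family_id", "branch"])
              if omega_rows else None)
    records = propensity.build_shift_records(
        {fam: r for fam, r in results.items()}, omegas)
    census_rows = []
    for fam, r in results.items():
        for node in r["tree"].edges():
            census_rows.append({
                "family_id": fam, "branch_id": node.name,
                "category": r["categories"].get(node.name, "S"),
                "duration": node.parent.age - node.age})
    census = pd.DataFrame(census_rows)
    stats_cfg = propensity.StatsConfig(n_perm=cfg.n_perm, n_boot=cfg.n_boot,
                                       seed=stage_seed(cfg.seed, "stats"))
    report: dict = {"n_records": int(len(records))}
    if len(records):
        rates = propensity.shift_rates(records, census)
        report["rates"] = json.loads(rates.to_json())
        report["rates_chi2"] = {k: rates.attrs[k] for k in rates.attrs}
        if records["peo_switch"].any():
            tm = propensity.transition_matrix(records)
            report["transition_total"] = tm.total
            try:
                pvals = propensity.permutation_enrichment(tm, stats_cfg)
                report["enrichment_min_p"] = float(np.nanmin(pvals.to_numpy()))
            except ValueError as exc:
                report["enrichment_error"] = str(exc)
            pol = propensity.polarity(tm, records, stats_cfg)
            report["polarity"] = pol["polarity"]
        if "omega_shift" in records.columns:
            try:
                report["omega"] = _plain(propensity.omega_analysis(
                    records, stats_cfg))
            except ValueError:
                pass
    manifest.stages.append("stats")

    # ---- outputs ----------------------------------------------------------
    rec_path = os.path.join(cfg.outdir, "shift_records.tsv")
    if len(records):
        records.to_csv(rec_path, sep="\t", index=False, float_format="%.10g")
        manifest.outputs.append(os.path.basename(rec_path))
    stats_path = os.path.join(cfg.outdir, "statistics.json")
    with open(stats_path, "w") as fh:
        json.dump(_plain(report), fh, sort_keys=True, indent=1, default=_plain)
    manifest.outputs.append(os.path.basename(stats_path))
    trees_path = os.path.join(cfg.outdir, "gene_trees.nwk")
    with open(trees_path, "w") as fh:
        for fam, d in sorted(fam_data.items()):
            fh.write(to_newick(d["tree"], annotations=True) + "\n")
    manifest.outputs.append(os.path.basename(trees_path))
    man_path = os.path.join(cfg.outdir, "manifest.json")
    with open(man_path, "w") as fh:
        fh.write(manifest.to_json())
    manifest.outputs.append(os.path.basename(man_path))
    return manifest


def _plain(obj):
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (pd.DataFrame, pd.Series)):
        return json.loads(obj.to_json())
    return obj


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------

def validate_inputs(paths: dict) -> list[str]:
    """Schema/consistency checks; returns a list of issues (report-only)."""
    issues: list[str] = []
    sp_tree = None
    if "species_tree" in paths:
        try:
            sp_tree = parse_newick(open(paths["species_tree"]).read())
            sp_tree.set_ages_from_lengths()
            if not sp_tree.is_ultrametric(tol=1e-6):
                issues.append("species tree is not ultrametric")
        except Exception as exc:
            issues.append(f"species tree unreadable: {exc}")
    if "gene_tree" in paths:
        try:
            gt = parse_newick(open(paths["gene_tree"]).read())
            species = None
            if "tip_map" in paths:
                tm = pd.read_csv(paths["tip_map"], sep="\t")
                if not {"tip", "species"} <= set(tm.columns):
                    issues.append("tip map needs columns: tip, species")
                else:
                    species = dict(zip(tm["tip"], tm["species"]))
            if species is not None:
                for leaf in gt.leaves():
                    if leaf.name not in species:
                        issues.append(f"tip without species map: {leaf.name}")
                    elif sp_tree is not None and species[leaf.name] not in \
                            set(sp_tree.leaf_names()):
                        issues.append(
                            f"species {species[leaf.name]} not in species tree")
        except Exception as exc:
            issues.append(f"gene tree unreadable: {exc}")
    if "expression" in paths:
        try:
            df = pd.read_csv(paths["expression"], sep="\t", index_col=0)
            if df.isna().any().any():
                issues.append("expression table has missing values")
        except Exception as exc:
            issues.append(f"expression table unreadable: {exc}")
    if "metadata" in paths:
        try:
            meta = pd.read_csv(paths["metadata"], sep="\t")
            need = {"sample_id", "project_id", "species", "organ"}
            if not need <= set(meta.columns):
                issues.append(f"metadata needs columns {sorted(need)}")
            elif not set(meta["organ"]) <= set(synth.ORGANS):
                issues.append("metadata contains organs outside the "
                              "six-organ vocabulary")
        except Exception as exc:
            issues.append(f"metadata unreadable: {exc}")
    return issues
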