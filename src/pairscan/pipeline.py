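"""End-to-end orchestration: simulate -> analyze -> report.

``run_pipeline`` executes every stage on synthetic data with planted ground
truth and writes tidy TSV reports plus a JSON summary into the output
directory. Each run emits a resolved-config snapshot and a provenance sidecar
(config + seed), and is byte-identical under a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import classify, differential, peptidome, structure, synthetic
from .config import ConfigError, SyntheticConfig, child_rng

__all__ = ["RunConfig", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)


def _strict(cls, data: dict, where: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where} config")
    return cls(**data)


@dataclass(frozen=True)
class PeptidomeOptions:
    ratio_mode: str = "fraction"
    len_lo: int = 8
    len_hi: int = 12
    agg_len_lo: int = 6
    agg_len_hi: int = 15
    n_tau_peptides: int = 300
    tau_ip_fraction: float = 0.90


@dataclass(frozen=True)
class DifferentialOptions:
    knn_k: int = 5
    max_missing_frac: float = 0.25
    fdr: float = 0.05


@dataclass(frozen=True)
class OverlapOptions:
    size_a: int = 403
    size_b: int = 91
    n_shared: int = 48


@dataclass(frozen=True)
class MotifOptions:
    n_elements: int = 3
    len_lo: int = 25
    len_hi: int = 35
    rsasa_thresh: float = 0.2
    min_exposed_frac: float = 0.4
    scope: str = "full"


@dataclass(frozen=True)
class ClassifierOptions:
    n_splits: int = 20
    train_frac: float = 0.7
    l1_strength: float = 1.0
    l2_strength: float = 1.0
    stratified: bool = False


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run: a global seed, an output directory, and one
    parameter block per stage (defaults mirror each module's defaults)."""

    seed: int = 0
    outdir: str = "results/pipeline"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    peptidome: PeptidomeOptions = field(default_factory=PeptidomeOptions)
    differential: DifferentialOptions = field(default_factory=DifferentialOptions)
    overlap: OverlapOptions = field(default_factory=OverlapOptions)
    motifs: MotifOptions = field(default_factory=MotifOptions)
    classifier: ClassifierOptions = field(default_factory=ClassifierOptions)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        blocks = {
            "synthetic": SyntheticConfig,
            "peptidome": PeptidomeOptions,
            "differential": DifferentialOptions,
            "overlap": OverlapOptions,
            "motifs": MotifOptions,
            "classifier": ClassifierOptions,
        }
        kwargs = {}
        for name, blk_cls in blocks.items():
            if name in data:
                block = data.pop(name)
                if not isinstance(block, dict):
                    raise ConfigError(f"{name} block must be a mapping")
                if name == "synthetic":
                    block = dict(block)
                    if "ss_transition" in block:
                        block["ss_transition"] = tuple(
                            tuple(row) for row in block["ss_transition"])
                kwargs[name] = _strict(blk_cls, block, name)
        unknown = set(data) - {"seed", "outdir"}
        if unknown:
            raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")
        kwargs.update({k: data[k] for k in ("seed", "outdir") if k in data})
        cfg = cls(**kwargs)
        if "seed" in data:
            cfg = dataclasses.replace(
                cfg, synthetic=cfg.synthetic.replace(seed=int(data["seed"])))
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"] = self.synthetic.to_dict()
        return d


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _dump_json(data: dict, path: Path) -> None:
    path.write_text(json.dumps(data, indent=2, sort_keys=True,
                               default=_json_default) + "\n")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, outdir: Path) -> dict:
    """Generate every synthetic input and write it as TSV + provenance."""
    sc = cfg.synthetic
    table = synthetic.gen_peptidome(sc)
    parent = synthetic.gen_parent_protein(sc.seed)
    tau_rng = child_rng(sc.seed, "tau_peptides")
    tau_seqs = synthetic.gen_substring_peptides(
        parent, cfg.peptidome.n_tau_peptides, cfg.peptidome.tau_ip_fraction,
        tau_rng)
    tau_inten = tau_rng.lognormal(sc.intensity_logmean, sc.intensity_logsd,
                                  size=(len(tau_seqs), len(table.design)))
    tau_rows = pd.DataFrame(
        [(s, 2, *tau_inten[i]) for i, s in enumerate(tau_seqs)],
        columns=["sequence", "charge", *table.design.index])
    full = peptidome.PeptideTable(
        data=pd.concat([table.data, tau_rows], ignore_index=True),
        design=table.design).validate()

    sim = synthetic.gen_intensity_matrix(sc)
    profiles, labels = synthetic.gen_structures(sc)
    emb = synthetic.gen_embeddings(profiles, sc, labels)
    list_a, list_b = synthetic.gen_id_lists(
        cfg.overlap.size_a, cfg.overlap.size_b, cfg.overlap.n_shared, sc.seed)

    peptidome.write_peptide_table(full, outdir / "peptides.tsv",
                                  outdir / "design.tsv")
    (outdir / "tau_parent.fasta").write_text(
        ">synthetic_tau_like_parent\n" + parent + "\n")
    differential.write_intensity_matrix(sim.matrix, outdir / "matrix.tsv",
                                        outdir / "conditions.tsv")
    sim.is_de.rename("is_de").to_csv(outdir / "truth_de.tsv", sep="\t",
                                     index_label="feature_id")
    structure.write_structure_profiles(profiles, outdir / "structures.tsv")
    classify.write_embeddings(emb, outdir / "embeddings.tsv")
    (outdir / "list_a.txt").write_text("\n".join(list_a) + "\n")
    (outdir / "list_b.txt").write_text("\n".join(list_b) + "\n")
    _dump_json({"config": cfg.to_dict(), "seed": sc.seed},
               outdir / "provenance.json")
    return {"peptide_table": full, "tau_parent": parent, "sim_matrix": sim,
            "profiles": profiles, "labels": labels, "embeddings": emb,
            "list_a": list_a, "list_b": list_b}


def stage_peptidome(cfg: RunConfig, art: dict, outdir: Path) -> dict:
    """Per-sample peptidome statistics and the factorial comparison."""
    po = cfg.peptidome
    table = peptidome.collapse_charge_states(art["peptide_table"])
    tau = peptidome.restrict_to_protein(table, art["tau_parent"])
    rows = []
    for sample in table.samples:
        rows.append({
            "sample_id": sample,
            "ip_fraction": peptidome.ip_fraction(table, sample,
                                                 mode=po.ratio_mode),
            "length_fraction": peptidome.length_fraction(
                table, sample, lo=po.len_lo, hi=po.len_hi),
            "aggregation_score": peptidome.aggregation_score(
                table, sample, len_lo=po.agg_len_lo, len_hi=po.agg_len_hi),
            "tau_ip_fraction": peptidome.ip_fraction(tau, sample,
                                                     mode=po.ratio_mode),
        })
    stats = pd.DataFrame(rows).set_index("sample_id")
    stats.to_csv(outdir / "peptidome_stats.tsv", sep="\t")
    anova_rows = []
    for stat_name in stats.columns:
        cmp = peptidome.compare_groups(stats[stat_name], table.design)
        a = cmp.anova.reset_index().rename(columns={"index": "term"})
        a.insert(0, "statistic", stat_name)
        anova_rows.append(a)
    pd.concat(anova_rows, ignore_index=True).to_csv(
        outdir / "peptidome_anova.tsv", sep="\t", index=False)
    return {"stats": stats}


def stage_differential(cfg: RunConfig, art: dict, outdir: Path) -> dict:
    """Prepare -> filter -> impute -> moderated fit, plus overlap accounting."""
    do = cfg.differential
    sim = art["sim_matrix"]
    prepared = differential.prepare_matrix(sim.matrix)
    filtered = differential.filter_missingness(prepared, do.max_missing_frac)
    imputed = differential.knn_impute(filtered, k=do.knn_k)
    conds = list(pd.unique(imputed.conditions))
    result = differential.moderated_fit(imputed, contrast=(conds[1], conds[0]))
    result.table.to_csv(outdir / "differential.tsv", sep="\t",
                        index_label="feature_id")
    truth = sim.is_de.reindex(result.table.index)
    called = result.table["q"] < do.fdr
    sens = float((called & truth).sum() / truth.sum()) if truth.sum() else np.nan
    fdp = float((called & ~truth).sum() / called.sum()) if called.sum() else 0.0
    ov = differential.overlap_counts(art["list_a"], art["list_b"])
    pd.DataFrame([{"only_a": ov.only_a, "only_b": ov.only_b,
                   "shared": ov.shared}]).to_csv(
        outdir / "overlap.tsv", sep="\t", index=False)
    return {"result": result, "sensitivity": sens, "fdp": fdp, "overlap": ov,
            "n_tested": int(len(result.table)), "n_called": int(called.sum())}


def stage_motifs(cfg: RunConfig, art: dict, model, outdir: Path) -> dict:
    """Segment, enumerate, exposure-filter, score, and contrast motifs."""
    mo = cfg.motifs
    candidates = []
    for profile in art["profiles"]:
        candidates.extend(structure.enumerate_composites(
            profile, n_elements=mo.n_elements, len_lo=mo.len_lo,
            len_hi=mo.len_hi))
    motifs = structure.exposure_filter(candidates, mo.rsasa_thresh,
                                       mo.min_exposed_frac)
    embedder = synthetic.make_motif_embedder(cfg.synthetic)
    scored = structure.score_motifs(motifs, embedder, model)
    report = pd.DataFrame([{
        "protein_id": m.protein_id, "start": m.start, "end": m.end,
        "states": "".join(m.states), "length": m.length,
        "exposed_frac": m.exposed_frac, "score": m.score,
    } for m in scored])
    report.to_csv(outdir / "motifs.tsv", sep="\t", index=False)
    contrast = structure.quartile_contrast(scored, scope=mo.scope)
    contrast.table.to_csv(outdir / "motif_contrast.tsv", sep="\t",
                          index_label="feature")
    return {"motifs": scored, "contrast": contrast,
            "n_candidates": len(candidates), "n_retained": len(motifs)}


def stage_classifier(cfg: RunConfig, art: dict, outdir: Path) -> dict:
    """Repeated-split evaluation plus the abundance-only baseline, and one
    model trained on the full item set for motif scoring."""
    co = cfg.classifier
    emb = art["embeddings"]
    plan = classify.make_splits(emb.ids, emb.labels, n_splits=co.n_splits,
                                train_frac=co.train_frac, seed=cfg.seed,
                                stratified=co.stratified)
    summary = classify.evaluate(emb, plan, l1_strength=co.l1_strength,
                                l2_strength=co.l2_strength)
    abundance_rng = child_rng(cfg.seed, "baseline_abundance")
    abundance = abundance_rng.normal(0.0, 1.0, size=len(emb))
    baseline = classify.baseline_single_feature(abundance, emb.labels, plan,
                                                l1_strength=co.l1_strength,
                                                l2_strength=co.l2_strength)
    pd.DataFrame({
        "split": np.arange(len(summary.aucs)),
        "auc_embedding": summary.aucs,
        "auc_baseline": baseline.aucs,
    }).to_csv(outdir / "classifier_aucs.tsv", sep="\t", index=False)
    model = classify.fit_pipeline(emb.X, emb.labels,
                                  l1_strength=co.l1_strength,
                                  l2_strength=co.l2_strength)
    return {"summary": summary, "baseline": baseline, "model": model}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage; returns the summary dict written to summary.json."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        art = stage_simulate(cfg, outdir)
        stage = "peptidome"
        pep = stage_peptidome(cfg, art, outdir)
        stage = "differential"
        diff = stage_differential(cfg, art, outdir)
        stage = "classifier"
        clf = stage_classifier(cfg, art, outdir)
        stage = "motifs"
        mot = stage_motifs(cfg, art, clf["model"], outdir)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    acidic = mot["contrast"].table.loc["acidic"]
    summary = {
        "seed": cfg.seed,
        "peptidome": {
            "mean_ip_fraction": float(pep["stats"]["ip_fraction"].mean()),
            "mean_tau_ip_fraction": float(
                pep["stats"]["tau_ip_fraction"].mean()),
            "mean_length_fraction": float(
                pep["stats"]["length_fraction"].mean()),
            "mean_aggregation_score": float(
                pep["stats"]["aggregation_score"].mean()),
        },
        "differential": {
            "n_tested": diff["n_tested"], "n_called": diff["n_called"],
            "sensitivity": diff["sensitivity"], "fdp": diff["fdp"],
            "prior_df": diff["result"].prior_df,
            "overlap": {"only_a": diff["overlap"].only_a,
                        "only_b": diff["overlap"].only_b,
                        "shared": diff["overlap"].shared},
        },
        "classifier": {
            "median_auc": clf["summary"].median,
            "p16_auc": clf["summary"].p16, "p84_auc": clf["summary"].p84,
            "baseline_median_auc": clf["baseline"].median,
        },
        "motifs": {
            "n_candidates": mot["n_candidates"],
            "n_retained": mot["n_retained"],
            "acidic_median_high": float(acidic["median_high"]),
            "acidic_median_low": float(acidic["median_low"]),
            "acidic_q": float(acidic["q"]),
        },
    }
    _dump_json(summary, outdir / "summary.json")
    return summary
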