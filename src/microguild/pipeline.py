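"""End-to-end orchestration: simulate/load -> rarefy -> diversity ->
guilds -> group comparisons -> Random-Forest association.

Every stochastic stage draws its seed deterministically from the master
seed plus the stage name, so stages can be re-run standalone and a full
run is reproducible byte-for-byte (the manifest's wall-clock timings are
the only non-deterministic output).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, diversity, guilds, stats
from .io import (
    FeatureTable,
    SampleFrame,
    read_feature_table,
    read_newick,
    read_sample_frame,
    write_feature_table,
    write_newick,
    write_sample_frame,
)
from .simulate import SimParams, default_params, generate_dataset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the master seed via a stable hash."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    """One object holding every pipeline parameter.

    Exactly one of ``table_path`` (with ``metadata_path``/``tree_path``)
    or ``simulate`` must be set.
    """

    table_path: str | None = None
    table_orientation: str = "samples"
    metadata_path: str | None = None
    tree_path: str | None = None
    simulate: SimParams | None = None

    rarefaction_depth: int = 17_000
    min_prevalence: float = 0.25
    prevalence_inclusive: bool = True
    pseudocount: float = guilds.DEFAULT_PSEUDOCOUNT
    guild_alpha: float = 0.001
    n_permutations: int = 9999
    min_leaves_to_test: int = 3
    test_alpha: float = 0.05
    dunn_adjust: str = "bonferroni"
    shannon_base: float = 2.0
    reference_group: str = "WT"
    train_timepoint: str | None = None  # default: first timepoint observed
    rf_params: association.RFParams = field(default_factory=association.RFParams)
    rfcv_step: float = 0.5
    seed: int = 0
    outdir: str = "microguild_run"

    def __post_init__(self) -> None:
        has_paths = self.table_path is not None
        has_sim = self.simulate is not None
        if has_paths == has_sim:
            raise ValueError(
                "exactly one of input paths or a simulate block is required"
            )
        if has_paths and self.metadata_path is None:
            raise ValueError("metadata_path is required with table_path")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulate", None)
        rf = d.pop("rf_params", None)
        cfg = {}
        if sim is not None:
            if isinstance(sim, dict):
                for key in ("mu_guild", "gamma", "delta"):
                    if key in sim:
                        sim[key] = np.asarray(sim[key], dtype=float)
                for key in ("members_per_guild", "causal_guilds", "causal_betas",
                            "group_weight_offsets", "timepoint_weight_offsets"):
                    if key in sim:
                        sim[key] = tuple(sim[key])
                sim = SimParams(**sim) if sim else default_params()
            cfg["simulate"] = sim
        if rf is not None:
            cfg["rf_params"] = (association.RFParams(**rf)
                                if isinstance(rf, dict) else rf)
        cfg.update(d)
        return cls(**cfg)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            sim = dataclasses.asdict(self.simulate)
            for key in ("mu_guild", "gamma", "delta"):
                sim[key] = np.asarray(sim[key]).tolist()
            d["simulate"] = sim
        return d


def _load_inputs(cfg: RunConfig, outdir: Path):
    if cfg.simulate is not None:
        params = dataclasses.replace(
            cfg.simulate, seed=stage_seed(cfg.seed, "simulate")
        )
        table, frame, tree, truth = generate_dataset(params)
        write_feature_table(table, outdir / "simulated_counts.tsv")
        write_sample_frame(frame, outdir / "simulated_metadata.tsv")
        write_newick(tree, outdir / "simulated_tree.nwk")
        truth_json = {
            "guild_of": {k: v for k, v in truth.guild_of.items()},
            "causal_guilds": list(truth.causal_guilds),
            "causal_betas": list(truth.causal_betas),
            "seed": truth.seed,
        }
        (outdir / "simulated_truth.json").write_text(
            json.dumps(truth_json, indent=1)
        )
        return table, frame, tree
    table = read_feature_table(cfg.table_path, orientation=cfg.table_orientation)
    frame = read_sample_frame(cfg.metadata_path)
    tree = read_newick(cfg.tree_path) if cfg.tree_path else None
    shared = [s for s in table.sample_ids if s in frame.sample_ids]
    if not shared:
        raise ValueError("no samples shared between table and metadata")
    table = table.filter_samples(shared)
    return table, frame, tree


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns the in-memory results bundle and writes
    every table to ``cfg.outdir``."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    decisions = {
        "prevalence_inclusive": cfg.prevalence_inclusive,
        "shannon_base": cfg.shannon_base,
        "unifrac_variant": "unnormalized",
        "correlation_transform": f"log10(relabund + {cfg.pseudocount})",
        "ward_variant": "ward.D2",
        "dunn_adjust": cfg.dunn_adjust,
        "rarefaction_seed": stage_seed(cfg.seed, "rarefy"),
    }
    bundle: dict = {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            timings[name] = round(time.perf_counter() - t0, 3)
        return deco

    @stage("inputs")
    def _():
        bundle["table"], bundle["frame"], bundle["tree"] = _load_inputs(cfg, outdir)

    frame: SampleFrame = bundle["frame"]

    @stage("rarefy")
    def _():
        bundle["rarefied"] = diversity.rarefy(
            bundle["table"], cfg.rarefaction_depth, stage_seed(cfg.seed, "rarefy")
        )

    rarefied: FeatureTable = bundle["rarefied"]
    sample_ids = rarefied.sample_ids

    @stage("diversity")
    def _():
        alpha = diversity.alpha_table(rarefied, base=cfg.shannon_base)
        alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t")
        bundle["alpha"] = alpha
        if bundle["tree"] is None:
            logger.info("no tree supplied; UniFrac/PCoA skipped")
            return
        dm = diversity.unifrac_matrix(bundle["tree"], rarefied)
        dm.to_data_frame().to_csv(outdir / "weighted_unifrac.tsv", sep="\t")
        bundle["unifrac"] = dm
        ord_ = diversity.pcoa(dm, k=min(3, len(sample_ids) - 1))
        coords = ord_.coordinates.copy()
        coords.to_csv(outdir / "pcoa_coordinates.tsv", sep="\t")
        pd.DataFrame({
            "axis": [f"PC{i+1}" for i in range(len(ord_.proportion_explained))],
            "eigenvalue": ord_.eigenvalues[: len(ord_.proportion_explained)],
            "proportion_explained": ord_.proportion_explained,
        }).to_csv(outdir / "pcoa_eigenvalues.tsv", sep="\t", index=False)
        bundle["pcoa"] = ord_
        groups = frame.groups(sample_ids)
        ref = [s for s in sample_ids if groups[s] == cfg.reference_group]
        if ref:
            rows = []
            for tp in pd.unique(frame.timepoints(sample_ids)):
                tp_ref = [s for s in ref if frame.timepoints([s]).iloc[0] == tp]
                if not tp_ref:
                    continue
                for s in sample_ids:
                    if frame.timepoints([s]).iloc[0] != tp:
                        continue
                    if groups[s] == cfg.reference_group:
                        continue
                    val = diversity.distances_to_group(dm, [s], tp_ref).iloc[0]
                    rows.append({"sample_id": s, "group": groups[s],
                                 "timepoint": tp, "distance_to_reference": val})
            dist_ref = pd.DataFrame(rows)
            dist_ref.to_csv(outdir / "distance_to_reference.tsv", sep="\t",
                            index=False)
            bundle["distance_to_reference"] = dist_ref

    @stage("guilds")
    def _():
        prevalent, coverage = guilds.prevalence_filter(
            rarefied, cfg.min_prevalence, inclusive=cfg.prevalence_inclusive
        )
        bundle["prevalent"] = prevalent
        bundle["coverage"] = coverage
        log_ab = guilds.log_relative_abundance(prevalent, cfg.pseudocount)
        subjects = frame.subjects(prevalent.sample_ids).to_numpy()
        dist, degenerate = guilds.correlation_distance_matrix(log_ab, subjects)
        dend = guilds.ward_linkage(dist)
        gm = guilds.split_guilds(
            dend, dist, alpha=cfg.guild_alpha, n_perm=cfg.n_permutations,
            seed=stage_seed(cfg.seed, "guilds"),
            min_leaves_to_test=cfg.min_leaves_to_test,
        )
        bundle["guild_map"] = gm
        gm.labels().to_csv(outdir / "guild_membership.tsv", sep="\t",
                           index_label="asv")
        gm.decision_log.to_csv(outdir / "guild_decision_log.tsv", sep="\t",
                               index=False)
        abund = guilds.guild_abundance(rarefied.relative_abundance(), gm)
        bundle["guild_abundance"] = abund
        abund.to_csv(outdir / "guild_abundance.tsv", sep="\t",
                     index_label="sample_id")
        (outdir / "guild_parameters.json").write_text(json.dumps({
            **gm.params,
            "min_prevalence": cfg.min_prevalence,
            "inclusive": cfg.prevalence_inclusive,
            "coverage": coverage,
            "n_degenerate_pairs": len(degenerate),
        }, indent=1))

    @stage("compare")
    def _():
        abund = bundle["guild_abundance"]
        groups = frame.groups(sample_ids)
        tps = frame.timepoints(sample_ids)
        rows = []
        for tp in pd.unique(tps):
            sel = [s for s in sample_ids if tps[s] == tp]
            for gcol in abund.columns:
                vals = abund.loc[sel, gcol].to_numpy()
                labs = groups[sel].to_numpy()
                h, p = stats.kruskal_wallis(vals, labs)
                pairs = stats.dunn_posthoc(vals, labs, adjust=cfg.dunn_adjust)
                letters = stats.compact_letters(pairs, alpha=cfg.test_alpha)
                row = {"timepoint": tp, "guild": gcol, "H": h, "p": p}
                for g, letter in letters.items():
                    row[f"letters_{g}"] = letter
                for _, pr in pairs.table.iterrows():
                    row[f"p_adj_{pr.group_a}_vs_{pr.group_b}"] = pr.p_adj
                rows.append(row)
        comp = pd.DataFrame(rows)
        comp.to_csv(outdir / "guild_comparisons.tsv", sep="\t", index=False)
        bundle["comparisons"] = comp

    @stage("associate")
    def _():
        abund = bundle["guild_abundance"]
        tps = frame.timepoints(sample_ids)
        weights = frame.body_weights(sample_ids)
        order = list(pd.unique(tps))
        train_tp = cfg.train_timepoint or order[0]
        seed = stage_seed(cfg.seed, "associate")
        train_ids = [s for s in sample_ids
                     if tps[s] == train_tp and pd.notna(weights[s])]
        if len(train_ids) < 5:
            logger.info("too few weighted samples at %s; association skipped",
                        train_tp)
            return
        X = abund.loc[train_ids]
        y = weights[train_ids]
        report = association.rfcv_select(
            X, y, step=cfg.rfcv_step, params=cfg.rf_params, seed=seed
        )
        bundle["rf_report"] = report
        report.cv_curve.rename_axis("n_predictors").to_csv(
            outdir / "rf_cv_curve.tsv", sep="\t")
        report.importances.rename_axis("guild").to_csv(
            outdir / "rf_importances.tsv", sep="\t")
        pd.DataFrame({
            "predicted": report.loo_predictions,
            "measured": y,
        }).to_csv(outdir / "rf_loo_predictions.tsv", sep="\t",
                  index_label="sample_id")
        validation = {
            "r": report.validation_r, "p": report.validation_p,
            "n": len(train_ids), "k_star": report.k_star,
            "selected": list(report.selected), "seed": seed,
            "n_trees": cfg.rf_params.n_trees,
            "max_features": cfg.rf_params.max_features,
            "no_signal": bool(report.no_signal),
        }
        # cross-timepoint prediction with the model trained at train_tp
        other = [t for t in order if t != train_tp]
        if other:
            test_tp = other[0]
            test_ids = [s for s in sample_ids
                        if tps[s] == test_tp and pd.notna(weights[s])]
            if len(test_ids) >= 3:
                model = association.fit_forest(X, y, params=cfg.rf_params,
                                               seed=seed)
                pred = association.predict_external(model, abund.loc[test_ids])
                r2, p2 = association.pearson_validation(
                    pred, weights[test_ids])
                pd.DataFrame({
                    "predicted": pred, "measured": weights[test_ids],
                }).to_csv(outdir / "rf_cross_timepoint_predictions.tsv",
                          sep="\t", index_label="sample_id")
                validation["cross_timepoint"] = {
                    "train": train_tp, "test": test_tp, "r": r2, "p": p2,
                    "n": len(test_ids),
                }
        (outdir / "rf_validation.json").write_text(
            json.dumps(validation, indent=1))
        bundle["rf_validation"] = validation

    manifest = {
        "config": cfg.to_dict(),
        "stage_seeds": {s: stage_seed(cfg.seed, s)
                        for s in ("simulate", "rarefy", "guilds", "associate")},
        "decisions": decisions,
        "n_samples": len(sample_ids),
        "n_features": rarefied.n_features,
        "n_prevalent": bundle["prevalent"].n_features,
        "coverage": bundle["coverage"],
        "n_guilds": bundle["guild_map"].n_guilds,
        "timings": timings,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    bundle["manifest"] = manifest
    return bundle
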