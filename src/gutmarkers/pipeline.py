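"""Configuration-driven end-to-end runner.

One :func:`run_pipeline` call executes the whole study on a conforming
dataset (synthetic or user-supplied): rarefaction, diversity profiling and
ordination, differential-abundance screens, marker discovery on the
discovery cohort, POD-model training, evaluation on held-out cohorts, and
marker-clinical correlation. Every stage writes plain TSV/JSON into the run
directory; a manifest records the effective config, seeds and input hashes.
All outputs are deterministic given the config (wall-clock timings go to a
separate ``run.log``, never into compared outputs).

Synthetic runs emulate the original study design: one main cohort split
stratified into discovery and validation, plus an independent cohort drawn
separately (optionally with a site effect) standing in for a second
geographic site.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinical import spearman_matrix
from .diffabund import lda_effect_size, wilcoxon_screen
from .diversity import alpha_diversity, bray_curtis, group_overlap, pcoa
from .markers import MarkerDiscoveryConfig, discover_markers
from .pod import evaluate_cohorts, pod_index, roc_auc, train_pod_model
from .simulate import SyntheticSpec, generate_cohort
from .tables import (
    OtuTable,
    SampleMetadata,
    read_metadata,
    read_otu_table,
    relative_abundance,
    rarefy,
    write_metadata,
    write_otu_table,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips losslessly through YAML/JSON."""

    # either a synthetic spec...
    synthetic: SyntheticSpec | None = None
    validation_fraction: float = 0.25
    independent_spec: SyntheticSpec | None = None
    site_effect_sd: float = 0.25
    # ...or explicit inputs (tables already split by the metadata cohort column)
    otu_table_path: str | None = None
    metadata_path: str | None = None

    rarefaction_depth: int | None = None  # None = minimum sample total
    diversity_on_rarefied: bool = True
    screen_alpha: float = 0.05
    kw_alpha: float = 0.05
    lda_threshold: float = 2.0
    n_trials: int = 5
    n_folds: int = 5
    n_trees: int = 500
    seed: int = 0
    out_dir: str = "run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("synthetic", "independent_spec"):
            if d.get(key) is not None and not isinstance(d[key], SyntheticSpec):
                d[key] = SyntheticSpec.from_dict(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        d = yaml.safe_load(text)
        return cls.from_dict(d)

    def to_file(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _split_cohorts(table: OtuTable, meta: SampleMetadata, fraction: float,
                   seed: int) -> tuple[list[str], list[str]]:
    """Stratified random split of sample ids into discovery/validation."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0]))
    groups = meta.groups_for(table.sample_ids)
    discovery, validation = [], []
    for g in sorted(set(groups)):
        ids = [s for s, gg in zip(table.sample_ids, groups) if gg == g]
        n_val = int(round(len(ids) * fraction))
        order = rng.permutation(len(ids))
        validation += [ids[i] for i in order[:n_val]]
        discovery += [ids[i] for i in order[n_val:]]
    return sorted(discovery), sorted(validation)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage; returns the run directory.

    On a stage failure, outputs already written are retained and the
    manifest records the failure point before the exception propagates.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "gutmarkers_version": __version__,
        "config": config.to_dict(),
        "stages": [],
        "inputs": {},
    }
    log_lines: list[str] = []
    t_run = time.time()

    def stage(name: str):
        manifest["stages"].append(name)
        log_lines.append(f"{name} started at +{time.time() - t_run:.2f}s")

    def done(name: str, **shapes):
        log_lines.append(
            f"{name} finished at +{time.time() - t_run:.2f}s "
            + " ".join(f"{k}={v}" for k, v in shapes.items())
        )

    def fail(name: str, exc: Exception):
        manifest["failed_stage"] = name
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        (out / "run.log").write_text("\n".join(log_lines) + "\n")

    current = "load"
    try:
        # ------------------------------------------------------------ load
        stage("load")
        if config.synthetic is not None:
            table, meta, truth = generate_cohort(config.synthetic, cohort="discovery")
            disc_ids, val_ids = _split_cohorts(
                table, meta, config.validation_fraction, config.seed)
            # independent cohort: fresh samples from the same populations
            # (draw=1), optionally perturbed by a site effect
            ind_spec = config.independent_spec or config.synthetic
            ind_table, ind_meta, _ = generate_cohort(
                ind_spec, cohort="independent", sample_prefix="I",
                site_effect_sd=config.site_effect_sd, draw=1)
            frame = meta.frame.copy()
            frame.loc[frame["sample_id"].isin(val_ids), "cohort"] = "validation"
            meta = SampleMetadata(frame)
            full_table = table
            manifest["ground_truth"] = {
                "diff_otu_ids": sorted(truth.diff_otu_ids),
                "direction": truth.direction,
                "realized_fold_change": truth.realized_fold_change,
            }
            write_otu_table(full_table, out / "counts.tsv")
            write_otu_table(ind_table, out / "counts_independent.tsv")
            write_metadata(meta, out / "metadata.tsv")
            write_metadata(ind_meta, out / "metadata_independent.tsv")
        else:
            if not (config.otu_table_path and config.metadata_path):
                raise ValueError("need either a synthetic spec or input paths")
            full_table = read_otu_table(config.otu_table_path)
            meta = read_metadata(config.metadata_path)
            cohorts = meta.frame.get("cohort")
            if cohorts is None:
                raise ValueError("metadata must carry a cohort column")
            disc_ids = sorted(meta.frame.loc[cohorts == "discovery", "sample_id"])
            val_ids = sorted(meta.frame.loc[cohorts == "validation", "sample_id"])
            ind_ids = sorted(meta.frame.loc[cohorts == "independent", "sample_id"])
            ind_table = full_table.select_samples(ind_ids) if ind_ids else None
            ind_meta = meta.subset(ind_ids) if ind_ids else None
        overlap = set(disc_ids) & set(val_ids)
        if overlap:
            raise ValueError(
                f"discovery/validation cohorts overlap: {sorted(overlap)[:3]}")
        for p in out.glob("*.tsv"):
            manifest["inputs"][p.name] = _sha256(p)
        done("load", samples=full_table.n_samples, otus=full_table.n_otus)

        discovery = full_table.select_samples(disc_ids)
        validation = full_table.select_samples(val_ids) if val_ids else None
        disc_groups = meta.groups_for(disc_ids)

        # ------------------------------------------------------- diversity
        current = "diversity"
        stage(current)
        depth = config.rarefaction_depth or int(discovery.sample_totals().min())
        div_table = (rarefy(discovery, depth, seed=config.seed)
                     if config.diversity_on_rarefied else discovery)
        div_groups = meta.groups_for(div_table.sample_ids)
        alpha = alpha_diversity(div_table)
        alpha["group"] = div_groups
        alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
        from .diffabund import wilcoxon_rank_sum
        alpha_tests = {
            idx: wilcoxon_rank_sum(
                alpha.loc[alpha["group"] == "CASE", idx],
                alpha.loc[alpha["group"] == "CONTROL", idx])
            for idx in ("observed_otus", "shannon", "chao1", "ace")
        }
        manifest["alpha_diversity_p"] = alpha_tests
        dm = bray_curtis(div_table)
        dm.to_dataframe().to_csv(out / "bray_curtis.tsv", sep="\t")
        ord_res = pcoa(dm, n_axes=2)
        pd.DataFrame(ord_res.coordinates, index=ord_res.ids,
                     columns=[f"PCo{i+1}" for i in range(ord_res.coordinates.shape[1])]
                     ).to_csv(out / "pcoa.tsv", sep="\t")
        overlap_counts = group_overlap(div_table, div_groups)
        manifest["otu_overlap"] = overlap_counts
        done(current, depth=depth)

        # ---------------------------------------------------- differential
        current = "differential"
        stage(current)
        abund_disc = relative_abundance(discovery)
        screen = wilcoxon_screen(abund_disc, disc_groups, alpha=config.screen_alpha)
        screen.to_csv(out / "wilcoxon_screen.tsv", sep="\t")
        lefse = lda_effect_size(
            abund_disc, disc_groups, kw_alpha=config.kw_alpha,
            lda_threshold=config.lda_threshold, seed=config.seed)
        lefse.to_csv(out / "lda_effect_size.tsv", sep="\t")
        done(current, screened=int(screen["selected"].sum()),
             lda_pass=int(lefse["passes"].sum()))

        # -------------------------------------------------------- discover
        current = "discover"
        stage(current)
        mk_config = MarkerDiscoveryConfig(
            screen_alpha=config.screen_alpha, n_trees=config.n_trees,
            n_trials=config.n_trials, n_folds=config.n_folds, seed=config.seed)
        marker_set = discover_markers(discovery, meta.subset(disc_ids), mk_config)
        (out / "markers.json").write_text(json.dumps(marker_set.to_dict(), indent=2))
        mk_config.audit["curve"].to_frame().to_csv(
            out / "cv_error_curve.tsv", sep="\t", index=False)
        done(current, markers=marker_set.chosen_size)

        # -------------------------------------------------------- classify
        current = "classify"
        stage(current)
        model = train_pod_model(discovery, disc_groups, marker_set.markers,
                                n_trees=config.n_trees, seed=config.seed)
        train_scores = pod_index(model, discovery)
        train_scores["group"] = disc_groups
        train_scores.to_csv(out / "pod_discovery.tsv", sep="\t")
        disc_roc = roc_auc(train_scores, disc_groups)
        evaluation = {"discovery": {
            "auc": disc_roc.auc, "ci_low": disc_roc.ci_low,
            "ci_high": disc_roc.ci_high,
            "n_case": disc_roc.n_case, "n_control": disc_roc.n_control,
        }}
        done(current, trees=model.n_trees)

        # -------------------------------------------------------- evaluate
        current = "evaluate"
        stage(current)
        cohorts = {}
        if validation is not None and validation.n_samples:
            cohorts["validation"] = (validation, meta.groups_for(val_ids))
        if ind_table is not None:
            cohorts["independent"] = (
                ind_table, ind_meta.groups_for(ind_table.sample_ids))
        results = evaluate_cohorts(model, cohorts)
        for name, res in results.items():
            res["scores"].to_csv(out / f"pod_{name}.tsv", sep="\t")
            res["roc"].to_frame().to_csv(out / f"roc_{name}.tsv", sep="\t", index=False)
            evaluation[name] = {
                "auc": res["roc"].auc, "ci_low": res["roc"].ci_low,
                "ci_high": res["roc"].ci_high, "group_p": res["group_p"],
                "n_case": res["roc"].n_case, "n_control": res["roc"].n_control,
            }
        manifest["evaluation"] = evaluation
        done(current, cohorts=len(results))

        # ------------------------------------------------------- correlate
        current = "correlate"
        stage(current)
        case_ids = [s for s, g in zip(disc_ids, disc_groups) if g == "CASE"]
        corr = spearman_matrix(
            abund_disc.loc[case_ids, marker_set.markers],
            meta.subset(case_ids).clinical_table())
        corr.to_csv(out / "clinical_correlation.tsv", sep="\t", index=False)
        done(current, cells=len(corr))
    except Exception as exc:
        fail(current, exc)
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
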