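"""End-to-end two-strategy workflow on synthetic data.

``run_pipeline`` executes simulate -> preprocess -> stability -> select ->
screen -> express -> panel, writes every intermediate artifact as TSV/JSON
under the output directory, and emits a machine-readable run report.  The
whole run is deterministic for a fixed seed.

``study_scenario`` builds the default synthetic study: a cervical-cancer-
style cohort (66 tumor / 30 control FFPE samples, triplicate qPCR on 3
runs with pooled inter-run calibrators) measuring 8 endogenous-control
candidates — two of them planted as the stable pair — and 5 target
miRNAs, three of which carry planted group effects; plus a small-RNA-seq
layer of 2730 isoforms (2523 silent) with 8 planted differentially
expressed miRNAs, 3 of them low-expression.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import expression, ngs_screen, panel, qpcr_preprocess, selection, stability
from .containers import CtDataset, split_groups, write_matrix
from .synthetic_data import (
    CountSimSpec,
    CtSimSpec,
    simulate_count_matrix,
    simulate_ct_dataset,
    simulate_de_tables,
)

__all__ = ["PipelineConfig", "PipelineError", "study_scenario", "run_pipeline"]

EC_CANDIDATES = [
    "miR-451a", "miR-25-3p", "miR-423-5p", "miR-103a-3p",
    "miR-484", "let-7i-5p", "miR-181a-5p", "miR-423-3p",
]
STABLE_PAIR = ("miR-181a-5p", "miR-423-3p")
TARGETS = ["miR-26a-5p", "miR-4286", "miR-7704", "miR-4454", "miR-320a-3p"]
# tumor-vs-control Ct shifts for the planted deregulated targets:
# Ct shift = -log2(fold change), so up-regulation lowers Ct
PLANTED_FC = {"miR-320a-3p": 4.145, "miR-7704": 4.778, "miR-26a-5p": 1 / 11.144}


@dataclass
class PipelineConfig:
    """Thresholds, seed and output location for a pipeline run.

    Defaults are the conventional screening thresholds: detection limit 40
    cycles, base-mean floor 100, |log2FC| cap 2 for control candidates,
    stability-value shortlist < 5, CV exclusion > 200%, significance at
    p < 0.05 with |FC| >= 2, panel cutoff 0.5.
    """

    seed: int = 7
    out_dir: str = "mirnorm_run"
    detection_limit: float = 40.0
    max_replicate_sd: float = 0.5
    combine_k: int = 2
    cv_mode: str = "targets-vs-candidate"
    cv_max: float = 200.0
    stability_max: float = 5.0
    base_min: float = 100.0
    lfc_max: float = 2.0
    top_n: int = 5
    alpha: float = 0.05
    p_max: float = 0.05
    fc_min: float = 2.0
    cutoff: float = 0.5
    de_sensitivity: float = 1.0
    de_specificity: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.cutoff < 1:
            raise ValueError("cutoff must lie in (0, 1)")
        for name in ("alpha", "p_max"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.cv_max < 0 or self.base_min < 0:
            raise ValueError("thresholds must be non-negative")

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = dataclasses.asdict(self)
        if path.suffix == ".json":
            path.write_text(json.dumps(data, indent=2, sort_keys=True))
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**data)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def study_scenario(seed: int) -> tuple[CtSimSpec, CountSimSpec, pd.DataFrame | None]:
    """Synthetic study conditions mirroring a cervical-cancer FFPE cohort.

    qPCR layer: 13 assays (8 control candidates + 5 targets), 66 tumor and
    30 control samples, triplicates on 3 runs.  Technical noise 0.2 cycles
    per replicate, exchangeable sample effects of 0.25 cycles, run offsets
    of ~0.5 cycles removed later by the calibrator.  Biological
    between-sample scatter: 0.15 cycles for the planted stable pair,
    0.3-0.8 for the remaining candidates (plus small group shifts), and
    1.5 cycles for the disease targets — the scatter a heterogeneous FFPE
    cohort typically shows.  Three candidates are forced to drop out
    (undetected in at least one sample).

    Count layer: 2730 isoforms of which 2523 are silent; 8 planted DE
    miRNAs (3 below the base-mean floor of 100), the control candidates
    highly expressed with near-zero fold change.
    """
    rng = np.random.default_rng(seed)

    baselines: dict[str, float] = {}
    group_effects: dict[str, float] = {}
    gene_noise: dict[str, float] = {}

    cand_baseline = {
        "miR-451a": 33.0, "miR-25-3p": 24.0, "miR-423-5p": 25.5,
        "miR-103a-3p": 32.5, "miR-484": 33.5, "let-7i-5p": 23.5,
        "miR-181a-5p": 25.0, "miR-423-3p": 26.0,
    }
    cand_noise = {
        "miR-451a": 0.8, "miR-25-3p": 0.4, "miR-423-5p": 0.55,
        "miR-103a-3p": 0.7, "miR-484": 0.6, "let-7i-5p": 0.35,
        "miR-181a-5p": 0.15, "miR-423-3p": 0.15,
    }
    # group drifts of the imperfect candidates point both ways, as real
    # "recommended" controls do; the planted stable pair has none
    cand_beta = {
        "miR-451a": 1.2, "miR-25-3p": 0.35, "miR-423-5p": -0.6,
        "miR-103a-3p": -0.9, "miR-484": 0.7, "let-7i-5p": -0.3,
        "miR-181a-5p": 0.0, "miR-423-3p": 0.0,
    }
    baselines.update(cand_baseline)
    gene_noise.update(cand_noise)
    group_effects.update(cand_beta)

    target_baseline = {
        "miR-26a-5p": 24.5, "miR-4286": 27.0, "miR-7704": 29.0,
        "miR-4454": 26.5, "miR-320a-3p": 27.5,
    }
    baselines.update(target_baseline)
    for t in TARGETS:
        gene_noise[t] = 1.5
        fc = PLANTED_FC.get(t)
        group_effects[t] = 0.0 if fc is None else -math.log2(fc)

    ct_spec = CtSimSpec(
        gene_baselines=baselines,
        group_effects=group_effects,
        gene_noise_sd=gene_noise,
        n_tumor=66,
        n_control=30,
        sample_effect_sd=0.25,
        replicate_sd=0.2,
        n_replicates=3,
        n_runs=3,
        run_offset_sd=0.5,
        detection_limit=40.0,
        dropout_genes=("miR-451a", "miR-103a-3p", "miR-484"),
        seed=int(rng.integers(0, 2**31 - 1)),
    )

    # --- sequencing layer -------------------------------------------------
    n_isoforms = 2730
    n_silent = 2523
    base_means: dict[str, float] = {}
    log2fc: dict[str, float] = {}

    cand_rpm = {
        "miR-451a": 1800.0, "miR-25-3p": 2500.0, "miR-423-5p": 900.0,
        "miR-103a-3p": 1200.0, "miR-484": 700.0, "let-7i-5p": 4000.0,
        "miR-181a-5p": 3000.0, "miR-423-3p": 2200.0,
    }
    # planted |log2FC| ordering puts the screening top-5 on
    # let-7i-5p, miR-181a-5p, miR-451a, miR-423-3p, miR-25-3p
    cand_lfc = {
        "let-7i-5p": 0.02, "miR-181a-5p": 0.04, "miR-451a": 0.06,
        "miR-423-3p": 0.08, "miR-25-3p": 0.10, "miR-423-5p": 0.6,
        "miR-103a-3p": 0.8, "miR-484": 0.9,
    }
    base_means.update(cand_rpm)
    log2fc.update(cand_lfc)

    de_rpm = {
        "miR-320a-3p": 1500.0, "miR-26a-5p": 2400.0, "miR-7704": 450.0,
        "miR-4286": 600.0, "miR-4454": 350.0,
        # low-expression DE calls, later removed by the base-mean floor
        "miR-146a-5p": 60.0, "miR-142-3p": 45.0, "miR-663a-3p": 30.0,
    }
    de_lfc = {
        "miR-320a-3p": math.log2(4.145), "miR-26a-5p": -math.log2(11.144),
        "miR-7704": math.log2(4.778), "miR-4286": 1.4, "miR-4454": 1.2,
        "miR-146a-5p": 2.1, "miR-142-3p": -1.8, "miR-663a-3p": 1.6,
    }
    base_means.update(de_rpm)
    log2fc.update(de_lfc)

    n_background = n_isoforms - n_silent - len(base_means)
    bg_means = np.exp(rng.normal(np.log(80.0), 1.2, size=n_background))
    for i, m in enumerate(bg_means):
        base_means[f"iso-{i + 1:04d}"] = float(m)
    for i in range(n_silent):
        base_means[f"silent-{i + 1:04d}"] = 0.0

    count_spec = CountSimSpec(
        base_means=base_means,
        group_log2fc=log2fc,
        n_tumor=6,
        n_control=6,
        dispersion=0.05,
        library_sizes=2_000_000.0,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return ct_spec, count_spec, None


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(name, exc) from exc
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run the full workflow and return the machine-readable report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    report: dict[str, Any] = {"schema_version": 1, "seed": config.seed}

    # ---- simulate --------------------------------------------------------
    @_stage("simulate")
    def _simulate():
        ct_spec, count_spec, _ = study_scenario(config.seed)
        dataset = simulate_ct_dataset(ct_spec)
        counts, truth = simulate_count_matrix(count_spec)
        rng = np.random.default_rng(config.seed + 1)
        tables = simulate_de_tables(
            truth, n_methods=3,
            sensitivity=config.de_sensitivity,
            specificity=config.de_specificity,
            alpha=config.alpha,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        sim_dir = out / "sim"
        dataset.write(sim_dir)
        write_matrix(counts, sim_dir / "counts.tsv", index_label="mirna")
        write_matrix(truth, sim_dir / "truth.tsv", index_label="mirna")
        for i, t in enumerate(tables):
            t.to_csv(sim_dir / f"de_table_{i + 1}.tsv", sep="\t", index=False)
        log(f"simulate: {len(dataset.genes)} assays x {len(dataset.samples)} samples; "
            f"{counts.shape[0]} isoforms x {counts.shape[1]} libraries")
        return dataset, counts, truth, tables

    dataset, counts, truth, de_tables = _simulate()

    # ---- preprocess ------------------------------------------------------
    @_stage("preprocess")
    def _preprocess():
        collapsed, flags = qpcr_preprocess.collapse_replicates(
            dataset, max_sd=config.max_replicate_sd
        )
        det = qpcr_preprocess.detection_filter(collapsed, limit=config.detection_limit)
        retained = collapsed.loc[det.retained]
        calibrated = qpcr_preprocess.interrun_calibrate(retained, dataset.meta)
        pre_dir = out / "preprocess"
        pre_dir.mkdir(exist_ok=True)
        write_matrix(collapsed, pre_dir / "collapsed.tsv")
        write_matrix(flags.astype(int), pre_dir / "replicate_flags.tsv")
        write_matrix(calibrated, pre_dir / "calibrated.tsv")
        (pre_dir / "discarded.json").write_text(
            json.dumps(det.discard_log, indent=2, sort_keys=True)
        )
        log(f"preprocess: {len(det.retained)} assays retained, "
            f"{len(det.discarded)} discarded ({', '.join(det.discarded) or 'none'})")
        return collapsed, det, calibrated

    collapsed, det, calibrated = _preprocess()
    report["detection"] = {
        "retained": det.retained, "discarded": det.discarded,
    }

    # ---- stability -------------------------------------------------------
    @_stage("stability")
    def _stability():
        cands = [g for g in EC_CANDIDATES if g in calibrated.index]
        groups = dataset.meta.loc[calibrated.columns, "group"]
        rep = stability.stability_report(calibrated.loc[cands], groups)
        stab_dir = out / "stability"
        stab_dir.mkdir(exist_ok=True)
        rep.write(stab_dir / "stability_report.tsv")
        log(f"stability: {len(cands)} single candidates scored")
        return cands, rep

    cands, single_report = _stability()

    # ---- select ----------------------------------------------------------
    @_stage("select")
    def _select():
        extended_cal = selection.make_combinations(
            calibrated.loc[cands], k=config.combine_k
        )
        groups = dataset.meta.loc[extended_cal.columns, "group"]
        rep = stability.stability_report(extended_cal, groups)
        ranking = selection.aggregate_ranks(rep)
        # CV needs the uncalibrated matrix (it still carries the pools)
        targets_present = [
            t for t in TARGETS
            if t in collapsed.index and t in calibrated.index
        ]
        extended_raw = selection.make_combinations(
            collapsed.loc[cands], k=config.combine_k
        )
        extended_raw = pd.concat([extended_raw, collapsed.loc[targets_present]])
        cvs = selection.cv_of_candidates(
            extended_raw, dataset.meta, mode=config.cv_mode,
            targets=targets_present,
        )
        result = selection.select_endogenous_control(
            ranking, cvs, cv_max=config.cv_max, stability_max=config.stability_max
        )
        sel_dir = out / "select"
        sel_dir.mkdir(exist_ok=True)
        result.write(sel_dir / "verdicts.tsv")
        log(f"select: {result.selected} chosen from {len(ranking)} candidates "
            f"(shortlist: {', '.join(result.shortlist[:5])})")
        return result

    sel = _select()
    report["endogenous_control"] = {
        "selected": sel.selected,
        "shortlist": sel.shortlist,
        "n_candidates": int(len(sel.verdicts)),
        "n_excluded": int((sel.verdicts["verdict"] == "excluded").sum()),
    }

    # ---- screen ----------------------------------------------------------
    @_stage("screen")
    def _screen():
        expr = ngs_screen.expression_filter(counts)
        expressed = counts.loc[expr.retained]
        rpm = ngs_screen.rpm_normalize(expressed)
        tum = [c for c in counts.columns if c.startswith("T")]
        ctl = [c for c in counts.columns if c.startswith("C")]
        screen = ngs_screen.ec_candidate_screen(
            rpm, tum, ctl, base_min=config.base_min,
            lfc_max=config.lfc_max, top_n=config.top_n,
        )
        consensus = ngs_screen.de_consensus(
            de_tables, base_min=config.base_min, alpha=config.alpha
        )
        scr_dir = out / "screen"
        scr_dir.mkdir(exist_ok=True)
        write_matrix(rpm, scr_dir / "rpm.tsv", index_label="mirna")
        screen.to_csv(scr_dir / "ec_candidates.tsv", sep="\t", index_label="mirna")
        log(f"screen: {expr.n_retained}/{counts.shape[0]} isoforms expressed; "
            f"DE per table {consensus.per_table_counts}, "
            f"intersection {consensus.n_intersection}, "
            f"consensus after base-mean filter {len(consensus.consensus)}")
        return expr, screen, consensus

    expr_filter, screen_top, consensus = _screen()
    report["screen"] = {
        "n_isoforms": int(counts.shape[0]),
        "n_expressed": expr_filter.n_retained,
        "n_silent": expr_filter.n_discarded,
        "ec_candidates": list(screen_top.index),
        "de_per_table": consensus.per_table_counts,
        "de_intersection": consensus.intersection,
        "de_consensus": consensus.consensus,
        "de_dropped_low_expression": consensus.dropped_low_expression,
    }

    # ---- express ---------------------------------------------------------
    @_stage("express")
    def _express():
        targets_present = [t for t in TARGETS if t in calibrated.index]
        normalizer = selection.combination_members(sel.selected)
        normalized = qpcr_preprocess.delta_ct(
            calibrated, normalizer, targets=targets_present
        )
        tum, ctl = split_groups(dataset.meta, calibrated.columns)
        table = expression.quantify(
            normalized, tum, ctl,
            p_max=config.p_max, fc_min=config.fc_min,
        )
        _, ddct = expression.ddct_fold_change(normalized, tum, ctl)
        exp_dir = out / "express"
        exp_dir.mkdir(exist_ok=True)
        table.to_csv(exp_dir / "fold_changes.tsv", sep="\t", index_label="mirna")
        normalized.write(exp_dir / "delta_ct.tsv")
        sig = table.index[table["significant"]]
        log(f"express: {len(sig)}/{len(table)} targets significant "
            f"({', '.join(sig)})")
        return table, ddct, tum, ctl

    fc_table, ddct, tumor_samples, control_samples = _express()
    report["expression"] = {
        g: {
            "fc_reported": round(float(r["fc_reported"]), 3),
            "p_value": float(r["p_value"]),
            "test_used": r["test_used"],
            "significant": bool(r["significant"]),
            "direction": r["direction"],
        }
        for g, r in fc_table.iterrows()
    }

    # ---- panel -----------------------------------------------------------
    @_stage("panel")
    def _panel():
        sig = list(fc_table.index[fc_table["significant"]])
        if not sig:
            log("panel: skipped (no significant miRNAs)")
            return None
        # features: per-sample log2 relative expression (-ΔΔCt)
        features = (-ddct.loc[sig]).T
        labels = pd.Series(
            [1] * len(tumor_samples) + [0] * len(control_samples),
            index=list(tumor_samples) + list(control_samples),
        )
        features = features.loc[labels.index]
        result = panel.evaluate_panel(features, labels, cutoff=config.cutoff)
        pan_dir = out / "panel"
        pan_dir.mkdir(exist_ok=True)
        result.write(pan_dir / "panel_report.json", pan_dir / "roc_points.tsv")
        log(f"panel: AUC {result.auc:.3f}, sensitivity "
            f"{result.confusion.sensitivity_percent:.2f}%, specificity "
            f"{result.confusion.specificity_percent:.2f}%")
        return result

    panel_result = _panel()
    if panel_result is not None:
        report["panel"] = {
            "features": list(fc_table.index[fc_table["significant"]]),
            "auc": round(float(panel_result.auc), 4),
            "sensitivity_percent": round(panel_result.confusion.sensitivity_percent, 2),
            "specificity_percent": round(panel_result.confusion.specificity_percent, 2),
            "confusion": panel_result.confusion.as_dict(),
            "separation_flagged": panel_result.fit.separation_flagged,
        }
    else:
        report["panel"] = None

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (out / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    return report
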