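"""End-to-end pipeline: simulate -> QC -> select -> train -> score -> evaluate.

The driver mirrors a two-cohort PRS study: a GWAS-like training cohort goes
through array-scale QC, a smaller case-control validation cohort through
panel QC; SNP weights are estimated on the training cohort by RLR, LRR and
the ANN approach (overall and per ER subtype), scores are computed on the
validation cohort, and a results table with IQ-OR, Q4-vs-Q1 OR, O/E OR and
AUC (each with 95% CI) is written per method x case-set x adjustment.

All randomness flows from a single global seed expanded per stage; a run
manifest with config snapshot, seeds and output checksums is written even on
failure.
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

from . import io as pio
from .containers import status_to_binary
from .evaluate import evaluate_prs
from .prsmodels import (
    ANNConfig,
    attach_pcs,
    fit_ann,
    fit_lrr,
    fit_rlr,
    score_ann,
    score_prs,
)
from .qc import QCThresholds, apply_qc, array_thresholds, panel_thresholds
from .snpselect import ld_matrix, prune_tight_ld
from .synthdata import SimulationConfig, default_panel, simulate_cohort

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "demo_config",
           "verify_manifest"]


@dataclass
class PipelineConfig:
    train_sim: SimulationConfig
    valid_sim: SimulationConfig
    train_thresholds: QCThresholds = field(default_factory=array_thresholds)
    valid_thresholds: QCThresholds = field(default_factory=panel_thresholds)
    prune_r2_max: float = 0.95
    lambda_grid: tuple[float, ...] = (0.3, 1.0, 3.0, 10.0, 30.0)
    ann_config: ANNConfig = field(default_factory=ANNConfig)
    methods: tuple[str, ...] = ("rlr", "lrr", "ann")
    case_sets: tuple[str, ...] = ("overall", "er_pos", "er_neg")
    adjustments: tuple[str, ...] = ("none", "gail", "classical")
    cv_folds: int = 10
    seed: int = 0
    out_dir: str = "prsforge_run"


@dataclass
class RunManifest:
    config: dict
    version: str
    seeds: dict
    stages: list
    checksums: dict
    started: float
    finished: float | None = None
    error: str | None = None


def demo_config(seed: int = 0, out_dir: str = "prsforge_run") -> PipelineConfig:
    """Bundled demo: GWAS-like training cohort (2000 cases / 2000 controls)
    and case-control validation cohort (400/400) sharing a 24-SNP panel."""
    panel = default_panel(n_snps=24, seed=7)
    # pairwise kinship cannot be estimated from a 24-SNP panel (the estimator
    # needs thousands of loci), so the relatedness filter is off in the demo
    train_th = dataclasses.replace(array_thresholds(), kinship_max=None)
    train = SimulationConfig(
        n_cases=2000,
        n_controls=2000,
        snps=panel,
        covariate_effects={"age": 0.01},
        er_pos_fraction=0.66,
        seed=seed * 1000 + 1,
    )
    valid = SimulationConfig(
        n_cases=400,
        n_controls=400,
        snps=panel,
        covariate_effects={"age": 0.01},
        er_pos_fraction=0.70,
        missing_rate=0.002,
        seed=seed * 1000 + 2,
    )
    return PipelineConfig(
        train_sim=train,
        valid_sim=valid,
        train_thresholds=train_th,
        seed=seed,
        out_dir=out_dir,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def verify_manifest(out_dir: str | Path) -> list[str]:
    """Recompute output checksums against the run manifest; returns the list
    of mismatched or missing paths (empty when the run directory is intact)."""
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    bad = []
    for path, digest in manifest["checksums"].items():
        p = Path(path)
        if not p.exists() or _sha256(p) != digest:
            bad.append(path)
    return bad


def run_pipeline(config: PipelineConfig) -> RunManifest:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ["simulate_train", "simulate_valid", "cv", "ann"], ss.spawn(4)
        )
    }
    manifest = RunManifest(
        config=_jsonable(config),
        version="0.1.0",
        seeds=stage_seeds,
        stages=[],
        checksums={},
        started=time.time(),
    )

    def record(stage: str, paths: list[Path]) -> None:
        manifest.stages.append(stage)
        for p in paths:
            manifest.checksums[str(p)] = _sha256(p)

    try:
        # simulate
        tr_sim = dataclasses.replace(config.train_sim, seed=stage_seeds["simulate_train"])
        va_sim = dataclasses.replace(config.valid_sim, seed=stage_seeds["simulate_valid"])
        g_tr, t_tr = simulate_cohort(tr_sim)
        g_va, t_va = simulate_cohort(va_sim)
        paths = pio.write_genotypes(g_tr, out / "train_genotypes", "raw")
        paths += pio.write_genotypes(g_va, out / "valid_genotypes", "raw")
        paths.append(pio.write_sample_table(t_tr, out / "train_samples.tsv"))
        paths.append(pio.write_sample_table(t_va, out / "valid_samples.tsv"))
        record("simulate", paths)

        # qc
        g_tr, t_tr, rep_tr = apply_qc(g_tr, t_tr, config.train_thresholds)
        g_va, t_va, rep_va = apply_qc(g_va, t_va, config.valid_thresholds)
        qc_paths = []
        for name, rep in (("train", rep_tr), ("valid", rep_va)):
            p = out / f"qc_{name}_snps.tsv"
            rep.snp_decisions.drop(columns="metrics").to_csv(p, sep="\t", index=False)
            qc_paths.append(p)
            p2 = out / f"qc_{name}_summary.json"
            p2.write_text(json.dumps(rep.summary, indent=2))
            qc_paths.append(p2)
        record("qc", qc_paths)

        # select: tight-LD pruning on the training panel
        ld = ld_matrix(g_tr)
        decisions = prune_tight_ld(list(g_tr.snp_ids), ld, r2_max=config.prune_r2_max)
        kept = [d.snp_id for d in decisions if d.action == "keep"]
        sel_path = out / "selection.tsv"
        pd.DataFrame([dataclasses.asdict(d) for d in decisions]).to_csv(
            sel_path, sep="\t", index=False
        )
        record("select", [sel_path])
        keep_idx = [g_tr.snp_ids.index(s) for s in kept]
        g_tr = g_tr.subset(snp_idx=keep_idx)
        common = [s for s in g_tr.snp_ids if s in g_va.snp_ids]
        g_tr = g_tr.subset(snp_idx=[g_tr.snp_ids.index(s) for s in common])
        g_va = g_va.subset(snp_idx=[g_va.snp_ids.index(s) for s in common])

        # PCs on each cohort (population-structure covariates)
        t_tr = attach_pcs(g_tr, t_tr)
        t_va = attach_pcs(g_va, t_va)

        # train + score + evaluate
        rows = []
        score_paths = []
        y_va_all = status_to_binary(t_va)
        er_va = t_va["er_status"].to_numpy()
        for case_set in config.case_sets:
            for method in config.methods:
                if method == "rlr":
                    w = fit_rlr(g_tr, t_tr, case_set=case_set)
                    scores = score_prs(w, g_va)
                    pio.write_weights(w, out / f"weights_{method}_{case_set}")
                elif method == "lrr":
                    w, _ = fit_lrr(
                        g_tr, t_tr,
                        lambda_grid=config.lambda_grid,
                        case_set=case_set,
                        folds=config.cv_folds,
                        seed=stage_seeds["cv"],
                    )
                    scores = score_prs(w, g_va)
                    pio.write_weights(w, out / f"weights_{method}_{case_set}")
                elif method == "ann":
                    cfg = dataclasses.replace(config.ann_config, seed=stage_seeds["ann"])
                    model, _ = fit_ann(g_tr, t_tr, config=cfg, case_set=case_set,
                                       folds=config.cv_folds)
                    scores = score_ann(model, g_va)
                else:
                    raise ValueError(f"unknown method {method!r}")
                sp = out / f"scores_{method}_{case_set}.tsv"
                pio.write_scores(list(g_va.sample_ids), scores, sp)
                score_paths.append(sp)

                # evaluation restricted to controls + the target case stratum
                if case_set == "overall":
                    emask = np.ones(len(t_va), dtype=bool)
                else:
                    want = "positive" if case_set == "er_pos" else "negative"
                    emask = (y_va_all == 0) | (er_va == want)
                reports = evaluate_prs(
                    scores[emask],
                    y_va_all[emask],
                    covariate_table=t_va.loc[emask],
                    adjustments=config.adjustments,
                    case_set=case_set,
                )
                for r in reports:
                    row = {"method": method, **r.as_row()}
                    rows.append(row)
        record("score", score_paths)
        results = pd.DataFrame(rows)
        res_path = out / "evaluation.tsv"
        results.to_csv(res_path, sep="\t", index=False, float_format="%.6g")
        res_json = out / "evaluation.json"
        res_json.write_text(results.to_json(orient="records", indent=2))
        record("evaluate", [res_path, res_json])
        manifest.finished = time.time()
    except Exception as exc:  # manifest is written even on failure
        manifest.error = f"{type(exc).__name__}: {exc}"
        manifest.finished = time.time()
        (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2))
        raise
    (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2))
    return manifest
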