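"""End-to-end orchestration: phantom -> features -> screening -> models.

One config drives the whole run: generate (or load) a cohort, extract the
three segmentation-set feature tables, split 70/30 stratified, screen the
feature space on the training cohort, tune and train the requested
classifiers, and evaluate them on both cohorts.  Every stage draws its
randomness from named substreams of the single config seed, so a run is a
pure function of (config, seed); the manifest records a content hash that
is identical across re-runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidArgumentError
from .evaluation import DEFAULT_CLASS_ORDER, confusion, metrics, round_half_up
from .features import FeatureConfig, extract_all, feature_names
from .modeling import (SubtypeClassifier, default_ann_grid, default_rf_grid,
                       default_svm_grid, stratified_split)
from .phantom import (DEFAULT_CLASS_SIZES, clinical_table, default_class_specs,
                      generate_cohort)
from .screening import ScreeningConfig, screen_pipeline
from .seg_perturb import PerturbationSpec, make_segmentation_set
from .volume_io import read_case

log = logging.getLogger("pcnradiomics")

__all__ = ["PipelineConfig", "RunManifest", "run", "report_tables"]


@dataclass
class PipelineConfig:
    # input: exactly one of (phantom generation | a cohort directory with a
    # manifest.json written by the phantom module or following its schema)
    data_dir: str | None = None
    class_sizes: tuple[int, int, int] = DEFAULT_CLASS_SIZES
    class_specs: dict | None = None  # label -> ClassSpec field dict; None = defaults
    seed: int = 0
    # preprocessing
    n_levels: int = 64
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 5.0)
    wavelet: str = "db4"
    include_wavelet: bool = True
    # segmentation perturbation
    perturb_min_px: int = 1
    perturb_max_px: int = 4
    n_variants: int = 2
    # screening
    icc_threshold: float = 0.75
    corr_threshold: float = 0.75
    alpha: float = 0.05
    boruta_alpha: float = 0.01
    boruta_max_iter: int = 100
    boruta_trees: int = 100
    # modeling
    split_ratio: float = 0.7
    folds: int = 4
    models: tuple[str, ...] = ("svm", "rf", "ann")
    rf_trees_grid: tuple[int, ...] = (500, 1000)
    rf_mtry_grid: tuple[int, ...] = (1, 2, 3)
    ann_restarts: int = 2
    # output
    output_dir: str | None = None
    save_images: bool = False

    def __post_init__(self):
        for t, name in ((self.icc_threshold, "icc_threshold"),
                        (self.corr_threshold, "corr_threshold"),
                        (self.alpha, "alpha"), (self.boruta_alpha, "boruta_alpha")):
            if not 0.0 < t < 1.0:
                raise InvalidArgumentError(f"{name} must lie in (0, 1)")
        if not 0.0 < self.split_ratio <= 1.0:
            raise InvalidArgumentError("split_ratio must lie in (0, 1]")
        unknown = set(self.models) - {"svm", "rf", "ann"}
        if unknown:
            raise InvalidArgumentError(f"unknown models {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("class_sizes", "target_spacing", "models",
                    "rf_trees_grid", "rf_mtry_grid"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def content_hash(self) -> str:
        d = self.to_dict()
        d.pop("output_dir")  # where results land does not alter what they are
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def feature_config(self) -> FeatureConfig:
        return FeatureConfig(n_levels=self.n_levels,
                             wavelet=self.wavelet,
                             target_spacing=self.target_spacing,
                             include_wavelet=self.include_wavelet)

    def resolved_class_specs(self) -> dict:
        from .phantom import ClassSpec
        if self.class_specs is None:
            return default_class_specs()
        return {k: (v if isinstance(v, ClassSpec) else ClassSpec(**v))
                for k, v in self.class_specs.items()}


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    counts: dict
    selected_features: list[str]
    split_counts: dict
    models: dict
    notes: list[str] = field(default_factory=list)
    elapsed_s: float = 0.0

    def to_dict(self) -> dict:
        return {"config_hash": self.config_hash, "seed": self.seed,
                "counts": self.counts,
                "selected_features": self.selected_features,
                "split_counts": self.split_counts, "models": self.models,
                "notes": self.notes, "elapsed_s": self.elapsed_s}

    def content_hash(self) -> str:
        d = self.to_dict()
        d.pop("elapsed_s")
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_cohort_tables(config: PipelineConfig):
    """(case list, clinical df, labels) from phantom generation or disk."""
    if config.data_dir is not None:
        root = Path(config.data_dir)
        manifest = json.loads((root / "manifest.json").read_text())
        cases = []
        for e in manifest["cases"]:
            vol, mask = read_case(root / e["volume"], root / e["mask"])
            cases.append((e["patient_id"], vol, mask, e["label"]))
        clinical = pd.read_csv(root / "clinical.csv", index_col="patient_id")
        clinical = clinical.loc[[c[0] for c in cases]]
        labels = np.array([c[3] for c in cases])
        return cases, clinical.drop(columns=["label"], errors="ignore"), labels, None
    cohort = generate_cohort(config.class_sizes, config.resolved_class_specs(),
                             seed=config.seed)
    cases = [(c.patient_id, c.volume, c.mask, c.label) for c in cohort.cases]
    clinical = clinical_table(cohort).drop(columns=["label"])
    labels = np.array(cohort.labels())
    return cases, clinical, labels, cohort


def _extract_tables(cases, config: PipelineConfig) -> list[pd.DataFrame]:
    fc = config.feature_config()
    pspec = PerturbationSpec(config.perturb_min_px, config.perturb_max_px,
                             seed=config.seed, n_variants=config.n_variants)
    tables = [dict() for _ in range(config.n_variants + 1)]
    for pid, vol, mask, _ in cases:
        segs = make_segmentation_set(mask, pspec, case_id=pid)
        for k, seg in enumerate(segs):
            tables[k][pid] = extract_all(vol, seg, fc)
        log.debug("extracted %s", pid)
    names = feature_names(fc)
    out = []
    for tab in tables:
        df = pd.DataFrame.from_dict(tab, orient="index")[names]
        df.index.name = "patient_id"
        out.append(df)
    return out


def _model_grids(config: PipelineConfig) -> dict[str, list[dict]]:
    return {"svm": default_svm_grid(),
            "rf": default_rf_grid(config.rf_trees_grid, config.rf_mtry_grid),
            "ann": default_ann_grid()}


def _metrics_block(cm, rep) -> dict:
    return {
        "confusion": cm.counts.tolist(),
        "class_order": list(cm.class_order),
        "precision": {c: rep.precision[c] for c in cm.class_order},
        "recall": {c: rep.recall[c] for c in cm.class_order},
        "f1": {c: rep.f1[c] for c in cm.class_order},
        "overall_accuracy": rep.overall_accuracy,
        "n": rep.n,
    }


def run(config: PipelineConfig) -> RunManifest:
    """Execute every stage in order and return the run manifest."""
    t0 = time.time()
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.yaml").write_text(
            yaml.safe_dump(config.to_dict(), sort_keys=True))

    log.info("stage 1/5: cohort")
    cases, clinical, labels, cohort = _load_cohort_tables(config)
    if config.save_images and outdir and cohort is not None:
        from .phantom import write_cohort
        write_cohort(cohort, outdir / "cohort")

    log.info("stage 2/5: features (%d cases x %d segmentations)",
             len(cases), config.n_variants + 1)
    tables = _extract_tables(cases, config)
    if outdir:
        for k, t in enumerate(tables):
            t.to_csv(outdir / f"features_seg{k}.csv")
        clinical.to_csv(outdir / "clinical.csv")

    log.info("stage 3/5: split")
    plan = stratified_split(labels, config.split_ratio, config.seed)
    tr, va = plan.train_idx, plan.val_idx
    pids = list(tables[0].index)
    train_ids = [pids[i] for i in tr]
    val_ids = [pids[i] for i in va]

    log.info("stage 4/5: screening (training cohort)")
    sconf = ScreeningConfig(config.icc_threshold, config.corr_threshold,
                            config.alpha, config.boruta_alpha,
                            config.boruta_max_iter, config.boruta_trees,
                            seed=config.seed)
    report = screen_pipeline([t.loc[train_ids] for t in tables],
                             clinical.loc[train_ids], labels[tr], sconf)
    notes = list(report.notes)

    from .screening import encode_clinical
    selected = report.selected
    models_out: dict[str, dict] = {}
    if not selected:
        notes.append("empty selection; modeling skipped")
        log.warning("no feature confirmed; skipping model construction")
    else:
        log.info("stage 5/5: models on %d selected features", len(selected))
        sel_rad = [f for f in selected if f in tables[0].columns]
        sel_cli = [f for f in selected if f not in tables[0].columns]
        design = pd.concat([tables[0][sel_rad],
                            encode_clinical(clinical, sel_cli)], axis=1)
        Xtr = design.loc[train_ids]
        Xva = design.loc[val_ids]
        grids = _model_grids(config)
        order = tuple(c for c in DEFAULT_CLASS_ORDER if c in set(labels)) \
            or tuple(sorted(set(labels)))
        for kind in config.models:
            model = SubtypeClassifier(Xtr, labels[tr], kind=kind,
                                      grid=grids[kind], folds=config.folds,
                                      seed=config.seed)
            kwargs = {"ann_restarts": config.ann_restarts} if kind == "ann" else {}
            res = model.fit(**kwargs)
            cm_tr, rep_tr = res.evaluate(Xtr, labels[tr], class_order=order)
            cm_va, rep_va = res.evaluate(Xva, labels[va], class_order=order)
            block = {"spec": res.spec, "cv_points": len(res.cv_table),
                     "training": _metrics_block(cm_tr, rep_tr),
                     "validation": _metrics_block(cm_va, rep_va)}
            if kind == "rf" and "oob_trajectory" in res.classifier.extra:
                traj = res.classifier.extra["oob_trajectory"]
                block["oob_error_final"] = float(traj[-1])
                block["oob_trajectory_tail"] = [float(v) for v in traj[-20:]]
                if outdir:
                    np.savetxt(outdir / "rf_oob_trajectory.txt", traj)
            models_out[kind] = block
            log.info("%s: train OA %.4f / val OA %.4f", kind,
                     rep_tr.overall_accuracy, rep_va.overall_accuracy)

    manifest = RunManifest(
        config_hash=config.content_hash(), seed=config.seed,
        counts={"n_cases": len(cases),
                "n_features": tables[0].shape[1], **report.counts},
        selected_features=selected,
        split_counts={k: list(v) for k, v in plan.per_class.items()},
        models=models_out, notes=notes, elapsed_s=time.time() - t0,
    )
    if outdir:
        (outdir / "manifest.json").write_text(
            json.dumps(manifest.to_dict(), indent=2, default=str))
        screening_out = {
            "icc": {f: r.estimate for f, r in report.icc.items()},
            "feature_pvalues": report.feature_pvalues,
            "clinical_tests": {k: list(v) for k, v in report.clinical_tests.items()},
            "counts": report.counts,
            "selected": selected,
        }
        (outdir / "screening.json").write_text(
            json.dumps(screening_out, indent=2, default=str))
        (outdir / "report.txt").write_text(report_tables(manifest))
    return manifest


def _format_block(block: dict) -> list[str]:
    order = block["class_order"]
    head = "TP    " + "".join(f"{c:>6}" for c in order) + "     Pre     Rec      F1"
    lines = [head]
    cmat = np.asarray(block["confusion"])
    for i, c in enumerate(order):
        row = "".join(f"{int(v):>6}" for v in cmat[i])
        lines.append(
            f"{c:<6}{row}  {round_half_up(block['precision'][c]):.4f}  "
            f"{round_half_up(block['recall'][c]):.4f}  "
            f"{round_half_up(block['f1'][c]):.4f}")
    total = "".join(f"{int(v):>6}" for v in cmat.sum(axis=0))
    lines.append(f"Total {total}      OA  {round_half_up(block['overall_accuracy']):.4f}")
    return lines


def report_tables(manifest: RunManifest | dict) -> str:
    """Human-readable per-model tables (predicted x true counts + metrics)."""
    d = manifest.to_dict() if isinstance(manifest, RunManifest) else manifest
    if not d.get("models"):
        return "no models were trained (empty feature selection)\n"
    out = []
    for kind, block in d["models"].items():
        out.append(f"=== {kind.upper()} ===")
        for split in ("training", "validation"):
            if split not in block:
                out.append(f"[warning] missing {split} metrics")
                continue
            out.append(f"-- {split} --")
            out.extend(_format_block(block[split]))
        out.append("")
    return "\n".join(out)
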