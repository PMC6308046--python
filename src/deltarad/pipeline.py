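"""End-to-end orchestration: configuration, staging, reporting.

The pipeline mirrors the analytical workflow: (optional) voxel-path feature
extraction -> test/retest stability filtering on the training cohort ->
delta-feature construction -> per-size-class model search over selectors,
top-k, classifiers and SMOTE -> pooled overall statistics -> report.
Every stage writes its intermediate table so each reported number is
traceable, and a manifest records the configuration, seeds and versions.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .modeling import (
    CLASSIFIER_ORDER,
    SCHEMES,
    SELECTION_BIAS_NOTE,
    EvaluationResult,
    SearchCell,
    assign_size_class,
    default_grid,
    model_search,
    pool_results,
)
from .stability import delta_table, normalize_delta_names, stable_features

logger = logging.getLogger(__name__)

BASELINE_PREFIX = "T0 "


@dataclass
class RunConfig:
    """Validated settings for one full pipeline run.

    Defaults mirror the reference analysis: stability threshold 0.95,
    top-5/top-10 selection, SMOTE with 5 neighbours, and both the
    three-class and two-class size schemes.
    """

    t0_path: str = "features_t0.csv"
    t1_path: str = "features_t1.csv"
    design_path: str = "design.csv"
    out_dir: str = "deltarad_run"
    mode: str = "table"  # or "image": t0/t1 tables are extracted from images_dir
    images_dir: str | None = None
    stability_threshold: float = 0.95
    stability_on: str = "train"  # or "train_controls"
    schemes: tuple[str, ...] = ("three_class", "two_class")
    selectors: tuple[str, ...] = ("relieff", "cfs")
    ks: tuple[int, ...] = (5, 10)
    classifiers: tuple[str, ...] = CLASSIFIER_ORDER
    smote_options: tuple[bool, ...] = (False, True)
    seed: int = 0
    force: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("schemes", "selectors", "ks", "classifiers", "smote_options"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if self.mode not in ("table", "image"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "table":
            for p in (self.t0_path, self.t1_path, self.design_path):
                if not Path(p).exists():
                    raise FileNotFoundError(f"missing input: {p}")
        else:
            if self.images_dir is None or not Path(self.images_dir).exists():
                raise FileNotFoundError(f"missing images_dir: {self.images_dir}")
            if not Path(self.design_path).exists():
                raise FileNotFoundError(f"missing input: {self.design_path}")
        for s in self.schemes:
            if s not in SCHEMES:
                raise ValueError(f"unknown size scheme {s!r}")
        if not (0.0 < self.stability_threshold < 1.0):
            raise ValueError("stability_threshold must lie in (0, 1)")

    def to_dict(self) -> dict:
        return {k: list(v) if isinstance(v, tuple) else v
                for k, v in self.__dict__.items()}


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a subjects x features CSV (subject_id column or first column as index)."""
    df = pd.read_csv(path)
    idx = "subject_id" if "subject_id" in df.columns else df.columns[0]
    df = df.set_index(idx)
    df = df.drop(columns=[c for c in ("timepoint", "label", "cohort", "ld_mm") if c in df.columns])
    df.columns = normalize_delta_names(list(df.columns))
    return df


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValueError("design table requires a subject_id column")
    required = {"label", "cohort", "ld_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    return df.set_index("subject_id")


def _extract_tables_from_images(images_dir: str | Path, design: pd.DataFrame):
    from .images import load_nifti
    from .radiomics import extract_all_features

    images_dir = Path(images_dir)
    tables: dict[str, dict] = {"T0": {}, "T1": {}}
    for sid in design.index:
        for tp in ("T0", "T1"):
            img = load_nifti(images_dir / f"{sid}_{tp}_image.nii.gz", "image")
            mask = load_nifti(images_dir / f"{sid}_{tp}_mask.nii.gz", "mask")
            ctx = load_nifti(images_dir / f"{sid}_{tp}_context.nii.gz", "context")
            tables[tp][sid] = extract_all_features(img, mask, ctx)
    t0 = pd.DataFrame.from_dict(tables["T0"], orient="index")
    t1 = pd.DataFrame.from_dict(tables["T1"], orient="index")
    return t0, t1


def build_model_table(t0: pd.DataFrame, delta: pd.DataFrame) -> pd.DataFrame:
    """Combined design matrix: 'T0 '-prefixed baseline plus '∆ ' delta columns."""
    base = t0.copy()
    base.columns = [BASELINE_PREFIX + c for c in base.columns]
    return pd.concat([base, delta], axis=1)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the results dict written to JSON."""
    config.validate()
    out = Path(config.out_dir)
    results_path = out / "results.json"
    if results_path.exists() and not config.force:
        raise FileExistsError(f"{results_path} exists; pass force=True/--force to overwrite")
    out.mkdir(parents=True, exist_ok=True)

    timings: dict[str, float] = {}
    tic = time.perf_counter()
    design = read_design(config.design_path)
    if config.mode == "image":
        t0, t1 = _extract_tables_from_images(config.images_dir, design)
        t0.rename_axis("subject_id").to_csv(out / "features_t0_extracted.csv")
        t1.rename_axis("subject_id").to_csv(out / "features_t1_extracted.csv")
    else:
        t0 = read_feature_table(config.t0_path)
        t1 = read_feature_table(config.t1_path)
    missing = set(design.index) - set(t0.index)
    if missing:
        raise ValueError(f"subjects missing from T0 table: {sorted(missing)[:5]}")
    t0, t1 = t0.loc[design.index], t1.loc[design.index]
    timings["load"] = time.perf_counter() - tic

    # stability filter on the training cohort only (no test-set leakage)
    tic = time.perf_counter()
    train_ids = design.index[design["cohort"] == "train"]
    stab_ids = (
        design.index[(design["cohort"] == "train") & (design["label"] == "control")]
        if config.stability_on == "train_controls"
        else train_ids
    )
    report = stable_features(t0.loc[stab_ids], t1.loc[stab_ids], config.stability_threshold)
    report.to_csv(out / "stability.csv")
    stable = list(report.index[report["stable"]])
    if not stable:
        raise ValueError("no feature passed the stability filter")
    logger.info("%d/%d features stable at %.2f", len(stable), t0.shape[1],
                config.stability_threshold)
    delta = delta_table(t0[stable], t1[stable])
    delta.rename_axis("subject_id").to_csv(out / "delta.csv")
    X = build_model_table(t0[stable], delta)
    X.rename_axis("subject_id").to_csv(out / "model_table.csv")
    timings["stabilize_delta"] = time.perf_counter() - tic

    y = design["label"]
    test_ids = design.index[design["cohort"] == "test"]
    results: dict = {"schemes": {}, "note": SELECTION_BIAS_NOTE,
                     "n_stable_features": len(stable), "stable_features": stable}
    for scheme_name in config.schemes:
        tic = time.perf_counter()
        scheme = SCHEMES[scheme_name]
        strata = design["ld_mm"].map(lambda ld: assign_size_class(ld, scheme))
        scheme_out: dict = {"strata": {}, "pooled": {}}
        winners_by_kind: dict[str, list[EvaluationResult]] = {}
        for cls in scheme.class_names:
            tr = [s for s in train_ids if strata[s] == cls]
            te = [s for s in test_ids if strata[s] == cls]
            if not tr or not te:
                scheme_out["strata"][cls] = {"skipped": "empty stratum"}
                continue
            grid = default_grid(
                selectors=config.selectors, ks=config.ks,
                classifiers=config.classifiers, smote_options=config.smote_options,
                size_classes=(cls,), seed=config.seed,
            )
            cells = model_search(grid, X.loc[tr], y.loc[tr], X.loc[te], y.loc[te])
            cls_out = {}
            for (fk, _), cell in cells.items():
                if cell.winner is None:
                    cls_out[fk] = {"skipped": cell.skipped_reason}
                    continue
                cls_out[fk] = _winner_dict(cell)
                winners_by_kind.setdefault(fk, []).append(cell.winner)
            scheme_out["strata"][cls] = cls_out
        for fk, winners in winners_by_kind.items():
            pooled = pool_results(winners)
            scheme_out["pooled"][fk] = pooled.to_dict()
        results["schemes"][scheme_name] = scheme_out
        timings[f"search_{scheme_name}"] = time.perf_counter() - tic

    payload = json.dumps(results, indent=2, sort_keys=True)
    results_path.write_text(payload)
    # render from the serialised form so report.md and results.json agree
    (out / "report.md").write_text(write_report(json.loads(payload)))
    manifest = {
        "deltarad_version": __version__,
        "seed": config.seed,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return results


def _winner_dict(cell: SearchCell) -> dict:
    w = cell.winner
    d = w.to_dict()
    d["model"] = {
        "selector": w.spec.selector,
        "k": w.spec.k,
        "classifier": w.spec.classifier,
        "smote": w.spec.smote,
    }
    d["leaderboard_size"] = len(cell.leaderboard)
    return d


def _fmt(value, ci) -> str:
    if value is None:
        return "—"
    lo, hi = ci
    return f"{value:.2f} ({lo:.2f}–{hi:.2f})"


def write_report(results: dict) -> str:
    """Render the results dict as a Markdown report shaped like the final-model tables."""
    lines = ["# Delta-radiomics final models", "", f"> {results['note']}", ""]
    lines.append(f"Stable features retained: {results['n_stable_features']}")
    for scheme_name, scheme_out in results["schemes"].items():
        lines += ["", f"## Size scheme: {scheme_name}", ""]
        lines.append("| Feature kind | Size class | Model | Features | AUROC (95% CI) | "
                     "Accuracy (95% CI) | Specificity (95% CI) | Sensitivity (95% CI) |")
        lines.append("|---|---|---|---|---|---|---|---|")
        for cls, cls_out in scheme_out["strata"].items():
            if "skipped" in cls_out:
                lines.append(f"| — | {cls} | skipped: {cls_out['skipped']} | | | | | |")
                continue
            for fk, d in cls_out.items():
                if "skipped" in d:
                    lines.append(f"| {fk} | {cls} | skipped: {d['skipped']} | | | | | |")
                    continue
                model = d["model"]
                mdesc = (f"{model['selector']} top-{model['k']}, {model['classifier']}"
                         + (", SMOTE" if model["smote"] else ""))
                feats = "; ".join(d["features"])
                lines.append(
                    f"| {fk} | {cls} | {mdesc} | {feats} | "
                    f"{_fmt(d['auroc'], d['auroc_ci'])} | "
                    f"{_fmt(d['accuracy'], d['accuracy_ci'])} | "
                    f"{_fmt(d['specificity'], d['specificity_ci'])} | "
                    f"{_fmt(d['sensitivity'], d['sensitivity_ci'])} |"
                )
        for fk, d in scheme_out["pooled"].items():
            lines.append(
                f"| {fk} | overall (pooled) | — | — | "
                f"{_fmt(d['auroc'], d['auroc_ci'])} | "
                f"{_fmt(d['accuracy'], d['accuracy_ci'])} | "
                f"{_fmt(d['specificity'], d['specificity_ci'])} | "
                f"{_fmt(d['sensitivity'], d['sensitivity_ci'])} |"
            )
    lines.append("")
    return "\n".join(lines)
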