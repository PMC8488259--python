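"""End-to-end experiment orchestration driven by one configuration.

``run_experiment`` executes simulate -> extract -> evaluate -> compare ->
importance -> report, writing every intermediate artifact plus a manifest
that ties outputs to the configuration hash and seed.  Rerunning with the
same configuration reproduces the deterministic artifacts byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import evaluate as ev
from .classify import ModelSpec
from .cohort import CohortSpec, EffectProfile, generate_cohort
from .errors import ConfigurationError
from .extract import extract_cohort, read_feature_tables, write_feature_tables

log = logging.getLogger("gazespeech")


@dataclass(frozen=True)
class RunConfig:
    """All knobs of one experiment run, serialisable to YAML.

    The named constants of the study protocol (60-ms minimum fixation,
    250-ms pause threshold, correlation thresholds 0.85 / 0.2, 10 trees,
    k = 10 folds x 10 repeats) appear here with those defaults.
    """

    n_patients: int = 79
    n_controls: int = 83
    effect_scale: float = 1.0
    missing_gaze_fraction: float = 36 / 162
    seed: int = 0
    sampling_rate_hz: float = 120.0
    pupil_duration_ms: float = 10_000.0
    picture_duration_ms: float = 40_000.0
    memory_duration_ms: float = 45_000.0

    dispersion_px: float = 40.0
    min_fixation_ms: float = 60.0
    validity_threshold: float = 0.75
    min_pause_ms: float = 250.0

    cv_folds: int = 10
    cv_repeats: int = 10
    algorithms: tuple = ("GNB", "LR", "RF")
    r_pair: float = 0.85
    r_label: float = 0.2
    rf_n_trees: int = 10

    out_dir: str = "results/run"

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            n_patients=self.n_patients,
            n_controls=self.n_controls,
            effect_scale=self.effect_scale,
            missing_gaze_fraction=self.missing_gaze_fraction,
            seed=self.seed,
            sampling_rate_hz=self.sampling_rate_hz,
            pupil_duration_ms=self.pupil_duration_ms,
            picture_duration_ms=self.picture_duration_ms,
            memory_duration_ms=self.memory_duration_ms,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["algorithms"] = list(self.algorithms)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        if "algorithms" in raw:
            raw["algorithms"] = tuple(raw["algorithms"])
        return cls(**raw)


def _stage(name):
    log.info("stage: %s", name)


def run_simulate(config: RunConfig, out: Path, profile: EffectProfile | None = None):
    _stage("simulate")
    generate_cohort(config.cohort_spec(), profile or EffectProfile.default(),
                    out_dir=out / "cohort")


def run_extract(config: RunConfig, out: Path) -> dict:
    _stage("extract")
    extracted = extract_cohort(
        out / "cohort",
        validity_threshold=config.validity_threshold,
        dispersion_px=config.dispersion_px,
        min_fixation_ms=config.min_fixation_ms,
    )
    write_feature_tables(extracted, out)
    return extracted


def run_evaluate(config: RunConfig, out: Path, extracted: dict | None = None):
    _stage("evaluate")
    if extracted is None:
        extracted = read_feature_tables(out)
    records, predictions = ev.run_evaluation(
        extracted["features"], extracted["labels"], extracted["gaze_valid"],
        k=config.cv_folds, repeats=config.cv_repeats, seed=config.seed,
        algorithms=config.algorithms,
    )
    records.to_csv(out / "evaluation_records.csv", index=False)
    predictions.to_csv(out / "predictions.csv", index=False)
    ev.aggregate(records).to_csv(out / "results_matrix.csv", index=False)
    return records


def run_compare(config: RunConfig, out: Path, records: pd.DataFrame | None = None):
    _stage("compare")
    if records is None:
        records = pd.read_csv(out / "evaluation_records.csv")
    batteries = ev.hypothesis_batteries(records)
    batteries.to_csv(out / "comparisons.csv", index=False)
    return batteries


def run_importance(config: RunConfig, out: Path, extracted: dict | None = None,
                   top_n: int = 5):
    _stage("importance")
    if extracted is None:
        extracted = read_feature_tables(out)
    labels = extracted["labels"]
    y = (labels == "patient").astype(int)
    spec = ModelSpec("LR", r_pair=config.r_pair, r_label=config.r_label)
    blocks = []
    for (task, modality), X in extracted["features"].items():
        if modality == "eye":
            keep = extracted["gaze_valid"].reindex(X.index).fillna(False)
            X = X[keep.to_numpy()]
        yy = y.reindex(X.index)
        from .classify import cfs_select

        medians = X.median()
        Xi = X.fillna(medians).dropna(axis=1)  # drop all-missing columns
        selected = cfs_select(Xi, yy.to_numpy(), spec.r_pair, spec.r_label)
        if not selected:
            continue
        imp = ev.lr_importance(Xi[selected], yy.to_numpy(), spec)
        imp.insert(0, "task", task)
        imp.insert(1, "modality", modality)
        blocks.append(imp.head(top_n))
    table = pd.concat(blocks, ignore_index=True) if blocks else pd.DataFrame()
    table.to_csv(out / "importance.csv", index=False)
    return table


def write_report(out_dir) -> str:
    """Render a human-readable markdown report from run artifacts."""
    out = Path(out_dir)
    lines = ["# Multi-task classification report", ""]
    missing = []

    matrix_path = out / "results_matrix.csv"
    if matrix_path.exists():
        m = pd.read_csv(matrix_path)
        lines += ["## AUC matrix (mean +/- sd over repeats)", ""]
        algos = [a for a in ("GNB", "LR", "RF", "uniform") if a in set(m["algorithm"])]
        header = "| Feature set | " + " | ".join(algos) + " |"
        lines += [header, "|" + "---|" * (len(algos) + 1)]
        for model in m["model"].drop_duplicates():
            row = [model]
            for algo in algos:
                sel = m[(m["model"] == model) & (m["algorithm"] == algo)]
                row.append(
                    f"{sel['mean_auc'].iloc[0]:.3f} +/- {sel['sd'].iloc[0]:.3f}"
                    if len(sel) else ""
                )
            lines.append("| " + " | ".join(row) + " |")
        lines.append("")
    else:
        missing.append("results_matrix.csv")

    comp_path = out / "comparisons.csv"
    lines += ["## Hypothesis batteries", ""]
    if comp_path.exists():
        c = pd.read_csv(comp_path)
        if len(c):
            for b in ("H1", "H2", "H3"):
                sub = c[c["battery"] == b]
                n_sig = int(sub["significant"].sum()) if len(sub) else 0
                lines.append(f"- {b}: {n_sig}/{len(sub)} Tukey-adjusted pairs significant")
        else:
            lines.append("- not run")
    else:
        lines.append("- not run")
        missing.append("comparisons.csv")
    lines.append("")

    imp_path = out / "importance.csv"
    lines += ["## Top predictive features (LR Wald t)", ""]
    if imp_path.exists():
        imp = pd.read_csv(imp_path)
        for (task, modality), sub in imp.groupby(["task", "modality"], sort=False):
            lines.append(f"### {task} / {modality}")
            for _, r in sub.iterrows():
                ci = (f"({r['ci_low']:.3g}, {r['ci_high']:.3g})"
                      if r["ci_low"] == r["ci_low"] else "(separation)")
                lines.append(
                    f"- {r['feature']} [{r['direction']}] OR {r['odds_ratio']:.3g} {ci}"
                )
            lines.append("")
    else:
        missing.append("importance.csv")

    if missing:
        lines += ["## Missing artifacts", ""] + [f"- {m}" for m in missing]
    text = "\n".join(lines) + "\n"
    (out / "report.md").write_text(text)
    return text


def run_experiment(config: RunConfig, profile: EffectProfile | None = None) -> Path:
    """Execute all stages in order; returns the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    stages = []
    try:
        run_simulate(config, out, profile)
        stages.append("simulate")
        extracted = run_extract(config, out)
        stages.append("extract")
        records = run_evaluate(config, out, extracted)
        stages.append("evaluate")
        run_compare(config, out, records)
        stages.append("compare")
        run_importance(config, out, extracted)
        stages.append("importance")
        write_report(out)
        stages.append("report")
    except Exception as exc:
        raise type(exc)(
            f"[stage {len(stages) + 1} after {stages or 'start'}] {exc}"
        ) from exc
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": stages,
        "outputs": sorted(
            str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
        )[:50],
        "n_outputs": sum(1 for p in out.rglob("*") if p.is_file()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out
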