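"""End-to-end orchestration: extract -> select -> evaluate -> explain.

A :class:`PipelineConfig` (loadable from YAML) names the inputs, the
window/selection/bootstrap settings and the seeds; :func:`run_pipeline`
executes the four stages in order, writes every artifact under the output
directory and returns a :class:`RunReport`.  All randomness flows from the
named seeds, so a rerun with the same config reproduces every number
bit for bit; the config hash is embedded in every artifact for
provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, io, registry
from .annotation import annotate
from .attribution import AttributionResult, explain_case, explain_logistic_refit, global_importance
from .biomarkers import WindowConfig, extract_feature_table
from .errors import AdspeechError, StageError
from .modeling import MetricsReport, default_model_specs, evaluate_models
from .selection import SelectionResult, make_stratified_folds, stability_select
from .synthetic import (ad_speech_params, build_toy_frequency_tables,
                        chc_speech_params, generate_transcript_cohort)

log = logging.getLogger("adspeech")


@dataclass
class PipelineConfig:
    """Settings of one pipeline run.

    ``corpus``/``tables`` are file paths; leave them unset to simulate a
    synthetic cohort and toy tables from ``seed``.
    """

    out_dir: str = "adspeech_out"
    corpus: str | None = None
    tables: str | None = None
    seed: int = 0
    n_per_group: int = 22
    window: dict = field(default_factory=lambda: {"window_len": 50, "stride": 10,
                                                  "aggregate": "mean"})
    selection: dict = field(default_factory=lambda: {"k": 5, "m": 10,
                                                     "threshold": 0.6})
    bootstrap: dict = field(default_factory=lambda: {"B": 1000, "level": 0.95})
    cut: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in raw.items() if k in known})

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    """Everything one run produced, with provenance."""

    config: dict
    config_hash: str
    version: str
    feature_table_path: str
    selection: SelectionResult
    metrics: dict            # family -> MetricsReport
    attribution: AttributionResult
    waterfall: dict          # local explanation of one reference case

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "config_hash": self.config_hash,
            "version": self.version,
            "feature_table": self.feature_table_path,
            "selection": self.selection.to_dict(),
            "metrics": {k: v.to_dict() for k, v in self.metrics.items()},
            "attribution": self.attribution.to_dict(),
            "waterfall": self.waterfall,
        }


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except AdspeechError:
                raise
            except Exception as e:  # pragma: no cover - defensive
                raise StageError(name, str(e)) from e
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


@_stage("simulate")
def _load_or_simulate(cfg: PipelineConfig):
    if cfg.corpus is not None:
        records = io.read_corpus(io.require_exists(cfg.corpus, "corpus"))
    else:
        records = generate_transcript_cohort(
            ad_speech_params(), chc_speech_params(),
            n_per_group=cfg.n_per_group, seed=cfg.seed)
    if cfg.tables is not None:
        tables = io.read_frequency_tables(io.require_exists(cfg.tables,
                                                            "frequency tables"))
    else:
        tables = build_toy_frequency_tables(seed=cfg.seed + 1)
    return records, tables


@_stage("extract")
def _extract(cfg: PipelineConfig, records, tables) -> pd.DataFrame:
    anns, labels = [], []
    for r in records:
        ann = r.get("gold") or annotate(r["text"], id=r["id"])
        ann.id = r["id"]
        anns.append(ann)
        labels.append(r["label"])
    wcfg = WindowConfig(**cfg.window)
    return extract_feature_table(anns, labels, tables, wcfg)


@_stage("select")
def _select(cfg: PipelineConfig, features, labels) -> SelectionResult:
    return stability_select(features, labels, seed=cfg.seed,
                            **{k: cfg.selection[k] for k in ("k", "m", "threshold")})


@_stage("evaluate")
def _evaluate(cfg: PipelineConfig, features, labels, stable_set):
    folds = make_stratified_folds(labels, k=cfg.selection["k"], seed=cfg.seed)
    return evaluate_models(features, labels, stable_set,
                           model_specs=default_model_specs(), folds=folds,
                           seed=cfg.seed, bootstrap_B=cfg.bootstrap["B"])


@_stage("explain")
def _explain(features, labels, stable_set):
    attr = explain_logistic_refit(features, labels, stable_set)
    # reference local case: the participant with the highest final log-odds
    pid = attr.final_value.idxmax()
    waterfall = explain_case(attr.base_value, attr.phi.loc[pid].to_dict())
    waterfall["participant"] = str(pid)
    return attr, waterfall


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute all four stages and write the artifacts.

    Stage failures surface as :class:`StageError` carrying the stage name;
    artifacts written before the failure stay on disk flagged by the
    missing ``run_report.json``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, tables = _load_or_simulate(cfg)
    if cfg.corpus is None:
        io.write_corpus(records, out / "corpus.jsonl")
    if cfg.tables is None:
        io.write_frequency_tables(tables, out / "frequency_tables.tsv")

    table = _extract(cfg, records, tables)
    ft_path = out / "feature_table.csv"
    io.write_feature_table(table, ft_path)
    features, labels = io.split_feature_table(table)

    sel = _select(cfg, features, labels)
    io.write_json(sel.to_dict(), out / "selection.json")
    pd.Series(sel.frequency, name="frequency").rename_axis("feature") \
        .to_csv(out / "selection_frequency.csv")

    reports = _evaluate(cfg, features, labels, sel.stable_set)
    for fam, rep in reports.items():
        rep.oof.to_csv(out / f"predictions_{fam}.csv")
    attr, waterfall = _explain(features, labels, sel.stable_set)
    attr.phi.assign(base=attr.base_value, final=attr.final_value) \
        .rename_axis("id").to_csv(out / "shapley_phi.csv")
    global_importance(attr).to_csv(out / "global_importance.csv")

    report = RunReport(
        config=cfg.to_dict(), config_hash=cfg.hash(), version=__version__,
        feature_table_path=str(ft_path), selection=sel, metrics=reports,
        attribution=attr, waterfall=waterfall)
    io.write_json(report.to_dict(), out / "run_report.json")
    return report


# ---------------------------------------------------------------------------
# rendering


def render_report(report: RunReport) -> str:
    """Human-readable summary: metric table, pooled confusion matrix,
    global importance shares and the reference local waterfall."""
    lines = []
    lines.append(f"adspeech {report.version}  (config {report.config_hash})")
    lines.append("")
    lines.append(f"Stable feature set ({len(report.selection.stable_set)} of "
                 f"{registry.N_BIOMARKERS}, threshold "
                 f">={report.selection.threshold:g}): "
                 + ", ".join(report.selection.stable_set))
    lines.append("")
    hdr = f"{'model':<20}" + "".join(f"{m:>28}" for m in
                                     ("accuracy", "f1", "auroc"))
    lines.append(hdr)
    for fam, rep in report.metrics.items():
        row = f"{fam:<20}"
        for m in ("accuracy", "f1", "auroc"):
            lo, hi = rep.ci[m]
            row += f"{rep.mean[m]:.3f}+/-{rep.sd[m]:.3f} [{lo:.2f},{hi:.2f}]".rjust(28)
        lines.append(row)
    lines.append("")
    ref = report.metrics.get("logistic_regression") or next(iter(report.metrics.values()))
    c = ref.pooled_confusion
    lines.append(f"Pooled confusion ({ref.family}):  TP={c.TP}  FN={c.FN}  "
                 f"FP={c.FP}  TN={c.TN}")
    lines.append("")
    lines.append("Global importance (mean |phi|, % share):")
    imp = global_importance(report.attribution)
    for feat, row in imp.iterrows():
        lines.append(f"  {int(row['rank']):>2}. {feat:<8} {row['mean_abs_phi']:.3f}"
                     f"  ({row['share_pct']:.1f}%)")
    lines.append("")
    w = report.waterfall
    lines.append(f"Local explanation ({w.get('participant', '?')}): "
                 f"base {w['base']:+.2f}")
    for s in w["steps"]:
        lines.append(f"    {s['feature']:<8} {s['phi']:+.2f}  -> {s['cumulative']:+.2f}")
    lines.append(f"  final log-odds {w['final']:+.2f}")
    return "\n".join(lines)
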