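"""End-to-end run orchestration: config, staged execution, artifacts, manifest.

A run takes a dataset (either files — annotation, bedGraph tracks, expression
table — or the bundled simulator), executes the staged pipeline

    D1/D2 split -> bestbin on D1 -> pseudocount on D1 ->
    ten-fold CV on D2 -> evaluation -> importance

and writes a self-describing run directory: metrics, model JSON, importance
and prediction tables, the split, a human-readable log, and a manifest with
content hashes of every input.  All randomness flows from the single master
seed via fixed per-stage offsets, so re-running a config reproduces every
artifact byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .annotation import filter_by_length, read_transcript_annotation
from .binning import BinnedFeatureMatrix, build_bin_layout, read_track, summarize_track
from .expression import ExpressionTable
from .importance import ImportanceReport
from .model import (
    DEFAULT_N_TREES,
    FeatureTransform,
    crossvalidate,
    fit_two_step,
    make_split,
)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    outdir: str
    seed: int = 0
    simulate: dict | None = None          # {"n": ..., "zero_fraction": ..., ...}
    annotation: str | None = None
    tracks: dict[str, str] = field(default_factory=dict)   # feature -> path
    expression: str | None = None
    layout_mode: str = "tx81"
    strategy: str = "bestbin"
    grid_size: int = 50
    method: str = "linear"
    n_estimators: int = DEFAULT_N_TREES
    min_length: int = 4100

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            cfg = cls(**raw)
        except TypeError as exc:
            raise ValueError(f"invalid config {path}: {exc}") from exc
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.simulate is None:
            missing = []
            if not self.annotation or not Path(self.annotation).exists():
                missing.append(f"annotation: {self.annotation!r}")
            for feat, p in self.tracks.items():
                if not Path(p).exists():
                    missing.append(f"track {feat}: {p!r}")
            if not self.expression or not Path(self.expression).exists():
                missing.append(f"expression: {self.expression!r}")
            if missing:
                raise FileNotFoundError(
                    "config validation failed; missing inputs: " + "; ".join(missing)
                )
        if self.method not in ("linear", "rf"):
            raise ValueError(f"unsupported method {self.method!r}")
        if self.layout_mode not in ("tx81", "tss41"):
            raise ValueError(f"unsupported layout mode {self.layout_mode!r}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_file_dataset(config: RunConfig, log: list[str]):
    transcripts = read_transcript_annotation(config.annotation)
    transcripts = filter_by_length(transcripts, config.min_length)
    log.append(f"annotation: {len(transcripts)} transcripts after length filter")
    expr = ExpressionTable.from_tsv(config.expression)
    keep = [tx for tx in transcripts if tx.gene_id in expr.ids]
    layouts = {tx.gene_id: build_bin_layout(tx, config.layout_mode) for tx in keep}
    binned = {}
    for feat, path in config.tracks.items():
        track = read_track(path)
        rows = {gid: summarize_track(track, lay) for gid, lay in layouts.items()}
        binned[feat] = pd.DataFrame.from_dict(rows, orient="index")
        log.append(f"track {feat}: binned {len(rows)} genes x {config.layout_mode}")
    y = expr.values.loc[list(layouts)]
    return binned, y


def run_pipeline(config: RunConfig) -> Path:
    """Execute the staged pipeline and write the run directory.

    Returns the output directory.  Any stage error aborts the run with the
    stage name in the exception message.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"chromtx run (seed={config.seed}, method={config.method})"]
    inputs: dict[str, str] = {}

    stage = "load"
    try:
        if config.simulate is not None:
            from .simulate import simulate_dataset

            sim_kw = dict(config.simulate)
            n = int(sim_kw.pop("n", 1000))
            ds = simulate_dataset(n=n, seed=config.seed, **sim_kw)
            binned, y = ds.binned, ds.y
            log.append(
                f"simulate: n={n} zero_fraction={ds.achieved['zero_fraction']:.3f} "
                f"achievable_r={ds.achieved['achievable_r']:.3f}"
            )
            inputs["simulate"] = hashlib.sha256(
                json.dumps(config.simulate, sort_keys=True).encode()
            ).hexdigest()
        else:
            binned, y = _load_file_dataset(config, log)
            inputs = {
                "annotation": _sha256(config.annotation),
                "expression": _sha256(config.expression),
                **{f"track:{k}": _sha256(v) for k, v in config.tracks.items()},
            }

        stage = "split"
        plan = make_split(list(y.index), seed=config.seed + 1)
        log.append(f"split: |D1|={len(plan.d1_ids)} |D2|={len(plan.d2_ids)} folds=10")
        (outdir / "split.json").write_text(
            json.dumps(
                {
                    "seed": plan.seed,
                    "d1_ids": list(map(str, plan.d1_ids)),
                    "folds": [list(map(str, f)) for f in plan.folds],
                },
                indent=None,
            )
        )

        stage = "transform"
        ft = FeatureTransform(strategy=config.strategy, grid_size=config.grid_size)
        ft.fit(binned, y, plan.d1_ids)
        X = ft.transform(binned)
        for name in ft.feature_names:
            spec = ft.bin_specs[name]
            log.append(
                f"transform {name}: bins={spec.selected_bins} "
                f"r={spec.selection_correlation:.3f} a={ft.pseudocounts[name].a:.4g}"
            )

        stage = "crossvalidate"
        cv = crossvalidate(
            X, y, plan, method=config.method, seed=config.seed + 2,
            n_estimators=config.n_estimators,
        )
        log.append(
            f"cv: pooled r={cv.result.pcc_r:.4f} rmse={cv.result.rmse:.4f} "
            f"auc={cv.result.auc:.4f}"
        )
        preds = pd.DataFrame(
            {"measured": y.loc[cv.predictions.index], "predicted_log2": cv.predictions,
             "on_vote": cv.proba}
        )
        preds.rename_axis("gene_id").to_csv(outdir / "predictions.tsv", sep="\t")
        pd.DataFrame([cv.result.as_dict()]).to_csv(
            outdir / "metrics.tsv", sep="\t", index=False
        )

        stage = "fit-final"
        d2 = pd.Index(plan.d2_ids)
        res = fit_two_step(
            X.loc[d2], y.loc[d2], method=config.method, seed=config.seed + 3,
            n_estimators=config.n_estimators,
        )
        model_payload = {
            "feature_names": res.feature_names,
            "method": config.method,
            "seed": config.seed,
            "transform": ft.to_dict(),
            "regressor": (
                {k: float(v) for k, v in res.params.items()}
                if config.method == "linear"
                else {"type": "random_forests", "n_estimators": config.n_estimators}
            ),
        }
        (outdir / "model.json").write_text(json.dumps(model_payload, indent=1))

        stage = "importance"
        report = ImportanceReport.from_results(res)
        report.to_frame().to_csv(outdir / "importance.tsv", sep="\t")
        log.append("importance: " + report.regressor_method + " written")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "inputs": inputs,
        "seed": config.seed,
        "artifacts": sorted(
            [p.name for p in outdir.iterdir() if p.name != "manifest.json"]
            + ["run.log"]
        ),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (outdir / "run.log").write_text("\n".join(log) + "\n")
    return outdir
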