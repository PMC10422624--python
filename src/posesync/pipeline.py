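"""End-to-end pipeline: simulate → sync → join → analyze → train.

Each stage is a plain function over files so the CLI stays thin; the
``run_pipeline`` driver chains them, logs row counts, and writes a
manifest that makes a run reproducible from its config and seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cnn import build_model, evaluate as cnn_evaluate, train as cnn_train
from .emotions import EMOTIONS, JoinedDataset, SYNC_COLUMNS, join, read_fer_csv, write_fer_csv
from .simulate import SyncScenario, generate_emotion_series, generate_pose_sequence
from .skeleton import parse_keypoint_frames, write_keypoint_frames
from .stats import (
    minmax_normalize,
    pearson_matrix,
    smote_oversample,
    stepwise_forward,
    stratified_kfold,
)
from .synchrony import MetricVariant, synchrony_dataframe, synchrony_timeseries

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable configuration of one full pipeline run."""

    out_dir: str = "posesync_run"
    n_persons: int = 3
    n_seconds: int = 120
    fps: float = 5.0
    sync_level: float = 0.6
    jitter_deg: float = 3.0
    dropout: float = 0.0
    coupling: float = 8.0
    mapping: str = "perpendicular"
    sides: str = "same"
    c_min: float = 0.1
    p_enter: float = 0.05
    smote_k: int = 5
    kfold: int = 3
    seed: int = 0
    paper_mode: bool = False  # SMOTE before the split instead of train-only

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def stage_simulate(cfg: RunConfig, frames_path: Path, fer_path: Path) -> dict:
    scenario = SyncScenario(
        n_persons=cfg.n_persons, n_seconds=cfg.n_seconds, fps=cfg.fps,
        sync_level=cfg.sync_level, jitter_deg=cfg.jitter_deg,
        dropout=cfg.dropout, seed=cfg.seed,
    )
    seq = generate_pose_sequence(scenario)
    frames_path.write_text(write_keypoint_frames(seq))
    metric = MetricVariant(cfg.mapping, cfg.sides)
    series = synchrony_timeseries(seq, metric)
    emotions = generate_emotion_series(
        series, coupling=cfg.coupling, seed=cfg.seed + 1
    )
    write_fer_csv(emotions, fer_path)
    return {"frames": len(seq), "seconds": len(series)}


def stage_sync(cfg: RunConfig, frames_path: Path, sync_path: Path) -> dict:
    seq = parse_keypoint_frames(frames_path.read_text(), c_min=cfg.c_min)
    metric = MetricVariant(cfg.mapping, cfg.sides)
    df = synchrony_dataframe(seq, metric)
    df.to_csv(sync_path, index=False)
    return {"rows": len(df)}


def stage_join(cfg: RunConfig, fer_path: Path, sync_path: Path,
               dataset_path: Path) -> dict:
    emotions = read_fer_csv(fer_path)
    sync_df = pd.read_csv(sync_path)
    ds = join(emotions, sync_df)
    out = ds.to_frame()
    probs = pd.DataFrame(
        [{"t": s.t, **{e: s.probs[e] for e in EMOTIONS}} for s in emotions]
    )
    out = out.merge(probs, on="t", how="left")
    out.to_csv(dataset_path, index=False)
    return {"rows": len(out)}


def stage_analyze(cfg: RunConfig, dataset_path: Path, report_dir: Path,
                  heatmap: bool = True) -> dict:
    report_dir.mkdir(parents=True, exist_ok=True)
    df = pd.read_csv(dataset_path)
    X = df[list(SYNC_COLUMNS)]
    emo_cols = [e for e in EMOTIONS if e in df.columns]
    if not emo_cols:
        raise ValueError("dataset has no emotion-probability columns to analyze")
    Y = df[emo_cols]
    r, p, n = pearson_matrix(X, Y)
    r.to_csv(report_dir / "correlation_r.csv")
    p.to_csv(report_dir / "correlation_p.csv")
    # Bonferroni column emitted for reference; decisions use raw p.
    (p * p.size).clip(upper=1.0).to_csv(report_dir / "correlation_p_bonferroni.csv")
    report = stepwise_forward(X, df["disgusted"], p_enter=cfg.p_enter)
    table = report.table.copy()
    table.index.name = "Model"
    table.columns = ["B", "Std. Error", "Beta", "t", "Sig."]
    table.to_csv(report_dir / "regression_disgusted.csv")
    (report_dir / "regression_summary.json").write_text(json.dumps(
        {"selected": report.selected, "adj_r2": report.adj_r2,
         "path": report.path}, indent=2))
    if heatmap:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(7, 6))
        im = ax.imshow(r.to_numpy(dtype=float), vmin=-1, vmax=1, cmap="vlag"
                       if "vlag" in plt.colormaps() else "coolwarm")
        ax.set_xticks(range(len(r.columns)), r.columns, rotation=45, ha="right")
        ax.set_yticks(range(len(r.index)), r.index, fontsize=7)
        fig.colorbar(im, ax=ax, label="Pearson r")
        fig.tight_layout()
        fig.savefig(report_dir / "correlation_heatmap.png", dpi=120)
        plt.close(fig)
    return {"rows": int(len(df)), "selected": len(report.selected),
            "adj_r2": report.adj_r2}


def prepare_training_sets(df: pd.DataFrame, cfg: RunConfig,
                          fold_index: int = 0):
    """Min-max scale, split stratified, SMOTE-balance.

    Default order is split-then-balance (SMOTE on the training fold
    only, avoiding leakage of synthetic points into the test fold);
    ``paper_mode`` balances the full dataset before splitting.
    """
    counts = df["label"].value_counts()
    rare = counts[counts < cfg.kfold].index
    if len(rare):
        log.info("dropping %d rows of label(s) too rare to stratify: %s",
                 int(counts[rare].sum()), list(rare))
        df = df[~df["label"].isin(rare)].reset_index(drop=True)
    X = df[list(SYNC_COLUMNS)]
    y = df["label"]
    X_scaled, _ = minmax_normalize(X)
    if cfg.paper_mode:
        Xb, yb = smote_oversample(X_scaled, y, k=cfg.smote_k, seed=cfg.seed)
        folds = stratified_kfold(yb, K=cfg.kfold, seed=cfg.seed)
        tr, te = folds.split(fold_index)
        return Xb.iloc[tr], yb.iloc[tr], Xb.iloc[te], yb.iloc[te]
    folds = stratified_kfold(y, K=cfg.kfold, seed=cfg.seed)
    tr, te = folds.split(fold_index)
    Xb, yb = smote_oversample(
        X_scaled.iloc[tr], y.iloc[tr], k=cfg.smote_k, seed=cfg.seed
    )
    return Xb, yb, X_scaled.iloc[te], y.iloc[te]


def stage_train(cfg: RunConfig, dataset_path: Path, model_dir: Path,
                figures: bool = True) -> dict:
    model_dir.mkdir(parents=True, exist_ok=True)
    df = pd.read_csv(dataset_path)
    X_tr, y_tr, X_te, y_te = prepare_training_sets(df, cfg)
    model = build_model(n_features=len(SYNC_COLUMNS),
                        n_classes=max(3, y_tr.nunique()), seed=cfg.seed)
    hist = cnn_train(model, X_tr.to_numpy(), list(y_tr),
                     X_te.to_numpy(), list(y_te), seed=cfg.seed)
    acc, confusion = cnn_evaluate(model, X_te.to_numpy(), list(y_te))
    pd.DataFrame({
        "epoch": range(1, len(hist) + 1),
        "train_loss": hist.train_loss, "train_acc": hist.train_acc,
        "test_loss": hist.test_loss, "test_acc": hist.test_acc,
    }).to_csv(model_dir / "history.csv", index=False)
    pd.DataFrame(confusion, index=model.classes_,
                 columns=model.classes_).to_csv(model_dir / "confusion.csv")
    np.savez(model_dir / "weights.npz", **model.params)
    if figures:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        epochs = range(1, len(hist) + 1)
        axes[0].plot(epochs, hist.train_acc, label="train")
        axes[0].plot(epochs, hist.test_acc, label="test")
        axes[0].set_xlabel("epoch"); axes[0].set_ylabel("accuracy")
        axes[0].legend()
        axes[1].plot(epochs, hist.train_loss, label="train")
        axes[1].plot(epochs, hist.test_loss, label="test")
        axes[1].set_xlabel("epoch"); axes[1].set_ylabel("loss")
        axes[1].legend()
        fig.tight_layout()
        fig.savefig(model_dir / "curves.png", dpi=120)
        plt.close(fig)
    return {"train_rows": len(X_tr), "test_rows": len(X_te),
            "test_accuracy": acc}


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every stage in order; write artifacts and a manifest.

    Any stage failure aborts with the stage name attached.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = out / "frames.json"
    fer = out / "fer.csv"
    sync = out / "sync.csv"
    dataset = out / "dataset.csv"
    manifest: dict = {
        "posesync_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "stages": {},
    }
    stages = [
        ("simulate", lambda: stage_simulate(cfg, frames, fer)),
        ("sync", lambda: stage_sync(cfg, frames, sync)),
        ("join", lambda: stage_join(cfg, fer, sync, dataset)),
        ("analyze", lambda: stage_analyze(cfg, dataset, out / "report")),
        ("train", lambda: stage_train(cfg, dataset, out / "model")),
    ]
    for name, fn in stages:
        log.info("pipeline stage: %s", name)
        try:
            manifest["stages"][name] = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
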