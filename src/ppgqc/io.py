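"""Dataset files, model checkpoints, plots and experiment orchestration.

Dataset dialect: comma-delimited text, one signal per row —
``id,label,fs,s0,s1,...`` with a header row.  Values are written with
17 significant digits so a write/read round trip is bit-exact for finite
samples.  A sidecar ``<path>.meta`` file records provenance (seed and
generation settings) as plain ``key=value`` lines.

``run_experiment`` ties the whole pipeline together: generate or load,
preprocess, stratified 40/30/30 split, train (with early stopping and
best-epoch checkpointing), evaluate on the held-out test set, and write a
metrics report, an ROC-point table, a checkpoint and a log — every stage
seeded from the run seed.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .architectures import ModelConfig, build_model, count_trainable_parameters
from .kan import SplineSpec
from .nn import Network
from .preprocess import PreprocessConfig, preprocess_dataset, preprocess_pipeline
from .signal import LabeledDataset, Signal
from .synthetic import generate_dataset
from .train import TrainConfig, evaluate_scores, stratified_split, train

__all__ = [
    "read_dataset",
    "write_dataset",
    "save_checkpoint",
    "load_checkpoint",
    "plot_signal",
    "RunConfig",
    "run_experiment",
]


def write_dataset(dataset: LabeledDataset, path, metadata: dict | None = None) -> None:
    """Write a labeled dataset as delimited text, one signal per row."""
    path = Path(path)
    if len(dataset) == 0:
        raise ValueError("refusing to write an empty dataset")
    lengths = {len(s) for s in dataset.signals}
    if len(lengths) != 1:
        raise ValueError(f"signals have inconsistent lengths: {sorted(lengths)}")
    n = lengths.pop()
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "label", "fs"] + [f"s{i}" for i in range(n)])
        for s in dataset.signals:
            writer.writerow(
                [s.id, s.label, f"{s.fs:.17g}"] + [f"{v:.17g}" for v in s.samples]
            )
    if metadata:
        meta_path = path.with_name(path.name + ".meta")
        with meta_path.open("w") as fh:
            for key, value in metadata.items():
                fh.write(f"{key}={value}\n")


def read_dataset(path) -> LabeledDataset:
    """Read a dataset file written by :func:`write_dataset`.

    Malformed rows, unknown labels and non-finite samples are rejected
    with the offending row index in the error message.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise ValueError(f"{path}: empty dataset file")
    header = rows[0]
    if len(header) < 4 or header[:3] != ["id", "label", "fs"]:
        raise ValueError(f"{path}: malformed header {header[:4]}")
    signals = []
    for i, row in enumerate(rows[1:], start=1):
        if len(row) != len(header):
            raise ValueError(
                f"{path}: row {i} has {len(row)} fields, expected {len(header)}"
            )
        sig_id, label_str, fs_str = row[0], row[1], row[2]
        try:
            label = int(label_str)
        except ValueError:
            raise ValueError(f"{path}: row {i} has non-integer label {label_str!r}") from None
        if label not in (1, 2, 3):
            raise ValueError(f"{path}: row {i} has unknown label {label}")
        samples = np.array(row[3:], dtype=np.float64)
        if not np.all(np.isfinite(samples)):
            raise ValueError(f"{path}: row {i} contains non-finite samples")
        signals.append(Signal(samples=samples, fs=float(fs_str), label=label, id=sig_id))
    if not signals:
        raise ValueError(f"{path}: dataset contains a header but no signals")
    return LabeledDataset(signals)


def _config_to_json(cfg) -> str:
    def default(obj):
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        raise TypeError(f"not serializable: {type(obj)}")

    return json.dumps(dataclasses.asdict(cfg), default=default)


def _model_config_from_dict(d: dict) -> ModelConfig:
    d = dict(d)
    spec = d.pop("kan_spec")
    d["kan_spec"] = SplineSpec(**spec)
    d["ff_dims"] = tuple(d["ff_dims"])
    return ModelConfig(**d)


def save_checkpoint(path, network: Network, model_config: ModelConfig,
                    metadata: dict | None = None) -> None:
    """Single-archive checkpoint: config JSON + named parameter tensors."""
    state = network.state_dict()
    np.savez(
        path,
        __config__=np.array(_config_to_json(model_config)),
        __metadata__=np.array(json.dumps(metadata or {})),
        **state,
    )


def load_checkpoint(path) -> tuple[Network, ModelConfig, dict]:
    """Rebuild the network from a checkpoint archive."""
    with np.load(path, allow_pickle=False) as archive:
        cfg = _model_config_from_dict(json.loads(str(archive["__config__"])))
        metadata = json.loads(str(archive["__metadata__"]))
        state = {k: archive[k] for k in archive.files if not k.startswith("__")}
    network = build_model(cfg, np.random.default_rng(0))
    network.load_state_dict(state)
    return network, cfg, metadata


def plot_signal(signal: Signal, before: Signal | None = None, path=None):
    """Render amplitude versus time; optionally a before/after panel pair."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if len(signal) == 0:
        raise ValueError("cannot plot an empty signal")
    n_panels = 2 if before is not None else 1
    fig, axes = plt.subplots(n_panels, 1, sharex=True, figsize=(8, 3 * n_panels))
    axes = np.atleast_1d(axes)
    if before is not None:
        axes[0].plot(before.times, before.samples, lw=0.7)
        axes[0].set_title(f"before ({before.fs:g} Hz)")
        axes[0].set_ylabel("amplitude")
    ax = axes[-1]
    ax.plot(signal.times, signal.samples, lw=0.7)
    ax.set_title(f"{signal.id or 'signal'} ({signal.fs:g} Hz)")
    ax.set_xlabel("time [s]")
    ax.set_ylabel("amplitude")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=110)
        plt.close(fig)
    return fig


@dataclass(frozen=True)
class RunConfig:
    """Everything one end-to-end experiment needs, seeded once."""

    seed: int = 0
    family: str = "cnn_kan"
    data_path: str | None = None  # load this dataset instead of generating
    n_good: int = 300
    n_fair: int = 150
    n_poor: int = 150
    fs: float = 512.0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model_overrides: dict = field(default_factory=dict)
    train: TrainConfig = field(default_factory=TrainConfig)
    out_dir: str = "ppgqc-run"


def run_experiment(cfg: RunConfig) -> dict:
    """Generate-or-load, preprocess, split, train, evaluate, write artifacts.

    Returns the report dict; also writes ``report.tsv`` (metric/value rows
    including the trainable-parameter count and the seed), ``roc.tsv``,
    ``checkpoint.npz`` and ``run.log`` under ``cfg.out_dir``.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(f"[{time.strftime('%H:%M:%S')}] {msg}")

    def fail(stage: str, exc: Exception):
        (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
        raise RuntimeError(f"experiment failed in stage {stage!r}: {exc}") from exc

    try:
        if cfg.data_path is not None:
            raw = read_dataset(cfg.data_path)
            log(f"loaded {len(raw)} signals from {cfg.data_path}")
        else:
            raw = generate_dataset(cfg.n_good, cfg.n_fair, cfg.n_poor,
                                   fs=cfg.fs, seed=cfg.seed)
            log(f"generated {len(raw)} synthetic signals (seed {cfg.seed})")
    except Exception as exc:
        fail("load", exc)

    try:
        processed = preprocess_dataset(raw, cfg.preprocess)
        log(f"preprocessed to {cfg.preprocess.target_fs:g} Hz, "
            f"{len(processed.signals[0])} samples/segment")
    except Exception as exc:
        fail("preprocess", exc)

    try:
        train_ds, val_ds, test_ds = stratified_split(
            processed, cfg.train.split_fractions, seed=cfg.seed
        )
        log(f"split {len(train_ds)}/{len(val_ds)}/{len(test_ds)} (train/val/test)")
    except Exception as exc:
        fail("split", exc)

    try:
        model_cfg = ModelConfig.for_family(
            cfg.family, input_length=len(processed.signals[0]), **cfg.model_overrides
        )
        network = build_model(model_cfg, np.random.default_rng(cfg.seed))
        n_params = count_trainable_parameters(network)
        log(f"built {cfg.family} with {n_params} trainable parameters")
        network, history = train(
            network,
            (train_ds.as_matrix(), train_ds.binary_labels),
            (val_ds.as_matrix(), val_ds.binary_labels),
            dataclasses.replace(cfg.train, seed=cfg.seed),
        )
        log(f"trained for {history['stopped_epoch']} epochs; "
            f"best epoch {history['best_epoch']} "
            f"(val loss {history['best_val_loss']:.4f})")
    except Exception as exc:
        fail("train", exc)

    try:
        scores = network.scores(test_ds.as_matrix())
        metrics = evaluate_scores(test_ds.binary_labels, scores, cfg.train.threshold)
        log("evaluated on test set: "
            + ", ".join(f"{k}={v:.4f}" for k, v in metrics.as_dict().items()))
    except Exception as exc:
        fail("evaluate", exc)

    report = {
        "family": cfg.family,
        "seed": cfg.seed,
        "n_parameters": n_params,
        "n_train": len(train_ds),
        "n_val": len(val_ds),
        "n_test": len(test_ds),
        "best_epoch": history["best_epoch"],
        "epochs_run": history["stopped_epoch"],
        **metrics.as_dict(),
    }

    with (out_dir / "report.tsv").open("w") as fh:
        for key, value in report.items():
            fh.write(f"{key}\t{value}\n")
        fh.write(f"config\t{_config_to_json(model_cfg)}\n")
    with (out_dir / "roc.tsv").open("w") as fh:
        fh.write("fpr\ttpr\n")
        for fpr, tpr in metrics.roc_points:
            fh.write(f"{fpr:.6f}\t{tpr:.6f}\n")
    save_checkpoint(
        out_dir / "checkpoint.npz", network, model_cfg,
        metadata={"seed": cfg.seed, "best_epoch": history["best_epoch"],
                  "best_val_loss": history["best_val_loss"]},
    )
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return report
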