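"""Joint training, stratified splitting, metrics and the ablation driver."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nn
from .headpos import gaze_coordinates, near_singularity
from .model import BPPVModel, ModelConfig
from .preprocess import assemble_input
from .simulate import LABELS, SimulatorConfig, generate_case, DATASET_PROTOCOL


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30            # reference runs use 1000
    lr: float = 0.01
    batch_size: int = 20
    lambda_penalty: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 0 or self.batch_size <= 0:
            raise ValueError("epochs must be >= 0 and batch_size positive")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.lambda_penalty < 0:
            raise ValueError("lambda_penalty must be >= 0")


# ---------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------

@dataclass
class ArrayDataset:
    """In-memory model-ready dataset."""

    clips: np.ndarray         # (N, 6, 300, H, W) uint8
    positions: np.ndarray     # (N, 6, 2) normalised
    gaze_targets: np.ndarray  # (N, 6, 3)
    labels: np.ndarray        # (N,) int class indices
    label_names: tuple[str, ...] = LABELS

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx) -> "ArrayDataset":
        idx = np.asarray(idx)
        return ArrayDataset(self.clips[idx], self.positions[idx],
                            self.gaze_targets[idx], self.labels[idx],
                            self.label_names)


def safe_gaze_target(main_deg: float, aux_deg: float) -> np.ndarray:
    """Gaze coordinates with the main angle nudged off tan singularities."""
    theta = math.radians(main_deg)
    phi = math.radians(aux_deg)
    if near_singularity(theta):
        theta += 2e-3
    return gaze_coordinates(theta, phi).as_array()


def build_dataset(n_per_class: dict[str, int] | int, seed: int = 0,
                  sim_config: SimulatorConfig | None = None,
                  protocol=DATASET_PROTOCOL) -> ArrayDataset:
    """Simulate, preprocess and stack `n_per_class` cases per label."""
    sim_config = sim_config or SimulatorConfig()
    if isinstance(n_per_class, int):
        n_per_class = {label: n_per_class for label in LABELS}
    rng = np.random.default_rng(seed)
    clips, positions, targets, labels = [], [], [], []
    for ci, label in enumerate(LABELS):
        for _ in range(n_per_class.get(label, 0)):
            case = generate_case(label, protocol,
                                 seed=int(rng.integers(0, 2**31 - 1)),
                                 config=sim_config)
            std = assemble_input(case)
            clips.append(std.clips)
            positions.append(std.positions)
            targets.append(np.stack([
                safe_gaze_target(p[0] * 360.0, p[1] * 360.0)
                for p in std.positions]))
            labels.append(ci)
    return ArrayDataset(np.stack(clips), np.stack(positions),
                        np.stack(targets), np.asarray(labels, dtype=np.intp))


# ---------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------

def split_indices(labels: np.ndarray, ratio: float = 0.8,
                  seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Per-class stratified split; the train side takes ceil(ratio * n_c)."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise ValueError(
                f"class {cls} has {len(idx)} case(s); need >= 2 to split")
        idx = rng.permutation(idx)
        n_train = math.ceil(ratio * len(idx))
        train.extend(idx[:n_train])
        test.extend(idx[n_train:])
    return np.sort(np.asarray(train)), np.sort(np.asarray(test))


def split_dataset(manifest: pd.DataFrame, ratio: float = 0.8,
                  seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified 8:2 split of a segment manifest by case.

    Returns (train_manifest, test_manifest); every class must be present
    with at least two cases.
    """
    cases = manifest[["case_id", "label"]].drop_duplicates("case_id")
    tr_idx, te_idx = split_indices(cases["label"].to_numpy(), ratio, seed)
    train_ids = set(cases["case_id"].to_numpy()[tr_idx])
    in_train = manifest["case_id"].isin(train_ids)
    return manifest[in_train].copy(), manifest[~in_train].copy()


# ---------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------

def joint_loss(logits, labels, lambda_penalty: float = 1.0,
               positions: np.ndarray | None = None,
               gaze_targets: np.ndarray | None = None,
               encoder=None, decoder=None) -> nn.Tensor:
    """Cross entropy plus the autoencoder reconstruction penalty.

    loss = CE(logits, labels) + lambda * MSE(decode(encode(pos)), gaze)
    The penalty term is skipped when no encoder/decoder is supplied.
    """
    if lambda_penalty < 0:
        raise ValueError("lambda_penalty must be >= 0")
    loss = nn.cross_entropy_logits(logits, labels)
    if lambda_penalty > 0 and encoder is not None and decoder is not None:
        flat_pos = np.asarray(positions).reshape(-1, 2)
        flat_tgt = np.asarray(gaze_targets).reshape(-1, 3)
        pred = decoder(encoder(flat_pos.astype(nn.DEFAULT_DTYPE)))
        loss = loss + nn.mse(pred, flat_tgt) * lambda_penalty
    return loss


# ---------------------------------------------------------------------
# training
# ---------------------------------------------------------------------

def train(model: BPPVModel, data: ArrayDataset, config: TrainConfig,
          pretrained=None) -> list[dict]:
    """Seeded minibatch training loop with sine-decayed learning rate.

    `pretrained` may be a ``headpos.PretrainResult`` (or an
    (encoder, decoder) pair) whose parameters are loaded into the model's
    self-encoder before training.  Returns per-epoch history records
    (epoch, lr, loss).  On a non-finite loss the last finite-epoch
    parameters are restored and a RuntimeError is raised.
    """
    if pretrained is not None and model.encoder is not None:
        enc = getattr(pretrained, "encoder", None) or pretrained[0]
        dec = getattr(pretrained, "decoder", None) or pretrained[1]
        model.load_pretrained_encoder(enc, dec)
    opt = nn.Adam(model.parameters(), lr=config.lr)
    rng = np.random.default_rng(config.seed)
    history: list[dict] = []
    last_good = model.state_dict()
    for epoch in range(config.epochs):
        opt.lr = nn.sine_decay_lr(config.lr, epoch, config.epochs)
        order = rng.permutation(len(data))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = data.subset(idx)
            opt.zero_grad()
            logits = model.forward(batch.clips, batch.positions
                                   if model.config.multimodal else None)
            loss = joint_loss(logits, batch.labels, config.lambda_penalty,
                              batch.positions, batch.gaze_targets,
                              model.encoder, model.decoder)
            value = float(loss.data)
            if not np.isfinite(value):
                model.load_state_dict(last_good)
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}; restored parameters "
                    f"from last finite epoch")
            loss.backward()
            opt.step()
            losses.append(value)
        last_good = model.state_dict()
        history.append({"epoch": epoch, "lr": opt.lr,
                        "loss": float(np.mean(losses))})
    return history


# ---------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------

@dataclass
class Metrics:
    """One-vs-rest confusion counts and the derived metrics per class.

    accuracy / precision / sensitivity / specificity follow
        Acc = (TP+TN)/(TP+TN+FP+FN),  Prec = TP/(TP+FP),
        Sens = TP/(TP+FN),            Spec = TN/(TN+FP)
    computed per class and macro-averaged over the classes for which they
    are defined; undefined entries are NaN, never silently zero.
    """

    confusion: np.ndarray                  # (K, K) rows = true class
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)
    accuracy: float = float("nan")         # macro one-vs-rest accuracy
    precision: float = float("nan")
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    overall_accuracy: float = float("nan")  # plain fraction correct
    undefined: list[str] = field(default_factory=list)


def metrics_from_predictions(y_true, y_pred,
                             label_names: tuple[str, ...] = LABELS) -> Metrics:
    y_true = np.asarray(y_true, dtype=np.intp)
    y_pred = np.asarray(y_pred, dtype=np.intp)
    if len(y_true) == 0:
        raise ValueError("metrics require a non-empty test set")
    k = len(label_names)
    conf = np.zeros((k, k), dtype=np.int64)
    np.add.at(conf, (y_true, y_pred), 1)
    total = conf.sum()
    per_class: dict[str, dict[str, float]] = {}
    undefined: list[str] = []
    for c, name in enumerate(label_names):
        tp = conf[c, c]
        fn = conf[c].sum() - tp
        fp = conf[:, c].sum() - tp
        tn = total - tp - fn - fp
        row = {
            "tp": int(tp), "tn": int(tn), "fp": int(fp), "fn": int(fn),
            "accuracy": (tp + tn) / total,
            "precision": tp / (tp + fp) if tp + fp else float("nan"),
            "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
            "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        }
        if tp + fn == 0:
            undefined.append(name)
        per_class[name] = row

    def macro(key):
        vals = [m[key] for m in per_class.values()]
        vals = [v for v in vals if not math.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    return Metrics(
        confusion=conf, per_class=per_class,
        accuracy=macro("accuracy"), precision=macro("precision"),
        sensitivity=macro("sensitivity"), specificity=macro("specificity"),
        overall_accuracy=float((y_true == y_pred).mean()),
        undefined=undefined)


def evaluate(model: BPPVModel, data: ArrayDataset,
             batch_size: int = 8) -> Metrics:
    """Argmax predictions over the test set -> one-vs-rest metrics."""
    if len(data) == 0:
        raise ValueError("evaluate: test set is empty")
    preds = []
    for start in range(0, len(data), batch_size):
        batch = data.subset(np.arange(start, min(start + batch_size, len(data))))
        preds.append(model.predict(
            batch.clips, batch.positions if model.config.multimodal else None))
    return metrics_from_predictions(data.labels, np.concatenate(preds),
                                    data.label_names)


# ---------------------------------------------------------------------
# ablation driver
# ---------------------------------------------------------------------

#: The ten ablation configurations of the results grid:
#: (kernel_mode, multimodal, fusion variant).
TABLE2_GRID: tuple[tuple[str, bool, str], ...] = (
    ("big", True, "cross"),
    ("big", False, "self"),
    ("big", False, "none"),
    ("big", True, "self"),
    ("big", True, "concat"),
    ("baseline", True, "cross"),
    ("baseline", True, "self"),
    ("baseline", True, "concat"),
    ("big", True, "weighted_sum"),
    ("big", True, "weighted_sum_self"),
)


def make_model_config(kernel_mode: str, multimodal: bool, variant: str,
                      base: ModelConfig | None = None) -> ModelConfig:
    base = base or ModelConfig()
    return ModelConfig(
        backbone=replace(base.backbone, kernel_mode=kernel_mode),
        fusion=replace(base.fusion, variant=variant, multimodal=multimodal))


def run_ablation(train_data: ArrayDataset, test_data: ArrayDataset,
                 config: TrainConfig, grid=TABLE2_GRID, n_runs: int = 5,
                 base: ModelConfig | None = None,
                 pretrained=None) -> pd.DataFrame:
    """Train `n_runs` seeded models per grid cell; report mean accuracy.

    Mirrors the published ablation: each configuration is trained from
    `n_runs` random initialisations and the mean test accuracy reported.
    """
    rows = []
    for kernel_mode, multimodal, variant in grid:
        mc = make_model_config(kernel_mode, multimodal, variant, base)
        accs = []
        for run in range(n_runs):
            model = BPPVModel(mc, seed=config.seed + 1000 * run + hash((kernel_mode, variant)) % 97)
            train(model, train_data, replace(config, seed=config.seed + run),
                  pretrained=pretrained if multimodal else None)
            accs.append(evaluate(model, test_data).overall_accuracy)
        rows.append({
            "model": "BKTDN" if kernel_mode == "big" else "TDN",
            "input": "Multimodal" if multimodal else "Unimodal",
            "fusion": variant,
            "accuracy_mean": float(np.mean(accs)),
            "accuracies": accs,
            "n_runs": n_runs,
        })
    return pd.DataFrame(rows)
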