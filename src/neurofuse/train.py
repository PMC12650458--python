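"""Training loop, cross-validation protocols, ablations and metrics.

Each 3 s window is one sample. Splits are clip-wise (made before
windowing) so overlapping windows from one stimulus clip never straddle
train and test. Two protocols are provided: 5-fold subject-dependent
cross-validation rotating a per-(subject, class) clip hold-out, and
leave-one-subject-out (LOSO). Metrics are window-level accuracy
(mean/SD across folds), per-class accuracy, and the 4x4 confusion
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .loss import LossState, local_loss, total_loss, update_branch_accuracies
from .model import MFACNN, FeatureBundle
from .nn import softmax, softmax_cross_entropy
from .preprocess import ClipMeta, SplitPlan, make_splits

__all__ = [
    "TrainConfig",
    "TrainedModel",
    "EvalReport",
    "VARIANTS",
    "FeatureScaler",
    "partition_bundles",
    "train",
    "evaluate",
    "cross_validate",
    "run_ablation",
]

#: variant name -> (use_mfa, use_local_loss, local_weighting)
VARIANTS = {
    "backbone": (False, False, "off"),
    "backbone_mfa": (True, False, "off"),
    "backbone_wml": (False, True, "learned"),
    "mfa_cnn_unweighted": (True, True, "unit"),
    "mfa_cnn": (True, True, "learned"),
}

N_CLASSES = 4


@dataclass
class TrainConfig:
    variant: str = "mfa_cnn"
    learning_rate: float = 0.005
    batch_size: int = 32
    dropout: float = 0.3
    epochs: int = 100
    early_stop_patience: int = 20
    mu: float = 1.0
    ema_decay: float = 0.9
    attention_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; choose from {sorted(VARIANTS)}"
            )


class FeatureScaler:
    """Per-stream standardisation fitted on the training partition.

    GC matrices are standardised with one (mean, sd) per band stream,
    the fNIRS block with one (mean, sd) per channel row.
    """

    def fit(self, bundles: list[FeatureBundle]) -> "FeatureScaler":
        eeg = np.stack([b.eeg_gc for b in bundles]).astype(np.float64)
        fn = np.stack([b.fnirs_ts for b in bundles]).astype(np.float64)
        xm = np.stack([b.xmodal_gc for b in bundles]).astype(np.float64)
        self.eeg_mean = eeg.mean(axis=(0, 2, 3), keepdims=True)[0]
        self.eeg_sd = eeg.std(axis=(0, 2, 3), keepdims=True)[0] + 1e-8
        self.fn_mean = fn.mean(axis=(0, 2), keepdims=True)[0]
        self.fn_sd = fn.std(axis=(0, 2), keepdims=True)[0] + 1e-8
        self.xm_mean = xm.mean(axis=(0, 2, 3), keepdims=True)[0]
        self.xm_sd = xm.std(axis=(0, 2, 3), keepdims=True)[0] + 1e-8
        return self

    def batch(self, bundles: list[FeatureBundle]) -> dict[str, np.ndarray]:
        raw = MFACNN.batch_from_bundles(bundles)
        return {
            "eeg": ((raw["eeg"] - self.eeg_mean) / self.eeg_sd).astype(np.float32),
            "fnirs": ((raw["fnirs"] - self.fn_mean) / self.fn_sd).astype(np.float32),
            "xmodal": ((raw["xmodal"] - self.xm_mean) / self.xm_sd).astype(np.float32),
            "labels": raw["labels"],
        }


@dataclass
class TrainedModel:
    model: MFACNN
    scaler: FeatureScaler
    config: TrainConfig
    history: dict[str, list]

    def save(self, path) -> None:
        """Single-file archive: model parameters, scaler state, config."""
        import io
        import json
        from pathlib import Path

        arrays = {f"param:{n}": p.value for n, p in self.model.named_params()}
        for field_name in ("eeg_mean", "eeg_sd", "fn_mean", "fn_sd", "xm_mean", "xm_sd"):
            arrays[f"scaler:{field_name}"] = getattr(self.scaler, field_name)
        buf = io.BytesIO()
        np.savez_compressed(buf, **arrays)
        header = json.dumps(
            {"model_config": self.model.config, "train_config": vars(self.config)}
        )
        Path(path).write_bytes(header.encode() + b"\n" + buf.getvalue())

    @classmethod
    def load(cls, path) -> "TrainedModel":
        import io
        import json
        from pathlib import Path

        raw = Path(path).read_bytes()
        header, blob = raw.split(b"\n", 1)
        meta = json.loads(header)
        model = MFACNN(**meta["model_config"])
        scaler = FeatureScaler()
        with np.load(io.BytesIO(blob)) as z:
            for name, p in model.named_params():
                p.value = np.ascontiguousarray(z[f"param:{name}"], dtype=p.value.dtype)
            for field_name in ("eeg_mean", "eeg_sd", "fn_mean", "fn_sd", "xm_mean", "xm_sd"):
                setattr(scaler, field_name, z[f"scaler:{field_name}"])
        return cls(
            model=model,
            scaler=scaler,
            config=TrainConfig(**meta["train_config"]),
            history={},
        )


@dataclass
class EvalReport:
    accuracy_mean: float  # percent
    accuracy_sd: float  # percent
    per_class_accuracy: dict[int, float]
    confusion: np.ndarray  # [4, 4] counts, rows = true class
    fold_results: list[float] = field(default_factory=list)

    @staticmethod
    def from_confusion(confusion: np.ndarray, fold_results: list[float]) -> "EvalReport":
        confusion = np.asarray(confusion)
        totals = confusion.sum(axis=1)
        per_class = {
            c: (100.0 * confusion[c, c] / totals[c]) if totals[c] else float("nan")
            for c in range(confusion.shape[0])
        }
        folds = np.asarray(fold_results, dtype=np.float64)
        sd = float(folds.std(ddof=1)) if folds.size > 1 else 0.0
        return EvalReport(
            accuracy_mean=float(folds.mean()),
            accuracy_sd=sd,
            per_class_accuracy=per_class,
            confusion=confusion,
            fold_results=list(map(float, fold_results)),
        )


def partition_bundles(
    bundles: list[FeatureBundle], plan: SplitPlan
) -> tuple[list[FeatureBundle], list[FeatureBundle]]:
    """Apply a clip-level split to windowed bundles, guarding leakage."""
    plan.validate()
    train_clips, test_clips = plan.train_clips(), plan.test_clips()
    if train_clips & test_clips:
        raise ValueError("split plan leaks clips across partitions")
    tr = [b for b in bundles if b.clip_id in train_clips]
    te = [b for b in bundles if b.clip_id in test_clips]
    seen_tr = {b.clip_id for b in tr}
    seen_te = {b.clip_id for b in te}
    if seen_tr & seen_te:
        raise ValueError("windows from one clip appear in both partitions")
    return tr, te


def _branch_losses_and_grads(head_logits, labels, weights, mu):
    grads = {}
    losses = {}
    for k, w in zip(("eeg", "fnirs", "xmodal"), weights):
        lb, db = softmax_cross_entropy(head_logits[k], labels)
        losses[k] = lb
        grads[k] = (mu * w) * db
    return losses, grads


def train(
    bundles_train: list[FeatureBundle],
    config: TrainConfig,
    bundles_val: list[FeatureBundle] | None = None,
) -> TrainedModel:
    """Seeded, deterministic training of one variant.

    History records per epoch: total/global/local loss, training
    accuracy, branch accuracies (EMA), and the mean attention weight per
    stream. If a validation set is given, early stopping monitors its
    global loss with the configured patience.
    """
    if not bundles_train:
        raise ValueError("empty training partition")
    use_mfa, use_local, weighting = VARIANTS[config.variant]
    ne = bundles_train[0].eeg_gc.shape[1]
    nf = bundles_train[0].xmodal_gc.shape[1]
    wl = bundles_train[0].fnirs_ts.shape[1]
    model = MFACNN(
        n_eeg_channels=ne,
        n_fnirs_channels=nf,
        window_len=wl,
        use_mfa=use_mfa,
        attention_scale=config.attention_scale,
        dropout=config.dropout,
        seed=config.seed,
    )
    scaler = FeatureScaler().fit(bundles_train)
    data = scaler.batch(bundles_train)
    labels_all = data["labels"]
    n = labels_all.shape[0]
    opt = model.make_optimizer(lr=config.learning_rate)
    state = LossState(mu=config.mu, ema_decay=config.ema_decay)
    shuffle_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0x7368])
    )
    val_batch = scaler.batch(bundles_val) if bundles_val else None
    history: dict[str, list] = {
        "loss": [],
        "global_loss": [],
        "local_loss": [],
        "train_accuracy": [],
        "branch_accuracy": [],
        "attention_mean": [],
        "val_loss": [],
    }
    best_val, since_best = np.inf, 0
    best_params = None
    for _epoch in range(config.epochs):
        perm = shuffle_rng.permutation(n)
        ep_loss = ep_global = ep_local = 0.0
        n_correct = 0
        att_sum = np.zeros(9)
        n_batches = 0
        branch_preds = {k: np.empty(n, dtype=np.int64) for k in ("eeg", "fnirs", "xmodal")}
        epoch_labels = np.empty(n, dtype=np.int64)
        pos = 0
        for lo in range(0, n, config.batch_size):
            idx = perm[lo : lo + config.batch_size]
            batch = {k: data[k][idx] for k in ("eeg", "fnirs", "xmodal")}
            labels = labels_all[idx]
            out = model.forward(batch, train=True)
            l_global, dlogits = softmax_cross_entropy(out["logits"], labels)
            if use_local:
                weights = (1.0, 1.0, 1.0) if weighting == "unit" else state.weights()
                blosses, bgrads = _branch_losses_and_grads(
                    out["head_logits"], labels, weights, config.mu
                )
                l_local = local_loss(
                    blosses["eeg"], blosses["fnirs"], blosses["xmodal"], weights
                )
                model.backward(dlogits, bgrads)
            else:
                l_local = 0.0
                model.backward(dlogits, None)
            opt.step()
            opt.zero_grad()
            ep_global += l_global
            ep_local += l_local
            ep_loss += total_loss(l_global, l_local, config.mu if use_local else 0.0)
            n_correct += int((out["logits"].argmax(axis=1) == labels).sum())
            att_sum += out["attention"].mean(axis=0)
            n_batches += 1
            m = idx.shape[0]
            for k in branch_preds:
                branch_preds[k][pos : pos + m] = out["head_logits"][k].argmax(axis=1)
            epoch_labels[pos : pos + m] = labels
            pos += m
        if use_local and weighting == "learned":
            state = update_branch_accuracies(state, branch_preds, epoch_labels)
        history["loss"].append(ep_loss / n_batches)
        history["global_loss"].append(ep_global / n_batches)
        history["local_loss"].append(ep_local / n_batches)
        history["train_accuracy"].append(100.0 * n_correct / n)
        history["branch_accuracy"].append(dict(state.branch_acc))
        history["attention_mean"].append((att_sum / n_batches).tolist())
        if val_batch is not None:
            vout = model.forward(
                {k: val_batch[k] for k in ("eeg", "fnirs", "xmodal")}, train=False
            )
            vloss, _ = softmax_cross_entropy(vout["logits"], val_batch["labels"])
            history["val_loss"].append(vloss)
            if vloss < best_val - 1e-6:
                best_val, since_best = vloss, 0
                best_params = [p.value.copy() for _, p in model.named_params()]
            else:
                since_best += 1
                if since_best >= config.early_stop_patience:
                    break
    if best_params is not None:
        for (_, p), v in zip(model.named_params(), best_params):
            p.value = v
    return TrainedModel(model=model, scaler=scaler, config=config, history=history)


def evaluate(trained: TrainedModel, bundles_test: list[FeatureBundle]) -> EvalReport:
    """Window-level accuracy, per-class accuracy and confusion counts."""
    if not bundles_test:
        raise ValueError("empty test partition")
    batch = trained.scaler.batch(bundles_test)
    probs = trained.model.predict_proba(
        {k: batch[k] for k in ("eeg", "fnirs", "xmodal")}
    )
    preds = probs.argmax(axis=1)
    labels = batch["labels"]
    confusion = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    for t, p in zip(labels, preds):
        confusion[t, p] += 1
    acc = 100.0 * float((preds == labels).mean())
    return EvalReport.from_confusion(confusion, [acc])


def _clip_metas(bundles: list[FeatureBundle]) -> list[ClipMeta]:
    seen = {}
    for b in bundles:
        seen[b.clip_id] = ClipMeta(b.clip_id, b.subject_id, b.label)
    return sorted(seen.values(), key=lambda c: c.clip_id)


def cross_validate(
    bundles: list[FeatureBundle],
    protocol: str,
    config: TrainConfig,
    n_folds: int = 5,
) -> EvalReport:
    """Rotate clip-level splits and aggregate fold metrics.

    protocol "fivefold_subject_dependent" rotates the per-(subject,
    class) hold-out across 5 folds; "loso" holds out each subject once.
    """
    metas = _clip_metas(bundles)
    if protocol == "fivefold_subject_dependent":
        mode, folds = "subject_dependent", n_folds
    elif protocol == "loso":
        subjects = sorted({m.subject_id for m in metas})
        if len(subjects) < 2:
            raise ValueError("LOSO requires at least 2 subjects")
        mode, folds = "loso", len(subjects)
    else:
        raise ValueError(f"unknown protocol {protocol!r}")
    confusion = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    fold_accs: list[float] = []
    for fold in range(folds):
        plan = make_splits(metas, mode=mode, fold_index=fold, seed=config.seed)
        tr, te = partition_bundles(bundles, plan)
        trained = train(tr, config)
        rep = evaluate(trained, te)
        confusion += rep.confusion
        fold_accs.append(rep.accuracy_mean)
    return EvalReport.from_confusion(confusion, fold_accs)


def run_ablation(
    bundles: list[FeatureBundle],
    config: TrainConfig,
    protocol: str = "fivefold_subject_dependent",
) -> dict[str, dict]:
    """Accuracy and parameter count for each architectural variant."""
    from dataclasses import replace

    table: dict[str, dict] = {}
    for variant in VARIANTS:
        cfg = replace(config, variant=variant)
        rep = cross_validate(bundles, protocol, cfg)
        ne = bundles[0].eeg_gc.shape[1]
        nf = bundles[0].xmodal_gc.shape[1]
        wl = bundles[0].fnirs_ts.shape[1]
        model = MFACNN(
            n_eeg_channels=ne,
            n_fnirs_channels=nf,
            window_len=wl,
            use_mfa=VARIANTS[variant][0],
            seed=cfg.seed,
        )
        table[variant] = {
            "accuracy_mean": rep.accuracy_mean,
            "accuracy_sd": rep.accuracy_sd,
            "parameters": model.count_parameters("all"),
        }
    return table


def predict_proba_bundles(
    trained: TrainedModel, bundles: list[FeatureBundle]
) -> np.ndarray:
    batch = trained.scaler.batch(bundles)
    out = trained.model.forward(
        {k: batch[k] for k in ("eeg", "fnirs", "xmodal")}, train=False
    )
    return softmax(out["logits"].astype(np.float64))
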