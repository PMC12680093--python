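"""Patient-level leave-one-out cross-validation training.

Each fold trains a freshly initialized model on all patients but one
(AdamW, lr 1e-3, cosine annealing to zero, batch size 8, cross-entropy) and
predicts the held-out patient.  Patient-level leakage is impossible by
construction and re-asserted before every fold.  Everything derives from a
single root seed: model initialization, batch shuffling, and dropout masks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import zscore
from .metrics import PredictionSet
from .model import ModelConfig, TumorClassifier, tiny_model_config
from .nn import AdamW, CosineAnnealingLR, Dropout, Tensor
from .nn import functional as F
from .phantom import PatientSample

log = logging.getLogger("neurofuse")


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 8
    epochs: int = 50
    weight_decay: float = 1e-4
    eta_min: float = 0.0
    seed: int = 0
    preset: str = "full"  # "full" | "tiny"
    augment: str = "flip"  # "none" | "flip" | "flip-shift"

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise TrainingError("learning_rate > 0, batch_size >= 1, epochs >= 0")


def tiny_train_config(seed: int = 0, epochs: int = 20, batch_size: int = 4,
                      **kw) -> TrainConfig:
    """Desk-scale preset: shorter schedule, smaller batches (more optimizer
    steps per epoch) on the width-reduced model, flip augmentation."""
    kw.setdefault("augment", "flip")
    return TrainConfig(epochs=epochs, batch_size=batch_size, seed=seed,
                       preset="tiny", **kw)


@dataclass
class FoldResult:
    patient_id: str
    true_label: int
    predicted_label: int
    scores: np.ndarray  # softmax over classes
    epochs_completed: int


def loocv_folds(patient_ids) -> list[tuple[list, object]]:
    """One fold per patient: (train_ids, held_out_id)."""
    ids = list(patient_ids)
    if len(set(ids)) != len(ids):
        raise TrainingError("duplicate patient_ids in manifest")
    if len(ids) < 2:
        raise TrainingError("LOOCV needs at least 2 patients")
    return [([p for p in ids if p != test], test) for test in ids]


def _normalized(sample: PatientSample) -> PatientSample:
    return PatientSample(sample.patient_id, zscore(sample.dwi),
                         zscore(sample.t2), sample.label, sample.lesion_mask,
                         sample.lesion)


def _batch(samples: list[PatientSample]):
    dwi = Tensor(np.stack([s.dwi for s in samples]).astype(np.float32))
    t2 = Tensor(np.stack([s.t2 for s in samples]).astype(np.float32))
    labels = np.array([s.label for s in samples])
    return dwi, t2, labels


def _augment(dwi: np.ndarray, t2: np.ndarray, rng: np.random.Generator,
             mode: str = "flip"):
    """Geometry-preserving augmentation applied coherently to both
    modalities: random in-plane flips per minibatch, optionally plus
    circular shifts (T2 shifts at 2x the DWI offset, matching its finer
    grid)."""
    if rng.random() < 0.5:
        dwi, t2 = dwi[..., ::-1, :], t2[..., ::-1, :]
    if rng.random() < 0.5:
        dwi, t2 = dwi[..., ::-1], t2[..., ::-1]
    if mode == "flip-shift":
        max_shift = max(1, dwi.shape[-1] // 8)
        dh, dw = rng.integers(-max_shift, max_shift + 1, size=2)
        dwi = np.roll(dwi, (dh, dw), axis=(-2, -1))
        t2 = np.roll(t2, (2 * dh, 2 * dw), axis=(-2, -1))
    return np.ascontiguousarray(dwi), np.ascontiguousarray(t2)


def train_model(train_samples: list[PatientSample], model_config: ModelConfig,
                train_config: TrainConfig, seed: int) -> TumorClassifier:
    """Train one model from scratch on the given samples."""
    model = TumorClassifier(model_config, seed=seed)
    rng = np.random.default_rng(seed + 1)
    for m in model.modules():
        if isinstance(m, Dropout):
            m.set_rng(np.random.default_rng(seed + 2))
    opt = AdamW(model.parameters(), lr=train_config.learning_rate,
                weight_decay=train_config.weight_decay)
    sched = CosineAnnealingLR(opt, t_max=train_config.epochs,
                              eta_min=train_config.eta_min)
    model.train()
    n = len(train_samples)
    for epoch in range(train_config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, train_config.batch_size):
            batch = [train_samples[i] for i in order[start:start + train_config.batch_size]]
            dwi, t2, labels = _batch(batch)
            if train_config.augment != "none":
                aug_dwi, aug_t2 = _augment(dwi.data, t2.data, rng,
                                           train_config.augment)
                dwi, t2 = Tensor(aug_dwi), Tensor(aug_t2)
            logits = model.forward(dwi, t2)
            loss = F.cross_entropy(logits, labels)
            if not np.isfinite(loss.data):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}: {float(loss.data)!r}; "
                    f"lr={opt.lr:.3g}, batch={[s.patient_id for s in batch]}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        sched.step()
        log.debug("epoch %d/%d loss %.4f lr %.2e", epoch + 1,
                  train_config.epochs, float(np.mean(losses)), opt.lr)
    return model


def train_fold(fold, samples_by_id: dict, model_config: ModelConfig,
               train_config: TrainConfig, fold_seed: int) -> FoldResult:
    train_ids, test_id = fold
    if test_id in train_ids:
        raise TrainingError(f"leakage: held-out {test_id!r} in training set")
    train_samples = [samples_by_id[i] for i in train_ids]
    model = train_model(train_samples, model_config, train_config, fold_seed)
    test = samples_by_id[test_id]
    dwi, t2, _ = _batch([test])
    pred, scores = model.predict(dwi, t2)
    return FoldResult(patient_id=test_id, true_label=test.label,
                      predicted_label=int(pred[0]), scores=scores[0],
                      epochs_completed=train_config.epochs)


def run_loocv(samples: list[PatientSample], model_config: ModelConfig,
              train_config: TrainConfig, normalize: bool = True,
              progress=None) -> PredictionSet:
    """Full LOOCV over in-memory samples -> one prediction per patient."""
    if normalize:
        samples = [_normalized(s) for s in samples]
    by_id = {s.patient_id: s for s in samples}
    folds = loocv_folds([s.patient_id for s in samples])
    fold_seeds = np.random.SeedSequence(train_config.seed).generate_state(
        len(folds), dtype=np.uint32) >> 1
    results = []
    for k, fold in enumerate(folds):
        res = train_fold(fold, by_id, model_config, train_config,
                         int(fold_seeds[k]))
        results.append(res)
        log.info("fold %d/%d patient %s: true=%d pred=%d", k + 1, len(folds),
                 res.patient_id, res.true_label, res.predicted_label)
        if progress is not None:
            progress(k + 1, len(folds), res)
    return PredictionSet(
        patient_ids=np.array([r.patient_id for r in results]),
        y_true=np.array([r.true_label for r in results]),
        y_pred=np.array([r.predicted_label for r in results]))


def configs_for_preset(preset: str, variant: str = "full",
                       seed: int = 0) -> tuple[ModelConfig, TrainConfig]:
    if preset == "tiny":
        return tiny_model_config(variant), tiny_train_config(seed=seed)
    if preset == "full":
        return ModelConfig(variant=variant), TrainConfig(seed=seed)
    raise TrainingError(f"unknown preset {preset!r}")
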