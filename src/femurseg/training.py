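"""Loss, augmentation, sampling, optimization loop and cross-validation.

The loss is the class-re-weighted cross-entropy

    CE = -(1/N) * sum_i [ (N_b/N) * y_i * log p_i
                          + (N_p/N) * (1 - y_i) * log(1 - p_i) ]

with ``N_p``/``N_b`` the foreground/background voxel counts of the sample's
own mask (batch size is 1, so per-sample and per-batch weighting coincide).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import inference as _inference
from ._nn import adam_step
from .core_io import ImageVolume, LabelMask, RunLogger
from .metrics import confusion, dsc
from .nets import ArchitectureSpec, UNet, build_network

EPS = 1e-7  # probability clipping for numerical safety


class DegenerateMaskError(ValueError):
    """Mask with no foreground or no background voxels."""


@dataclass
class TrainConfig:
    learning_rate: float = 5e-5
    batch_size: int = 1
    max_epochs: int = 100
    warmup_epochs_no_stop: int = 30
    patience_epochs: int = 10
    min_improvement: float = 1e-4
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.patience_epochs < 1:
            raise ValueError("patience_epochs must be >= 1")
        if self.warmup_epochs_no_stop < 0:
            raise ValueError("warmup_epochs_no_stop must be >= 0")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class TrainHistory:
    train_loss: List[float] = field(default_factory=list)
    val_score: List[float] = field(default_factory=list)
    stop_epoch: int = 0
    stop_reason: str = ""
    best_epoch: int = 0


@dataclass
class FoldAssignment:
    """Subject-to-fold map with per-subject strata; folds are disjoint,
    exhaustive and stratum-balanced within one subject."""

    assignment: Dict[str, int]
    k: int
    strata: Dict[str, int]

    def fold_subjects(self, fold: int) -> List[str]:
        return [s for s, f in self.assignment.items() if f == fold]


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def class_weights(m: LabelMask) -> Tuple[float, float]:
    """Foreground/background loss weights ``(N_b/N, N_p/N)``; they sum to 1."""
    n = m.data.size
    n_p = int(m.data.sum())
    n_b = n - n_p
    if n_p == 0 or n_b == 0:
        raise DegenerateMaskError(
            f"mask has N_p={n_p}, N_b={n_b}; class weights are undefined")
    return n_b / n, n_p / n


def weighted_cross_entropy(p: np.ndarray, y: np.ndarray,
                           w: Tuple[float, float]) -> float:
    """Class-re-weighted cross-entropy of foreground probabilities ``p``
    against the binary target ``y``."""
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: p {p.shape} vs mask {y.shape}")
    w_fg, w_bg = w
    pc = np.clip(p, EPS, 1.0 - EPS)
    n = p.size
    loss = -(w_fg * y * np.log(pc) + w_bg * (1.0 - y) * np.log(1.0 - pc)).sum() / n
    return float(loss)


def wce_probability_and_logit_grad(logits: np.ndarray, y: np.ndarray,
                                   w: Tuple[float, float]) -> Tuple[float, np.ndarray, np.ndarray]:
    """Loss, foreground probability and analytic gradient w.r.t. the
    2-channel logits of the softmax head."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e[..., 1] / (e[..., 0] + e[..., 1])
    w_fg, w_bg = w
    n = p.size
    loss = weighted_cross_entropy(p, y, w)
    # d loss / d z_fg = (1/N)(-w_fg*y*(1-p) + w_bg*(1-y)*p); d z_bg = -that
    g_fg = (-w_fg * y * (1.0 - p) + w_bg * (1.0 - y) * p) / n
    grad = np.stack([-g_fg, g_fg], axis=-1).astype(np.float32)
    return loss, p, grad


# ---------------------------------------------------------------------------
# Augmentation and sampling
# ---------------------------------------------------------------------------

def augment_flip(sample: Tuple[np.ndarray, np.ndarray], rng: np.random.Generator,
                 force: Optional[bool] = None) -> Tuple[np.ndarray, np.ndarray]:
    """With probability 0.5, reflect image and mask jointly along the
    in-plane left-right (first) axis."""
    image, mask = sample
    do = bool(rng.random() < 0.5) if force is None else force
    if do:
        return np.flip(image, axis=0).copy(), np.flip(mask, axis=0).copy()
    return image, mask


def make_2d_samples(v: ImageVolume, m: LabelMask) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Three-consecutive-slice stacks (channels-last) with the center-slice
    mask as target; one sample per interior slice index."""
    if v.shape != m.shape:
        raise ValueError("image and mask shapes differ")
    nz = v.shape[2]
    if nz < 3:
        raise ValueError(f"need at least 3 slices, got {nz}")
    samples = []
    data = np.asarray(v.data, dtype=np.float32)
    for k in range(1, nz - 1):
        stack = np.stack([data[:, :, k - 1], data[:, :, k], data[:, :, k + 1]], axis=-1)
        samples.append((stack, m.data[:, :, k].copy()))
    return samples


def stratified_folds(subjects: Sequence[str], strata: Sequence[int], k: int = 4,
                     seed: int = 0) -> FoldAssignment:
    """Seed-reproducible stratified partition into ``k`` folds whose sizes
    and per-stratum counts each differ by at most 1."""
    subjects = list(subjects)
    strata = list(strata)
    if len(subjects) != len(strata):
        raise ValueError("subjects and strata must have equal length")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(subjects):
        raise ValueError(f"k={k} exceeds the {len(subjects)} subjects")
    if len(set(subjects)) != len(subjects):
        raise ValueError("subject ids must be unique")
    rng = np.random.default_rng(seed)
    assignment: Dict[str, int] = {}
    fold_order = rng.permutation(k)  # rotate which folds absorb remainders
    offset = 0
    for stratum in sorted(set(strata)):
        members = [s for s, st in zip(subjects, strata) if st == stratum]
        members = [members[i] for i in rng.permutation(len(members))]
        for i, s in enumerate(members):
            assignment[s] = int(fold_order[(i + offset) % k])
        offset += len(members)
    return FoldAssignment(assignment=assignment, k=k,
                          strata=dict(zip(subjects, strata)))


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def _should_stop(scores: List[float], warmup: int, patience: int, min_improvement: float) -> bool:
    e = len(scores)
    if e < warmup + patience or e <= patience:
        return False
    recent = max(scores[e - patience:])
    before = max(scores[:e - patience])
    return recent < before + min_improvement


def _expand_samples(dataset: Sequence[Tuple[ImageVolume, LabelMask]],
                    spec: ArchitectureSpec) -> List[Tuple[np.ndarray, np.ndarray]]:
    samples: List[Tuple[np.ndarray, np.ndarray]] = []
    for v, m in dataset:
        if spec.dims == 3:
            samples.append((np.asarray(v.data, dtype=np.float32)[..., None],
                            m.data.astype(np.float32)))
        else:
            samples.extend((s, t.astype(np.float32)) for s, t in make_2d_samples(v, m))
    return samples


def _pad_for_net(x: np.ndarray, y: np.ndarray, spec: ArchitectureSpec):
    """Zero-pad a sample's in-plane/volume extents up to net admissibility."""
    from .inference import pad_to_multiple

    if spec.padded:
        xp, sl = pad_to_multiple(x, 2 ** spec.layers, n_spatial=spec.dims)
        yp, _ = pad_to_multiple(y, 2 ** spec.layers, n_spatial=spec.dims)
        return xp, yp, sl
    return x, y, None


def validation_score(model: UNet, val: Sequence[Tuple[ImageVolume, LabelMask]],
                     threshold: float = 0.5) -> float:
    """Mean foreground Dice at a fixed threshold over validation subjects."""
    scores = []
    for v, m in val:
        prob = _inference.predict_padded(model, v) if model.spec.padded else \
            _inference.predict_tiled(model, v)
        pred = (prob.data > threshold).astype(np.uint8)
        scores.append(dsc(confusion(LabelMask(pred, m.spacing), m)))
    return float(np.mean(scores))


def train_model(train: Sequence[Tuple[ImageVolume, LabelMask]],
                val: Sequence[Tuple[ImageVolume, LabelMask]],
                spec: ArchitectureSpec, cfg: TrainConfig,
                logger: Optional[RunLogger] = None) -> Tuple[UNet, TrainHistory]:
    """Adam optimization of the weighted cross-entropy with flip augmentation
    on the training set and Dice-based early stopping on the validation set.

    Returns the parameters from the best validation epoch.
    """
    if not len(train) or not len(val):
        raise ValueError("train and validation datasets must be nonempty")
    model = build_network(spec, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed + 1)
    samples = _expand_samples(train, spec)

    kept = []
    for x, y in samples:
        if y.sum() == 0 or y.sum() == y.size:
            warnings.warn("excluding degenerate (single-class) training sample")
            continue
        kept.append((x, y))
    if not kept:
        raise ValueError("no non-degenerate training samples")

    params = model.parameters()
    m_state = [np.zeros_like(p) for p in params]
    v_state = [np.zeros_like(p) for p in params]
    t_step = 0

    history = TrainHistory()
    best_score = -np.inf
    best_state = model.get_state()

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(kept))
        losses = []
        for idx in order:
            x, y = kept[int(idx)]
            x, y = augment_flip((x, y), rng)
            xp, yp, _ = _pad_for_net(x, y, spec)
            if not spec.padded:
                # crop target to the net's valid output window
                from .nets import output_shape
                out_sp = output_shape(spec, xp.shape[:-1])
                lo = [(s - o) // 2 for s, o in zip(yp.shape, out_sp)]
                yp = yp[tuple(slice(l, l + o) for l, o in zip(lo, out_sp))]
            n_p = float(yp.sum())
            w = (1.0 - n_p / yp.size, n_p / yp.size)
            model.zero_grad()
            logits = model.forward(xp)
            loss, _, grad = wce_probability_and_logit_grad(logits, yp, w)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            model.backward(grad)
            t_step += 1
            adam_step(params, model.gradients(), m_state, v_state, t_step,
                      lr=cfg.learning_rate)
            losses.append(loss)

        score = validation_score(model, val)
        history.train_loss.append(float(np.mean(losses)))
        history.val_score.append(score)
        if logger is not None:
            logger.log("epoch", epoch=epoch, train_loss=history.train_loss[-1],
                       val_score=score)

        if score > best_score:
            best_score = score
            best_state = model.get_state()
            history.best_epoch = epoch

        if _should_stop(history.val_score, cfg.warmup_epochs_no_stop,
                        cfg.patience_epochs, cfg.min_improvement):
            history.stop_epoch = epoch
            history.stop_reason = "early"
            break
    else:
        history.stop_epoch = cfg.max_epochs
        history.stop_reason = "max_epochs"

    model.set_state(best_state)
    return model, history


@dataclass
class FoldResult:
    fold: int
    model: UNet
    history: TrainHistory
    val_probabilities: Dict[str, "object"]  # subject_id -> ProbabilityMap


def crossvalidate(cohort, spec: ArchitectureSpec, cfg: TrainConfig, k: int = 4,
                  seed: int = 0, logger: Optional[RunLogger] = None) -> List[FoldResult]:
    """Stratified k-fold cross-validation: per fold, train on the other k-1
    folds and predict every validation subject; validation predictions
    collectively cover each subject exactly once."""
    if len(cohort) < k:
        raise ValueError(f"cohort of {len(cohort)} subjects is smaller than k={k}")
    ids = [s.subject_id for s in cohort]
    strata = [s.stratum for s in cohort]
    folds = stratified_folds(ids, strata, k=k, seed=seed)
    by_id = {s.subject_id: s for s in cohort}
    results: List[FoldResult] = []
    for fold in range(k):
        val_ids = folds.fold_subjects(fold)
        train_ids = [i for i in ids if i not in val_ids]
        train_ds = [(by_id[i].image, by_id[i].mask) for i in train_ids]
        val_ds = [(by_id[i].image, by_id[i].mask) for i in val_ids]
        try:
            model, history = train_model(train_ds, val_ds, spec, cfg, logger=logger)
        except Exception as exc:  # tag failures with the fold id
            raise RuntimeError(f"training failed in fold {fold}") from exc
        probs = {}
        for i in val_ids:
            sub = by_id[i]
            prob = _inference.predict_padded(model, sub.image) if spec.padded \
                else _inference.predict_tiled(model, sub.image)
            prob.subject_id = i
            probs[i] = prob
        results.append(FoldResult(fold=fold, model=model, history=history,
                                  val_probabilities=probs))
    return results
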