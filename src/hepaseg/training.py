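"""Staged training protocol for the segmentation models.

The hybrid model is trained in four strictly ordered phases so that high
learning rates cannot destroy previously learned weights:

1. ``decoder2d_only`` — only the new 2D decoding side trains (encoder and the
   3D network frozen), against the slice-wise 2D head.
2. ``full_2d``        — the whole 2D network fine-tunes (3D still frozen).
3. ``dense3d_only``   — only the 3D network trains on the extracted 2D
   features (all 2D weights frozen), against the 3D head.
4. ``end_to_end``     — everything unfrozen.

Each phase optimizes the per-voxel two-class cross-entropy with Adam under a
triangular cyclical learning rate; the usable rate band can be found per phase
with an exponential learning-rate sweep (`find_lr_range`).  Validation is
performed on whole livers (never on slabs) as the patient-wise mean Dice of
the thresholded prediction; training ends a phase after a fixed number of
evaluations without improvement.  Runs are repeated from random restarts and
the best run is selected by validation Dice.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Callable, Literal, Sequence

import numpy as np

from .architectures import ModelSpec
from .errors import ConfigError
from .nn import Adam, sparse_categorical_crossentropy
from .slabs import Slab, random_flip

log = logging.getLogger(__name__)

PhaseName = Literal["decoder2d_only", "full_2d", "dense3d_only", "end_to_end"]
PHASE_ORDER: tuple[PhaseName, ...] = ("decoder2d_only", "full_2d", "dense3d_only",
                                      "end_to_end")

# which scopes stay frozen and which output head carries the loss, per phase
PHASE_FROZEN: dict[str, tuple[str, ...]] = {
    "decoder2d_only": ("2d.encoder", "3d"),
    "full_2d": ("3d",),
    "dense3d_only": ("2d",),
    "end_to_end": (),
}
PHASE_HEAD: dict[str, str] = {
    "decoder2d_only": "out2d", "full_2d": "out2d",
    "dense3d_only": "out", "end_to_end": "out",
}


@dataclasses.dataclass
class TrainingPhase:
    name: PhaseName
    frozen_scope: tuple[str, ...] | None = None   # None -> canonical scopes above
    lr_min: float | None = None                   # None -> run the LR finder
    lr_max: float | None = None
    steps_per_cycle: int = 20
    max_epochs: int = 20

    def __post_init__(self):
        if self.name not in PHASE_ORDER:
            raise ConfigError(f"unknown phase {self.name!r}")
        if self.frozen_scope is None:
            self.frozen_scope = PHASE_FROZEN[self.name]
        if self.lr_min is not None and self.lr_max is not None:
            if not (0 < self.lr_min <= self.lr_max):
                raise ValueError("require 0 < lr_min <= lr_max")

    @property
    def head(self) -> str:
        return PHASE_HEAD[self.name]


def default_schedule(**kw) -> list[TrainingPhase]:
    return [TrainingPhase(name, **kw) for name in PHASE_ORDER]


@dataclasses.dataclass
class RunRecord:
    run_seed: int
    losses: list[float] = dataclasses.field(default_factory=list)        # per epoch
    val_dsc: list[float] = dataclasses.field(default_factory=list)       # per evaluation
    best_validation_dsc: float = 0.0
    checkpoint: dict | None = None          # state dict of the best weights
    lr_traces: list[list] = dataclasses.field(default_factory=list)
    phase_names: list[str] = dataclasses.field(default_factory=list)


# ------------------------------------------------------------------ schedules

def cyclical_lr(step: int, lr_min: float, lr_max: float, steps_per_cycle: int) -> float:
    """Triangular wave: linear lr_min -> lr_max over the first half cycle and back."""
    if lr_min > lr_max:
        raise ValueError("lr_min must not exceed lr_max")
    if steps_per_cycle < 2 or steps_per_cycle % 2:
        raise ValueError("steps_per_cycle must be even and >= 2")
    pos = step % steps_per_cycle
    half = steps_per_cycle / 2
    frac = pos / half if pos <= half else (steps_per_cycle - pos) / half
    return lr_min + (lr_max - lr_min) * frac


@dataclasses.dataclass
class LRRange:
    lr_min: float
    lr_max: float
    trace: list[tuple[float, float, float]]   # (lr, loss, smoothed loss)

    def __iter__(self):
        return iter((self.lr_min, self.lr_max))


# --------------------------------------------------------------- single steps

def _prep_batch(slabs: Sequence[Slab]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    image = np.stack([s.image for s in slabs]).astype(np.float32)
    liver = np.stack([s.liver for s in slabs]).astype(np.float32)
    label = np.stack([s.label for s in slabs]).astype(np.int64)
    return image, liver, label


def train_step(model: ModelSpec, images: np.ndarray, livers: np.ndarray,
               labels: np.ndarray, optimizer: Adam, lr: float, head: str = "out") -> float:
    """One optimization step; returns the batch loss.

    Inputs are reflect-padded to the model's pooling multiple; the loss is
    computed on the original (uncropped) voxels only, with zero gradient on
    the padding.
    """
    img_p, orig = model.pad_batch(images[..., None].astype(np.float32))
    liv_p, _ = model.pad_batch(livers[..., None].astype(np.float32))
    out = model.network.forward({"image": img_p, "liver": liv_p}, [head],
                                training=True)[head]
    stacked_2d = out.ndim == 4          # 2D head emits (B*D_padded, H, W, C)
    if stacked_2d:
        out = out.reshape(images.shape[0], -1, *out.shape[1:])
    crop = (slice(None), slice(0, orig[0]), slice(0, orig[1]), slice(0, orig[2]))
    loss, gprobs = sparse_categorical_crossentropy(out[crop], labels)
    grad = np.zeros_like(out)
    grad[crop] = gprobs
    if stacked_2d:
        grad = grad.reshape(-1, *grad.shape[2:])
    model.network.zero_grad()
    model.backward_from(head, grad)
    optimizer.step(lr)
    return loss


def validation_dice(model: ModelSpec, val_cases, head: str = "out",
                    threshold: float = 0.5) -> float:
    """Patient-wise mean Dice on whole livers at training resolution."""
    dscs = []
    for image, liver, gt in val_cases:
        prob = model.forward(np.asarray(image, np.float32), np.asarray(liver, np.float32),
                             head=head)
        pred = prob[..., 1] >= threshold
        g = np.asarray(gt, bool)
        denom = pred.sum() + g.sum()
        dscs.append(1.0 if denom == 0 else 2.0 * (pred & g).sum() / denom)
    return float(np.mean(dscs)) if dscs else 0.0


# ---------------------------------------------------------------- LR finder

def analyze_lr_sweep(lrs: Sequence[float], losses: Sequence[float],
                     tolerance: float = 0.2, smoothing: float = 0.98) -> LRRange:
    """Pick the usable rate band from an exponential-sweep loss trace.

    The largest rate whose exponentially smoothed (bias-corrected) loss stays
    within ``(1 + tolerance)`` of the running minimum becomes ``lr_max``;
    ``lr_min = lr_max / 10``.  A single-step spike far above the running raw
    minimum also ends the sweep (the smoothed curve reacts too slowly to a
    sudden blow-up when the sweep is short).  A trace that never diverges
    yields the widest stable range with a warning.
    """
    trace: list[tuple[float, float, float]] = []
    smoothed = 0.0
    best = math.inf
    best_raw = math.inf
    lr_max = None
    for i, (lr, loss) in enumerate(zip(lrs, losses)):
        if not math.isfinite(loss):
            break
        smoothed = smoothing * smoothed + (1 - smoothing) * loss
        corr = smoothed / (1 - smoothing ** (i + 1))   # bias-corrected
        trace.append((float(lr), float(loss), float(corr)))
        if corr > (1 + tolerance) * best or loss > (1 + 5 * tolerance) * best_raw:
            break
        best = min(best, corr)
        best_raw = min(best_raw, loss)
        lr_max = float(lr)
    if lr_max is None:
        lr_max = float(lrs[0])
    if trace and lr_max == float(lrs[-1]):
        log.warning("loss never diverged within the sweep; returning the widest stable range")
    return LRRange(lr_min=lr_max / 10.0, lr_max=lr_max, trace=trace)


def find_lr_range(model: ModelSpec, sample_batches, lr_lo: float = 1e-5,
                  lr_hi: float = 1.0, n_steps: int = 25, tolerance: float = 0.2,
                  smoothing: float = 0.98, head: str = "out",
                  cycle_batches: bool = False) -> LRRange:
    """Exponential learning-rate sweep; returns the usable (lr_min, lr_max) band.

    By default every sweep step uses the same batch: batch-to-batch loss
    variation easily spans a factor of two on small cohorts, which would
    drown the divergence signal the sweep looks for.  Weights and optimizer
    state are restored afterwards, so the sweep has no side effects on the
    model.
    """
    if lr_lo >= lr_hi:
        raise ValueError("lr_lo must be < lr_hi")
    state = model.network.state_dict()
    opt = Adam(model.network.parameters())
    lrs = np.geomspace(lr_lo, lr_hi, n_steps)
    losses: list[float] = []
    try:
        for i, lr in enumerate(lrs):
            images, livers, labels = sample_batches[i % len(sample_batches)
                                                    if cycle_batches else 0]
            loss = train_step(model, images, livers, labels, opt, float(lr), head)
            if not math.isfinite(loss) and i == 0:
                raise FloatingPointError(
                    f"loss is non-finite at the lowest rate {lr_lo}; "
                    f"model or loss is misconfigured")
            losses.append(loss)
            if not math.isfinite(loss):
                break
    finally:
        model.network.load_state_dict(state)
    return analyze_lr_sweep(lrs[:len(losses)], losses, tolerance, smoothing)


# -------------------------------------------------------------- phase training

def train_phase(model: ModelSpec, phase: TrainingPhase, train_slabs: Sequence[Slab],
                val_cases, rng_seed: int = 0, batch_size: int = 8,
                eval_every: int | None = None, patience: int = 5,
                augment: bool = True, snapshot_dir=None,
                lr_finder_steps: int = 25, lr_finder_hi: float = 0.05) -> RunRecord:
    """Run one training phase; frozen-scope weights are bit-identical afterwards.

    ``val_cases`` is a list of (image, liver, gt) whole-liver arrays; slabs are
    used only for optimization.  The record's checkpoint holds the best
    weights, which are also loaded back into the model at the end.
    """
    if not train_slabs:
        raise ValueError("no training slabs")
    rng = np.random.default_rng(rng_seed)
    model.freeze(phase.frozen_scope)
    head = phase.head
    if phase.lr_min is None or phase.lr_max is None:
        batches = _make_batches(train_slabs, batch_size, rng, augment=False)
        lr_range = find_lr_range(model, batches, head=head, n_steps=lr_finder_steps,
                                 lr_hi=lr_finder_hi)
        lr_min, lr_max = lr_range.lr_min, lr_range.lr_max
        trace = lr_range.trace
    else:
        lr_min, lr_max, trace = phase.lr_min, phase.lr_max, []

    opt = Adam(model.network.parameters())
    record = RunRecord(run_seed=rng_seed, lr_traces=[trace], phase_names=[phase.name])
    best_state = model.network.state_dict()
    best_dsc = -1.0
    since_improve = 0
    step = 0
    n_batches = max(1, math.ceil(len(train_slabs) / batch_size))
    eval_every = eval_every or 1   # evaluations per epoch

    for epoch in range(phase.max_epochs):
        order = rng.permutation(len(train_slabs))
        epoch_losses = []
        for bi in range(n_batches):
            idx = order[bi * batch_size:(bi + 1) * batch_size]
            batch = [train_slabs[i] for i in idx]
            if augment:
                batch = [random_flip(s, rng) for s in batch]
            images, livers, labels = _prep_batch(batch)
            lr = cyclical_lr(step, lr_min, lr_max, phase.steps_per_cycle)
            epoch_losses.append(train_step(model, images, livers, labels, opt, lr, head))
            step += 1
        record.losses.append(float(np.mean(epoch_losses)))
        if (epoch + 1) % eval_every == 0:
            dsc = validation_dice(model, val_cases, head=head)
            record.val_dsc.append(dsc)
            if snapshot_dir is not None and val_cases:
                _snapshot(model, val_cases[0], head, snapshot_dir,
                          f"{phase.name}_epoch{epoch:03d}")
            if dsc > best_dsc:
                best_dsc = dsc
                best_state = model.network.state_dict()
                since_improve = 0
            else:
                since_improve += 1
                if since_improve >= patience:
                    break
    model.network.load_state_dict(best_state)
    record.best_validation_dsc = max(record.val_dsc) if record.val_dsc else 0.0
    record.checkpoint = best_state
    return record


def _make_batches(slabs, batch_size, rng, augment):
    out = []
    for i in range(0, len(slabs), batch_size):
        chunk = list(slabs[i:i + batch_size])
        if augment:
            chunk = [random_flip(s, rng) for s in chunk]
        out.append(_prep_batch(chunk))
    return out


def _snapshot(model, case, head, out_dir, tag):
    """Image-grid dump (input / ground truth / prediction rows) for visual QA."""
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:          # plotting is an optional extra
        return
    from pathlib import Path
    image, liver, gt = case
    prob = model.forward(np.asarray(image, np.float32), np.asarray(liver, np.float32),
                         head=head)[..., 1]
    mid = image.shape[0] // 2
    rows = [image[mid], np.asarray(gt)[mid], prob[mid] >= 0.5]
    titles = ["input", "ground truth", "prediction"]
    fig, axes = plt.subplots(3, 1, figsize=(4, 10))
    for ax, arr, t in zip(axes, rows, titles):
        ax.imshow(arr, cmap="gray")
        ax.set_title(t)
        ax.axis("off")
    Path(out_dir).mkdir(parents=True, exist_ok=True)
    fig.savefig(Path(out_dir) / f"{tag}.png", dpi=72)
    plt.close(fig)


# ------------------------------------------------------------- staged training

def staged_train(model: ModelSpec, schedule: Sequence[TrainingPhase], train_slabs,
                 val_cases, rng_seed: int = 0, **phase_kw) -> RunRecord:
    """Run the four phases in order, carrying weights forward between them."""
    names = [p.name for p in schedule]
    if names != list(PHASE_ORDER):
        raise ConfigError(f"schedule must be {list(PHASE_ORDER)} in order, got {names}")
    combined = RunRecord(run_seed=rng_seed)
    for i, phase in enumerate(schedule):
        rec = train_phase(model, phase, train_slabs, val_cases,
                          rng_seed=rng_seed + i, **phase_kw)
        combined.losses.extend(rec.losses)
        combined.val_dsc.extend(rec.val_dsc)
        combined.lr_traces.extend(rec.lr_traces)
        combined.phase_names.append(phase.name)
    combined.best_validation_dsc = max(combined.val_dsc) if combined.val_dsc else 0.0
    combined.checkpoint = model.network.state_dict()
    return combined


def select_best(runs: Sequence[RunRecord]) -> RunRecord:
    """The run with maximal validation Dice; ties resolve to the lowest seed."""
    if not runs:
        raise ValueError("need at least one run")
    return min(runs, key=lambda r: (-r.best_validation_dsc, r.run_seed))


def train_with_restarts(build_model: Callable[[int], ModelSpec],
                        schedule_factory: Callable[[], Sequence[TrainingPhase]],
                        train_slabs, val_cases, n_restarts: int = 3,
                        base_seed: int = 0, **phase_kw
                        ) -> tuple[ModelSpec, RunRecord, list[RunRecord]]:
    """Repeat staged training from random initializations; keep the best run."""
    runs = []
    models = []
    for r in range(n_restarts):
        seed = base_seed + 1000 * r
        model = build_model(seed)
        rec = staged_train(model, list(schedule_factory()), train_slabs, val_cases,
                           rng_seed=seed, **phase_kw)
        runs.append(rec)
        models.append(model)
    best = select_best(runs)
    best_model = models[runs.index(best)]
    return best_model, best, runs
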