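"""Training and inference orchestration.

Training follows the regime the architecture was designed for: single-image
iterations (batch size 1) over the augmented training list in seeded
shuffled order, ADAM at a constant learning rate (default 1e-3), xavier
initialisation, and the random-drop loss summed over every supervised head.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from . import fundus_io
from ._nn import Adam
from .config import TrainConfig
from .loss import class_balanced_ce, random_drop_loss
from .metrics import MetricReport, evaluate_maps
from .model import LightEyesModel, ProbabilityMaps

__all__ = ["TrainResult", "train", "step_loss", "predict", "evaluate"]

PROB_SCALE = 65535  # probability maps are stored as 16-bit PNGs


@dataclass
class TrainResult:
    weights_path: Path
    log: list[dict]  # one record per iteration
    model: LightEyesModel
    run_record: dict


def step_loss(
    model: LightEyesModel,
    maps: ProbabilityMaps,
    gt: np.ndarray,
    config: TrainConfig,
    rng: np.random.Generator,
):
    """Loss of one training step: the per-head breakdowns, the weighted
    total, and the gradient to feed back per head (dL/dlogit)."""
    use_cb = config.loss.kind == "class_balanced"
    breakdowns, head_grads = {}, {}
    total = 0.0
    for head in config.loss.heads:
        if head not in maps.logits:
            continue  # variant without this head
        p = {"fused": maps.fused, "aux1": maps.aux1,
             "aux2": maps.aux2, "aux3": maps.aux3}[head]
        bd = (class_balanced_ce(p, gt, config.loss) if use_cb
              else random_drop_loss(p, gt, config.loss, rng))
        w = config.loss.weight(head)
        total += w * bd.loss
        head_grads[head] = w * bd.grad_p * p * (1.0 - p)  # chain through sigmoid
        breakdowns[head] = bd
    if not breakdowns:
        raise ValueError("no supervised head matches the model's outputs")
    return total, breakdowns, head_grads


def train(
    train_manifest,
    config: TrainConfig,
    out_dir,
) -> TrainResult:
    """Train a model on the samples listed in a CSV manifest.

    Writes ``weights.npz``, a per-iteration ``loss_log.csv`` and a JSON run
    record (config, seed, parameter count) under ``out_dir``.  Deterministic
    given ``config.seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples = fundus_io.load_manifest_samples(train_manifest)
    if config.augment:
        samples = [a for s in samples for a in fundus_io.augment_six(s)]

    model = LightEyesModel(config.network)
    rng_init = np.random.default_rng(config.seed)
    model.init_weights(rng_init)
    n_params = model.count_parameters()
    opt = model.make_optimizer(lr=config.learning_rate)
    rng_order = np.random.default_rng(config.seed + 1)
    rng_drop = np.random.default_rng(config.seed + 2)

    log: list[dict] = []
    order: list[int] = []
    for it in range(1, config.iterations + 1):
        if not order:
            order = list(rng_order.permutation(len(samples)))
        idx = order.pop()
        sample = samples[idx]
        maps = model.forward(sample.image, keep_cache=True)
        total, bds, head_grads = step_loss(model, maps, sample.gt, config, rng_drop)
        if not np.isfinite(total):
            diag = {h: {"beta": b.beta, "Nn": b.n_neg_kept, "Np": b.n_pos}
                    for h, b in bds.items()}
            raise RuntimeError(
                f"non-finite loss at iteration {it} on sample "
                f"{sample.identifier!r}; per-head state: {diag}"
            )
        model.zero_grads()
        model.backward(head_grads)
        opt.step(model.gradients())
        rec = {"iteration": it, "sample": sample.identifier, "total": total}
        for h, b in bds.items():
            rec[f"loss_{h}"] = b.loss
            rec[f"beta_{h}"] = b.beta
        log.append(rec)
        if config.checkpoint_every and it % config.checkpoint_every == 0:
            model.save(out_dir / f"weights_iter{it}.npz")

    weights_path = out_dir / "weights.npz"
    model.save(weights_path)
    _write_log(log, out_dir / "loss_log.csv")
    run_record = {
        "config": dataclasses.asdict(config),
        "n_train_samples": len(samples),
        "n_parameters": n_params,
        "adam": {"beta1": opt.beta1, "beta2": opt.beta2, "eps": opt.eps},
        "final_loss": log[-1]["total"],
    }
    (out_dir / "run_record.json").write_text(json.dumps(run_record, indent=2))
    return TrainResult(weights_path, log, model, run_record)


def _write_log(log: list[dict], path: Path) -> None:
    import csv

    keys = sorted({k for rec in log for k in rec}, key=lambda k: (k != "iteration", k))
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=keys)
        writer.writeheader()
        writer.writerows(log)


def _pad_even(image: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = image.shape[:2]
    ph, pw = h % 2, w % 2
    if ph or pw:
        image = np.pad(image, ((0, ph), (0, pw), (0, 0)), mode="reflect")
    return image, (h, w)


def predict(
    weights_path,
    image_paths,
    out_dir,
    save_raw: bool = False,
) -> list[Path]:
    """Run inference; writes one full-resolution 16-bit PNG probability map
    per image (value = round(p * 65535)).  Odd-sized inputs are reflect-
    padded to even size and the map cropped back."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model = LightEyesModel.load(weights_path)
    written = []
    for path in image_paths:
        path = Path(path)
        image = fundus_io._read_rgb(path)
        padded, (h, w) = _pad_even(image)
        maps = model.forward(padded)
        prob = maps.fused[:h, :w]
        out = out_dir / f"{path.stem.removesuffix('_image')}_prob.png"
        iio.imwrite(out, np.round(prob * PROB_SCALE).astype(np.uint16))
        if save_raw:
            np.save(out.with_suffix(".npy"), prob)
        written.append(out)
    return written


def load_probability_map(path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / PROB_SCALE
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    return arr.astype(np.float64)


def evaluate(
    pred_dir,
    test_manifest,
    use_fov: bool = False,
    grid=None,
) -> MetricReport:
    """Dataset-level evaluation of saved probability maps against a test
    manifest (global equilibrium threshold over the pooled pixels).

    ``use_fov`` restricts counting to the field of view, the convention for
    vessel benchmarks; lesion evaluation counts the whole image.
    """
    pred_dir = Path(pred_dir)
    rows = fundus_io.read_manifest(test_manifest)
    probs, gts, fovs = [], [], []
    for row in rows:
        stem = Path(row["image"]).stem.removesuffix("_image")
        pred_path = pred_dir / f"{stem}_prob.png"
        if not pred_path.exists():
            raise FileNotFoundError(f"no probability map for {stem!r} in {pred_dir}")
        sample = fundus_io.load_sample(row["image"], row["gt"], row.get("fov"))
        probs.append(load_probability_map(pred_path))
        gts.append(sample.gt)
        fovs.append(sample.fov if use_fov else None)
    return evaluate_maps(probs, gts, fovs, grid=grid)
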