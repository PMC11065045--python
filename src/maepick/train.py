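"""Stage 1: train the masked autoencoder on one reference micrograph.

The procedure has two phases.  A reconstruction-only *pre-training*
phase runs on a broad pool of randomly cropped unlabeled regions, so the
encoder sees the background variability of the micrograph.  The
*fine-tuning* phase then optimizes the total loss (reconstruction +
beta * self-cross similarity) on batches that always contain the full
exemplar set plus a random minibatch of unlabeled crops — the similarity
terms are defined over all m exemplars, so all of them enter every step.
Latent features for the similarity terms come from the same masked
forward pass that drives reconstruction.

Everything is deterministic under ``TrainPlan.seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from ._nn import AdamW
from .io import Micrograph
from .losses import LossConfig, scs_from_features
from .mae import MaeConfig, MaskedAutoencoder, random_mask

logger = logging.getLogger("maepick")


@dataclass
class TrainPlan:
    """Sizes and optimization settings for stage-1 training."""

    m: int = 15  # exemplar count (few-shot budget)
    n: int = 64  # unlabeled crop pool for fine-tuning
    pretrain_pool_factor: int = 4  # pre-training pool = factor * n
    pretrain_steps: int = 150
    finetune_steps: int = 300
    batch_size: int = 32  # unlabeled crops per step (exemplars always all in)
    learning_rate: float = 3e-4
    weight_decay: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.m < 1 or self.n < 1:
            raise ValueError("m and n must be >= 1")
        if self.pretrain_steps < 0 or self.finetune_steps < 0:
            raise ValueError("step counts must be >= 0")


@dataclass
class RegionCrop:
    """A square crop of a micrograph with its provenance."""

    pixels: np.ndarray  # (s, s) float32
    center: tuple  # (x, y) in the source micrograph
    role: str  # exemplar | unlabeled | query-window
    source_id: str = ""


def contrast_scale(image: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Scale an image to unit global standard deviation.

    Applied to every micrograph before crops or windows are taken, so
    that crop amplitudes are comparable across micrographs while the
    LOCAL amplitude differences (particle vs background) survive; the
    encoder then only removes each crop's mean (``demean``).
    """
    sd = float(np.std(image))
    return np.asarray(image, dtype=np.float32) / (sd + eps)


def _crop_at(image: np.ndarray, cx: float, cy: float, size: int) -> np.ndarray:
    half = size / 2.0
    x0 = int(round(cx - half))
    y0 = int(round(cy - half))
    return image[y0 : y0 + size, x0 : x0 + size]


def extract_exemplars(micrograph: Micrograph, coordinates: np.ndarray,
                      crop_size: int) -> list:
    """Crop exemplar regions centered on labeled particle coordinates.

    Coordinates closer than crop_size/2 to an edge are skipped with a
    warning; an error is raised if none remain.
    """
    coords = np.atleast_2d(np.asarray(coordinates, dtype=float))
    h, w = micrograph.image.shape
    image = contrast_scale(micrograph.image)
    half = crop_size / 2.0
    crops = []
    for cx, cy in coords:
        if cx < half or cy < half or cx > w - half or cy > h - half:
            logger.warning(
                "skipping exemplar at (%.1f, %.1f): closer than %.1f px to the edge",
                cx, cy, half)
            continue
        crops.append(RegionCrop(_crop_at(image, cx, cy, crop_size),
                                (float(cx), float(cy)), "exemplar",
                                micrograph.micrograph_id))
    if not crops:
        raise ValueError("no usable exemplar coordinates (all out of bounds)")
    return crops


def sample_unlabeled(micrograph: Micrograph, n: int, crop_size: int,
                     seed: int | np.random.Generator = 0,
                     exclude: np.ndarray | None = None) -> list:
    """Uniformly sample n random in-bounds crops.

    With ``exclude`` given, candidate centers closer than crop_size/2 to
    any excluded coordinate are resampled (off by default: random crops
    are drawn blindly, which is exactly what makes them "unlabeled").
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = micrograph.image.shape
    image = contrast_scale(micrograph.image)
    half = crop_size / 2.0
    excl = None if exclude is None else np.atleast_2d(np.asarray(exclude, float))
    crops = []
    attempts, budget = 0, 1000 * n
    while len(crops) < n:
        if attempts >= budget:
            raise RuntimeError("could not sample unlabeled crops away from the "
                               "excluded coordinates within the attempt budget")
        attempts += 1
        cx = rng.uniform(half, w - half)
        cy = rng.uniform(half, h - half)
        if excl is not None and len(excl):
            if np.min(np.hypot(excl[:, 0] - cx, excl[:, 1] - cy)) < half:
                continue
        crops.append(RegionCrop(_crop_at(image, cx, cy, crop_size),
                                (float(cx), float(cy)), "unlabeled",
                                micrograph.micrograph_id))
    return crops


def resize_crops(crops: list, size: int) -> np.ndarray:
    """Stack crop pixel arrays, resized to (size, size) if needed."""
    stack = np.stack([c.pixels if isinstance(c, RegionCrop) else c for c in crops])
    if stack.shape[-1] == size and stack.shape[-2] == size:
        return stack.astype(np.float32)
    zoom = (1.0, size / stack.shape[-2], size / stack.shape[-1])
    return ndimage.zoom(stack.astype(np.float32), zoom, order=1)


def param_hash(model: MaskedAutoencoder) -> str:
    import hashlib

    h = hashlib.sha256()
    for k, v in sorted(model.state_dict().items()):
        h.update(k.encode())
        h.update(np.ascontiguousarray(v).tobytes())
    return h.hexdigest()


def pretrain(model: MaskedAutoencoder, unlabeled_crops: list,
             plan: TrainPlan) -> pd.DataFrame:
    """Reconstruction-only optimization on unlabeled crops.

    Returns the per-step loss log (one row per optimizer step).
    """
    if not unlabeled_crops:
        raise ValueError("pretrain needs a nonempty crop set")
    cfg = model.cfg
    images = resize_crops(unlabeled_crops, cfg.input_size)
    rng = np.random.default_rng(plan.seed + 1)
    opt = AdamW(model.parameters(), lr=plan.learning_rate,
                weight_decay=plan.weight_decay)
    rows = []
    for step in range(plan.pretrain_steps):
        take = min(plan.batch_size, len(images))
        idx = rng.choice(len(images), size=take, replace=False)
        batch = images[idx]
        mask = random_mask(cfg.n_patches, cfg.mask_ratio, rng, batch_size=take)
        loss, _, _ = model.forward_loss(batch, mask)
        opt.zero_grad()
        loss.backward()
        opt.step()
        rows.append({"step": step, "l_mse": loss.item()})
        if step % 50 == 0:
            logger.debug("pretrain step %d l_mse=%.4f", step, loss.item())
    return pd.DataFrame(rows, columns=["step", "l_mse"])


def finetune(model: MaskedAutoencoder, exemplar_crops: list,
             unlabeled_crops: list, plan: TrainPlan,
             loss_cfg: LossConfig) -> pd.DataFrame:
    """Joint optimization of reconstruction + self-cross similarity loss.

    Every step masks the full exemplar set plus a sampled unlabeled
    minibatch, encodes them in one forward pass, and optimizes
    ``L_MSE + beta * L_SCS`` computed from the masked-input latents.
    Returns a log with columns step, l_mse, l_scs, s_self, s_cross.
    """
    if not exemplar_crops or not unlabeled_crops:
        raise ValueError("finetune needs nonempty exemplar and unlabeled crop sets")
    if loss_cfg.adjusted and len(unlabeled_crops) == 0:
        raise ValueError("adjusted similarities require unlabeled crops")
    cfg = model.cfg
    ex_images = resize_crops(exemplar_crops, cfg.input_size)
    un_images = resize_crops(unlabeled_crops, cfg.input_size)
    m = len(ex_images)
    rng = np.random.default_rng(plan.seed + 2)
    opt = AdamW(model.parameters(), lr=plan.learning_rate,
                weight_decay=plan.weight_decay)
    rows = []
    for step in range(plan.finetune_steps):
        take = min(plan.batch_size, len(un_images))
        idx = rng.choice(len(un_images), size=take, replace=False)
        batch = np.concatenate([ex_images, un_images[idx]], axis=0)
        mask = random_mask(cfg.n_patches, cfg.mask_ratio, rng,
                           batch_size=len(batch))
        l_mse, latent, _ = model.forward_loss(batch, mask)
        l_scs, s_self, s_cross = scs_from_features(latent[:m], latent[m:], loss_cfg)
        loss = l_mse + loss_cfg.beta * l_scs
        opt.zero_grad()
        loss.backward()
        opt.step()
        rows.append({"step": step, "l_mse": l_mse.item(), "l_scs": l_scs.item(),
                     "s_self": float(s_self.item()), "s_cross": float(s_cross.item()),
                     "l_total": loss.item()})
        if step % 50 == 0:
            logger.debug("finetune step %d l_total=%.4f s_self=%.3f s_cross=%.3f",
                         step, loss.item(), s_self.item(), s_cross.item())
    return pd.DataFrame(rows, columns=["step", "l_mse", "l_scs", "s_self",
                                       "s_cross", "l_total"])


def train_reference(micrograph: Micrograph, exemplar_coords: np.ndarray,
                    mae_cfg: MaeConfig, plan: TrainPlan, loss_cfg: LossConfig,
                    crop_size: int | None = None, out_dir: str | Path | None = None):
    """Full stage-1 pipeline on one reference micrograph.

    Crop size defaults to the particle diameter implied by the exemplar
    annotations' config; pass it explicitly otherwise.  Returns
    ``(model, logs)`` where ``logs`` is a dict of DataFrames; when
    ``out_dir`` is given, the checkpoint and CSV logs are written there.
    """
    crop_size = int(crop_size or mae_cfg.input_size)
    model = MaskedAutoencoder(mae_cfg, seed=plan.seed)
    exemplars = extract_exemplars(micrograph, exemplar_coords, crop_size)[: plan.m]
    rng = np.random.default_rng(plan.seed + 3)
    pool = sample_unlabeled(micrograph, plan.pretrain_pool_factor * plan.n,
                            crop_size, rng)
    pre_log = pretrain(model, pool, plan)
    unlabeled = pool[: plan.n]  # fine-tune on a subset of the same pool
    fine_log = finetune(model, exemplars, unlabeled, plan, loss_cfg)
    logs = {"pretrain": pre_log, "finetune": fine_log}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        model.save(out / "checkpoint.npz")
        pre_log.to_csv(out / "pretrain_log.csv", index=False)
        fine_log.to_csv(out / "finetune_log.csv", index=False)
    return model, logs
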