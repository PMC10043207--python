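"""Feature-attribution maps and their agreement with ablation lesions.

Three post-hoc attribution methods explain the outcome classifier's
per-strategy scores: GradCAM (gradient-weighted activation maps from the
last convolution block), occlusion sensitivity (class-score drops under a
sliding masked patch) and LIME (a weighted sparse linear surrogate over
superpixel on/off perturbations).  Each map is thresholded at a multiple of
its mean attribution over tissue pixels into an "informative region", which
is scored against the hidden ablation lesions with three set metrics:

* IoU          |R n L| / |R u L|
* lesion %     |R n L| / |L|   (lesions captured by the region)
* NAT %        |R n H| / |R|   (region wasted on non-arrhythmogenic tissue,
                                H = tissue that is neither lesion nor fibrosis)

All maps are resampled to the disk grid before thresholding so that regions,
lesions and tissue classes share one coordinate system.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from skimage.transform import resize
from sklearn.linear_model import Ridge

from .ablation import LesionMask, Strategy, StrategyOutcome
from .model import CLASS_NAMES, Model, disk_to_image
from .tissue import TissueDisk


class FAMethod(str, Enum):
    GRADCAM = "gradcam"
    LIME = "lime"
    OCCLUSION = "occlusion"


@dataclass
class FAMap:
    """Per-pixel attribution for one (method, strategy class, disk)."""

    attribution: np.ndarray  # on the disk grid
    method: FAMethod
    class_index: int
    disk_ref: str = ""
    model_ref: str = ""


@dataclass
class InformativeRegion:
    mask: np.ndarray
    threshold_factor: float
    threshold_value: float


def _to_disk_grid(arr: np.ndarray, disk: TissueDisk) -> np.ndarray:
    target = disk.label_grid.shape
    if arr.shape == target:
        return arr
    return resize(arr, target, order=1, preserve_range=True, anti_aliasing=False)


# ---------------------------------------------------------------------------
# attribution methods


def gradcam(model: Model, disk: TissueDisk | None, class_index: int,
            image: np.ndarray | None = None,
            conv_block: int | None = None) -> FAMap:
    """Gradient-weighted class activation map from a convolution block.

    Channel weights are the global-average-pooled gradients of the class
    logit w.r.t. the block's activation maps; the map is the rectified
    weighted sum, upsampled bilinearly.  ``conv_block`` selects the block
    (1-based; None = the last).  With reduced model inputs the last block's
    maps can be coarser than the reference configuration's 8x8; passing the
    block at matching spatial resolution keeps the maps comparable.
    ``image`` (1, S, S) bypasses the disk encoding; without a disk the map
    stays at input resolution.
    """
    x = (image if image is not None else disk_to_image(disk, model.spec))[None]
    A, dA = model.gradcam_ingredients(x, class_index, conv_block=conv_block)
    alpha = dA.mean(axis=(2, 3))            # (1, C): 1/z * sum_ij dy/dA_ij
    cam = np.einsum("nc,nchw->nhw", alpha, A)[0]
    cam = np.maximum(cam, 0.0)
    if cam.shape != x.shape[-2:]:
        cam = resize(cam, x.shape[-2:], order=1, preserve_range=True,
                     anti_aliasing=False)
    if disk is None:
        return FAMap(cam, FAMethod.GRADCAM, class_index)
    return FAMap(_to_disk_grid(cam, disk), FAMethod.GRADCAM, class_index)


def occlusion_map(
    model: Model, disk: TissueDisk | None, class_index: int,
    patch_size: int = 16, stride: int = 8, baseline_value: float = 0.0,
    image: np.ndarray | None = None,
) -> FAMap:
    """Mean class-score drop over all sliding patches covering each pixel."""
    if patch_size < 1 or stride < 1:
        raise ValueError("patch_size and stride must be >= 1")
    x = image if image is not None else disk_to_image(disk, model.spec)
    S = x.shape[-1]
    if patch_size > S:
        raise ValueError("patch larger than the model input")
    starts = sorted(set(list(range(0, S - patch_size + 1, stride)) + [S - patch_size]))
    base = float(model.predict(x[None])[0, class_index])

    batch, spans = [], []
    for r in starts:
        for c in starts:
            xo = x.copy()
            xo[0, r:r + patch_size, c:c + patch_size] = baseline_value
            batch.append(xo)
            spans.append((r, c))
    scores = model.predict(np.stack(batch))[:, class_index]

    total = np.zeros((S, S))
    count = np.zeros((S, S))
    for (r, c), s in zip(spans, scores):
        total[r:r + patch_size, c:c + patch_size] += base - s
        count[r:r + patch_size, c:c + patch_size] += 1
    attr = total / np.maximum(count, 1)
    if disk is None:
        return FAMap(attr, FAMethod.OCCLUSION, class_index)
    return FAMap(_to_disk_grid(attr, disk), FAMethod.OCCLUSION, class_index)


def _grid_segments(side: int, n_superpixels: int) -> np.ndarray:
    """Regular grid segmentation with about n_superpixels cells."""
    per_side = max(2, int(round(np.sqrt(n_superpixels))))
    edges = np.linspace(0, side, per_side + 1).astype(int)
    seg = np.zeros((side, side), dtype=int)
    k = 0
    for i in range(per_side):
        for j in range(per_side):
            seg[edges[i]:edges[i + 1], edges[j]:edges[j + 1]] = k
            k += 1
    return seg


def lime_map(
    model: Model, disk: TissueDisk | None, class_index: int,
    n_superpixels: int = 49, n_samples: int = 1000,
    kernel_width: float = 0.25, seed: int = 0,
    baseline_value: float = 0.0, top_k: int | None = None,
    ridge_alpha: float = 1.0, image: np.ndarray | None = None,
) -> FAMap:
    """Sparse linear surrogate over superpixel on/off perturbations.

    Binary perturbation vectors z are scored by the model; a ridge
    regression weighted by exp(-d(z, 1)^2 / kernel_width^2) (d = normalised
    L2 distance to the unperturbed point) is fitted and each superpixel's
    coefficient is broadcast to its pixels.  Optionally only the ``top_k``
    largest-magnitude coefficients are kept (sparsity).
    """
    if n_superpixels < 2:
        raise ValueError("degenerate segmentation: need at least 2 superpixels")
    if n_samples < n_superpixels:
        raise ValueError("need at least as many samples as superpixels")
    rng = np.random.default_rng(seed)
    x = image if image is not None else disk_to_image(disk, model.spec)
    S = x.shape[-1]
    seg = _grid_segments(S, n_superpixels)
    n_seg = seg.max() + 1

    Z = rng.integers(0, 2, size=(n_samples, n_seg)).astype(float)
    Z[0] = 1.0  # include the unperturbed point
    batch = np.empty((n_samples, 1, S, S))
    for i in range(n_samples):
        off = ~Z[i].astype(bool)[seg]
        xi = x.copy()
        xi[0][off] = baseline_value
        batch[i] = xi
    scores = model.predict(batch)[:, class_index]

    d = np.linalg.norm(1.0 - Z, axis=1) / np.sqrt(n_seg)
    weights = np.exp(-(d**2) / kernel_width**2)
    reg = Ridge(alpha=ridge_alpha, fit_intercept=True)
    reg.fit(Z, scores, sample_weight=weights)
    coef = reg.coef_.copy()
    if top_k is not None and top_k < n_seg:
        keep = np.argsort(np.abs(coef))[-top_k:]
        sparse = np.zeros_like(coef)
        sparse[keep] = coef[keep]
        coef = sparse
    attr = coef[seg]
    if disk is None:
        return FAMap(attr, FAMethod.LIME, class_index)
    return FAMap(_to_disk_grid(attr, disk), FAMethod.LIME, class_index)


# ---------------------------------------------------------------------------
# informative regions and metrics


def threshold_fa(fa: FAMap, disk: TissueDisk, factor: float = 1.0) -> InformativeRegion:
    """Region of pixels strictly above factor x (mean attribution over
    tissue pixels); background is excluded from both mean and region."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    tissue = disk.tissue_mask
    thr = factor * float(fa.attribution[tissue].mean())
    mask = (fa.attribution > thr) & tissue
    return InformativeRegion(mask=mask, threshold_factor=factor, threshold_value=thr)


@dataclass
class InterpMetrics:
    iou: float
    lesion_pct: float
    nat_pct: float


def compute_metrics(region: InformativeRegion, lesions: LesionMask,
                    disk: TissueDisk) -> InterpMetrics:
    """IoU, lesion percentage and NAT percentage of a region vs lesions.

    Empty denominators give NaN (reported as missing and excluded pairwise
    from downstream statistics).
    """
    R = region.mask
    L = lesions.mask
    if R.shape != L.shape or R.shape != disk.label_grid.shape:
        raise ValueError("region, lesions and disk must share one grid")
    nat = disk.tissue_mask & ~L & ~disk.fibrosis_mask
    inter = float((R & L).sum())
    union = float((R | L).sum())
    iou = inter / union if union else float("nan")
    lesion_pct = inter / float(L.sum()) if L.sum() else float("nan")
    nat_pct = float((R & nat).sum()) / float(R.sum()) if R.sum() else float("nan")
    return InterpMetrics(iou=iou, lesion_pct=lesion_pct, nat_pct=nat_pct)


def population_average(items: list) -> np.ndarray:
    """Pixel-wise mean of per-item min-max normalised grids."""
    if not items:
        raise ValueError("empty list")
    grids = []
    for it in items:
        g = getattr(it, "attribution", None)
        if g is None:
            g = getattr(it, "mask", it)
        g = np.asarray(g, dtype=float)
        lo, hi = g.min(), g.max()
        grids.append((g - lo) / (hi - lo) if hi > lo else np.zeros_like(g))
    return np.mean(grids, axis=0)


# ---------------------------------------------------------------------------
# study driver


@dataclass
class InterpretConfig:
    factors: tuple[float, ...] = (0.75, 1.0, 1.25)
    #: conv block GradCAM taps (1-based; None = last block)
    gradcam_block: int | None = None
    occlusion_patch: int = 16
    occlusion_stride: int = 8
    lime_superpixels: int = 49
    lime_samples: int = 1000
    lime_kernel_width: float = 0.25
    seed: int = 0


def run_interpretability_study(
    model: Model,
    disks: dict[str, TissueDisk],
    outcomes: dict[str, dict[Strategy, StrategyOutcome]],
    labels: dict[str, np.ndarray],
    config: InterpretConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """FA maps, informative regions and metrics for every disk x method x
    strategy x threshold factor on a labelled hold-out set.

    Returns the long-format metrics table (with the per-disk correct/
    incorrect classification flag) and population-level averaged maps and
    lesions per method/strategy.
    """
    cfg = config or InterpretConfig()
    strategies = list(Strategy)
    rows = []
    maps_by = {(m, s): [] for m in FAMethod for s in strategies}
    lesions_by = {s: [] for s in strategies}

    for disk_id, disk in disks.items():
        x = disk_to_image(disk, model.spec)[None]
        scores = model.predict(x)[0]
        preds = (scores >= 0.5).astype(int)
        for ci, strat in enumerate(strategies):
            out = outcomes[disk_id][strat]
            lesions_by[strat].append(out.lesions.mask.astype(float))
            correct = bool(preds[ci] == int(labels[disk_id][ci]))
            fa_maps = {
                FAMethod.GRADCAM: gradcam(model, disk, ci,
                                          conv_block=cfg.gradcam_block),
                FAMethod.OCCLUSION: occlusion_map(
                    model, disk, ci, cfg.occlusion_patch, cfg.occlusion_stride),
                FAMethod.LIME: lime_map(
                    model, disk, ci, cfg.lime_superpixels, cfg.lime_samples,
                    cfg.lime_kernel_width, seed=cfg.seed),
            }
            for method, fa in fa_maps.items():
                maps_by[(method, strat)].append(fa)
                for factor in cfg.factors:
                    region = threshold_fa(fa, disk, factor)
                    m = compute_metrics(region, out.lesions, disk)
                    rows.append(dict(
                        disk=disk_id, method=method.value, strategy=strat.value,
                        factor=factor, iou=m.iou, lesion_pct=m.lesion_pct,
                        nat_pct=m.nat_pct, correct_classification=correct,
                    ))

    table = pd.DataFrame(rows)
    averages = {
        "fa": {(m.value, s.value): population_average(v)
               for (m, s), v in maps_by.items() if v},
        "lesions": {s.value: population_average(v)
                    for s, v in lesions_by.items() if v},
    }
    return table, averages
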