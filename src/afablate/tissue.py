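"""Synthetic 2D left-atrial tissue disks with pulmonary veins and fibrosis.

The simulation and learning pipeline operates on standardised circular 2D
tissue "disks": an unfolded left atrium represented as a labelled pixel grid
(outside / healthy / fibrotic / pulmonary-vein opening) at 0.3 mm spacing.
This module generates such disks synthetically: a spatially correlated
fibrosis intensity field stands in for a normalised LGE-MRI intensity map,
and a virtual cohort is built by weighted averaging of base intensity maps,
random affine transforms, random fibrosis thresholds, and one of six fixed
pulmonary-vein layout variants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage


class Label(IntEnum):
    """Per-pixel tissue class."""

    OUTSIDE = 0
    HEALTHY = 1
    FIBROTIC = 2
    PV = 3


N_PV_VARIANTS = 6

# Six fixed pulmonary-vein layout variants: {small, large} radius x three
# angular layouts (rotations of a 4-vein arrangement).  Radii and the ring
# the PV centres sit on are fractions of the grid size so the layouts scale
# with the disk.
_PV_RADIUS_FRAC = {"small": 0.045, "large": 0.07}
_PV_ANGLE_OFFSETS_DEG = (0.0, 15.0, 30.0)
_PV_BASE_ANGLES_DEG = (45.0, 135.0, 225.0, 315.0)
_PV_RING_FRAC = 0.72  # PV centres at this fraction of the disk radius


class GeometryError(ValueError):
    """Raised when a requested disk geometry cannot be constructed."""


@dataclass(frozen=True)
class DiskGeometry:
    """Circular tissue domain with pulmonary-vein openings.

    Attributes
    ----------
    grid_shape : (H, W) pixel shape.
    pixel_spacing : pixel edge length in mm.
    disk_mask : boolean grid, True inside the tissue disk.
    pv_list : list of (row, col, radius_px) pulmonary-vein discs.
    pv_variant : which of the six fixed PV layouts was used (1-based).
    """

    grid_shape: tuple[int, int]
    pixel_spacing: float
    disk_mask: np.ndarray
    pv_list: tuple[tuple[float, float, float], ...]
    pv_variant: int

    @property
    def pv_mask(self) -> np.ndarray:
        H, W = self.grid_shape
        rr, cc = np.mgrid[0:H, 0:W]
        mask = np.zeros((H, W), dtype=bool)
        for r0, c0, rad in self.pv_list:
            mask |= (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
        return mask


def make_disk_geometry(
    size: int, pv_variant: int, pixel_spacing: float = 0.3
) -> DiskGeometry:
    """Build the deterministic disk geometry for one PV layout variant.

    Parameters
    ----------
    size : grid edge length in pixels (square grid), >= 64.
    pv_variant : integer in 1..6 selecting PV radius/placement.
    """
    if size < 64:
        raise GeometryError(f"grid size {size} too small to contain PVs (min 64)")
    if not 1 <= pv_variant <= N_PV_VARIANTS:
        raise GeometryError(f"pv_variant must be in 1..{N_PV_VARIANTS}, got {pv_variant}")

    H = W = int(size)
    centre = (H - 1) / 2.0
    disk_radius = size / 2.0 - 2.0
    rr, cc = np.mgrid[0:H, 0:W]
    disk_mask = (rr - centre) ** 2 + (cc - centre) ** 2 <= disk_radius**2

    size_key = "small" if pv_variant <= 3 else "large"
    offset = _PV_ANGLE_OFFSETS_DEG[(pv_variant - 1) % 3]
    pv_radius = _PV_RADIUS_FRAC[size_key] * size
    ring = _PV_RING_FRAC * disk_radius

    pv_list = []
    for base in _PV_BASE_ANGLES_DEG:
        theta = np.deg2rad(base + offset)
        r0 = centre - ring * np.sin(theta)
        c0 = centre + ring * np.cos(theta)
        if np.hypot(r0 - centre, c0 - centre) + pv_radius >= disk_radius:
            raise GeometryError("PV disc does not fit strictly inside the disk")
        pv_list.append((r0, c0, pv_radius))

    return DiskGeometry(
        grid_shape=(H, W),
        pixel_spacing=pixel_spacing,
        disk_mask=disk_mask,
        pv_list=tuple(pv_list),
        pv_variant=pv_variant,
    )


@dataclass
class FibrosisField:
    """Smooth intensity surrogate for a normalised LGE-MRI map, in [0, 1]."""

    intensity: np.ndarray
    correlation_length: float
    seed: int
    geometry: DiskGeometry


def sample_base_fibrosis(
    geometry: DiskGeometry, correlation_length: float = 4.0, seed: int = 0
) -> FibrosisField:
    """Sample a spatially correlated fibrosis intensity field.

    Gaussian-filtered white noise with filter sigma chosen so the field's
    autocorrelation falls to 1/e at a lag of ``correlation_length`` (mm),
    then min-max normalised to [0, 1] inside the disk and zeroed outside.
    """
    if correlation_length <= geometry.pixel_spacing:
        raise ValueError("correlation_length must exceed the pixel spacing")
    rng = np.random.default_rng(seed)
    H, W = geometry.grid_shape
    noise = rng.standard_normal((H, W))
    # autocorr of g_sigma-filtered white noise is exp(-lag^2 / (4 sigma^2))
    sigma_px = (correlation_length / geometry.pixel_spacing) / 2.0
    smooth = ndimage.gaussian_filter(noise, sigma=sigma_px, mode="reflect")
    inside = geometry.disk_mask
    vals = smooth[inside]
    lo, hi = vals.min(), vals.max()
    out = np.zeros((H, W))
    if hi > lo:
        out[inside] = (smooth[inside] - lo) / (hi - lo)
    return FibrosisField(out, correlation_length, seed, geometry)


def weighted_average_augment(
    fields: list[FibrosisField], seed: int = 0
) -> FibrosisField:
    """Blend intensity maps with one random scalar weight per map.

    Each map receives a weight drawn uniform(0, 1) applied to all of its
    pixels; the output is the weight-normalised average, which stays in
    [0, 1] by construction (clipped for float safety).
    """
    if not fields:
        raise ValueError("need at least one field")
    geom = fields[0].geometry
    for f in fields[1:]:
        if f.intensity.shape != fields[0].intensity.shape:
            raise ValueError("all fields must share the same grid shape")
    rng = np.random.default_rng(seed)
    weights = rng.uniform(0.0, 1.0, size=len(fields))
    total = weights.sum()
    if total == 0:  # pragma: no cover - probability zero
        weights[:] = 1.0
        total = float(len(fields))
    stack = np.stack([f.intensity for f in fields])
    avg = np.tensordot(weights, stack, axes=1) / total
    avg = np.clip(avg, 0.0, 1.0)
    avg[~geom.disk_mask] = 0.0
    return FibrosisField(avg, fields[0].correlation_length, seed, geom)


def affine_augment(
    fld: FibrosisField, seed: int = 0, transforms: list[tuple] | None = None
) -> FibrosisField:
    """Apply a random non-empty subset of {translation, rotation, flip}.

    Transforms act on the fibrosis intensity only; the disk and PV geometry
    are left untouched.  Intensity carried outside the disk is discarded
    (zeroed), uncovered pixels are filled with 0.  An explicit ``transforms``
    list such as ``[("flip", 0), ("rotate", 90.0), ("translate", (2, -3))]``
    overrides the random selection.
    """
    rng = np.random.default_rng(seed)
    geom = fld.geometry
    out = fld.intensity.copy()

    if transforms is None:
        chosen: list[tuple] = []
        while not chosen:
            max_shift = geom.grid_shape[0] // 8
            if rng.random() < 0.5:
                chosen.append(
                    ("translate", tuple(rng.integers(-max_shift, max_shift + 1, size=2)))
                )
            if rng.random() < 0.5:
                chosen.append(("rotate", float(rng.uniform(0.0, 360.0))))
            if rng.random() < 0.5:
                chosen.append(("flip", int(rng.integers(0, 2))))
        transforms = chosen

    for kind, arg in transforms:
        if kind == "translate":
            out = ndimage.shift(out, arg, order=1, mode="constant", cval=0.0)
        elif kind == "rotate":
            out = ndimage.rotate(
                out, arg, order=1, reshape=False, mode="constant", cval=0.0
            )
        elif kind == "flip":
            out = np.flip(out, axis=arg)
        else:
            raise ValueError(f"unknown transform {kind!r}")

    out = np.clip(out, 0.0, 1.0)
    out[~geom.disk_mask] = 0.0
    return FibrosisField(np.ascontiguousarray(out), fld.correlation_length, seed, geom)


@dataclass
class TissueDisk:
    """Labelled 2D tissue disk: the simulation domain and the CNN input."""

    geometry: DiskGeometry
    label_grid: np.ndarray  # uint8 of Label values
    fibrotic_fraction: float
    provenance: dict = field(default_factory=dict)

    @property
    def tissue_mask(self) -> np.ndarray:
        """Excitable pixels: healthy or fibrotic."""
        return (self.label_grid == Label.HEALTHY) | (self.label_grid == Label.FIBROTIC)

    @property
    def fibrosis_mask(self) -> np.ndarray:
        return self.label_grid == Label.FIBROTIC

    def recompute_fibrotic_fraction(self) -> float:
        n_fib = int(self.fibrosis_mask.sum())
        n_tissue = int(self.tissue_mask.sum())
        return n_fib / n_tissue if n_tissue else 0.0


def threshold_fibrosis(
    fld: FibrosisField, geometry: DiskGeometry, threshold: float
) -> TissueDisk:
    """Binarise an intensity field into a labelled disk at a given threshold.

    Pixels with intensity >= threshold (inside the disk, outside the PVs)
    become fibrotic; remaining disk pixels are healthy.
    """
    if not 0.0 < threshold:
        raise ValueError("threshold must be positive")
    H, W = geometry.grid_shape
    label_grid = np.full((H, W), Label.OUTSIDE, dtype=np.uint8)
    pv = geometry.pv_mask
    inside = geometry.disk_mask
    label_grid[inside] = Label.HEALTHY
    label_grid[inside & (fld.intensity >= threshold)] = Label.FIBROTIC
    label_grid[pv & inside] = Label.PV

    disk = TissueDisk(
        geometry=geometry,
        label_grid=label_grid,
        fibrotic_fraction=0.0,
        provenance={"threshold": float(threshold), "field_seed": fld.seed},
    )
    disk.fibrotic_fraction = disk.recompute_fibrotic_fraction()
    return disk


@dataclass
class CohortConfig:
    """Knobs for virtual-cohort generation.

    ``threshold_range`` controls the uniform draw of the fibrosis threshold
    per disk (lower thresholds give heavier fibrotic burden).
    """

    size: int = 128
    pixel_spacing: float = 0.3
    correlation_length: float = 4.0
    threshold_range: tuple[float, float] = (0.55, 0.75)


def generate_cohort(
    n_base: int,
    n_synthetic: int,
    seed: int = 0,
    config: CohortConfig | None = None,
) -> tuple[list[TissueDisk], pd.DataFrame]:
    """Generate ``n_base`` independent disks plus ``n_synthetic`` augmented ones.

    Synthetic disks are built the way the virtual cohort is enlarged: a
    randomly weighted average of all base intensity maps, followed by random
    affine transforms, a randomly drawn fibrosis threshold and a random PV
    layout variant.  Fully reproducible from (seed, config).
    """
    if n_base < 1:
        raise ValueError("need at least one base disk")
    cfg = config or CohortConfig()
    root = np.random.SeedSequence(seed)
    ss_fields, ss_disks, ss_synth = root.spawn(3)

    canonical = make_disk_geometry(cfg.size, 1, cfg.pixel_spacing)
    field_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss_fields.spawn(n_base)]
    base_fields = [
        sample_base_fibrosis(canonical, cfg.correlation_length, s) for s in field_seeds
    ]

    disks: list[TissueDisk] = []
    rows = []
    rng = np.random.default_rng(ss_disks)
    lo, hi = cfg.threshold_range
    for i, fld in enumerate(base_fields):
        variant = int(rng.integers(1, N_PV_VARIANTS + 1))
        thr = float(rng.uniform(lo, hi))
        geom = make_disk_geometry(cfg.size, variant, cfg.pixel_spacing)
        disk = threshold_fibrosis(fld, geom, thr)
        disk.provenance.update(kind="base", cohort_index=i)
        disks.append(disk)
        rows.append(
            dict(
                id=f"base-{i:04d}",
                kind="base",
                seed=fld.seed,
                fibrotic_fraction=disk.fibrotic_fraction,
                pv_variant=variant,
                threshold=thr,
            )
        )

    rng_s = np.random.default_rng(ss_synth)
    for j in range(n_synthetic):
        w_seed = int(rng_s.integers(0, 2**31))
        a_seed = int(rng_s.integers(0, 2**31))
        variant = int(rng_s.integers(1, N_PV_VARIANTS + 1))
        thr = float(rng_s.uniform(lo, hi))
        blended = weighted_average_augment(base_fields, seed=w_seed)
        # averaging many maps compresses the intensity range towards the
        # middle; restretch inside the disk (before the affine step, whose
        # zero-filled uncovered margins would skew the range) so the
        # threshold draw spans the same burden range as for base disks
        inside = canonical.disk_mask
        vals = blended.intensity[inside]
        lo, hi = vals.min(), vals.max()
        if hi - lo > 1e-9:
            blended.intensity[inside] = (vals - lo) / (hi - lo)
        warped = affine_augment(blended, seed=a_seed)
        geom = make_disk_geometry(cfg.size, variant, cfg.pixel_spacing)
        disk = threshold_fibrosis(warped, geom, thr)
        disk.provenance.update(
            kind="synthetic", cohort_index=n_base + j, weight_seed=w_seed, affine_seed=a_seed
        )
        disks.append(disk)
        rows.append(
            dict(
                id=f"synth-{j:04d}",
                kind="synthetic",
                seed=w_seed,
                fibrotic_fraction=disk.fibrotic_fraction,
                pv_variant=variant,
                threshold=thr,
            )
        )

    manifest = pd.DataFrame(rows)
    return disks, manifest


def make_sheet(shape: tuple[int, int], pixel_spacing: float = 0.3) -> TissueDisk:
    """All-healthy rectangular sheet (1-px outside rim), for calibration and
    protocol studies that do not need the disk anatomy."""
    H, W = shape
    label_grid = np.full((H, W), Label.OUTSIDE, dtype=np.uint8)
    label_grid[1:-1, 1:-1] = Label.HEALTHY
    disk_mask = label_grid != Label.OUTSIDE
    geom = DiskGeometry(
        grid_shape=(H, W),
        pixel_spacing=pixel_spacing,
        disk_mask=disk_mask,
        pv_list=(),
        pv_variant=1,
    )
    return TissueDisk(geometry=geom, label_grid=label_grid, fibrotic_fraction=0.0)


# ---------------------------------------------------------------------------
# serialisation


def save_disk(disk: TissueDisk, path: str | Path) -> None:
    """Write one disk as a compressed array archive plus a JSON sidecar."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), label_grid=disk.label_grid)
    geom = disk.geometry
    sidecar = {
        "grid_shape": list(geom.grid_shape),
        "pixel_spacing": geom.pixel_spacing,
        "pv_list": [list(p) for p in geom.pv_list],
        "pv_variant": geom.pv_variant,
        "fibrotic_fraction": disk.fibrotic_fraction,
        "provenance": disk.provenance,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_disk(path: str | Path) -> TissueDisk:
    path = Path(path)
    arrays = np.load(path.with_suffix(".npz"))
    meta = json.loads(path.with_suffix(".json").read_text())
    geom = make_disk_geometry(
        meta["grid_shape"][0], meta["pv_variant"], meta["pixel_spacing"]
    )
    disk = TissueDisk(
        geometry=geom,
        label_grid=arrays["label_grid"],
        fibrotic_fraction=meta["fibrotic_fraction"],
        provenance=meta["provenance"],
    )
    return disk
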