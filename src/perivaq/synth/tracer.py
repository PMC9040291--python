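"""Synthetic CSF tracer slices: region masks with planted coverage fronts.

Emulates the coronal-section tracer assays: five standard slices per animal,
each carrying a whole-brain mask subdivided into cortex, hippocampus,
striatum and diencephalon.  Intracisternally delivered tracer enters from the
brain surface, so the planted front fills each region from its shallowest
pixels (smallest depth below the surface) inward until the requested area
fraction is covered, then receives a soft edge and noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ..image import Image2D
from ..tracer import RegionMaskSet

__all__ = [
    "SliceSpec",
    "TracerSpec",
    "make_region_masks",
    "generate_tracer_slices",
    "INFLUX_BREGMA_MM",
    "EFFLUX_BREGMA_MM",
]

#: standard coronal levels, mm relative to bregma
INFLUX_BREGMA_MM = (1.0, 0.0, -1.5, -2.5, -3.5)
EFFLUX_BREGMA_MM = (2.5, 1.5, 0.0, -1.0, -2.0)

REGIONS = ("cortex", "hippocampus", "striatum", "diencephalon")


@dataclass(frozen=True)
class SliceSpec:
    bregma_mm: float
    coverage: dict  # region -> planted fraction in [0, 1]

    def __post_init__(self):
        for region, frac in self.coverage.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"coverage[{region!r}] = {frac} outside [0, 1]")


@dataclass(frozen=True)
class TracerSpec:
    slices: tuple[SliceSpec, ...]
    height_px: int = 240
    width_px: int = 300
    pixel_size_um: float = 10.0  # slide-scanner scale
    tracer_intensity: float = 100.0
    front_decay_um: float = 20.0
    noise_sigma: float = 3.0
    split_hemispheres: bool = False  # efflux mode: ipsi/contra sublabels
    seed: int = 0

    def __post_init__(self):
        if not self.slices:
            raise ValueError("TracerSpec.slices is empty")
        if self.tracer_intensity <= 0:
            raise ValueError("tracer_intensity must be > 0")


def make_region_masks(
    height_px: int,
    width_px: int,
    bregma_mm: float,
    slice_id: str | None = None,
    split_hemispheres: bool = False,
) -> RegionMaskSet:
    """Deterministic stylised coronal-section masks at one bregma level.

    The whole-brain outline is an ellipse; cortex is its outer shell and the
    three deep regions are disjoint interior sectors.  Geometry varies
    slightly with the bregma coordinate so no two levels are identical.
    """
    h, w = height_px, width_px
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = h / 2, w / 2
    # slight level-dependent shrink toward the poles of the cerebrum
    scale = 1.0 - 0.06 * abs(bregma_mm) / 3.5
    ry, rx = 0.42 * h * scale, 0.45 * w * scale
    r2 = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
    whole = r2 <= 1.0

    cortex = (r2 <= 1.0) & (r2 > 0.55)
    interior = r2 <= 0.55
    upper = yy < cy - 0.05 * h
    lower = yy >= cy + 0.12 * h
    middle = ~upper & ~lower
    regions = {
        "cortex": cortex,
        "hippocampus": interior & upper,
        "striatum": interior & middle,
        "diencephalon": interior & lower,
    }
    if split_hemispheres:
        left = xx < cx
        split = {}
        for name, m in regions.items():
            split[f"{name}_ipsi"] = m & left
            split[f"{name}_contra"] = m & ~left
        regions = split
    return RegionMaskSet(
        slice_id=slice_id or f"bregma{bregma_mm:+.1f}",
        bregma_mm=bregma_mm,
        whole=whole,
        regions=regions,
    )


def _plant_front(region: np.ndarray, depth: np.ndarray, fraction: float) -> np.ndarray:
    """Fill the shallowest ``fraction`` of region pixels (+-1 px quantization)."""
    n = int(region.sum())
    k = int(round(fraction * n))
    if k == 0:
        return np.zeros_like(region)
    idx = np.flatnonzero(region.ravel())
    order = np.argsort(depth.ravel()[idx], kind="stable")
    mask = np.zeros(region.size, dtype=bool)
    mask[idx[order[:k]]] = True
    return mask.reshape(region.shape)


def generate_tracer_slices(
    spec: TracerSpec,
) -> tuple[list[tuple[Image2D, RegionMaskSet]], pd.DataFrame]:
    """Render tracer channels over region masks with planted coverage.

    Returns one ``(image, masks)`` pair per slice and a ground-truth table
    with the planted and the quantized (pixel-exact) coverage fraction per
    region.  Thresholding the tracer channel at half the planted intensity
    recovers the quantized fractions.
    """
    rng = np.random.default_rng(spec.seed)
    out = []
    rows = []
    for s in spec.slices:
        masks = make_region_masks(
            spec.height_px,
            spec.width_px,
            s.bregma_mm,
            split_hemispheres=spec.split_hemispheres,
        )
        # depth below the CSF-facing brain surface
        depth = ndimage.distance_transform_edt(masks.whole) * spec.pixel_size_um
        tracer = np.zeros((spec.height_px, spec.width_px))
        for region, frac in s.coverage.items():
            if region not in masks.regions:
                raise KeyError(f"unknown region {region!r} in slice {masks.slice_id}")
            m = masks.regions[region]
            front = _plant_front(m, depth, frac)
            tracer[front] = spec.tracer_intensity
            rows.append(
                {
                    "slice_id": masks.slice_id,
                    "bregma_mm": s.bregma_mm,
                    "region": region,
                    "planted_fraction": frac,
                    "quantized_fraction": front.sum() / max(m.sum(), 1),
                }
            )
        if spec.front_decay_um > 0:
            sigma_px = spec.front_decay_um / spec.pixel_size_um / 4.0
            tracer = ndimage.gaussian_filter(tracer, sigma_px)
        if spec.noise_sigma > 0:
            tracer = tracer + rng.normal(0, spec.noise_sigma, tracer.shape)
        tracer = np.clip(tracer, 0, None)
        image = Image2D(
            channels={"tracer": tracer},
            pixel_size_um=spec.pixel_size_um,
            metadata={"generator": "generate_tracer_slices", "slice_id": masks.slice_id},
        )
        out.append((image, masks))
    return out, pd.DataFrame(rows)
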