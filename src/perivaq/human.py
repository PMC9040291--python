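"""Threshold-based AQP4 analysis of human post-mortem cortex and hippocampus.

Post-mortem human tissue carries too much autofluorescence and lipofuscin for
line-based perivascular profiling, so quantification is coarser: two
intensity thresholds partition each 1000x1000-px ROI into a *vessel* class
(bright perivascular endfoot signal at vessel edges, pixels >= the vessel
threshold) and a *cellular* class (astrocyte fine-process signal, pixels in
the half-open band [cellular threshold, vessel threshold)).  The AQP4
polarization ratio is the mean of the vessel class over the mean of the
cellular class; cellular area coverage is the fraction of pixels at or above
the cellular threshold.  Local p-tau burden is a count of AT8-positive
somata per mm^2 over the same ROIs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .image import Image2D

__all__ = [
    "ROISpec",
    "ThresholdPair",
    "HumanROIMeasures",
    "place_rois",
    "auto_thresholds",
    "measure_roi_aqp4",
    "ptau_density",
    "aggregate_subject",
]

log = logging.getLogger(__name__)

REGION_TAGS = ("gray", "white", "CA1", "CA2", "CA3")
DEFAULT_ROI_PX = 1000


@dataclass(frozen=True)
class ROISpec:
    """Axis-aligned ROI: pixel offsets, size and region tag."""

    x: int
    y: int
    width_px: int = DEFAULT_ROI_PX
    height_px: int = DEFAULT_ROI_PX
    label: str = "gray"

    def __post_init__(self):
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("ROI width and height must be > 0")
        if self.x < 0 or self.y < 0:
            raise ValueError("ROI offsets must be >= 0")

    def extract(self, arr: np.ndarray) -> np.ndarray:
        h, w = arr.shape
        if self.y + self.height_px > h or self.x + self.width_px > w:
            raise ValueError(f"ROI {self} exceeds image {h}x{w}")
        return arr[self.y : self.y + self.height_px, self.x : self.x + self.width_px]


@dataclass(frozen=True)
class ThresholdPair:
    """Cellular and vessel intensity thresholds (AU), cellular < vessel.

    In the degenerate fully-depolarized limit the two populations merge and
    vessel == the common tier value is tolerated only through
    ``ThresholdPair(cellular, vessel)`` with ``vessel > cellular`` still
    enforced; a merged population simply leaves one class empty downstream.
    """

    cellular_threshold: float
    vessel_threshold: float

    def __post_init__(self):
        if self.cellular_threshold < 0 or self.vessel_threshold < 0:
            raise ValueError("thresholds must be >= 0")
        if not self.cellular_threshold < self.vessel_threshold:
            raise ValueError(
                f"cellular_threshold ({self.cellular_threshold}) must be < "
                f"vessel_threshold ({self.vessel_threshold})"
            )


@dataclass
class HumanROIMeasures:
    """Per-ROI outputs of the dual-threshold workflow."""

    mean_if: float
    cellular_area_coverage: float
    polarization_ratio: float  # NaN when undefined
    roi: ROISpec | None = None
    ptau_density: float = np.nan  # counts / mm^2, filled separately
    undefined_reason: str | None = None

    @property
    def defined(self) -> bool:
        return np.isfinite(self.polarization_ratio)


def place_rois(
    image: Image2D | np.ndarray,
    layout: list[str],
    roi_size_px: int = DEFAULT_ROI_PX,
    seed: int | None = None,
    coords: list[tuple[int, int]] | None = None,
) -> list[ROISpec]:
    """Place non-overlapping square ROIs and tag them per ``layout``.

    ROIs occupy disjoint grid slots; with a ``seed`` the slots are sampled
    without replacement (deterministically), otherwise filled row-major.
    Explicit ``coords`` (x, y) override placement entirely.
    """
    arr = image.channels[next(iter(image.channels))] if isinstance(image, Image2D) else image
    h, w = arr.shape
    if coords is not None:
        if len(coords) != len(layout):
            raise ValueError("coords and layout length mismatch")
        return [
            ROISpec(x=x, y=y, width_px=roi_size_px, height_px=roi_size_px, label=tag)
            for (x, y), tag in zip(coords, layout)
        ]
    n_rows, n_cols = h // roi_size_px, w // roi_size_px
    n_slots = n_rows * n_cols
    if len(layout) > n_slots:
        raise ValueError(
            f"image {h}x{w} fits at most {n_slots} non-overlapping "
            f"{roi_size_px}-px ROIs; {len(layout)} requested"
        )
    slots = np.arange(n_slots)
    if seed is not None:
        slots = np.random.default_rng(seed).permutation(slots)
    chosen = slots[: len(layout)]
    rois = []
    for slot, tag in zip(chosen, layout):
        r, c = divmod(int(slot), n_cols)
        rois.append(
            ROISpec(
                x=c * roi_size_px,
                y=r * roi_size_px,
                width_px=roi_size_px,
                height_px=roi_size_px,
                label=tag,
            )
        )
    return rois


def auto_thresholds(
    roi_image: np.ndarray,
    method: str = "percentile",
    vessel_percentile: float = 99.5,
    cellular_percentile: float = 90.0,
) -> ThresholdPair:
    """Suggest a threshold pair from the ROI's intensity distribution.

    The default mirrors the manual practice of thresholding down from the
    brightest (vessel-edge) pixels: the vessel threshold at an upper
    percentile, the cellular threshold at a lower one.  Values are meant to
    be reviewed and overridable by explicit config, exactly as manual
    uniform thresholds would be.
    """
    arr = np.asarray(roi_image, dtype=float)
    if arr.std() == 0:
        raise ValueError("constant ROI: thresholds undefined (zero variance)")
    if method != "percentile":
        raise ValueError(f"unknown threshold method {method!r}")
    if not cellular_percentile < vessel_percentile:
        raise ValueError("cellular_percentile must be < vessel_percentile")
    v = float(np.percentile(arr, vessel_percentile))
    c = float(np.percentile(arr, cellular_percentile))
    if not c < v:
        # heavily quantized histograms can collapse the percentiles
        raise ValueError(
            f"percentiles collapse to a single value ({c}); supply manual thresholds"
        )
    return ThresholdPair(cellular_threshold=c, vessel_threshold=v)


def measure_roi_aqp4(
    roi_image: np.ndarray, thresholds: ThresholdPair, roi: ROISpec | None = None
) -> HumanROIMeasures:
    """Dual-threshold ROI measurement.

    vessel class = pixels >= vessel_threshold; cellular class = pixels in
    [cellular_threshold, vessel_threshold); coverage counts every pixel at or
    above the cellular threshold (the vessel class is a subset of the
    covered area).  An empty class leaves the ratio NaN with a recorded
    reason -- undefined measures propagate as missing, never as zeros.
    """
    arr = np.asarray(roi_image, dtype=float)
    vessel = arr >= thresholds.vessel_threshold
    cellular = (arr >= thresholds.cellular_threshold) & ~vessel
    coverage = float((vessel.sum() + cellular.sum()) / arr.size)
    mean_if = float(arr.mean())

    reason = None
    if not vessel.any() and not cellular.any():
        reason = "both threshold classes empty"
    elif not vessel.any():
        reason = "empty vessel class"
    elif not cellular.any():
        reason = "empty cellular class"
    if reason is not None:
        log.info("ROI %s: polarization undefined (%s)", roi, reason)
        ratio = np.nan
    else:
        ratio = float(arr[vessel].mean() / arr[cellular].mean())
    return HumanROIMeasures(
        mean_if=mean_if,
        cellular_area_coverage=coverage,
        polarization_ratio=ratio,
        roi=roi,
        undefined_reason=reason,
    )


def ptau_density(
    source: int | np.ndarray,
    pixel_size_um: float | None,
    roi_shape_px: tuple[int, int] = (DEFAULT_ROI_PX, DEFAULT_ROI_PX),
    intensity_percentile: float = 99.0,
    soma_area_um2: tuple[float, float] = (20.0, 400.0),
    smooth_sigma_um: float = 1.0,
) -> float:
    """p-tau-positive somata per mm^2, from a manual count or an image.

    With an integer ``source`` the count is simply normalised by the ROI
    area.  With an image, somata are detected as connected components above
    the ``intensity_percentile`` threshold whose area lies in
    ``soma_area_um2`` (gating out speckle and confluent artefact).
    """
    if pixel_size_um is None or not pixel_size_um > 0:
        raise ValueError("pixel_size_um is required and must be > 0")
    if isinstance(source, (int, np.integer)):
        if source < 0:
            raise ValueError("count must be >= 0")
        count = int(source)
        h, w = roi_shape_px
    else:
        arr = np.asarray(source, dtype=float)
        h, w = arr.shape
        smoothed = ndimage.gaussian_filter(arr, smooth_sigma_um / pixel_size_um)
        thr = np.percentile(smoothed, intensity_percentile)
        lab = measure.label(smoothed >= thr)
        lo, hi = soma_area_um2
        px2 = pixel_size_um**2
        count = sum(
            1 for r in measure.regionprops(lab) if lo <= r.area * px2 <= hi
        )
    area_mm2 = h * w * pixel_size_um**2 * 1e-6
    return count / area_mm2


def aggregate_subject(
    measures: list[HumanROIMeasures],
    region: str,
    excluded: set[int] | None = None,
) -> dict:
    """Mean per-subject value over the region's valid ROIs.

    ROIs flagged out-of-focus (indices in ``excluded``) and ROIs with an
    undefined ratio are dropped; the number actually used is recorded.  With
    no valid ROI the aggregate is missing with the reason logged.
    """
    excluded = excluded or set()
    kept = [
        m for i, m in enumerate(measures) if i not in excluded
    ]
    valid_ratio = [m.polarization_ratio for m in kept if m.defined]
    out = {
        "region": region,
        "n_rois": len(measures),
        "n_used": len(valid_ratio),
        "mean_if": float(np.mean([m.mean_if for m in kept])) if kept else np.nan,
        "cellular_area_coverage": float(np.mean([m.cellular_area_coverage for m in kept]))
        if kept
        else np.nan,
        "polarization_ratio": float(np.mean(valid_ratio)) if valid_ratio else np.nan,
        "ptau_density": float(np.nanmean([m.ptau_density for m in kept]))
        if kept and np.any(np.isfinite([m.ptau_density for m in kept]))
        else np.nan,
    }
    if not valid_ratio:
        out["missing_reason"] = "no valid ROI (all excluded or undefined)"
        log.warning("region %s: %s", region, out["missing_reason"])
    return out
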