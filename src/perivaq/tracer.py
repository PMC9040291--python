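"""CSF tracer influx/efflux coverage per brain region and coronal slice.

A single uniform intensity threshold (chosen once per experiment and applied
identically to every animal and slice) converts the tracer channel into a
covered-area mask; coverage is reported per region as covered mm^2 over
region mm^2, and integrated across the standard coronal levels as the
area-weighted ratio sum(covered) / sum(region area), which tolerates missing
or excluded slices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import filters

from .image import Image2D

__all__ = [
    "RegionMaskSet",
    "tracer_coverage",
    "integrate_slices",
    "suggest_threshold",
]

log = logging.getLogger(__name__)


@dataclass
class RegionMaskSet:
    """Region label rasters for one coronal slice.

    Subregion masks must be subsets of ``whole`` and pairwise disjoint;
    efflux mode uses ``<region>_ipsi`` / ``<region>_contra`` sublabels.
    """

    slice_id: str
    bregma_mm: float
    whole: np.ndarray  # bool
    regions: dict  # name -> bool mask

    def __post_init__(self):
        for name, m in self.regions.items():
            if m.shape != self.whole.shape:
                raise ValueError(f"region {name!r} shape mismatch")
            if np.any(m & ~self.whole):
                raise ValueError(f"region {name!r} extends outside the whole-slice mask")
        names = list(self.regions)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if np.any(self.regions[a] & self.regions[b]):
                    raise ValueError(f"regions {a!r} and {b!r} overlap")


def tracer_coverage(
    tracer: np.ndarray | Image2D,
    masks: RegionMaskSet,
    threshold: float,
    pixel_size_um: float | None = None,
) -> pd.DataFrame:
    """Thresholded area coverage per region for one slice.

    Returns one row per region (plus ``whole``) with covered area, region
    area (mm^2) and the coverage fraction.  An empty region mask yields a
    missing row with a log entry rather than a crash.
    """
    if isinstance(tracer, Image2D):
        pixel_size_um = tracer.pixel_size_um
        tracer = tracer.channel("tracer")
    if pixel_size_um is None or not pixel_size_um > 0:
        raise ValueError("pixel_size_um required and must be > 0")
    px2_mm2 = pixel_size_um**2 * 1e-6
    covered = tracer >= threshold
    rows = []
    for name, m in [("whole", masks.whole), *masks.regions.items()]:
        n = int(m.sum())
        if n == 0:
            log.warning("slice %s: region %s empty, coverage missing", masks.slice_id, name)
            rows.append(
                {
                    "slice_id": masks.slice_id,
                    "bregma_mm": masks.bregma_mm,
                    "region": name,
                    "covered_mm2": np.nan,
                    "area_mm2": 0.0,
                    "fraction": np.nan,
                    "threshold": threshold,
                }
            )
            continue
        c = int((covered & m).sum())
        rows.append(
            {
                "slice_id": masks.slice_id,
                "bregma_mm": masks.bregma_mm,
                "region": name,
                "covered_mm2": c * px2_mm2,
                "area_mm2": n * px2_mm2,
                "fraction": c / n,
                "threshold": threshold,
            }
        )
    return pd.DataFrame(rows)


def integrate_slices(
    measures: pd.DataFrame,
    expected_bregma_mm: tuple[float, ...] | None = None,
) -> pd.DataFrame:
    """Area-weighted coverage across coronal slices, per region.

    integrated fraction = sum(covered mm^2) / sum(region mm^2) over the
    available (non-missing) slices; animals with excluded slices simply
    contribute the remainder.  Slices listed in ``expected_bregma_mm`` but
    absent are logged; a region with no valid slice at all comes back NaN.
    """
    df = measures.copy()
    if expected_bregma_mm is not None:
        have = set(np.round(df["bregma_mm"].unique(), 3))
        missing = [b for b in expected_bregma_mm if round(b, 3) not in have]
        if missing:
            log.warning("missing slices at bregma %s; integrating the remainder", missing)
    rows = []
    for region, sub in df.groupby("region", sort=False):
        valid = sub.dropna(subset=["covered_mm2"])
        if valid.empty:
            rows.append(
                {"region": region, "covered_mm2": np.nan, "area_mm2": np.nan,
                 "fraction": np.nan, "n_slices": 0}
            )
            continue
        cov = valid["covered_mm2"].sum()
        area = valid["area_mm2"].sum()
        rows.append(
            {
                "region": region,
                "covered_mm2": float(cov),
                "area_mm2": float(area),
                "fraction": float(cov / area) if area > 0 else np.nan,
                "n_slices": int(valid.shape[0]),
            }
        )
    return pd.DataFrame(rows)


def suggest_threshold(tracer_images: list[np.ndarray | Image2D]) -> float:
    """Otsu threshold over the pooled tracer histogram.

    A starting point for the one uniform per-experiment threshold; review it
    and then fix it in config for the whole experiment.
    """
    arrays = [
        im.channel("tracer") if isinstance(im, Image2D) else np.asarray(im, float)
        for im in tracer_images
    ]
    pooled = np.concatenate([a.ravel() for a in arrays])
    return float(filters.threshold_otsu(pooled))
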