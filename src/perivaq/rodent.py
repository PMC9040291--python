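"""Rodent perivascular AQP4 quantification.

Vessels are segmented from the lectin (endothelial) channel; capillaries
(< 10 um diameter) are measured as endfoot-annulus vs remote-neuropil mean
intensity, while large vessels (>= 10 um) get a folded cross-sectional
intensity profile perpendicular to the vessel axis, segmented into the
perivascular endfoot (0-1.5 um from the wall), perivascular astrocyte
(1.5-20 um) and neuropil (20-68 um) compartments.  GFP puncta are sized by
their above-half-maximum area and classed large (>= 2 um^2) vs small
(<= 1 um^2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import ndimage
from skimage import filters, measure, morphology
from skimage.feature import peak_local_max

from .image import Image2D

__all__ = [
    "CAPILLARY_CUTOFF_UM",
    "COMPARTMENT_BOUNDARIES_UM",
    "VesselAnnotation",
    "CrossSectionProfile",
    "CompartmentMeasures",
    "PunctaSet",
    "classify_vessel",
    "segment_vessels",
    "capillary_compartments",
    "cross_section_profile",
    "segment_profile",
    "diameter_association",
    "puncta_metrics",
    "gfp_localization_ratio",
]

log = logging.getLogger(__name__)

#: capillaries are vessels strictly below this diameter (um)
CAPILLARY_CUTOFF_UM = 10.0
#: endfoot / perivascular-astrocyte / neuropil boundaries from the wall (um)
COMPARTMENT_BOUNDARIES_UM = (1.5, 20.0, 68.0)
COMPARTMENT_NAMES = ("pv_endfoot", "pv_astro", "neuropil")


def classify_vessel(diameter_um: float) -> str:
    """'capillary' iff diameter < 10 um, else 'large' (10 um goes to large)."""
    if not diameter_um > 0:
        raise ValueError(f"diameter must be > 0, got {diameter_um}")
    return "capillary" if diameter_um < CAPILLARY_CUTOFF_UM else "large"


@dataclass
class VesselAnnotation:
    """One detected vessel: lumen geometry, caliber and class."""

    vessel_id: int
    lumen_mask: np.ndarray  # bool, full image size
    wall_mask: np.ndarray  # bool, lumen boundary pixels
    center: tuple[float, float]  # (row, col)
    axis: tuple[float, float]  # unit vector (drow, dcol) along the vessel
    diameter_um: float
    vessel_class: str

    def __post_init__(self):
        if self.vessel_class != classify_vessel(self.diameter_um):
            raise ValueError("vessel_class inconsistent with diameter")


@dataclass
class CrossSectionProfile:
    """Folded radial intensity profile, distance measured from the wall."""

    distances_um: np.ndarray  # strictly increasing, first tissue sample at 1 px
    mean_intensity: np.ndarray  # NaN where no samples
    n_samples: np.ndarray
    truncated: bool = False
    vessel_id: int | None = None


@dataclass
class CompartmentMeasures:
    pv_endfoot_if: float
    pv_astro_if: float
    neuropil_if: float
    boundaries_um: tuple[float, float, float] = COMPARTMENT_BOUNDARIES_UM
    vessel_id: int | None = None
    animal_id: str | None = None


@dataclass
class PunctaSet:
    areas_um2: list[float] = field(default_factory=list)

    @property
    def n_large(self) -> int:
        return int(np.sum(np.asarray(self.areas_um2) >= 2.0)) if self.areas_um2 else 0

    @property
    def n_small(self) -> int:
        return int(np.sum(np.asarray(self.areas_um2) <= 1.0)) if self.areas_um2 else 0

    @property
    def ratio_large_small(self) -> float:
        """n_large / n_small; NaN (flagged undefined) when n_small is zero."""
        return self.n_large / self.n_small if self.n_small else np.nan


def segment_vessels(
    image: Image2D,
    channel: str = "lectin",
    threshold: float | None = None,
    min_area_px: int = 16,
    closing_radius_px: int = 2,
) -> list[VesselAnnotation]:
    """Detect vessel lumens in the lectin channel.

    Otsu threshold (overridable) -> morphological closing -> connected
    components.  Diameter is twice the maximum inscribed-disk radius from
    the in-lumen distance transform; the wall is the component boundary; the
    axis is the component's principal axis of elongation (defaults to the
    image x-axis, with a log note, for near-circular cross-sections).
    A blank channel yields an empty list.
    """
    lectin = image.channel(channel)
    px = image.pixel_size_um
    if threshold is None:
        if lectin.max() == lectin.min():
            return []
        threshold = filters.threshold_otsu(lectin)
    mask = lectin > threshold
    if closing_radius_px > 0:
        mask = morphology.closing(mask, morphology.disk(closing_radius_px))
    if min_area_px > 1:
        mask = morphology.remove_small_objects(mask, max_size=min_area_px - 1)
    if not mask.any():
        return []
    labels = measure.label(mask)
    annotations = []
    for region in measure.regionprops(labels):
        lumen = labels == region.label
        edt = ndimage.distance_transform_edt(lumen)
        # EDT reaches background pixel *centers*: half a pixel beyond the
        # boundary on each side, hence the -1 px correction
        diameter_um = max(2.0 * float(edt.max()) - 1.0, 1.0) * px
        wall = lumen & ~ndimage.binary_erosion(lumen)
        if region.eccentricity > 0.5:
            theta = region.orientation  # angle of major axis vs row axis
            axis = (float(np.cos(theta)), float(-np.sin(theta)))
        else:
            log.info(
                "vessel %d near-circular (ecc=%.2f): axis defaults to image x-axis",
                region.label,
                region.eccentricity,
            )
            axis = (0.0, 1.0)
        annotations.append(
            VesselAnnotation(
                vessel_id=int(region.label),
                lumen_mask=lumen,
                wall_mask=wall,
                center=tuple(map(float, region.centroid)),
                axis=axis,
                diameter_um=diameter_um,
                vessel_class=classify_vessel(diameter_um),
            )
        )
    return annotations


def _annulus_fraction_present(lumen: np.ndarray, lo_px: float, hi_px: float) -> float:
    """Fraction of the (lo, hi]-px annulus that lies inside the image."""
    pad = int(np.ceil(hi_px)) + 2
    padded = np.pad(lumen, pad)
    d_pad = ndimage.distance_transform_edt(~padded)
    full = (d_pad > lo_px) & (d_pad <= hi_px)
    inside = full[pad:-pad, pad:-pad]
    n_full = int(full.sum())
    return inside.sum() / n_full if n_full else 0.0


def capillary_compartments(
    aqp4: np.ndarray | Image2D,
    vessel: VesselAnnotation,
    pixel_size_um: float | None = None,
    band_um: float = 1.5,
    neuropil_range_um: tuple[float, float] = (5.0, 15.0),
    other_vessel_exclusion: np.ndarray | None = None,
    min_annulus_fraction: float = 0.5,
) -> tuple[float, float] | None:
    """Endfoot-annulus and remote-neuropil mean AQP4 for one capillary.

    The endfoot is the 0-``band_um`` annulus outside the wall; the neuropil
    reference is the ``neuropil_range_um`` annulus, minus any pixels inside
    ``other_vessel_exclusion`` (other lumens plus their endfoot bands).  A
    vessel whose endfoot annulus is clipped below ``min_annulus_fraction``
    by the image edge is skipped with a log entry; partial annuli above the
    cutoff are used as-is.
    """
    if isinstance(aqp4, Image2D):
        pixel_size_um = aqp4.pixel_size_um
        aqp4 = aqp4.channel("aqp4")
    if pixel_size_um is None:
        raise ValueError("pixel_size_um required with a bare array")
    if vessel.vessel_class != "capillary":
        raise ValueError("capillary_compartments requires a capillary vessel")
    px = pixel_size_um
    frac = _annulus_fraction_present(vessel.lumen_mask, 0.0, band_um / px)
    if frac < min_annulus_fraction:
        log.warning(
            "vessel %d skipped: only %.0f%% of endfoot annulus in bounds",
            vessel.vessel_id,
            100 * frac,
        )
        return None
    d = ndimage.distance_transform_edt(~vessel.lumen_mask) * px
    endfoot = (d > 0) & (d <= band_um)
    lo, hi = neuropil_range_um
    neuropil = (d > lo) & (d <= hi)
    if other_vessel_exclusion is not None:
        neuropil &= ~other_vessel_exclusion
        endfoot &= ~other_vessel_exclusion
    if not endfoot.any() or not neuropil.any():
        log.warning("vessel %d skipped: empty compartment mask", vessel.vessel_id)
        return None
    return float(aqp4[endfoot].mean()), float(aqp4[neuropil].mean())


def cross_section_profile(
    aqp4: np.ndarray | Image2D,
    vessel: VesselAnnotation,
    pixel_size_um: float | None = None,
    max_distance_um: float = COMPARTMENT_BOUNDARIES_UM[2],
) -> CrossSectionProfile:
    """Folded line profile perpendicular to a large vessel's axis.

    Samples run from the vessel center outward on both sides along the
    normal to the axis, one pixel per step (nearest-neighbour lookup).
    In-lumen samples are excluded; on each side distance is counted from the
    wall crossing, the first tissue sample sitting one pixel from the wall
    (matching the distance-transform convention).  The two half-profiles are
    folded and averaged per distance bin, weighting by sample count; if both
    sides end before ``max_distance_um`` the profile is flagged truncated.
    """
    if isinstance(aqp4, Image2D):
        pixel_size_um = aqp4.pixel_size_um
        aqp4 = aqp4.channel("aqp4")
    if pixel_size_um is None:
        raise ValueError("pixel_size_um required with a bare array")
    if vessel.vessel_class != "large":
        raise ValueError("cross_section_profile requires a large vessel")
    px = pixel_size_um
    h, w = aqp4.shape
    normal = np.array([-vessel.axis[1], vessel.axis[0]])
    n_bins = int(np.floor(max_distance_um / px)) + 1
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    sides_complete = 0
    for sign in (+1.0, -1.0):
        direction = sign * normal
        t = 0
        # walk out of the lumen first
        while True:
            r = int(round(vessel.center[0] + t * direction[0]))
            c = int(round(vessel.center[1] + t * direction[1]))
            if not (0 <= r < h and 0 <= c < w):
                t = None
                break
            if not vessel.lumen_mask[r, c]:
                break
            t += 1
        if t is None:
            continue
        t_wall = t - 1  # last in-lumen step
        k = 1
        while True:
            tt = t_wall + k
            r = int(round(vessel.center[0] + tt * direction[0]))
            c = int(round(vessel.center[1] + tt * direction[1]))
            if not (0 <= r < h and 0 <= c < w):
                break
            dist_um = k * px
            if dist_um > max_distance_um:
                sides_complete += 1
                break
            if vessel.lumen_mask[r, c]:  # another vessel's lumen: exclude
                k += 1
                continue
            b = k - 1
            sums[b] += aqp4[r, c]
            counts[b] += 1
            k += 1
    distances = (np.arange(n_bins) + 1) * px
    mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return CrossSectionProfile(
        distances_um=distances,
        mean_intensity=mean,
        n_samples=counts,
        truncated=sides_complete == 0,
        vessel_id=vessel.vessel_id,
    )


def segment_profile(
    profile: CrossSectionProfile,
    boundaries_um: tuple[float, float, float] = COMPARTMENT_BOUNDARIES_UM,
    vessel_id: int | None = None,
    animal_id: str | None = None,
) -> CompartmentMeasures:
    """Three-compartment means over [0, b1), [b1, b2), [b2, b3] um.

    Bin means are weighted by their sample counts; missing bins are excluded
    rather than interpolated, and a compartment with no bins at all comes
    back NaN.
    """
    b1, b2, b3 = boundaries_um
    if not (0 < b1 < b2 < b3):
        raise ValueError(f"boundaries must be strictly increasing, got {boundaries_um}")
    d = profile.distances_um
    if d[profile.n_samples > 0].size == 0 or d[profile.n_samples > 0].min() > b1:
        raise ValueError("profile does not reach the first compartment boundary")
    intervals = [(0.0, b1, False), (b1, b2, False), (b2, b3, True)]
    vals = []
    for lo, hi, inclusive in intervals:
        sel = (d >= lo) & ((d <= hi) if inclusive else (d < hi)) & (profile.n_samples > 0)
        if not sel.any():
            vals.append(np.nan)
            continue
        wsum = profile.n_samples[sel].sum()
        vals.append(float(np.sum(profile.mean_intensity[sel] * profile.n_samples[sel]) / wsum))
    return CompartmentMeasures(
        pv_endfoot_if=vals[0],
        pv_astro_if=vals[1],
        neuropil_if=vals[2],
        boundaries_um=boundaries_um,
        vessel_id=vessel_id if vessel_id is not None else profile.vessel_id,
        animal_id=animal_id,
    )


def diameter_association(
    data: pd.DataFrame,
    value_col: str = "value",
    diameter_col: str = "diameter_um",
    group_col: str = "group",
) -> dict:
    """Per-group OLS of compartment intensity on vessel diameter.

    Returns ``{"groups": {label: {slope, intercept, r2, p, n}},
    "interaction_p": float}`` where the interaction p tests whether slopes
    differ between groups (group x diameter term).
    """
    df = data[[value_col, diameter_col, group_col]].dropna().copy()
    groups = df[group_col].unique()
    if any((df[df[group_col] == g].shape[0] < 3) for g in groups):
        raise ValueError("need >= 3 vessels per group")
    per_group = {}
    for g in groups:
        sub = df[df[group_col] == g]
        if sub[diameter_col].nunique() < 2:
            raise ValueError(f"group {g!r}: all diameters equal, slope undefined")
        fit = smf.ols(f"{value_col} ~ {diameter_col}", data=sub).fit()
        per_group[str(g)] = {
            "slope": float(fit.params[diameter_col]),
            "intercept": float(fit.params["Intercept"]),
            "r2": float(fit.rsquared),
            "p": float(fit.pvalues[diameter_col]),
            "n": int(sub.shape[0]),
        }
    interaction_p = np.nan
    if len(groups) >= 2:
        full = smf.ols(
            f"{value_col} ~ {diameter_col} * C({group_col})", data=df
        ).fit()
        reduced = smf.ols(
            f"{value_col} ~ {diameter_col} + C({group_col})", data=df
        ).fit()
        f_res = full.compare_f_test(reduced)
        interaction_p = float(f_res[1])
    return {"groups": per_group, "interaction_p": interaction_p}


def puncta_metrics(
    source,
    pixel_size_um: float | None = None,
    min_distance_px: int = 3,
    threshold_abs: float | None = None,
) -> PunctaSet:
    """Puncta areas and the large (>= 2 um^2) : small (<= 1 um^2) count ratio.

    ``source`` may be an explicit list of areas (um^2), or a GFP channel in
    which puncta are seeded at local maxima and sized by the connected
    region above half the seed's intensity.  Areas strictly between 1 and
    2 um^2 belong to neither class.
    """
    if isinstance(source, (list, tuple, np.ndarray)) and np.ndim(source) == 1:
        areas = [float(a) for a in source]
        if any(a <= 0 for a in areas):
            raise ValueError("puncta areas must be > 0")
        return PunctaSet(areas_um2=areas)
    if isinstance(source, Image2D):
        pixel_size_um = source.pixel_size_um
        arr = source.channel("gfp")
    else:
        arr = np.asarray(source, dtype=float)
    if pixel_size_um is None or not pixel_size_um > 0:
        raise ValueError("pixel_size_um required when measuring an image")
    if arr.max() == arr.min():
        return PunctaSet(areas_um2=[])
    if threshold_abs is None:
        threshold_abs = arr.min() + 0.25 * (arr.max() - arr.min())
    peaks = peak_local_max(arr, min_distance=min_distance_px, threshold_abs=threshold_abs)
    px2 = pixel_size_um**2
    areas = []
    seen_components: set[tuple[int, int]] = set()
    for r, c in peaks:
        half = arr[r, c] / 2.0
        above = arr >= half
        lab = measure.label(above)
        comp = lab[r, c]
        key = (int(comp), int(np.flatnonzero(lab.ravel() == comp)[0]))
        if key in seen_components:
            continue
        seen_components.add(key)
        areas.append(float((lab == comp).sum() * px2))
    return PunctaSet(areas_um2=areas)


def gfp_localization_ratio(
    gfp: np.ndarray | Image2D,
    vessels: list[VesselAnnotation],
    pixel_size_um: float | None = None,
    band_um: float = 1.5,
) -> float:
    """Perivascular-band vs remaining-tissue mean GFP ratio.

    Band = pixels within ``band_um`` of any vessel wall (lumens excluded);
    remainder = all other non-lumen pixels.  An empty remainder (band covers
    the whole field) is an error.
    """
    if isinstance(gfp, Image2D):
        pixel_size_um = gfp.pixel_size_um
        gfp = gfp.channel("gfp")
    if pixel_size_um is None:
        raise ValueError("pixel_size_um required with a bare array")
    if not vessels:
        raise ValueError("need at least one vessel annotation")
    lumen = np.any([v.lumen_mask for v in vessels], axis=0)
    d = ndimage.distance_transform_edt(~lumen) * pixel_size_um
    band = (d > 0) & (d <= band_um)
    rest = ~lumen & ~band
    if not rest.any():
        raise ValueError("no tissue outside the perivascular band")
    if not band.any():
        raise ValueError("perivascular band is empty")
    return float(gfp[band].mean() / gfp[rest].mean())
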