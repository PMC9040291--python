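"""Vessel scenes: AQP4 + lectin channels with a planted compartment raster.

A scene is a neuropil baseline with one or more vessels.  Each vessel
contributes a dark lumen (bright in the lectin channel), a thin bright
endfoot ring hugging the wall, and a diffuse perivascular-astrocyte halo
whose amplitude grows linearly with vessel diameter -- the generative
counterpart of the aged phenotype in which fine-process AQP4 around large
vessels rises while the endfoot pool is depleted.

Distances are measured outward from the vessel wall with the Euclidean
distance transform; the first tissue pixel outside the lumen sits one pixel
(`pixel_size_um`) from the wall.  Compartment labels (lumen / endfoot /
pv_astro / neuropil) tile the raster exactly, and the returned ground truth
records the per-compartment means of the noiseless render, so recovery tests
have an exact oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from ..image import Image2D

__all__ = [
    "VesselSpec",
    "SceneSpec",
    "SceneGroundTruth",
    "generate_vessel_scene",
    "LABEL_NAMES",
    "LUMEN",
    "ENDFOOT",
    "PV_ASTRO",
    "NEUROPIL",
]

LUMEN, ENDFOOT, PV_ASTRO, NEUROPIL = 0, 1, 2, 3
LABEL_NAMES = {LUMEN: "lumen", ENDFOOT: "endfoot", PV_ASTRO: "pv_astro", NEUROPIL: "neuropil"}


@dataclass(frozen=True)
class VesselSpec:
    """Geometry of one vessel.

    ``kind='tube'`` renders a straight capillary/vessel segment crossing the
    image (axis through ``center`` at ``orientation_deg`` from the x-axis);
    ``kind='disk'`` renders a penetrating vessel in cross-section.
    """

    center_px: tuple[float, float]  # (row, col)
    diameter_um: float
    orientation_deg: float = 0.0
    kind: str = "tube"

    def __post_init__(self):
        if self.diameter_um <= 0:
            raise ValueError(f"diameter_um must be > 0, got {self.diameter_um}")
        if self.kind not in ("tube", "disk"):
            raise ValueError(f"kind must be 'tube' or 'disk', got {self.kind!r}")


@dataclass(frozen=True)
class SceneSpec:
    """Full generative parameterisation of a two-channel vessel scene.

    Intensities are arbitrary fluorescence units (AU); the absolute scale is
    meaningless, only contrasts matter.  ``pv_astro_diameter_slope`` (AU/um)
    raises the diffuse halo amplitude with vessel diameter.
    ``noise_poisson_scale`` > 0 turns on shot noise (photons per AU);
    ``lipofuscin_density`` (puncta/mm^2) sprinkles bright autofluorescent
    granules into the AQP4 channel, default off.
    """

    width_px: int = 256
    height_px: int = 256
    pixel_size_um: float = 0.42
    vessels: tuple[VesselSpec, ...] = (VesselSpec((128.0, 128.0), 6.0),)
    endfoot_band_um: float = 1.5
    endfoot_intensity: float = 200.0
    pv_astro_intensity: float = 110.0
    neuropil_intensity: float = 100.0
    lumen_intensity: float = 10.0
    lectin_intensity: float = 180.0
    pv_astro_extent_um: float = 20.0
    pv_astro_diameter_slope: float = 0.0
    noise_gaussian_sigma: float = 0.0
    noise_poisson_scale: float = 0.0
    lipofuscin_density: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in (
            "endfoot_intensity",
            "pv_astro_intensity",
            "neuropil_intensity",
            "lumen_intensity",
            "lectin_intensity",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.endfoot_band_um <= 0:
            raise ValueError("endfoot_band_um must be > 0")
        if self.pv_astro_extent_um < self.endfoot_band_um:
            raise ValueError("pv_astro_extent_um must be >= endfoot_band_um")
        if self.noise_gaussian_sigma < 0 or self.noise_poisson_scale < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.lipofuscin_density < 0:
            raise ValueError("lipofuscin_density must be >= 0")

    def with_(self, **kw) -> "SceneSpec":
        return replace(self, **kw)


@dataclass
class SceneGroundTruth:
    """Planted truth for one scene: the oracle every recovery test reads."""

    labels: np.ndarray  # int raster over {LUMEN, ENDFOOT, PV_ASTRO, NEUROPIL}
    vessel_owner: np.ndarray  # index of the nearest vessel per pixel
    diameters_um: list[float]
    compartment_means: dict[str, float]  # noiseless means per label class
    contrast_ratio: float  # endfoot_intensity / neuropil_intensity
    seed: int
    extras: dict = field(default_factory=dict)

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


def _lumen_mask(vessel: VesselSpec, shape: tuple[int, int], pixel_size_um: float) -> np.ndarray:
    h, w = shape
    r_px = vessel.diameter_um / 2.0 / pixel_size_um
    cy, cx = vessel.center_px
    if not (0 <= cy < h and 0 <= cx < w):
        raise ValueError(f"vessel center {vessel.center_px} outside {h}x{w} image")
    yy, xx = np.mgrid[0:h, 0:w]
    if vessel.kind == "disk":
        if cy - r_px < 0 or cy + r_px >= h or cx - r_px < 0 or cx + r_px >= w:
            raise ValueError(
                f"disk vessel (d={vessel.diameter_um} um) at {vessel.center_px} "
                f"exceeds {h}x{w} image bounds"
            )
        return (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
    theta = np.deg2rad(vessel.orientation_deg)
    # perpendicular distance to the axis line; image axes: x = col, y = row
    nx, ny = -np.sin(theta), np.cos(theta)
    d_perp = np.abs((xx - cx) * nx + (yy - cy) * ny)
    return d_perp <= r_px


def generate_vessel_scene(spec: SceneSpec) -> tuple[Image2D, SceneGroundTruth]:
    """Render a deterministic two-channel scene and its planted ground truth.

    The AQP4 channel is ``neuropil_intensity`` everywhere, overwritten by the
    endfoot ring, the diffuse halo and the lumen; the lectin channel marks
    lumens.  Same spec + seed gives bit-identical output.
    """
    if not spec.vessels:
        raise ValueError("SceneSpec.vessels is empty")
    shape = (spec.height_px, spec.width_px)
    px = spec.pixel_size_um

    lumens = [_lumen_mask(v, shape, px) for v in spec.vessels]
    # distance (um) from each vessel's wall; 0 inside that vessel's lumen
    dists = np.stack(
        [ndimage.distance_transform_edt(~m) * px for m in lumens]
    )
    owner = np.argmin(dists, axis=0)
    d_wall = np.take_along_axis(dists, owner[None], axis=0)[0]
    any_lumen = np.any(lumens, axis=0)

    labels = np.full(shape, NEUROPIL, dtype=np.int8)
    labels[(d_wall > 0) & (d_wall <= spec.endfoot_band_um)] = ENDFOOT
    labels[(d_wall > spec.endfoot_band_um) & (d_wall <= spec.pv_astro_extent_um)] = PV_ASTRO
    labels[any_lumen] = LUMEN

    diam = np.array([v.diameter_um for v in spec.vessels])
    halo_amp = spec.pv_astro_intensity + spec.pv_astro_diameter_slope * diam[owner]

    aqp4 = np.full(shape, float(spec.neuropil_intensity))
    aqp4[labels == PV_ASTRO] = halo_amp[labels == PV_ASTRO]
    aqp4[labels == ENDFOOT] = spec.endfoot_intensity
    aqp4[labels == LUMEN] = spec.lumen_intensity

    lectin = np.zeros(shape)
    lectin[any_lumen] = spec.lectin_intensity

    means = {
        LABEL_NAMES[k]: float(aqp4[labels == k].mean()) if np.any(labels == k) else np.nan
        for k in LABEL_NAMES
    }

    rng = np.random.default_rng(spec.seed)
    aqp4_noisy = _apply_noise(aqp4, spec, rng)
    if spec.lipofuscin_density > 0:
        aqp4_noisy = _add_lipofuscin(aqp4_noisy, spec, rng)
    lectin_noisy = _apply_noise(lectin, spec, rng)

    image = Image2D(
        channels={"aqp4": aqp4_noisy, "lectin": lectin_noisy},
        pixel_size_um=px,
        metadata={"generator": "generate_vessel_scene", "seed": spec.seed},
    )
    truth = SceneGroundTruth(
        labels=labels,
        vessel_owner=owner,
        diameters_um=list(diam),
        compartment_means=means,
        contrast_ratio=spec.endfoot_intensity / spec.neuropil_intensity
        if spec.neuropil_intensity > 0
        else np.inf,
        seed=spec.seed,
        extras={"halo_base": spec.pv_astro_intensity, "halo_slope": spec.pv_astro_diameter_slope},
    )
    return image, truth


def _apply_noise(img: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    out = img.astype(np.float64)
    if spec.noise_poisson_scale > 0:
        s = spec.noise_poisson_scale
        out = rng.poisson(np.clip(out, 0, None) * s).astype(np.float64) / s
    if spec.noise_gaussian_sigma > 0:
        out = out + rng.normal(0.0, spec.noise_gaussian_sigma, out.shape)
    return np.clip(out, 0.0, None)


def _add_lipofuscin(img: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Sparse bright autofluorescent granules (a human-tissue confound)."""
    area_mm2 = img.size * spec.pixel_size_um**2 * 1e-6
    n = rng.poisson(spec.lipofuscin_density * area_mm2)
    out = img.copy()
    h, w = img.shape
    sigma_px = 0.8 / spec.pixel_size_um  # ~0.8 um granules
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        amp = rng.uniform(2.0, 4.0) * spec.endfoot_intensity
        out += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma_px**2))
    return out
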