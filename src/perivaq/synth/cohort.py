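"""Cohort-level generators: human ROI cohorts and rodent vessel measures.

Two levels of synthesis are provided.

* **Pixel level** -- :func:`generate_human_roi` renders a human-style
  cortical ROI (slide background, speckled astrocyte fine-process signal,
  perivascular endfoot rings at a planted endfoot:cellular contrast) and
  :func:`generate_cohort` assembles whole CN/MCI/AD-style cohorts of such
  ROIs with planted subject ratios and linked cognitive/pathological
  covariates.

* **Measurement level** -- :func:`generate_rodent_measures` draws per-vessel
  compartment intensities directly from the planted generative model
  (group effect + per-animal random intercept + vessel-level noise), which
  is what replicate power/type-I simulations over many cohorts use; single
  cohorts are additionally rendered and measured at pixel level in the
  test-suite to show the two levels agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..image import Image2D

__all__ = [
    "GroupSpec",
    "CohortSpec",
    "DEFAULT_COVARIATE_LINKS",
    "generate_human_roi",
    "generate_cohort",
    "RodentGroupSpec",
    "generate_rodent_measures",
]

# covariate = intercept + slope * planted_ratio + N(0, sd), then clipped to
# its clinical range (ordinals rounded).  Slopes are signed so that lower
# polarization tracks worse cognition and heavier pathology.
DEFAULT_COVARIATE_LINKS: dict[str, tuple[float, float, float, tuple[float, float], bool]] = {
    #  name:       (intercept, slope,  sd,   (lo, hi), ordinal)
    "MMSE": (2.0, 12.5, 2.0, (0.0, 30.0), False),
    "CDR_SoB": (20.0, -9.0, 1.5, (0.0, 18.0), False),
    "CERAD": (6.0, -2.5, 0.5, (0.0, 3.0), True),
    "Braak": (10.0, -3.8, 0.7, (0.0, 6.0), True),
    "ptau_per_mm2": (120.0, -50.0, 8.0, (0.0, np.inf), False),
}


@dataclass(frozen=True)
class GroupSpec:
    """One diagnostic group: label, size and planted polarization distribution."""

    label: str
    n_subjects: int
    mean_ratio: float
    sd_ratio: float
    covariate_links: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_LINKS))

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError(f"group {self.label!r}: n_subjects must be >= 1")
        if self.sd_ratio < 0:
            raise ValueError(f"group {self.label!r}: sd_ratio must be >= 0")
        if self.mean_ratio <= 0:
            raise ValueError(f"group {self.label!r}: mean_ratio must be > 0")


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[GroupSpec, ...]
    rois_per_subject: int = 6
    image_size_px: int = 300
    pixel_size_um: float = 0.65
    noise_sigma: float = 5.0  # AU, on a 100-AU cellular tier
    seed: int = 0

    def __post_init__(self):
        if not self.groups:
            raise ValueError("CohortSpec.groups is empty")
        if self.rois_per_subject < 1:
            raise ValueError("rois_per_subject must be >= 1")


# planted intensity tiers of a human-style ROI (AU)
BACKGROUND_AU = 10.0
CELLULAR_AU = 100.0
LUMEN_AU = 5.0

# ground-truth label codes for human ROIs
ROI_BG, ROI_CELLULAR, ROI_ENDFOOT, ROI_LUMEN = 0, 1, 2, 3


def generate_human_roi(
    ratio: float,
    size_px: int = 300,
    pixel_size_um: float = 0.65,
    noise_sigma: float = 5.0,
    seed: int = 0,
    cellular_fraction: float = 0.25,
) -> tuple[Image2D, dict]:
    """Render one cortical ROI with a planted endfoot:cellular contrast.

    The ROI holds slide background at 10 AU, a speckled fine-process
    ("cellular") tier at 100 AU covering ``cellular_fraction`` of the tissue,
    and perivascular endfoot rings at ``ratio`` x 100 AU around two
    penetrating vessels and one longitudinal capillary.  Returns the image
    and a ground-truth dict with the label raster, planted threshold pair
    and tier intensities.

    At ``ratio`` = 1 the rings are rendered at the cellular level: the
    depolarized phenotype in which endfeet are no longer separable from the
    rest of the astrocyte by intensity.
    """
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    rng = np.random.default_rng(seed)
    h = w = int(size_px)
    px = pixel_size_um
    endfoot_au = ratio * CELLULAR_AU

    labels = np.full((h, w), ROI_BG, dtype=np.int8)
    # speckled fine-process tier: deterministic given seed
    speckle = rng.random((h, w)) < cellular_fraction
    labels[speckle] = ROI_CELLULAR

    yy, xx = np.mgrid[0:h, 0:w]
    band_px = 1.5 / px
    # two penetrating vessels in cross-section
    for cy, cx, d_um in ((h * 0.3, w * 0.3, 12.0), (h * 0.7, w * 0.65, 9.0)):
        r_px = d_um / 2 / px
        rr = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        labels[(rr > r_px) & (rr <= r_px + band_px)] = ROI_ENDFOOT
        labels[rr <= r_px] = ROI_LUMEN
    # one longitudinal capillary
    r_px = 6.0 / 2 / px
    d_perp = np.abs((xx - w * 0.5) * 0.447 + (yy - h * 0.5) * 0.894)
    labels[(d_perp > r_px) & (d_perp <= r_px + band_px)] = ROI_ENDFOOT
    labels[d_perp <= r_px] = ROI_LUMEN

    img = np.full((h, w), BACKGROUND_AU)
    img[labels == ROI_CELLULAR] = CELLULAR_AU
    img[labels == ROI_ENDFOOT] = endfoot_au
    img[labels == ROI_LUMEN] = LUMEN_AU
    if noise_sigma > 0:
        img = np.clip(img + rng.normal(0, noise_sigma, img.shape), 0, None)

    cellular_threshold = (BACKGROUND_AU + CELLULAR_AU) / 2
    vessel_threshold = (CELLULAR_AU + endfoot_au) / 2 if ratio > 1 else endfoot_au
    truth = {
        "labels": labels,
        "planted_ratio": float(ratio),
        "cellular_threshold": cellular_threshold,
        "vessel_threshold": vessel_threshold,
        "tiers": {
            "background": BACKGROUND_AU,
            "cellular": CELLULAR_AU,
            "endfoot": endfoot_au,
            "lumen": LUMEN_AU,
        },
        "seed": seed,
    }
    image = Image2D(
        channels={"aqp4": img},
        pixel_size_um=px,
        metadata={"generator": "generate_human_roi", "seed": seed},
    )
    return image, truth


def generate_cohort(
    spec: CohortSpec, render: bool = True
) -> tuple[pd.DataFrame, dict[tuple[str, int], tuple[Image2D, dict]]]:
    """Draw a cohort of subjects with planted ratios and covariates.

    Returns the ground-truth subject table and, when ``render`` is true, a
    mapping ``(subject_id, roi_index) -> (Image2D, roi ground truth)``.  With
    ``render=False`` only the table is produced (used by replicate
    simulations that feed the statistics layer directly).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    images: dict[tuple[str, int], tuple[Image2D, dict]] = {}
    for g in spec.groups:
        for i in range(g.n_subjects):
            sid = f"{g.label}-{i + 1:02d}"
            ratio = float(np.clip(rng.normal(g.mean_ratio, g.sd_ratio), 0.2, None))
            row = {"subject_id": sid, "group": g.label, "planted_ratio": ratio}
            for name, (a, b, sd, (lo, hi), ordinal) in g.covariate_links.items():
                v = a + b * ratio + rng.normal(0, sd)
                v = float(np.clip(v, lo, hi))
                row[name] = int(round(v)) if ordinal else v
            rows.append(row)
            if render:
                for r in range(spec.rois_per_subject):
                    roi_seed = int(rng.integers(0, 2**31 - 1))
                    images[(sid, r)] = generate_human_roi(
                        ratio,
                        size_px=spec.image_size_px,
                        pixel_size_um=spec.pixel_size_um,
                        noise_sigma=spec.noise_sigma,
                        seed=roi_seed,
                    )
    return pd.DataFrame(rows), images


@dataclass(frozen=True)
class RodentGroupSpec:
    """Planted compartment model for one rodent group.

    ``pv_astro_if(d) = pv_astro_base + pv_astro_slope * d`` for vessel
    diameter ``d`` (um).  The aged phenotype is expressed by lowering
    ``endfoot_if`` and scaling the perivascular-astrocyte pair up, leaving
    ``neuropil_if`` untouched.
    """

    label: str
    endfoot_if: float = 200.0
    pv_astro_base: float = 110.0
    pv_astro_slope: float = 1.0  # AU per um diameter
    neuropil_if: float = 100.0


#: study conditions for the aged-vs-young contrast: capillary endfoot -30%,
#: perivascular astrocyte +40% (base and diameter slope), neuropil unchanged
YOUNG = RodentGroupSpec("young")
AGED = RodentGroupSpec(
    "aged",
    endfoot_if=YOUNG.endfoot_if * 0.70,
    pv_astro_base=YOUNG.pv_astro_base * 1.40,
    pv_astro_slope=YOUNG.pv_astro_slope * 1.40,
)


def generate_rodent_measures(
    groups: tuple[RodentGroupSpec, ...] = (YOUNG, AGED),
    n_animals: int = 6,
    vessels_per_animal: int = 15,
    animal_sd: float = 5.0,
    residual_sd: float = 12.0,
    diameter_range_um: tuple[float, float] = (10.5, 40.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Tidy per-vessel compartment intensities from the planted model.

    One row per (animal, vessel, compartment); animals carry a shared random
    intercept (sd ``animal_sd`` AU), vessels carry independent residual noise
    (sd ``residual_sd`` AU).  Diameters are uniform over
    ``diameter_range_um``.  Defaults are the aged-vs-young study conditions.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for g in groups:
        for a in range(n_animals):
            animal = f"{g.label}-{a + 1:02d}"
            intercept = rng.normal(0, animal_sd)
            for v in range(vessels_per_animal):
                d = rng.uniform(*diameter_range_um)
                planted = {
                    "pv_endfoot": g.endfoot_if,
                    "pv_astro": g.pv_astro_base + g.pv_astro_slope * d,
                    "neuropil": g.neuropil_if,
                }
                for comp, mu in planted.items():
                    rows.append(
                        {
                            "group": g.label,
                            "animal": animal,
                            "vessel": f"{animal}-v{v + 1:02d}",
                            "diameter_um": d,
                            "compartment": comp,
                            "value": mu + intercept + rng.normal(0, residual_sd),
                            "planted_mean": mu,
                        }
                    )
    return pd.DataFrame(rows)
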