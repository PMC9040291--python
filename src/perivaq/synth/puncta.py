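"""GFP puncta fields with exactly controlled above-half-maximum areas.

Each punctum is an isotropic Gaussian blob.  The area enclosed by the
half-maximum contour of ``A * exp(-r^2 / (2 sigma^2))`` is
``2 * pi * ln(2) * sigma^2``, so a requested area in um^2 fixes sigma
exactly; rasterisation makes the realised pixelated area match the request
within about one pixel ring.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..image import Image2D

__all__ = ["generate_puncta_field", "sigma_for_area"]

_HALF_MAX_FACTOR = 2.0 * np.pi * np.log(2.0)


def sigma_for_area(area_um2: float) -> float:
    """Gaussian sigma (um) whose half-maximum contour encloses ``area_um2``."""
    return float(np.sqrt(area_um2 / _HALF_MAX_FACTOR))


def generate_puncta_field(
    areas_um2,
    pixel_size_um: float,
    seed: int = 0,
    image_size_px: int | None = None,
    amplitude: float = 100.0,
    noise_sigma: float = 0.0,
    max_retries: int = 500,
) -> tuple[Image2D, pd.DataFrame]:
    """Scatter non-overlapping Gaussian puncta of the requested areas.

    Puncta are placed by rejection sampling with a clearance of four sigma
    between footprints; if a punctum cannot be placed after ``max_retries``
    attempts a ``RuntimeError`` is raised rather than silently overlapping.
    Returns the rendered GFP channel and a table of planted centers, areas
    and sigmas.  An empty area list yields a blank image.
    """
    areas = np.asarray(list(areas_um2), dtype=float)
    if np.any(areas <= 0):
        raise ValueError("all puncta areas must be > 0")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    rng = np.random.default_rng(seed)

    sigmas_px = np.array([sigma_for_area(a) / pixel_size_um for a in areas])
    if image_size_px is None:
        # size the field so the requested count fits comfortably
        need = max(1.0, 40.0 * np.sum((4 * sigmas_px + 3) ** 2))
        image_size_px = int(max(128, np.ceil(np.sqrt(need))))
    h = w = int(image_size_px)

    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    for s in sigmas_px:
        margin = 4 * s + 2
        if 2 * margin >= min(h, w):
            raise RuntimeError(
                f"punctum (sigma={s:.1f} px) too large to place without overlap "
                f"in a {h}x{w} px field; enlarge image_size_px"
            )
        placed = False
        for _ in range(max_retries):
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            ok = all(
                (cy - py) ** 2 + (cx - px_) ** 2 > (4 * s + 4 * pr + 2) ** 2
                for (py, px_), pr in zip(centers, radii)
            )
            if ok:
                centers.append((cy, cx))
                radii.append(s)
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place punctum (sigma={s:.1f} px) without overlap "
                f"after {max_retries} retries; enlarge image_size_px"
            )

    img = np.zeros((h, w))
    yy, xx = np.mgrid[0:h, 0:w]
    for (cy, cx), s in zip(centers, sigmas_px):
        img += amplitude * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s**2))
    if noise_sigma > 0:
        img = np.clip(img + rng.normal(0, noise_sigma, img.shape), 0, None)

    table = pd.DataFrame(
        {
            "center_row": [c[0] for c in centers],
            "center_col": [c[1] for c in centers],
            "area_um2": areas,
            "sigma_um": sigmas_px * pixel_size_um,
        }
    )
    image = Image2D(
        channels={"gfp": img},
        pixel_size_um=pixel_size_um,
        metadata={"generator": "generate_puncta_field", "seed": seed},
    )
    return image, table
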