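"""Run configuration: validated parameters, lossless YAML round-trip."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ValidationError"]


class ValidationError(ValueError):
    """A configuration value outside its documented range."""


@dataclass
class RunConfig:
    """Parameters shared across the quantification stages.

    Units: boundaries, bands and cutoffs in micrometres; ROI size in pixels;
    thresholds in arbitrary fluorescence units (AU).
    """

    pixel_size_um: float = 0.42
    compartment_boundaries_um: tuple[float, float, float] = (1.5, 20.0, 68.0)
    capillary_cutoff_um: float = 10.0
    endfoot_band_um: float = 1.5
    neuropil_range_um: tuple[float, float] = (5.0, 15.0)
    roi_size_px: int = 1000
    vessel_threshold: float | None = None
    cellular_threshold: float | None = None
    tracer_threshold: float | None = None
    influx_bregma_mm: tuple[float, ...] = (1.0, 0.0, -1.5, -2.5, -3.5)
    efflux_bregma_mm: tuple[float, ...] = (2.5, 1.5, 0.0, -1.0, -2.0)
    channel_map: dict = field(default_factory=lambda: {"aqp4": 0, "lectin": 1})
    seed: int = 0
    out_dir: str = "out"

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        b = tuple(self.compartment_boundaries_um)
        if not (len(b) == 3 and 0 < b[0] < b[1] < b[2]):
            raise ValidationError(
                f"compartment_boundaries_um must be strictly increasing and positive, got {b}"
            )
        if not self.pixel_size_um > 0:
            raise ValidationError("pixel_size_um must be > 0")
        if not self.capillary_cutoff_um > 0:
            raise ValidationError("capillary_cutoff_um must be > 0")
        if not self.endfoot_band_um > 0:
            raise ValidationError("endfoot_band_um must be > 0")
        lo, hi = self.neuropil_range_um
        if not 0 <= lo < hi:
            raise ValidationError(f"neuropil_range_um must increase, got {(lo, hi)}")
        if self.roi_size_px < 1:
            raise ValidationError("roi_size_px must be >= 1")
        if (
            self.vessel_threshold is not None
            and self.cellular_threshold is not None
            and not self.cellular_threshold < self.vessel_threshold
        ):
            raise ValidationError("cellular_threshold must be < vessel_threshold")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        d = asdict(self)
        # tuples to lists for clean YAML; restored on load
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        path.write_text(yaml.safe_dump(d, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in (
            "compartment_boundaries_um",
            "neuropil_range_um",
            "influx_bregma_mm",
            "efflux_bregma_mm",
        ):
            if k in d and isinstance(d[k], list):
                d[k] = tuple(d[k])
        return cls(**d)

    def digest(self) -> str:
        """Stable hash of the canonical YAML form, for run manifests."""
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return hashlib.sha256(yaml.safe_dump(d, sort_keys=True).encode()).hexdigest()[:16]
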