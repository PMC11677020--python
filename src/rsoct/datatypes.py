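"""Core data containers shared across the pipeline.

The study hierarchy is subjects -> samples (biopsies) -> records, where a
record is a single measurement: either one Raman spectrum or one OCT enface
image.  Samples carry the diagnostic label; a tumor-labelled sample may still
contain healthy-looking measurement sites (mixed biopsies), which is why the
synthetic generator distinguishes the *label* of a record (inherited from its
sample) from its *latent* class (what the tissue under the probe actually
looked like).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

HEALTHY = "healthy"
TUMOR = "tumor"
LABELS = (HEALTHY, TUMOR)


def _check_label(label: str) -> None:
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")


@dataclass
class SpectrumRecord:
    """One Raman measurement on a common wavenumber axis (cm^-1)."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    subject_id: str
    sample_id: str
    record_id: str
    label: str

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D")
        if self.wavenumbers.shape != self.intensities.shape:
            raise ValueError("wavenumbers and intensities must have equal length")
        if not np.all(np.diff(self.wavenumbers) > 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        _check_label(self.label)


@dataclass
class EnfaceImage:
    """One grayscale OCT enface measurement.

    ``pixels`` is a square 2-D array scaled to [0, 1]; the physical extent is
    ``side * pixel_size_um`` and must agree with ``field_of_view_mm``.
    """

    pixels: np.ndarray
    subject_id: str
    sample_id: str
    record_id: str
    label: str
    pixel_size_um: float = 4.0
    field_of_view_mm: float = 2.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        ny, nx = self.pixels.shape
        if ny != nx:
            raise ValueError("enface image must be square")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel values must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("pixel values must be non-negative")
        extent_mm = ny * self.pixel_size_um / 1000.0
        if not np.isclose(extent_mm, self.field_of_view_mm, rtol=0.05):
            raise ValueError(
                f"side x pixel size ({extent_mm:.3f} mm) inconsistent with "
                f"field of view ({self.field_of_view_mm:.3f} mm)"
            )
        _check_label(self.label)

    @property
    def side(self) -> int:
        return self.pixels.shape[0]


@dataclass
class CohortSpec:
    """Size and contrast parameters of a synthetic cohort.

    Defaults reproduce the scale of the clinical study: 27 subjects with
    61 biopsy samples (21 healthy / 40 tumor) and on average ~303 Raman and
    ~346 OCT records in total.  Effect sizes are expressed in units of the
    generator's channel noise standard deviation (Raman) or speckle contrast
    (OCT); 0 means the two latent classes are drawn from one distribution.
    """

    n_subjects: int = 27
    n_healthy_samples: int = 21
    n_tumor_samples: int = 40
    mean_rs_records_per_sample: float = 303 / 61
    mean_oct_records_per_sample: float = 346 / 61
    tumor_purity_range: tuple[float, float] = (0.1, 1.0)
    rs_effect_size: float = 2.0
    oct_effect_size: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_healthy_samples < 1 or self.n_tumor_samples < 1:
            raise ValueError(
                "need at least one sample of each class (classifiers require both)"
            )
        if self.mean_rs_records_per_sample <= 0 or self.mean_oct_records_per_sample <= 0:
            raise ValueError("mean records per sample must be positive")
        lo, hi = self.tumor_purity_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("tumor_purity_range must be ordered and within [0, 1]")
        if self.rs_effect_size < 0 or self.oct_effect_size < 0:
            raise ValueError("effect sizes must be non-negative")
        n_samples = self.n_healthy_samples + self.n_tumor_samples
        if self.n_subjects > n_samples:
            raise ValueError("cannot give every subject a sample: n_subjects > n_samples")

    @property
    def n_samples(self) -> int:
        return self.n_healthy_samples + self.n_tumor_samples


@dataclass
class GroundTruth:
    """Generator-side truth for recovery tests.

    ``sample_purity`` maps sample_id -> tumor-area fraction (0 for healthy
    samples, > 0 for tumor samples); ``record_latent`` maps record_id -> the
    latent tissue class under the probe; ``fiber_orientation_deg`` maps OCT
    record_id -> the wave-vector angle of the fibrous texture component.
    """

    sample_purity: dict[str, float] = field(default_factory=dict)
    record_latent: dict[str, str] = field(default_factory=dict)
    fiber_orientation_deg: dict[str, float] = field(default_factory=dict)
    spike_channels: dict[str, list[int]] = field(default_factory=dict)
    raman_params: Any = None
    oct_params: Any = None

    def shifted_bands(self) -> np.ndarray:
        """Wavenumbers of bands whose amplitude differs between classes."""
        p = self.raman_params
        pos = np.asarray(p.peak_positions, dtype=float)
        w = np.asarray(p.tumor_shift_weights, dtype=float)
        return pos[w != 0]
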