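"""Synthetic FT-NIR diffuse-reflectance spectra with storage-class structure.

Generates labeled absorbance matrices that mimic a refrigerated-storage
study: six storage-day classes, smooth baseline plus Gaussian absorption
peaks near the 5200 cm^-1 O-H/N-H combination band and the 6900 cm^-1 first
overtone, per-sample affine scatter distortion (the model MSC assumes) and
additive noise that is elevated inside the 4000-4350 cm^-1 water band.
Storage time shifts the peak amplitudes progressively, so adjacent days
overlap more than distant ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "SpectraSet",
    "class_template",
    "generate_dataset",
    "well_separated_config",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the spectra generator.

    Amplitude-like quantities are in absorbance units; positions and widths
    in cm^-1.  ``class_amplitude_step`` is the per-class increment added to
    each peak amplitude, the only class-dependent effect.
    """

    n_classes: int = 6
    samples_per_class: int = 67
    wavenumber_start: float = 10_000.0
    wavenumber_end: float = 4_000.0
    n_points: int = 1557
    baseline_coeffs: tuple[float, float, float] = (0.30, 0.10, 0.05)
    peak_centers: tuple[float, ...] = (5200.0, 6900.0)
    peak_widths: tuple[float, ...] = (200.0, 300.0)
    peak_amplitudes: tuple[float, ...] = (0.80, 0.50)
    class_amplitude_step: tuple[float, ...] = (0.012, 0.008)
    scatter_slope_sd: float = 0.05
    scatter_offset_sd: float = 0.02
    noise_sd: float = 0.005
    water_band: tuple[float, float] = (4000.0, 4350.0)
    water_noise_multiplier: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("n_points must be at least 2")
        if self.wavenumber_start <= self.wavenumber_end:
            raise ValueError("wavenumber grid must be strictly decreasing")
        if self.samples_per_class < 1:
            raise ValueError("samples_per_class must be >= 1")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        for name in ("scatter_slope_sd", "scatter_offset_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        k = len(self.peak_centers)
        if not (len(self.peak_widths) == len(self.peak_amplitudes)
                == len(self.class_amplitude_step) == k):
            raise ValueError("peak parameter tuples must have equal length")

    @property
    def wavenumbers(self) -> np.ndarray:
        """Grid in cm^-1, strictly decreasing from start to end."""
        return np.linspace(self.wavenumber_start, self.wavenumber_end,
                           self.n_points)

    @property
    def n_samples(self) -> int:
        return self.n_classes * self.samples_per_class


@dataclass
class SpectraSet:
    """Sample x wavenumber absorbance matrix with optional day labels."""

    absorbance: np.ndarray          # [n_samples, n_points]
    wavenumbers: np.ndarray         # [n_points], cm^-1
    labels: np.ndarray | None = None  # class indices in 1..n_classes
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be 2-D (samples x points)")
        if self.absorbance.shape[1] != self.wavenumbers.shape[0]:
            raise ValueError("wavenumber grid does not match spectra width")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance must be finite")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape[0] != self.absorbance.shape[0]:
                raise ValueError("labels length does not match sample count")
        if not self.sample_ids:
            self.sample_ids = [f"s{i:04d}" for i in range(len(self))]

    def __len__(self) -> int:
        return self.absorbance.shape[0]

    def subset(self, idx: np.ndarray) -> "SpectraSet":
        idx = np.asarray(idx)
        return SpectraSet(
            absorbance=self.absorbance[idx],
            wavenumbers=self.wavenumbers,
            labels=None if self.labels is None else self.labels[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
        )

    def to_csv(self, path, labels: bool = True) -> None:
        """Write sample_id, label, then one absorbance column per wavenumber."""
        df = pd.DataFrame(self.absorbance,
                          columns=[f"{w:.4f}" for w in self.wavenumbers])
        df.insert(0, "sample_id", self.sample_ids)
        if labels and self.labels is not None:
            df.insert(1, "label", self.labels)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectraSet":
        df = pd.read_csv(path)
        ids = df.pop("sample_id").astype(str).tolist()
        labels = df.pop("label").to_numpy() if "label" in df.columns else None
        wn = np.array([float(c) for c in df.columns])
        return cls(absorbance=df.to_numpy(float), wavenumbers=wn,
                   labels=labels, sample_ids=ids)


def class_template(class_index: int, config: SyntheticConfig) -> np.ndarray:
    """Noiseless spectrum of one storage-day class.

    Quadratic baseline plus a sum of Gaussian peaks whose amplitudes grow
    by ``class_amplitude_step`` per class, so neighbouring days overlap at
    the peak bottoms while distant days separate.
    """
    if not 1 <= class_index <= config.n_classes:
        raise ValueError(
            f"class_index {class_index} outside 1..{config.n_classes}")
    w = config.wavenumbers
    # baseline on a normalized coordinate so coefficients are unit-scale
    t = (w - config.wavenumber_end) / (
        config.wavenumber_start - config.wavenumber_end)
    b0, b1, b2 = config.baseline_coeffs
    spectrum = b0 + b1 * t + b2 * t ** 2
    for center, width, amp, step in zip(
            config.peak_centers, config.peak_widths,
            config.peak_amplitudes, config.class_amplitude_step):
        amplitude = amp + (class_index - 1) * step
        spectrum = spectrum + amplitude * np.exp(
            -0.5 * ((w - center) / width) ** 2)
    return spectrum


def _noise_scale(config: SyntheticConfig) -> np.ndarray:
    """Per-point noise s.d.; elevated inside the water band."""
    w = config.wavenumbers
    lo, hi = min(config.water_band), max(config.water_band)
    scale = np.full(config.n_points, config.noise_sd)
    scale[(w >= lo) & (w <= hi)] *= config.water_noise_multiplier
    return scale


def generate_dataset(config: SyntheticConfig) -> SpectraSet:
    """Draw the full labeled dataset.

    Each sample is ``slope * template + offset + noise`` with
    slope ~ 1 + N(0, scatter_slope_sd), offset ~ N(0, scatter_offset_sd)
    and heteroscedastic Gaussian noise.  One generator is seeded per
    dataset; the draw order is slopes, then offsets, then noise, samples in
    class-major order, so outputs are bitwise reproducible.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    slopes = 1.0 + rng.normal(0.0, config.scatter_slope_sd, size=n)
    offsets = rng.normal(0.0, config.scatter_offset_sd, size=n)
    noise = rng.normal(0.0, 1.0, size=(n, config.n_points)) * _noise_scale(config)

    templates = np.stack([class_template(c + 1, config)
                          for c in range(config.n_classes)])
    labels = np.repeat(np.arange(1, config.n_classes + 1),
                       config.samples_per_class)
    absorbance = (slopes[:, None] * templates[labels - 1]
                  + offsets[:, None] + noise)
    ids = [f"day{c}_{i:03d}" for c in range(1, config.n_classes + 1)
           for i in range(config.samples_per_class)]
    return SpectraSet(absorbance=absorbance, wavenumbers=config.wavenumbers,
                      labels=labels, sample_ids=ids)


def well_separated_config(seed: int = 0) -> SyntheticConfig:
    """Preset with large class steps and low noise.

    Classes are recoverable essentially perfectly; used for parameter
    recovery checks where the generating labels are the ground truth.
    """
    return SyntheticConfig(
        class_amplitude_step=(0.05, 0.035),
        noise_sd=0.002,
        water_noise_multiplier=2.0,
        seed=seed,
    )
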