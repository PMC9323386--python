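"""Multiplicative scatter correction (MSC).

Each spectrum is regressed (ordinary least squares) on a reference
"standard spectrum" -- by convention the mean spectrum of the calibration
set -- and the fitted additive offset and multiplicative slope are removed:
``corrected = (x - intercept) / slope``.  Under the affine scatter model
this recovers the undistorted spectrum exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import SpectraSet

__all__ = ["MSCReference", "MSCFit", "fit_msc_reference", "apply_msc"]

SLOPE_TOL = 1e-8  # |slope| below this is degenerate; sample left uncorrected


@dataclass
class MSCReference:
    """Standard spectrum (mean over calibration samples)."""

    reference: np.ndarray
    n_source_samples: int

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        if not np.all(np.isfinite(self.reference)):
            raise ValueError("reference spectrum must be finite")
        if np.ptp(self.reference) == 0:
            raise ValueError("reference spectrum is constant; MSC undefined")

    def to_csv(self, path) -> None:
        pd.DataFrame([self.reference]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MSCReference":
        ref = pd.read_csv(path).to_numpy(float)[0]
        return cls(reference=ref, n_source_samples=0)


@dataclass
class MSCFit:
    """Per-sample regression coefficients of the correction."""

    slope: np.ndarray
    intercept: np.ndarray
    degenerate: np.ndarray  # True where |slope| < SLOPE_TOL (left uncorrected)


def fit_msc_reference(spectra: SpectraSet) -> MSCReference:
    """Mean spectrum over all samples of ``spectra``."""
    if len(spectra) < 2:
        raise ValueError("need at least 2 spectra to fit an MSC reference")
    return MSCReference(reference=spectra.absorbance.mean(axis=0),
                        n_source_samples=len(spectra))


def apply_msc(spectra: SpectraSet, ref: MSCReference) -> tuple[SpectraSet, MSCFit]:
    """Correct every spectrum against ``ref``.

    For each sample x the OLS fit x ~ intercept + slope * reference is
    solved in closed form over all wavenumbers; degenerate slopes
    (|slope| < 1e-8) leave the sample uncorrected with a warning.
    """
    r = ref.reference
    if r.shape[0] != spectra.wavenumbers.shape[0]:
        raise ValueError("reference and spectra are on different grids")
    X = spectra.absorbance
    rc = r - r.mean()
    denom = rc @ rc
    if denom <= 0:
        raise ValueError("reference spectrum is constant; MSC undefined")
    slope = (X - X.mean(axis=1, keepdims=True)) @ rc / denom
    intercept = X.mean(axis=1) - slope * r.mean()

    degenerate = np.abs(slope) < SLOPE_TOL
    if degenerate.any():
        warnings.warn(
            f"MSC: {int(degenerate.sum())} sample(s) with near-zero slope "
            "left uncorrected", RuntimeWarning)
    safe_slope = np.where(degenerate, 1.0, slope)
    safe_intercept = np.where(degenerate, 0.0, intercept)
    corrected = (X - safe_intercept[:, None]) / safe_slope[:, None]

    out = SpectraSet(absorbance=corrected, wavenumbers=spectra.wavenumbers,
                     labels=spectra.labels, sample_ids=list(spectra.sample_ids))
    return out, MSCFit(slope=slope, intercept=intercept, degenerate=degenerate)
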