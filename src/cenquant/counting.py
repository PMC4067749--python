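"""Molecule counting against tetO/TetR calibration standards.

Arrays of 7, 14 or 21 tet operators bound by a GFP-tagged repressor
homodimer carry a known maximum fluorophore number (2 per operator site).
A through-origin regression of median spot photon rate against that maximum
yields photons per fluorophore per second, which converts cluster photon
rates into molecule counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .photometry import ClusterMeasurement, summarize_quartiles

__all__ = [
    "CalibrationStandard",
    "CountingCalibration",
    "CountEstimate",
    "CalibrationDataError",
    "max_fluorophores",
    "fit_calibration",
    "estimate_count",
]


class CalibrationDataError(ValueError):
    """Calibration impossible with the supplied standards."""


@dataclass
class CalibrationStandard:
    """One tetO array strain with its photometry measurements."""

    n_operator_sites: int
    fluorophores_per_site: int = 2  # TetR binds as a homodimer
    label: str | None = None
    measured: list[ClusterMeasurement] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_operator_sites < 0:
            raise ValueError("n_operator_sites must be >= 0")
        if self.fluorophores_per_site < 1:
            raise ValueError("fluorophores_per_site must be >= 1")
        if self.label is None:
            self.label = f"{self.n_operator_sites}x"

    @property
    def expected_max(self) -> int:
        return self.n_operator_sites * self.fluorophores_per_site

    def median_rate(self) -> float:
        if not self.measured:
            raise CalibrationDataError(f"standard {self.label} has no measurements")
        return float(np.median([m.photon_rate for m in self.measured]))


def max_fluorophores(std: CalibrationStandard) -> int:
    """Maximum fluorophore count an array can carry (sites x per-site)."""
    return std.expected_max


@dataclass
class CountingCalibration:
    """Photons per fluorophore per second, from a through-origin fit."""

    photons_per_fluorophore_per_s: float
    fit_standards: list[str]
    residuals: np.ndarray

    def __post_init__(self) -> None:
        if self.photons_per_fluorophore_per_s <= 0:
            raise CalibrationDataError("calibration slope must be > 0")


@dataclass
class CountEstimate:
    molecules: float
    molecules_per_centromere: float
    interval: dict | None = None

    def __post_init__(self) -> None:
        if self.molecules < 0:
            raise ValueError("molecules must be >= 0")


def fit_calibration(
    standards: list[CalibrationStandard], min_measurements: int = 5
) -> CountingCalibration:
    """Least-squares regression through the origin on standard medians.

    Medians (not means) resist occupancy outliers and match the five-number
    summaries used for reporting.  Requires at least two standards with
    distinct expected maxima, each carrying ``min_measurements`` or more
    measurements at a common exposure (or rate-normalized).
    """
    usable = [s for s in standards if s.n_operator_sites > 0]
    if len({s.expected_max for s in usable}) < 2:
        raise CalibrationDataError("need >= 2 standards with distinct expected maxima")
    for s in usable:
        if len(s.measured) < min_measurements:
            raise CalibrationDataError(
                f"standard {s.label} has {len(s.measured)} < {min_measurements} measurements"
            )
    x = np.array([float(s.expected_max) for s in usable])
    y = np.array([s.median_rate() for s in usable])
    slope = float(np.dot(x, y) / np.dot(x, x))
    if slope <= 0:
        raise CalibrationDataError("degenerate data: nonpositive calibration slope")
    residuals = y - slope * x
    rel = np.abs(residuals) / np.maximum(np.abs(y), 1e-300)
    if np.any(rel > 0.25):
        warnings.warn(
            "calibration standards deviate >25% from proportionality; "
            "check occupancy or exposure normalization",
            stacklevel=2,
        )
    return CountingCalibration(
        photons_per_fluorophore_per_s=slope,
        fit_standards=[s.label for s in usable],
        residuals=residuals,
    )


def estimate_count(
    m: ClusterMeasurement | float,
    cal: CountingCalibration,
    n_centromeres: int = 16,
) -> CountEstimate:
    """Convert a photon rate (or measurement) into a molecule count.

    ``molecules_per_centromere`` divides by 16 for a telophase cluster (the
    canonical counting stage, with mature fluorophores).
    """
    rate = m.photon_rate if isinstance(m, ClusterMeasurement) else float(m)
    slope = cal.photons_per_fluorophore_per_s
    if slope <= 0:
        raise CalibrationDataError("calibration slope must be > 0")
    molecules = max(rate / slope, 0.0)
    return CountEstimate(
        molecules=molecules, molecules_per_centromere=molecules / n_centromeres
    )


def count_summary(rates, cal: CountingCalibration, n_centromeres: int = 16) -> dict:
    """Five-number summary of molecule counts for a set of photon rates."""
    counts = [max(r / cal.photons_per_fluorophore_per_s, 0.0) for r in rates]
    s = summarize_quartiles(counts)
    s["median_per_centromere"] = s["median"] / n_centromeres
    return s
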