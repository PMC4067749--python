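"""EMCCD camera model, frame calibration, and ADU/photoelectron conversion.

The camera model carries the experimentally established constants of the
back-illuminated EMCCD used for wide-field imaging (conversion gain in
photoelectrons per ADU at the working EM gain, readout noise, thermal
current).  Raw 16-bit frames are calibrated into 32-bit floating point by
subtracting the bias level and the expected thermal signal and dividing by a
mean-normalized flat field.  Background-corrected signals are converted to
photoelectrons (the equivalent of detected photons) by multiplying with the
conversion gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

__all__ = [
    "CameraModel",
    "ImageStack",
    "calibrate_stack",
    "uncalibrate_stack",
    "adu_to_photons",
    "load_stack",
    "save_stack",
]

#: Default wide-field lateral pixel size (nm); 4 px = 428 nm.
WIDEFIELD_PIXEL_NM = 107.0
#: Default wide-field focal step (nm).
WIDEFIELD_Z_STEP_NM = 333.0


class CalibrationError(ValueError):
    """Raised when calibration preconditions are violated."""


@dataclass
class CameraModel:
    """EMCCD calibration constants and reference frames.

    Parameters
    ----------
    conversion_gain : float
        Photoelectrons per ADU at the working EM gain (default 0.044).
    readout_noise : float
        Readout noise, photoelectrons RMS (default 0.470).
    dark_current : float
        Thermal current, photoelectrons per pixel per second (default 0.014).
    em_gain : float
        Electron-multiplication factor (default 50).
    bias_level : float or ndarray
        ADU offset; a scalar or a measured bias frame.
    flat_field : float or ndarray
        Per-pixel sensitivity map; renormalized to mean 1 on construction so
        that calibration is photometrically neutral.
    dark_frame : ndarray, optional
        Measured thermal frame in ADU at the working exposure.  When present
        it overrides the scalar ``dark_current * exposure`` model.
    """

    conversion_gain: float = 0.044
    readout_noise: float = 0.470
    dark_current: float = 0.014
    em_gain: float = 50.0
    bias_level: float | np.ndarray = 0.0
    flat_field: float | np.ndarray = 1.0
    dark_frame: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.conversion_gain <= 0:
            raise ValueError("conversion_gain must be > 0")
        if self.em_gain < 1:
            raise ValueError("em_gain must be >= 1")
        if self.readout_noise < 0 or self.dark_current < 0:
            raise ValueError("noise parameters must be >= 0")
        flat = np.asarray(self.flat_field, dtype=np.float64)
        if np.any(flat <= 0):
            raise ValueError("flat_field must be strictly positive")
        flat = flat / flat.mean()
        self.flat_field = float(flat) if flat.ndim == 0 else flat
        if isinstance(self.bias_level, np.ndarray):
            self.bias_level = np.asarray(self.bias_level, dtype=np.float64)

    def dark_adu(self, exposure: float) -> float | np.ndarray:
        """Expected thermal signal in ADU for a given exposure (seconds)."""
        if exposure < 0:
            raise ValueError("exposure must be >= 0")
        if self.dark_frame is not None:
            return np.asarray(self.dark_frame, dtype=np.float64)
        return self.dark_current * exposure / self.conversion_gain

    def to_dict(self) -> dict[str, Any]:
        d = {
            "conversion_gain": self.conversion_gain,
            "readout_noise": self.readout_noise,
            "dark_current": self.dark_current,
            "em_gain": self.em_gain,
        }
        if np.ndim(self.bias_level) == 0:
            d["bias_level"] = float(self.bias_level)
        if np.ndim(self.flat_field) == 0:
            d["flat_field"] = float(self.flat_field)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "CameraModel":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


@dataclass
class ImageStack:
    """Pixel data with physical scales and exposure metadata.

    ``pixels`` may be 2D (YX), 3D (ZYX) or 4D (TZYX).  Raw stacks hold
    nonnegative integer ADU; calibrated stacks hold 32-bit (or wider) floats
    in bias/dark/flat-corrected ADU (``value_format='calibrated_adu'``).
    """

    pixels: np.ndarray
    pixel_size_nm: float = WIDEFIELD_PIXEL_NM
    z_step_nm: float = WIDEFIELD_Z_STEP_NM
    exposure_s: float = 1.0
    timestamps: np.ndarray | None = None
    calibrated: bool = False
    value_format: str = "raw_adu"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3, 4):
            raise ValueError("pixels must be 2D, 3D or 4D")
        if min(self.pixels.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        if self.pixel_size_nm <= 0 or self.z_step_nm <= 0:
            raise ValueError("physical scales must be > 0")
        if self.value_format not in ("raw_adu", "calibrated_adu"):
            raise ValueError(f"unknown value_format {self.value_format!r}")
        if self.value_format == "raw_adu":
            if not np.issubdtype(self.pixels.dtype, np.integer):
                if not np.allclose(self.pixels, np.round(self.pixels)):
                    raise ValueError("raw stacks must hold integer ADU")
            if self.pixels.min() < 0:
                raise ValueError("raw ADU must be nonnegative")
        if self.timestamps is not None:
            ts = np.asarray(self.timestamps, dtype=np.float64)
            if np.any(np.diff(ts) < 0):
                raise ValueError("timestamps must be nondecreasing")
            self.timestamps = ts

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.pixels.shape[-2:]

    def frames(self) -> np.ndarray:
        """View of the data as a (n_frames, Y, X) array."""
        return self.pixels.reshape((-1,) + self.frame_shape)

    def metadata(self) -> dict[str, Any]:
        md = {
            "pixel_size_nm": self.pixel_size_nm,
            "z_step_nm": self.z_step_nm,
            "exposure_s": self.exposure_s,
            "calibrated": self.calibrated,
            "value_format": self.value_format,
        }
        if self.timestamps is not None:
            md["timestamps"] = [float(t) for t in self.timestamps]
        if self.provenance:
            md["provenance"] = dict(self.provenance)
        return md


def _check_ref_shape(name: str, ref, frame_shape: tuple[int, int]) -> None:
    if np.ndim(ref) == 0:
        return
    if np.shape(ref) != frame_shape:
        raise CalibrationError(
            f"{name} frame shape {np.shape(ref)} does not match "
            f"data frame shape {frame_shape}"
        )


def calibrate_stack(raw: ImageStack, cam: CameraModel) -> ImageStack:
    """Calibrate a raw ADU stack into 32-bit floating point.

    Applies ``(raw - bias - dark) / flat`` per pixel, where the dark term is
    either a measured thermal frame or the scalar expectation
    ``dark_current * exposure / conversion_gain`` (ADU).  The output keeps
    ADU units ("calibrated ADU"); :func:`adu_to_photons` converts net
    signals to photoelectrons.
    """
    if raw.value_format != "raw_adu" or raw.calibrated:
        raise CalibrationError("input stack is already calibrated")
    if raw.exposure_s < 0:
        raise ValueError("negative exposure")
    frame_shape = raw.frame_shape
    _check_ref_shape("bias", cam.bias_level, frame_shape)
    _check_ref_shape("flat", cam.flat_field, frame_shape)
    if cam.dark_frame is not None:
        _check_ref_shape("dark", cam.dark_frame, frame_shape)

    dark = cam.dark_adu(raw.exposure_s)
    data = raw.pixels.astype(np.float64)
    out = (data - cam.bias_level - dark) / cam.flat_field
    prov = dict(raw.provenance)
    prov.update(
        {
            "bias": "frame" if np.ndim(cam.bias_level) else float(cam.bias_level),
            "dark": "frame" if cam.dark_frame is not None else "scalar-model",
            "flat": "frame" if np.ndim(cam.flat_field) else "unity",
            "conversion_gain": cam.conversion_gain,
        }
    )
    return ImageStack(
        pixels=out.astype(np.float32) if out.dtype.itemsize < 4 else out,
        pixel_size_nm=raw.pixel_size_nm,
        z_step_nm=raw.z_step_nm,
        exposure_s=raw.exposure_s,
        timestamps=raw.timestamps,
        calibrated=True,
        value_format="calibrated_adu",
        provenance=prov,
    )


def uncalibrate_stack(cal: ImageStack, cam: CameraModel) -> np.ndarray:
    """Algebraic inverse of :func:`calibrate_stack` (returns raw ADU floats)."""
    if not cal.calibrated:
        raise CalibrationError("input stack is not calibrated")
    dark = cam.dark_adu(cal.exposure_s)
    return np.asarray(cal.pixels, dtype=np.float64) * cam.flat_field + cam.bias_level + dark


def adu_to_photons(net_adu, cam: CameraModel):
    """Convert background-corrected ADU into photoelectrons.

    Strictly linear and sign-preserving: ``photons = net_adu * conversion_gain``.
    Negative inputs pass through for the caller to interpret.
    """
    return np.multiply(net_adu, cam.conversion_gain)


# ---------------------------------------------------------------------------
# TIFF + YAML-sidecar persistence


def save_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF with a YAML metadata sidecar."""
    import tifffile
    import yaml

    path = Path(path)
    data = stack.pixels
    if stack.value_format == "raw_adu" and not np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.uint16)
    if stack.calibrated and data.dtype != np.float32 and data.dtype != np.float64:
        data = data.astype(np.float32)
    tifffile.imwrite(path, data, photometric="minisblack")
    sidecar = path.with_suffix(path.suffix + ".yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump(stack.metadata(), fh)
    return path


def load_stack(path: str | Path) -> ImageStack:
    """Read a TIFF written by :func:`save_stack` (sidecar optional)."""
    import tifffile
    import yaml

    path = Path(path)
    pixels = tifffile.imread(path)
    md: dict[str, Any] = {}
    sidecar = path.with_suffix(path.suffix + ".yaml")
    if sidecar.exists():
        with open(sidecar) as fh:
            md = yaml.safe_load(fh) or {}
    ts = md.get("timestamps")
    return ImageStack(
        pixels=pixels,
        pixel_size_nm=md.get("pixel_size_nm", WIDEFIELD_PIXEL_NM),
        z_step_nm=md.get("z_step_nm", WIDEFIELD_Z_STEP_NM),
        exposure_s=md.get("exposure_s", 1.0),
        timestamps=np.asarray(ts, dtype=float) if ts is not None else None,
        calibrated=md.get("calibrated", False),
        value_format=md.get("value_format", "raw_adu"),
        provenance=md.get("provenance", {}),
    )
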