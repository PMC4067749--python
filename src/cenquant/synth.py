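"""Synthetic-microscopy generator with ground truth.

Every pipeline input can be generated here with known truth: raw EMCCD
frames of cells carrying diffraction-scale clusters over diffuse nuclear and
cytoplasmic background, tetO titration series, maturation and recovery time
courses, pulse-chase panels, and MFM-PALM blinking movies with gold-nanorod
fiducials and stage drift.

Forward model of one frame: the expected photoelectron image sums per-pixel
Gaussian-PSF integrals over all visible emitters plus background and thermal
signal; the noise chain is Poisson -> EM-register gamma (shape = electron
count, scale = EM gain) -> Gaussian read noise -> division by (EM gain x
conversion scaling) -> bias offset -> integer quantization.  The gamma stage
gives the EMCCD excess noise factor of ~2.  Every generator is a pure
function of its spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .camera import CameraModel, ImageStack
from .kinetics import FluorophoreStateModel
from .palm3d import MFMGeometry, LOC_COLUMNS

__all__ = [
    "ClusterSpec",
    "SceneSpec",
    "render_frame",
    "expected_photon_image",
    "add_camera_noise",
    "sample_points_in_shape",
    "generate_titration",
    "generate_cluster_scenes",
    "generate_maturation_course",
    "generate_frap_course",
    "generate_pulse_chase_panel",
    "generate_palm_movie",
    "mfm_camera_frame",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: Photon rate per GFP molecule chosen so that a telophase cluster of
#: 32 molecules yields ~7,500 photons in a 5 s exposure.
DEFAULT_RATE_PER_FLUOROPHORE = 47.0


def sample_points_in_shape(
    shape: str, dims_nm, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform (n, 3) nm samples inside a sphere or ellipsoid.

    ``dims_nm`` is the diameter for a sphere, (equatorial_diameter,
    polar_distance) for an ellipsoid (polar axis along z), or the FWHM of an
    isotropic ``gaussian`` cloud (smooth diffuse distributions).
    """
    u = rng.normal(size=(n, 3))
    if shape == "point":
        return np.zeros((n, 3))
    if shape == "gaussian":
        return u * float(dims_nm) * FWHM_TO_SIGMA
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    r = rng.uniform(size=(n, 1)) ** (1.0 / 3.0)
    ball = u * r
    if shape == "sphere":
        return ball * (float(dims_nm) / 2.0)
    if shape == "ellipsoid":
        eq, polar = dims_nm
        return ball * np.array([eq / 2.0, eq / 2.0, polar / 2.0])
    if shape == "ellipsoid_xy":
        # oblate cluster with its short (polar) axis lying in the focal
        # plane at a random orientation, as for anaphase spindle geometry
        eq, polar = dims_nm
        pts = ball * np.array([eq / 2.0, polar / 2.0, eq / 2.0])  # polar along y
        theta = rng.uniform(0.0, 2.0 * np.pi)
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0.0],
                [np.sin(theta), np.cos(theta), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        return pts @ rot.T
    raise ValueError(f"unknown shape {shape!r}")


@dataclass
class ClusterSpec:
    """One emitter cluster: explicit positions or a sampled shape."""

    center_px: tuple[float, float]  # (row, col)
    n_emitters: int = 32
    rate_per_emitter: float = DEFAULT_RATE_PER_FLUOROPHORE  # photons/s
    shape: str = "sphere"
    dims_nm: float | tuple[float, float] = 300.0
    emitter_offsets_nm: np.ndarray | None = None  # explicit (n, 3), overrides shape
    visibility: float = 1.0  # state-model occupancy multiplier

    def offsets(self, rng: np.random.Generator) -> np.ndarray:
        if self.emitter_offsets_nm is not None:
            return np.asarray(self.emitter_offsets_nm, dtype=np.float64)
        return sample_points_in_shape(self.shape, self.dims_nm, self.n_emitters, rng)


@dataclass
class SceneSpec:
    """One synthetic cell scene (single 2D frame unless rendered repeatedly)."""

    frame_shape: tuple[int, int] = (64, 64)
    pixel_size_nm: float = 107.0
    exposure_s: float = 1.0
    psf_fwhm_nm: float = 225.0
    camera: CameraModel = field(default_factory=lambda: CameraModel(bias_level=100.0))
    clusters: list[ClusterSpec] = field(default_factory=list)
    nucleus_px: tuple[float, float, float] | None = None  # (row, col, radius)
    nuclear_rate: float = 0.0  # photons / pixel / s
    cyto_ellipse_px: tuple[float, float, float, float] | None = None  # (row, col, a, b)
    cyto_rate: float = 0.0
    # smooth diffuse pools: (row, col, fwhm_px, total photons/s)
    gaussian_blobs: list[tuple[float, float, float, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nuclear_rate < 0 or self.cyto_rate < 0:
            raise ValueError("background rates must be >= 0")
        sigma_px = self.psf_fwhm_nm * FWHM_TO_SIGMA / self.pixel_size_nm
        if 6 * sigma_px > min(self.frame_shape):
            raise ValueError("PSF wider than the frame")


def _background_map(spec: SceneSpec) -> np.ndarray:
    ny, nx = spec.frame_shape
    bg = np.zeros((ny, nx))
    yy, xx = np.mgrid[:ny, :nx]
    if spec.cyto_ellipse_px is not None and spec.cyto_rate > 0:
        r0, c0, a, b = spec.cyto_ellipse_px
        inside = ((yy - r0) / b) ** 2 + ((xx - c0) / a) ** 2 <= 1.0
        bg[inside] += spec.cyto_rate
    if spec.nucleus_px is not None and spec.nuclear_rate > 0:
        r0, c0, rad = spec.nucleus_px
        inside = (yy - r0) ** 2 + (xx - c0) ** 2 <= rad**2
        bg[inside] += spec.nuclear_rate
    for r0, c0, fwhm_px, rate in spec.gaussian_blobs:
        s = fwhm_px * FWHM_TO_SIGMA
        r2 = (yy - r0) ** 2 + (xx - c0) ** 2
        bg += rate * np.exp(-r2 / (2 * s * s)) / (2 * np.pi * s * s)
    return bg


def _emitter_flux(ny, nx, row, col, sigma_px, total):
    """Pixel-integrated Gaussian flux (erf quadrature) around one emitter."""
    half = int(math.ceil(5 * sigma_px)) + 1
    r0, r1 = max(int(row) - half, 0), min(int(row) + half + 1, ny)
    c0, c1 = max(int(col) - half, 0), min(int(col) + half + 1, nx)
    rows = np.arange(r0, r1)
    cols = np.arange(c0, c1)
    fy = ndtr((rows + 0.5 - row) / sigma_px) - ndtr((rows - 0.5 - row) / sigma_px)
    fx = ndtr((cols + 0.5 - col) / sigma_px) - ndtr((cols - 0.5 - col) / sigma_px)
    return (r0, r1, c0, c1), total * np.outer(fy, fx)


def expected_photon_image(
    spec: SceneSpec, rng: np.random.Generator
) -> tuple[np.ndarray, pd.DataFrame]:
    """Noise-free expected photoelectron image plus emitter ground truth."""
    ny, nx = spec.frame_shape
    sigma_px = spec.psf_fwhm_nm * FWHM_TO_SIGMA / spec.pixel_size_nm
    image = _background_map(spec) * spec.exposure_s
    truth_rows = []
    for ci, cl in enumerate(spec.clusters):
        offsets = cl.offsets(rng)
        for ei, off in enumerate(offsets):
            row = cl.center_px[0] + off[1] / spec.pixel_size_nm
            col = cl.center_px[1] + off[0] / spec.pixel_size_nm
            total = cl.rate_per_emitter * spec.exposure_s * cl.visibility
            (r0, r1, c0, c1), flux = _emitter_flux(ny, nx, row, col, sigma_px, total)
            image[r0:r1, c0:c1] += flux
            truth_rows.append(
                {
                    "cluster": ci,
                    "emitter": ei,
                    "row_px": row,
                    "col_px": col,
                    "photons": total,
                }
            )
    return image, pd.DataFrame(truth_rows)


def add_camera_noise(
    expected_photons: np.ndarray, cam: CameraModel, rng: np.random.Generator
) -> np.ndarray:
    """Apply the EMCCD noise chain and return quantized raw ADU (uint16)."""
    expected = np.asarray(expected_photons, dtype=np.float64) * cam.flat_field
    electrons = rng.poisson(np.clip(expected, 0, None)).astype(np.float64)
    amplified = np.zeros_like(electrons)
    mask = electrons > 0
    if np.any(mask):
        amplified[mask] = rng.gamma(electrons[mask], scale=cam.em_gain)
    adu = amplified / (cam.em_gain * cam.conversion_gain)
    adu = adu + rng.normal(0.0, cam.readout_noise / cam.conversion_gain, adu.shape)
    adu = adu + cam.bias_level
    return np.clip(np.rint(adu), 0, 65535).astype(np.uint16)


def render_frame(spec: SceneSpec, rng: np.random.Generator | None = None):
    """Render one raw frame; returns (ImageStack, emitter truth table)."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    expected, truth = expected_photon_image(spec, rng)
    expected = expected + spec.camera.dark_current * spec.exposure_s
    pixels = add_camera_noise(expected, spec.camera, rng)
    stack = ImageStack(
        pixels=pixels,
        pixel_size_nm=spec.pixel_size_nm,
        exposure_s=spec.exposure_s,
        value_format="raw_adu",
        provenance={"generator": "synthetic", "seed": spec.seed},
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Titration and counting scenes


def generate_titration(
    operator_counts=(7, 14, 21),
    per_fluorophore_rate: float = DEFAULT_RATE_PER_FLUOROPHORE,
    n_images: int = 15,
    exposure_s: float = 2.0,
    frame_shape=(64, 64),
    occupancy: float = 1.0,
    nuclear_rate: float = 10.0,
    seed: int = 0,
):
    """tetO array scenes (one spot each, homodimer = 2 fluorophores/site).

    Returns ``(scenes, truth)`` where scenes is a list of (stack, n_operators)
    and truth tabulates per-image expected maxima.  ``occupancy`` < 1 models
    incomplete repressor binding (known undercounting bias direction).
    """
    rng = np.random.default_rng(seed)
    center = (frame_shape[0] / 2.0, frame_shape[1] / 2.0)
    scenes, rows = [], []
    for n_ops in operator_counts:
        for i in range(n_images):
            n_fluor = int(round(n_ops * 2 * occupancy))
            spec = SceneSpec(
                frame_shape=frame_shape,
                exposure_s=exposure_s,
                clusters=[
                    ClusterSpec(
                        center_px=center,
                        n_emitters=n_fluor,
                        rate_per_emitter=per_fluorophore_rate,
                        shape="point",
                    )
                ],
                nucleus_px=(center[0], center[1], 12.0),
                nuclear_rate=nuclear_rate,
                seed=seed,
            )
            stack, _ = render_frame(spec, rng)
            scenes.append((stack, n_ops))
            rows.append(
                {"image": len(rows), "n_operators": n_ops, "expected_max": n_ops * 2}
            )
    return scenes, pd.DataFrame(rows)


def generate_cluster_scenes(
    n_images: int = 50,
    n_emitters: int = 32,
    per_fluorophore_rate: float = DEFAULT_RATE_PER_FLUOROPHORE,
    exposure_s: float = 2.0,
    frame_shape=(64, 64),
    cluster_diameter_nm: float = 300.0,
    nuclear_rate: float = 10.0,
    stage: str = "T",
    seed: int = 0,
):
    """Centromere-cluster scenes (telophase by default: 16 centromeres x 2)."""
    rng = np.random.default_rng(seed)
    center = (frame_shape[0] / 2.0, frame_shape[1] / 2.0)
    scenes = []
    for i in range(n_images):
        spec = SceneSpec(
            frame_shape=frame_shape,
            exposure_s=exposure_s,
            clusters=[
                ClusterSpec(
                    center_px=center,
                    n_emitters=n_emitters,
                    rate_per_emitter=per_fluorophore_rate,
                    shape="sphere",
                    dims_nm=cluster_diameter_nm,
                )
            ],
            nucleus_px=(center[0], center[1], 12.0),
            nuclear_rate=nuclear_rate,
            seed=seed,
        )
        stack, _ = render_frame(spec, rng)
        scenes.append(stack)
    truth = {
        "n_emitters": n_emitters,
        "photons_per_image": n_emitters * per_fluorophore_rate * exposure_s,
        "stage": stage,
    }
    return scenes, truth


# ---------------------------------------------------------------------------
# Kinetics time courses


def generate_maturation_course(
    model: FluorophoreStateModel | None = None,
    t_block_min: float = 0.0,
    timepoints=None,
    n_cells: int = 20,
    amplitude_photons: float = 1750.0,
    noise_cv: float = 0.05,
    seed: int = 0,
):
    """Cycloheximide-block maturation course: I(t) = A * green_fraction(t).

    Deposition happens at t=0 (the protein-synthesis block only prevents
    later synthesis), so intensity follows the state model's closed-form
    green occupancy with multiplicative measurement noise.  Truth carries
    the model half-time and amplitude.
    """
    model = model or FluorophoreStateModel()
    if timepoints is None:
        timepoints = np.arange(0.0, 181.0, 10.0)
    t = np.asarray(timepoints, dtype=np.float64)
    rng = np.random.default_rng(seed)
    rows = []
    for cell in range(n_cells):
        amp = amplitude_photons * rng.normal(1.0, 0.1)
        ideal = amp * model.green_fraction(t)
        noisy = ideal * rng.normal(1.0, noise_cv, size=t.shape)
        for ti, yi in zip(t, noisy):
            rows.append({"cell_id": cell, "t_min": float(ti), "net_photons": float(yi)})
    truth = {
        "t_half_min": model.maturation_halftime,
        "amplitude_photons": amplitude_photons,
        "t_block_min": t_block_min,
    }
    return pd.DataFrame(rows), truth


def generate_frap_course(
    bound_sites: int = 32,
    free_pool_ratio: float = 4.0,
    exchange_time_min: float = 10.0,
    pre_bleach_photons: float = 10_000.0,
    background_photons: float = 200.0,
    baseline_sigma: float = 1000.0,
    bleach_time_min: float = 0.0,
    sampling_interval_min: float = 1.0,
    duration_min: float = 30.0,
    n_cells: int = 42,
    stages=("G1", "S", "M", "A", "T"),
    seed: int = 0,
):
    """Post-bleach recovery of a chaperone exchanging with a nuclear pool.

    Signal follows ``plateau * (1 - exp(-(t - t_bleach)/tau))`` where the
    plateau is the pre-bleach level scaled by the pool-depletion factor
    ``free/(free + bound)`` (~4/5 at the fourfold nuclear excess).  Truth
    includes the exchange time and the detection time implied by the
    ``background + 3 sigma`` threshold.
    """
    rng = np.random.default_rng(seed)
    plateau = pre_bleach_photons * free_pool_ratio / (free_pool_ratio + 1.0)
    threshold = background_photons + 3.0 * baseline_sigma
    if threshold >= plateau:
        raise ValueError("detection threshold above the recovery plateau")
    implied = bleach_time_min - exchange_time_min * math.log(1.0 - threshold / plateau)
    t = np.arange(bleach_time_min, duration_min + 1e-9, sampling_interval_min)
    rows = []
    for cell in range(n_cells):
        stage = stages[cell % len(stages)]
        tau = exchange_time_min * rng.normal(1.0, 0.15)
        signal = plateau * (1.0 - np.exp(-(t - bleach_time_min) / max(tau, 0.1)))
        noisy = signal + rng.normal(0.0, baseline_sigma * 0.3, size=t.shape)
        noisy[0] = 0.0  # bleach frame
        for ti, yi in zip(t, noisy):
            rows.append(
                {"cell_id": cell, "stage": stage, "t_min": float(ti), "net_photons": float(yi)}
            )
    truth = {
        "exchange_time_min": exchange_time_min,
        "plateau_photons": plateau,
        "threshold": threshold,
        "background": background_photons,
        "baseline_sigma": baseline_sigma,
        "implied_detection_min": implied,
    }
    return pd.DataFrame(rows), truth


def generate_pulse_chase_panel(
    n_cells: int = 40,
    frac_crossing_g1s: float = 0.5,
    replacement_at_S: bool = True,
    bleach_factor: float = 0.8,
    pulse_photons: float = 7500.0,
    noise_cv: float = 0.05,
    detection_floor: float = 50.0,
    seed: int = 0,
):
    """Two-timepoint pulse-chase panel with second-photoconversion control.

    Cells crossing G1/S between pulse and chase lose the photoconverted
    signal entirely (replacement by new, unconverted molecules); all others
    retain it attenuated by the imaging bleach factor.  Truth labels each
    cell retained/replaced.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cell in range(n_cells):
        crossing = rng.uniform() < frac_crossing_g1s
        pulse = pulse_photons * rng.normal(1.0, 0.1)
        if crossing and replacement_at_S:
            chase = abs(rng.normal(0.0, detection_floor / 3.0))
            label = "lost_replaced"
        else:
            chase = pulse * bleach_factor * rng.normal(1.0, noise_cv)
            label = "retained"
        second_pc = pulse * rng.normal(1.0, 0.1)  # new mature molecules visible
        rows.append(
            {
                "cell_id": cell,
                "stage": "S" if crossing else "G1",
                "pulse": pulse,
                "chase": chase,
                "second_pc": second_pc,
                "truth": label,
            }
        )
    truth = {"bleach_factor": bleach_factor, "detection_floor": detection_floor}
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# MFM-PALM movies


def _drift_trace(drift_total, n_frames: int) -> np.ndarray:
    d = np.asarray(drift_total, dtype=np.float64)
    frac = np.linspace(0.0, 1.0, n_frames)[:, None]
    return d[None, :] * frac


def generate_palm_movie(
    clusters=None,
    activation: str = "sequential",
    event_len_mean: float = 2.0,
    loc_noise_nm=(20.0, 20.0, 50.0),
    fiducials=((-1500.0, -1500.0, 0.0),),
    fiducial_jitter_nm: float = 1.0,
    drift_total_nm=(0.0, 0.0, 0.0),
    n_frames: int | None = None,
    seed: int = 0,
):
    """Blinking movie as a localization table with per-fluorophore truth.

    ``clusters`` is a list of dicts with keys ``center_nm`` (x, y, z),
    ``shape`` ('sphere'/'ellipsoid'), ``dims_nm`` and ``n_fluorophores``.
    Sequential activation schedules one fluorophore at a time with an empty
    frame between events, so events never overlap and greedy grouping (with
    a generous link radius) must recover the exact per-cluster counts.
    Event lengths are 1 + geometric draws with mean ``event_len_mean``.
    Localizations are true positions + anisotropic Gaussian noise + drift.

    Returns ``(locs, truth)``: the standard localization table and a copy
    with ``fluorophore_id`` / ``cluster_id`` columns plus true positions.
    """
    if clusters is None:
        clusters = [
            {"center_nm": (0.0, 0.0, 1500.0), "shape": "sphere", "dims_nm": 450.0,
             "n_fluorophores": 20},
            {"center_nm": (2000.0, 0.0, 1500.0), "shape": "sphere", "dims_nm": 450.0,
             "n_fluorophores": 22},
        ]
    rng = np.random.default_rng(seed)
    sx, sy, sz = loc_noise_nm

    fluor_pos, fluor_cluster = [], []
    for ci, cl in enumerate(clusters):
        offs = sample_points_in_shape(
            cl.get("shape", "sphere"), cl["dims_nm"], cl["n_fluorophores"], rng
        )
        center = np.asarray(cl["center_nm"], dtype=np.float64)
        for off in offs:
            fluor_pos.append(center + off)
            fluor_cluster.append(ci)
    fluor_pos = np.asarray(fluor_pos)
    n_fluor = len(fluor_pos)

    if activation != "sequential":
        raise ValueError("only sequential activation is implemented")
    # geometric event lengths (support >= 1 frame), mean event_len_mean
    p = 1.0 / max(event_len_mean, 1.0)
    lengths = rng.geometric(p, size=n_fluor)
    order = rng.permutation(n_fluor)
    starts = np.empty(n_fluor, dtype=int)
    t = 0
    for idx in order:
        starts[idx] = t
        t += int(lengths[idx]) + 1  # one dark frame between events
    total_frames = t if n_frames is None else max(n_frames, t)

    drift = _drift_trace(drift_total_nm, total_frames)
    rows, truth_rows = [], []
    for i in range(n_fluor):
        for f in range(starts[i], starts[i] + int(lengths[i])):
            noise = rng.normal(0.0, [sx, sy, sz])
            obs = fluor_pos[i] + noise + drift[f]
            rows.append(
                {
                    "frame": f,
                    "x_nm": obs[0],
                    "y_nm": obs[1],
                    "z_nm": obs[2],
                    "photons": 1000.0,  # per-event budget: placeholder value
                    "sigma_xy_nm": sx,
                    "sigma_z_nm": sz,
                    "is_fiducial": False,
                }
            )
            truth_rows.append(
                {
                    "frame": f,
                    "fluorophore_id": i,
                    "cluster_id": fluor_cluster[i],
                    "x_true_nm": fluor_pos[i][0],
                    "y_true_nm": fluor_pos[i][1],
                    "z_true_nm": fluor_pos[i][2],
                }
            )
    for fi, fpos in enumerate(fiducials):
        fpos = np.asarray(fpos, dtype=np.float64)
        for f in range(total_frames):
            jitter = rng.normal(0.0, fiducial_jitter_nm, 3)
            obs = fpos + jitter + drift[f]
            rows.append(
                {
                    "frame": f,
                    "x_nm": obs[0],
                    "y_nm": obs[1],
                    "z_nm": obs[2],
                    "photons": 1e6,
                    "sigma_xy_nm": fiducial_jitter_nm,
                    "sigma_z_nm": fiducial_jitter_nm,
                    "is_fiducial": True,
                }
            )
            truth_rows.append(
                {
                    "frame": f,
                    "fluorophore_id": -1 - fi,
                    "cluster_id": -1,
                    "x_true_nm": fpos[0],
                    "y_true_nm": fpos[1],
                    "z_true_nm": fpos[2],
                }
            )
    locs = pd.DataFrame(rows, columns=LOC_COLUMNS).sort_values(
        ["frame"], kind="stable"
    ).reset_index(drop=True)
    truth = pd.DataFrame(truth_rows).sort_values(["frame"], kind="stable").reset_index(
        drop=True
    )
    truth_meta = {
        "per_cluster_fluorophores": [cl["n_fluorophores"] for cl in clusters],
        "cluster_centers_nm": [tuple(cl["center_nm"]) for cl in clusters],
        "cluster_shapes": [
            (cl.get("shape", "sphere"), cl["dims_nm"]) for cl in clusters
        ],
        "n_frames": total_frames,
        "drift_total_nm": tuple(float(v) for v in drift_total_nm),
    }
    return locs, (truth, truth_meta)


def mfm_camera_frame(volume: np.ndarray, geom: MFMGeometry) -> np.ndarray:
    """Forward model of the multifocal camera frame (inverse of assembly).

    Each Z-plane of ``volume`` is shifted by the tile's registration offset,
    scaled by its transmission, and placed at its tile position.
    """
    from scipy import ndimage as ndi

    volume = np.asarray(volume, dtype=np.float64)
    if volume.shape[0] != geom.n_planes:
        raise ValueError("volume plane count must match geometry")
    frame = np.zeros(geom.frame_shape())
    h, w = geom.tile_shape
    for k, (r0, c0) in enumerate(geom.tile_layout):
        tile = volume[k]
        dy, dx = geom.shifts[k]
        if dy or dx:
            tile = ndi.shift(tile, (dy, dx), order=3, mode="nearest")
        frame[r0 : r0 + h, c0 : c0 + w] = tile * geom.transmissions[k]
    return frame
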