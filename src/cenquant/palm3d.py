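"""MFM-PALM processing and 3D cluster geometry.

Multifocal-plane camera frames are assembled into single-shot Z-stacks,
sparse single-molecule events are detected and fitted, consecutive-frame
detections are grouped into fluorophore events, stage drift is removed with
gold-nanorod fiducials, and cluster dimensions are summarized as an
enclosing sphere (interphase) or ellipsoid (anaphase) containing the
majority of detections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

__all__ = [
    "MFMGeometry",
    "Localization",
    "FluorophoreEvent",
    "ClusterGeometry",
    "assemble_mfm",
    "detect_localizations",
    "group_events",
    "group_events_brute_force",
    "drift_correct",
    "cluster_geometry",
    "split_two_clusters",
    "compile_clusters",
    "volume_ratio",
    "airy_fwhm",
    "read_localizations",
    "write_localizations",
]

LOC_COLUMNS = [
    "frame",
    "x_nm",
    "y_nm",
    "z_nm",
    "photons",
    "sigma_xy_nm",
    "sigma_z_nm",
    "is_fiducial",
]


@dataclass
class MFMGeometry:
    """Layout of the multifocal camera frame.

    ``tile_layout`` maps plane index -> (row0, col0) of the camera
    sub-region; all tiles share ``tile_shape``.  Per-tile registration is a
    translation (dy, dx) in pixels (translation+scale by default; full
    affine is out of scope) plus a multiplicative transmission factor.
    Plane 0 is nearest the coverslip; plane k sits at ``k * plane_spacing``.
    """

    n_planes: int = 9
    plane_spacing_nm: float = 380.0
    lateral_pixel_nm: float = 120.0
    tile_shape: tuple[int, int] = (64, 64)
    tile_layout: list[tuple[int, int]] = field(default_factory=list)
    shifts: list[tuple[float, float]] = field(default_factory=list)
    transmissions: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_planes < 1 or self.plane_spacing_nm <= 0:
            raise ValueError("n_planes >= 1 and plane_spacing > 0 required")
        if not self.tile_layout:
            # default 3x3 grid in plane order, row-major
            side = int(np.ceil(np.sqrt(self.n_planes)))
            h, w = self.tile_shape
            self.tile_layout = [
                (h * (k // side), w * (k % side)) for k in range(self.n_planes)
            ]
        if not self.shifts:
            self.shifts = [(0.0, 0.0)] * self.n_planes
        if not self.transmissions:
            self.transmissions = [1.0] * self.n_planes
        if any(t <= 0 for t in self.transmissions):
            raise ValueError("transmission factors must be > 0")
        if not (len(self.tile_layout) == len(self.shifts) == len(self.transmissions) == self.n_planes):
            raise ValueError("per-tile parameters must match n_planes")

    @property
    def z_extent_nm(self) -> float:
        return (self.n_planes - 1) * self.plane_spacing_nm

    def frame_shape(self) -> tuple[int, int]:
        h, w = self.tile_shape
        return (
            max(r for r, _ in self.tile_layout) + h,
            max(c for _, c in self.tile_layout) + w,
        )


@dataclass
class Localization:
    x_nm: float
    y_nm: float
    z_nm: float
    frame: int
    photons: float = 0.0
    precision_xy_nm: float = 20.0
    precision_z_nm: float = 50.0
    is_fiducial: bool = False

    def __post_init__(self) -> None:
        if self.precision_xy_nm <= 0 or self.precision_z_nm <= 0:
            raise ValueError("precisions must be > 0")
        for v in (self.x_nm, self.y_nm, self.z_nm):
            if not np.isfinite(v):
                raise ValueError("coordinates must be finite")


@dataclass
class FluorophoreEvent:
    """Localizations in strictly consecutive frames treated as one fluorophore."""

    indices: list[int]
    position_nm: tuple[float, float, float]
    n_frames: int
    start_frame: int


def assemble_mfm(frame: np.ndarray, geom: MFMGeometry) -> np.ndarray:
    """Assemble one camera frame into a (Z, Y, X) stack.

    Each tile is cropped, divided by its transmission factor, and resampled
    by its registration translation onto the common lateral grid.
    """
    frame = np.asarray(frame, dtype=np.float64)
    h, w = geom.tile_shape
    ny, nx = frame.shape
    stack = np.empty((geom.n_planes, h, w))
    seen = np.zeros(frame.shape, dtype=bool)
    for k, (r0, c0) in enumerate(geom.tile_layout):
        if r0 < 0 or c0 < 0 or r0 + h > ny or c0 + w > nx:
            raise ValueError(f"tile {k} at ({r0},{c0}) out of camera frame bounds")
        if seen[r0 : r0 + h, c0 : c0 + w].any():
            raise ValueError(f"tile {k} overlaps a previous tile")
        seen[r0 : r0 + h, c0 : c0 + w] = True
        tile = frame[r0 : r0 + h, c0 : c0 + w] / geom.transmissions[k]
        dy, dx = geom.shifts[k]
        if dy or dx:
            tile = ndi.shift(tile, (-dy, -dx), order=3, mode="nearest")
        stack[k] = tile
    return stack


# ---------------------------------------------------------------------------
# Single-molecule detection


def _gauss3d(coords, amp, x0, y0, z0, sx, sz, offset):
    zz, yy, xx = coords
    return (
        amp
        * np.exp(
            -((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sx**2)
            - (zz - z0) ** 2 / (2 * sz**2)
        )
        + offset
    )


def detect_localizations(
    stacks: np.ndarray,
    geom: MFMGeometry,
    threshold_k: float = 5.0,
    window_xy: int = 7,
    window_z: int = 3,
    saturation_level: float | None = None,
) -> pd.DataFrame:
    """Detect and fit sparse emitters in a (T, Z, Y, X) stack time series.

    Candidate voxels exceed ``background + k * sigma`` (per-frame robust
    estimates) and are local maxima; each is fitted with a 3D Gaussian by
    least squares in a ``window_xy**2 x window_z`` box.  Candidates whose
    windows overlap another candidate's are rejected, as are saturated
    windows.  Coordinates are returned in nm using the MFM voxel size.
    """
    from scipy.optimize import curve_fit

    stacks = np.asarray(stacks, dtype=np.float64)
    if stacks.ndim == 3:
        stacks = stacks[None]
    T, Z, NY, NX = stacks.shape
    hw = window_xy // 2
    hz = window_z // 2
    rows = []
    for t in range(T):
        vol = stacks[t]
        bg = np.median(vol)
        sigma = 1.4826 * np.median(np.abs(vol - bg))
        thr = bg + threshold_k * max(sigma, 1e-12)
        is_max = vol == ndi.maximum_filter(vol, size=3, mode="nearest")
        cand = np.argwhere(is_max & (vol > thr))
        # merge duplicate maxima of one blob (noise shoulders within 2 px),
        # keeping the brightest, before applying the overlap rule
        if len(cand) > 1:
            order = np.argsort(vol[cand[:, 0], cand[:, 1], cand[:, 2]])[::-1]
            merged: list[np.ndarray] = []
            for idx in order:
                c = cand[idx]
                if all(
                    max(abs(int(c[1]) - int(m[1])), abs(int(c[2]) - int(m[2]))) > 2
                    or abs(int(c[0]) - int(m[0])) > 1
                    for m in merged
                ):
                    merged.append(c)
            cand = np.array(merged)
        # reject candidates with overlapping fit windows
        keep = []
        for i, (cz, cy, cx) in enumerate(cand):
            ok = True
            for j, (oz, oy, ox) in enumerate(cand):
                if i == j:
                    continue
                if (
                    abs(int(cy) - int(oy)) <= 2 * hw
                    and abs(int(cx) - int(ox)) <= 2 * hw
                    and abs(int(cz) - int(oz)) <= 2 * hz
                ):
                    ok = False
                    break
            if ok:
                keep.append((int(cz), int(cy), int(cx)))
        for cz, cy, cx in keep:
            z0, z1 = max(cz - hz, 0), min(cz + hz + 1, Z)
            y0, y1 = max(cy - hw, 0), min(cy + hw + 1, NY)
            x0, x1 = max(cx - hw, 0), min(cx + hw + 1, NX)
            win = vol[z0:z1, y0:y1, x0:x1]
            if saturation_level is not None and win.max() >= saturation_level:
                continue
            zz, yy, xx = np.mgrid[z0:z1, y0:y1, x0:x1].astype(float)
            p0 = (float(vol[cz, cy, cx] - bg), float(cx), float(cy), float(cz), 1.0, 0.8, bg)
            try:
                popt, _ = curve_fit(
                    _gauss3d,
                    (zz.ravel(), yy.ravel(), xx.ravel()),
                    win.ravel(),
                    p0=p0,
                    maxfev=5000,
                )
            except RuntimeError:
                continue
            amp, fx, fy, fz, sx, sz, off = popt
            if amp <= 0:
                continue
            photons = float(np.clip(win.sum() - off * win.size, 1.0, None))
            sx_nm = abs(sx) * geom.lateral_pixel_nm
            sz_nm = abs(sz) * geom.plane_spacing_nm
            rows.append(
                {
                    "frame": t,
                    "x_nm": fx * geom.lateral_pixel_nm,
                    "y_nm": fy * geom.lateral_pixel_nm,
                    "z_nm": fz * geom.plane_spacing_nm,
                    "photons": photons,
                    "sigma_xy_nm": max(sx_nm / np.sqrt(photons), 1e-3),
                    "sigma_z_nm": max(sz_nm / np.sqrt(photons), 1e-3),
                    "is_fiducial": False,
                }
            )
    return pd.DataFrame(rows, columns=LOC_COLUMNS)


# ---------------------------------------------------------------------------
# Event grouping


def group_events(
    locs: pd.DataFrame, link_radius_nm: float = 60.0, max_gap: int = 0
) -> list[FluorophoreEvent]:
    """Greedy frame-to-frame linking into fluorophore events.

    Localizations in consecutive frames (up to ``max_gap`` skipped frames)
    within ``link_radius_nm`` lateral distance are chained; ties resolve to
    the smallest distance, then the lowest index.  Every chain (length >= 1)
    is one event; events lasting more than one frame represent a single
    fluorophore.  The event position is the precision-weighted mean.
    """
    if link_radius_nm <= 0:
        raise ValueError("link_radius must be > 0")
    if locs.empty:
        return []
    df = locs.reset_index(drop=True)
    frames = df["frame"].to_numpy()
    xs, ys, zs = (df[c].to_numpy(dtype=float) for c in ("x_nm", "y_nm", "z_nm"))
    chains: list[list[int]] = []
    open_chains: list[list[int]] = []  # chains whose last loc may still extend
    for f in np.unique(frames):
        idx_f = np.nonzero(frames == f)[0]
        # candidate chains whose last frame is within the gap window
        active = [c for c in open_chains if f - frames[c[-1]] <= max_gap + 1 and f > frames[c[-1]]]
        pairs = []
        for ci, chain in enumerate(active):
            last = chain[-1]
            for i in idx_f:
                d = np.hypot(xs[i] - xs[last], ys[i] - ys[last])
                if d <= link_radius_nm:
                    pairs.append((d, ci, int(i)))
        pairs.sort(key=lambda p: (p[0], p[1], p[2]))
        used_chains: set[int] = set()
        used_locs: set[int] = set()
        for d, ci, i in pairs:
            if ci in used_chains or i in used_locs:
                continue
            active[ci].append(i)
            used_chains.add(ci)
            used_locs.add(i)
        for i in idx_f:
            if int(i) not in used_locs:
                c = [int(i)]
                chains.append(c)
                open_chains.append(c)
        open_chains = [c for c in open_chains if f - frames[c[-1]] <= max_gap]

    events = []
    sxy = df["sigma_xy_nm"].to_numpy(dtype=float) if "sigma_xy_nm" in df else np.full(len(df), 20.0)
    for chain in chains:
        w = 1.0 / np.maximum(sxy[chain], 1e-6) ** 2
        w = w / w.sum()
        pos = (
            float(np.dot(w, xs[chain])),
            float(np.dot(w, ys[chain])),
            float(np.dot(w, zs[chain])),
        )
        events.append(
            FluorophoreEvent(
                indices=[int(i) for i in chain],
                position_nm=pos,
                n_frames=len(chain),
                start_frame=int(frames[chain[0]]),
            )
        )
    events.sort(key=lambda e: (e.start_frame, e.indices[0]))
    return events


def group_events_brute_force(
    locs: pd.DataFrame, link_radius_nm: float = 60.0, max_gap: int = 0
) -> int:
    """Independent oracle: count connected components of the linking graph.

    Nodes are localizations; edges join pairs in frames that differ by
    1..max_gap+1 whose lateral distance is within the link radius.  Intended
    for small inputs only.
    """
    from scipy.sparse import lil_matrix
    from scipy.sparse.csgraph import connected_components

    n = len(locs)
    if n == 0:
        return 0
    df = locs.reset_index(drop=True)
    frames = df["frame"].to_numpy()
    xs, ys = df["x_nm"].to_numpy(dtype=float), df["y_nm"].to_numpy(dtype=float)
    adj = lil_matrix((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dt = abs(int(frames[i]) - int(frames[j]))
            if 1 <= dt <= max_gap + 1:
                if np.hypot(xs[i] - xs[j], ys[i] - ys[j]) <= link_radius_nm:
                    adj[i, j] = 1
    n_comp, _ = connected_components(adj.tocsr(), directed=False)
    return int(n_comp)


# ---------------------------------------------------------------------------
# Drift correction


def drift_correct(
    locs: pd.DataFrame,
    max_fiducial_jump_nm: float = 300.0,
    min_coverage: float = 0.8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subtract stage drift measured from fiducial trajectories.

    Fiducial localizations (``is_fiducial`` column) are tracked across
    frames by nearest-neighbour assignment; per-frame drift is the mean over
    fiducials of (position - that fiducial's first-frame position), linearly
    interpolated across frames without a fiducial fit.  Requires at least
    one fiducial visible in ``min_coverage`` of the frames.  Returns the
    corrected table and the drift trace (frame, dx, dy, dz).
    """
    df = locs.reset_index(drop=True).copy()
    fid = df[df["is_fiducial"].astype(bool)]
    if fid.empty:
        raise ValueError("no fiducial localizations present")
    frames = np.arange(int(df["frame"].min()), int(df["frame"].max()) + 1)
    n_frames = frames.size
    if n_frames == 1:
        drift = pd.DataFrame({"frame": frames, "dx_nm": 0.0, "dy_nm": 0.0, "dz_nm": 0.0})
        return df, drift

    # track fiducials: assign each localization to the nearest track end
    tracks: list[dict] = []  # {'ref': first pos, 'last': pos, 'obs': {frame: pos}}
    for f in np.unique(fid["frame"].to_numpy()):
        sub = fid[fid["frame"] == f]
        for _, row in sub.iterrows():
            p = np.array([row["x_nm"], row["y_nm"], row["z_nm"]])
            best, best_d = None, np.inf
            for tr in tracks:
                d = np.linalg.norm(p - tr["last"])
                if d < best_d:
                    best, best_d = tr, d
            if best is not None and best_d <= max_fiducial_jump_nm:
                best["last"] = p
                best["obs"][int(f)] = p
            else:
                tracks.append({"ref": p, "last": p, "obs": {int(f): p}})

    covered = set()
    for tr in tracks:
        covered.update(tr["obs"].keys())
    if len(covered) < min_coverage * n_frames:
        raise ValueError(
            f"fiducial coverage {len(covered)}/{n_frames} frames below "
            f"required {min_coverage:.0%}"
        )

    drift_sum = np.zeros((n_frames, 3))
    drift_cnt = np.zeros(n_frames)
    f0 = frames[0]
    for tr in tracks:
        for f, p in tr["obs"].items():
            drift_sum[f - f0] += p - tr["ref"]
            drift_cnt[f - f0] += 1
    have = drift_cnt > 0
    drift = np.empty((n_frames, 3))
    drift[have] = drift_sum[have] / drift_cnt[have, None]
    for ax in range(3):
        drift[:, ax] = np.interp(frames, frames[have], drift[have, ax])

    fidx = df["frame"].to_numpy().astype(int) - f0
    for ax, col in enumerate(("x_nm", "y_nm", "z_nm")):
        df[col] = df[col].to_numpy(dtype=float) - drift[fidx, ax]
    trace = pd.DataFrame(
        {"frame": frames, "dx_nm": drift[:, 0], "dy_nm": drift[:, 1], "dz_nm": drift[:, 2]}
    )
    return df, trace


# ---------------------------------------------------------------------------
# Cluster geometry


@dataclass
class ClusterGeometry:
    centroid_nm: tuple[float, float, float]
    enclosing_diameter_nm: float
    pca_axes: np.ndarray  # rows: major, mid, minor unit vectors
    axis_extents_nm: tuple[float, float, float]  # sorted descending
    equatorial_diameter_nm: float
    polar_distance_nm: float
    volume_nm3: float
    n_events: int
    majority_fraction: float
    degenerate: bool = False


def _axis_quantile_factor(q: float) -> float:
    """t in (0,1] with P(|u| <= t) = q for the axis marginal of a uniform ball.

    The marginal density of one coordinate of a uniform unit ball is
    (3/4)(1-u^2); solve (3t - t^3)/2 = q.
    """
    from scipy.optimize import brentq

    return float(brentq(lambda t: (3 * t - t**3) / 2 - q, 0.0, 1.0))


# Gauss-Legendre nodes for the uniform-ball axis marginal (density 3/4 (1-u^2))
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(64)


def _noisy_axis_quantile(semi_axis: float, sigma: float, q: float) -> float:
    """q-quantile of |c*u + N(0, sigma)| with u the uniform-ball axis marginal."""
    from scipy.optimize import brentq
    from scipy.special import ndtr

    if sigma <= 0:
        return semi_axis * _axis_quantile_factor(q)
    w = 0.75 * (1.0 - _GL_NODES**2) * _GL_WEIGHTS  # integrates to 1 on [-1, 1]

    def cdf_abs(x):
        z = semi_axis * _GL_NODES
        return float(np.sum(w * (ndtr((x - z) / sigma) - ndtr((-x - z) / sigma))))

    hi = semi_axis + 6 * sigma
    return float(brentq(lambda x: cdf_abs(x) - q, 1e-9, hi))


def _invert_axis_quantile(q_obs: float, sigma: float, q: float) -> float:
    """Semi-axis c whose noisy axis-marginal q-quantile equals ``q_obs``.

    Deconvolves known localization noise out of an extent estimate without
    relying on noisy sample variances; with sigma = 0 this reduces to the
    uniform-ball order-statistic correction.
    """
    from scipy.optimize import brentq

    if sigma <= 0:
        return q_obs / _axis_quantile_factor(q)
    # the pure-noise quantile is a lower bound on the observable quantile
    from scipy.special import ndtri

    noise_only = sigma * ndtri(0.5 + q / 2.0)
    if q_obs <= noise_only:
        return 0.0
    hi = max((q_obs / _axis_quantile_factor(q)) * 2.0, 4 * sigma)
    return float(brentq(lambda c: _noisy_axis_quantile(c, sigma, q) - q_obs, 0.0, hi))


def cluster_geometry(
    points_nm: np.ndarray,
    majority_fraction: float = 0.9,
    bias_correction: bool = True,
    precision_nm: tuple[float, float, float] | None = None,
) -> ClusterGeometry:
    """Summarize a drift-corrected 3D point set as sphere + ellipsoid metrics.

    ``enclosing_diameter`` is twice the ``majority_fraction`` quantile of
    radial distances from the centroid; axis extents are twice the same
    quantile of |projection| onto each principal axis.  With
    ``bias_correction`` both are rescaled by the corresponding order
    statistic of a uniform ball so that, for uniformly filled shapes, the
    estimate converges to the true diameter rather than its q-quantile.
    When localization precision is supplied, the known noise is deconvolved:
    axis extents invert the noisy-quantile model of a uniform marginal plus
    Gaussian noise (stable even at ~20 events per cluster), and radial
    distances are computed after per-axis variance shrinkage.
    """
    pts = np.asarray(points_nm, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be (n, 3)")
    n = pts.shape[0]
    if n < 4:
        raise ValueError(f"need >= 4 points, got {n}")
    if not 0 < majority_fraction <= 1:
        raise ValueError("majority_fraction must lie in (0, 1]")
    q = majority_fraction
    centroid = pts.mean(axis=0)
    centered = pts - centroid

    cov = np.cov(centered.T)
    evals, evecs = np.linalg.eigh(cov)
    noise = (
        np.asarray(precision_nm, dtype=np.float64) ** 2
        if precision_nm is not None
        else np.zeros(3)
    )
    # order axes by noise-subtracted (signal) variance: major, mid, minor
    signal_evals = evals - np.array([evecs[:, k] ** 2 @ noise for k in range(3)])
    order = np.argsort(signal_evals)[::-1]
    axes = evecs[:, order].T  # rows are unit vectors
    degenerate = evals[order][-1] <= 1e-9 * max(evals[order][0], 1e-30)

    proj = centered @ axes.T  # coordinates in the principal frame
    axis_noise_var = np.array([axes[k] ** 2 @ noise for k in range(3)])

    # radial metric: mild per-axis variance shrinkage before the quantile
    shrunk = proj.copy()
    for ax in range(3):
        var = proj[:, ax].var()
        if var > 0 and axis_noise_var[ax] > 0:
            shrunk[:, ax] *= np.sqrt(max(var - axis_noise_var[ax], 0.04 * var) / var)
    radii = np.linalg.norm(shrunk, axis=1)
    r_q = float(np.quantile(radii, q))
    sphere_corr = q ** (1.0 / 3.0) if bias_correction else 1.0
    enclosing = 2.0 * r_q / sphere_corr

    if degenerate:
        eq = polar = vol = float("nan")
        extents = (float("nan"),) * 3
    else:
        ext = []
        for ax in range(3):
            q_obs = float(np.quantile(np.abs(proj[:, ax]), q))
            if bias_correction:
                c = _invert_axis_quantile(q_obs, float(np.sqrt(axis_noise_var[ax])), q)
            else:
                c = q_obs
            ext.append(2.0 * c)
        ext_sorted = tuple(sorted(ext, reverse=True))
        eq = 0.5 * (ext_sorted[0] + ext_sorted[1])
        polar = ext_sorted[2]
        vol = (4.0 / 3.0) * np.pi * (eq / 2.0) ** 2 * (polar / 2.0)
        extents = ext_sorted

    return ClusterGeometry(
        centroid_nm=tuple(float(c) for c in centroid),
        enclosing_diameter_nm=enclosing,
        pca_axes=axes,
        axis_extents_nm=extents,
        equatorial_diameter_nm=float(eq),
        polar_distance_nm=float(polar),
        volume_nm3=float(vol),
        n_events=n,
        majority_fraction=q,
        degenerate=bool(degenerate),
    )


def split_two_clusters(points_nm: np.ndarray, seed: int = 0) -> list[np.ndarray]:
    """Split a cell's detections into clusters by 2-means when separated.

    Accepts the 2-means split only when the inter-centroid distance exceeds
    both cluster diameters; otherwise the points are one cluster.
    """
    pts = np.asarray(points_nm, dtype=np.float64)
    if len(pts) < 8:
        return [pts]
    rng = np.random.default_rng(seed)
    # simple 2-means
    centers = pts[rng.choice(len(pts), 2, replace=False)]
    for _ in range(50):
        d = np.linalg.norm(pts[:, None] - centers[None], axis=2)
        lab = np.argmin(d, axis=1)
        if len(np.unique(lab)) < 2:
            return [pts]
        new = np.array([pts[lab == k].mean(axis=0) for k in range(2)])
        if np.allclose(new, centers):
            break
        centers = new
    groups = [pts[lab == k] for k in range(2)]
    if min(len(g) for g in groups) < 4:
        return [pts]
    sep = np.linalg.norm(centers[0] - centers[1])
    diams = [2.0 * np.linalg.norm(g - g.mean(axis=0), axis=1).max() for g in groups]
    if sep > max(diams):
        return groups
    return [pts]


def compile_clusters(clusters: list[np.ndarray], mode: str = "G1") -> np.ndarray:
    """Center-align clusters (and in anaphase mode rotate long axes together).

    Each cluster is translated onto its centroid.  In ``anaphase`` mode it
    is additionally rotated *in the XY plane* so that its in-plane long
    (equatorial) axis lies along x — the spindle-compressed polar axis then
    lies along y for every cluster.  The pooled point set supports joint
    geometry estimation at low per-cluster event counts.
    """
    if mode not in ("G1", "anaphase"):
        raise ValueError("mode must be 'G1' or 'anaphase'")
    if not clusters:
        raise ValueError("no clusters supplied")
    pooled = []
    for pts in clusters:
        pts = np.asarray(pts, dtype=np.float64)
        centered = pts - pts.mean(axis=0)
        if mode == "anaphase":
            cov2 = np.cov(centered[:, :2].T)
            evals2, evecs2 = np.linalg.eigh(cov2)
            long_axis = evecs2[:, int(np.argmax(evals2))]
            c, s = float(long_axis[0]), float(long_axis[1])
            rot = np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])
            centered = centered @ rot.T
        pooled.append(centered)
    return np.vstack(pooled)


def volume_ratio(g_large: ClusterGeometry, g_small: ClusterGeometry) -> float:
    """Volume ratio between two cluster geometries (compaction factor)."""
    for g in (g_large, g_small):
        if not np.isfinite(g.volume_nm3) or g.volume_nm3 <= 0:
            raise ValueError("both geometries need positive finite volumes")
    return g_large.volume_nm3 / g_small.volume_nm3


def airy_fwhm(emission_wavelength_nm: float, numerical_aperture: float) -> float:
    """Diffraction-limited Airy-disk FWHM: 0.51 * lambda / NA (nm)."""
    if emission_wavelength_nm <= 0 or numerical_aperture <= 0:
        raise ValueError("wavelength and NA must be > 0")
    return 0.51 * emission_wavelength_nm / numerical_aperture


# ---------------------------------------------------------------------------
# Localization table I/O


def write_localizations(locs: pd.DataFrame, path) -> None:
    locs.to_csv(path, index=False, columns=LOC_COLUMNS)


def read_localizations(path) -> pd.DataFrame:
    """Read a localization CSV; also accepts bare three-column x/y/z lists."""
    df = pd.read_csv(path)
    if set(LOC_COLUMNS) <= set(df.columns):
        return df[LOC_COLUMNS]
    if df.shape[1] == 3:  # generic x, y, z list (ViSP-compatible ordering)
        df.columns = ["x_nm", "y_nm", "z_nm"]
        df["frame"] = np.arange(len(df))
        df["photons"] = 0.0
        df["sigma_xy_nm"] = 20.0
        df["sigma_z_nm"] = 50.0
        df["is_fiducial"] = False
        return df[LOC_COLUMNS]
    raise ValueError("unrecognized localization table layout")
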