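"""End-to-end analysis pipelines: counting, compaction, kinetics.

Each ``run_*`` function consumes a nested configuration dict (typically
loaded from YAML), generates or loads its inputs, executes the relevant
stages, and returns a plain report dict embedding the seed and a hash of the
configuration so identical inputs produce identical reports.  Stage errors
are re-raised with a stage-tagged message.
"""

from __future__ import annotations

import hashlib
import json
import logging

import numpy as np

from . import counting as _counting
from . import kinetics as _kinetics
from . import palm3d as _palm
from . import photometry as _phot
from . import synth as _synth
from .camera import CameraModel, calibrate_stack

__all__ = ["config_hash", "load_config", "run_counting", "run_compaction", "run_kinetics"]

log = logging.getLogger("cenquant")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def _stage(name):
    class _Ctx:
        def __enter__(self):
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise StageError(f"stage '{name}' failed: {exc}") from exc
            log.info("stage %s: done", name)
            return False

    return _Ctx()


def _measure_scene_spot(stack, cam, policy, spot_fwhm_px):
    """Calibrate, wavelet-filter, detect the brightest spot and measure it."""
    from .wavelet import max_feasible_scales, spot_and_background

    cal = calibrate_stack(stack, cam)
    frame = cal.frames()[0]
    spot, _ = spot_and_background(frame, (1, 2, 3), min(8, max_feasible_scales(frame.shape)))
    centers = _phot.detect_clusters(spot, min_snr=5.0, policy=policy)
    if not centers:
        raise ValueError("no spot detected")
    m = _phot.wavelet_photometry(
        frame,
        centers[0],
        policy,
        cam,
        exposure_s=stack.exposure_s,
        spot_fwhm_px=spot_fwhm_px,
    )
    return m


def run_counting(config: dict) -> dict:
    """Synthetic titration + cluster scenes -> calibration slope and counts."""
    seed = int(config.get("seed", 0))
    cfg = config.get("counting", {})
    cam = CameraModel.from_dict(config.get("camera", {}))
    policy = _phot.AperturePolicy(**config.get("policy", {}))
    spot_fwhm_px = float(cfg.get("spot_fwhm_px", 3.0))

    with _stage("synthesize"):
        scenes, _titr_truth = _synth.generate_titration(
            operator_counts=tuple(cfg.get("operator_counts", (7, 14, 21))),
            per_fluorophore_rate=float(cfg.get("per_fluorophore_rate", _synth.DEFAULT_RATE_PER_FLUOROPHORE)),
            n_images=int(cfg.get("n_titration_images", 15)),
            exposure_s=float(cfg.get("exposure_s", 2.0)),
            seed=seed,
        )
        cluster_stacks, cluster_truth = _synth.generate_cluster_scenes(
            n_images=int(cfg.get("n_cluster_images", 50)),
            n_emitters=int(cfg.get("n_emitters", 32)),
            per_fluorophore_rate=float(cfg.get("per_fluorophore_rate", _synth.DEFAULT_RATE_PER_FLUOROPHORE)),
            exposure_s=float(cfg.get("exposure_s", 2.0)),
            cluster_diameter_nm=float(cfg.get("cluster_diameter_nm", 300.0)),
            seed=seed + 1,
        )

    with _stage("photometry"):
        standards = {}
        for stack, n_ops in scenes:
            m = _measure_scene_spot(stack, cam, policy, spot_fwhm_px)
            standards.setdefault(n_ops, []).append(m)
        cluster_rates = []
        for stack in cluster_stacks:
            m = _measure_scene_spot(stack, cam, policy, spot_fwhm_px)
            cluster_rates.append(m.photon_rate)

    with _stage("calibration"):
        stds = [
            _counting.CalibrationStandard(n_operator_sites=n_ops, measured=ms)
            for n_ops, ms in sorted(standards.items())
        ]
        cal = _counting.fit_calibration(stds)

    with _stage("counting"):
        summary = _counting.count_summary(cluster_rates, cal)

    return {
        "seed": seed,
        "config_hash": config_hash(config),
        "slope_photons_per_fluorophore_per_s": cal.photons_per_fluorophore_per_s,
        "count_summary": summary,
        "molecules_per_centromere": summary["median_per_centromere"],
        "true_emitters_per_cluster": cluster_truth["n_emitters"],
    }


def run_compaction(config: dict) -> dict:
    """Synthetic MFM-PALM movies -> G1/anaphase geometry and volume ratio."""
    seed = int(config.get("seed", 0))
    cfg = config.get("palm", {})
    n_clusters = int(cfg.get("n_clusters_per_condition", 10))
    events = int(cfg.get("events_per_cluster", 21))
    g1_d = float(cfg.get("g1_diameter_nm", 450.0))
    ana_dims = tuple(cfg.get("anaphase_dims_nm", (350.0, 200.0)))
    noise = tuple(cfg.get("loc_noise_nm", (20.0, 20.0, 50.0)))
    drift = tuple(cfg.get("drift_total_nm", (100.0, -50.0, 200.0)))
    link_radius = float(cfg.get("link_radius_nm", 150.0))

    def condition(shape, dims, events_per_cluster, cond_seed):
        clusters = []
        event_prec: list[np.ndarray] = []
        for ci in range(n_clusters):
            spec = [{
                "center_nm": (0.0, 0.0, 1500.0),
                "shape": shape,
                "dims_nm": dims,
                "n_fluorophores": events_per_cluster,
            }]
            locs, (truth, meta) = _synth.generate_palm_movie(
                clusters=spec,
                loc_noise_nm=noise,
                drift_total_nm=drift,
                seed=cond_seed * 1000 + ci,
            )
            with _stage("drift"):
                corrected, _trace = _palm.drift_correct(locs)
            with _stage("grouping"):
                evts = _palm.group_events(
                    corrected[~corrected["is_fiducial"].astype(bool)],
                    link_radius_nm=link_radius,
                )
            clusters.append(np.array([e.position_nm for e in evts]))
            # precision-weighted event positions average down the noise
            event_prec.extend(np.asarray(noise) / np.sqrt(e.n_frames) for e in evts)
        eff = np.sqrt(np.mean(np.square(event_prec), axis=0))
        return clusters, tuple(float(v) for v in eff)

    with _stage("geometry"):
        g1_clusters, g1_prec = condition("sphere", g1_d, events, seed * 2 + 1)
        ana_clusters, ana_prec = condition("ellipsoid_xy", ana_dims, events, seed * 2 + 2)
        g1_points = _palm.compile_clusters(g1_clusters, mode="G1")
        ana_points = _palm.compile_clusters(ana_clusters, mode="anaphase")
        g1_geom = _palm.cluster_geometry(g1_points, precision_nm=g1_prec)
        ana_geom = _palm.cluster_geometry(ana_points, precision_nm=ana_prec)
        ratio = _palm.volume_ratio(g1_geom, ana_geom)

    return {
        "seed": seed,
        "config_hash": config_hash(config),
        "g1": {
            "enclosing_diameter_nm": g1_geom.enclosing_diameter_nm,
            "equatorial_diameter_nm": g1_geom.equatorial_diameter_nm,
            "polar_distance_nm": g1_geom.polar_distance_nm,
            "volume_nm3": g1_geom.volume_nm3,
            "n_events": g1_geom.n_events,
        },
        "anaphase": {
            "enclosing_diameter_nm": ana_geom.enclosing_diameter_nm,
            "equatorial_diameter_nm": ana_geom.equatorial_diameter_nm,
            "polar_distance_nm": ana_geom.polar_distance_nm,
            "volume_nm3": ana_geom.volume_nm3,
            "n_events": ana_geom.n_events,
        },
        "volume_ratio": ratio,
    }


def run_kinetics(config: dict) -> dict:
    """Maturation fit, pulse-chase confusion table, and recovery table."""
    seed = int(config.get("seed", 0))
    cfg = config.get("kinetics", {})
    model = _kinetics.FluorophoreStateModel(**cfg.get("model", {}))
    log.warning("dark-state and bleaching defaults are placeholder rates")

    with _stage("maturation"):
        course, mat_truth = _synth.generate_maturation_course(
            model=model, n_cells=int(cfg.get("n_cells", 20)), seed=seed
        )
        mean_course = course.groupby("t_min")["net_photons"].mean()
        fit = _kinetics.fit_maturation_halftime(
            mean_course.index.to_numpy(), mean_course.to_numpy()
        )

    with _stage("pulse_chase"):
        panel, pc_truth = _synth.generate_pulse_chase_panel(
            n_cells=int(cfg.get("n_pulse_chase_cells", 40)), seed=seed + 1
        )
        confusion: dict[str, dict[str, int]] = {}
        for _, row in panel.iterrows():
            call = _kinetics.classify_pulse_chase(
                row["pulse"],
                row["chase"],
                second_pc_signal=row["second_pc"],
                bleach_correction=pc_truth["bleach_factor"],
                detection_threshold=pc_truth["detection_floor"],
            )
            confusion.setdefault(row["truth"], {}).setdefault(call, 0)
            confusion[row["truth"]][call] += 1

    with _stage("frap"):
        series, frap_truth = _synth.generate_frap_course(
            n_cells=int(cfg.get("n_frap_cells", 42)), seed=seed + 2
        )
        if series.empty:
            log.warning("no cells in recovery series; empty report")
            table, pooled = {}, None
        else:
            records = []
            for cell_id, sub in series.groupby("cell_id"):
                rec = _kinetics.frap_recovery_time(
                    sub["t_min"].to_numpy(),
                    sub["net_photons"].to_numpy(),
                    baseline_sigma=frap_truth["baseline_sigma"],
                    sampling_interval_min=1.0,
                    background=frap_truth["background"],
                    cell_id=cell_id,
                    stage=sub["stage"].iloc[0],
                )
                records.append(rec)
            table = {}
            for rec in records:
                if not rec.censored:
                    table.setdefault(rec.stage, []).append(rec.recovery_time_min)
            table = {
                st: {"mean_recovery_min": float(np.mean(v)), "n": len(v)}
                for st, v in sorted(table.items())
            }
            pooled = _kinetics.pooled_mean_recovery(
                [v["mean_recovery_min"] for v in table.values()],
                [v["n"] for v in table.values()],
            )

    return {
        "seed": seed,
        "config_hash": config_hash(config),
        "maturation": {
            "t_half_min": fit.t_half,
            "amplitude": fit.amplitude,
            "plateau_empirical": fit.plateau_empirical,
            "truth_t_half_min": mat_truth["t_half_min"],
        },
        "pulse_chase_confusion": confusion,
        "recovery_by_stage": table,
        "pooled_mean_recovery_min": pooled,
        "implied_detection_min": frap_truth["implied_detection_min"],
    }
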