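import numpy as np
import pandas as pd
import pytest

from cenquant.palm3d import (
    ClusterGeometry,
    MFMGeometry,
    airy_fwhm,
    assemble_mfm,
    cluster_geometry,
    compile_clusters,
    detect_localizations,
    drift_correct,
    group_events,
    group_events_brute_force,
    read_localizations,
    split_two_clusters,
    volume_ratio,
    write_localizations,
)
from cenquant.synth import generate_palm_movie, mfm_camera_frame, sample_points_in_shape


def locs_frame(rows):
    df = pd.DataFrame(rows)
    for col, default in (
        ("photons", 1000.0),
        ("sigma_xy_nm", 20.0),
        ("sigma_z_nm", 50.0),
        ("is_fiducial", False),
    ):
        if col not in df:
            df[col] = default
        else:
            df[col] = df[col].fillna(default).infer_objects(copy=False)
    return df


class TestMFMGeometry:
    def test_z_extent_of_nine_planes(self):
        # (9 - 1) x 380 nm
        assert MFMGeometry().z_extent_nm == pytest.approx(3040.0)

    def test_default_voxel(self):
        g = MFMGeometry()
        assert g.lateral_pixel_nm == 120.0 and g.plane_spacing_nm == 380.0

    def test_invalid_transmission(self):
        with pytest.raises(ValueError):
            MFMGeometry(transmissions=[0.0] * 9)


class TestAssembleMFM:
    def test_identity_layout_maps_pixel_to_plane(self):
        geom = MFMGeometry(tile_shape=(16, 16))
        frame = np.zeros(geom.frame_shape())
        r0, c0 = geom.tile_layout[4]
        frame[r0 + 7, c0 + 9] = 42.0
        stack = assemble_mfm(frame, geom)
        assert stack.shape == (9, 16, 16)
        assert stack[4, 7, 9] == pytest.approx(42.0)
        assert stack[3].sum() == 0.0

    def test_roundtrip_with_shifts_and_transmissions(self, rng):
        geom = MFMGeometry(
            tile_shape=(32, 32),
            shifts=[(rng.uniform(-3, 3), rng.uniform(-3, 3)) for _ in range(9)],
            transmissions=list(rng.uniform(0.7, 1.3, 9)),
        )
        # smooth ground-truth volume (Gaussian blobs per plane)
        yy, xx = np.mgrid[:32, :32].astype(float)
        volume = np.stack(
            [np.exp(-((yy - 16) ** 2 + (xx - 14 + k) ** 2) / (2 * 3.0**2)) for k in range(9)]
        )
        frame = mfm_camera_frame(volume, geom)
        back = assemble_mfm(frame, geom)
        interior = (slice(None), slice(4, 28), slice(4, 28))
        rms = np.sqrt(np.mean((back[interior] - volume[interior]) ** 2))
        assert rms < 0.01 * volume.max()

    def test_overlapping_tiles_rejected(self):
        geom = MFMGeometry(tile_shape=(16, 16))
        geom.tile_layout[1] = geom.tile_layout[0]
        with pytest.raises(ValueError, match="overlap"):
            assemble_mfm(np.zeros((48, 48)), geom)

    def test_out_of_bounds_tile_rejected(self):
        geom = MFMGeometry(tile_shape=(16, 16))
        with pytest.raises(ValueError, match="bounds"):
            assemble_mfm(np.zeros((40, 40)), geom)


class TestDetectLocalizations:
    def _movie_with_emitters(self, emitters, n_frames=1, photons=1000.0, rng=None):
        geom = MFMGeometry(tile_shape=(24, 24))
        T, Z, NY, NX = n_frames, 9, 24, 24
        stacks = np.zeros((T, Z, NY, NX))
        sigma_xy, sigma_z = 0.9, 0.8
        zz, yy, xx = np.mgrid[:Z, :NY, :NX].astype(float)
        for ex, ey, ez in emitters:
            stacks[0] += photons * np.exp(
                -((xx - ex) ** 2 + (yy - ey) ** 2) / (2 * sigma_xy**2)
                - (zz - ez) ** 2 / (2 * sigma_z**2)
            ) / (sigma_xy**2 * sigma_z * (2 * np.pi) ** 1.5)
        if rng is not None:
            stacks = rng.poisson(np.clip(stacks, 0, None) + 2.0).astype(float)
        return stacks, geom

    def test_empty_movie_no_localizations(self):
        geom = MFMGeometry(tile_shape=(24, 24))
        stacks = np.zeros((2, 9, 24, 24))
        assert detect_localizations(stacks, geom).empty

    def test_single_emitter_localization_error_bounded(self):
        # >= 95% of seeded repeats localize within 3x the precision estimate
        rng = np.random.default_rng(0)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            true = (11.3, 12.6, 4.2)
            stacks, geom = self._movie_with_emitters([true], rng=rng)
            locs = detect_localizations(stacks, geom, threshold_k=6.0)
            if locs.empty:
                continue
            err = np.hypot(locs["x_nm"] - true[0] * 120.0, locs["y_nm"] - true[1] * 120.0)
            best = int(np.argmin(err.to_numpy()))
            if err.iloc[best] < 3 * max(locs["sigma_xy_nm"].iloc[best], 20.0):
                hits += 1
        assert hits >= 0.95 * n_rep

    def test_overlapping_candidate_windows_both_rejected(self):
        # two emitters ~3 px apart: distinct maxima, overlapping 7x7 windows
        stacks, geom = self._movie_with_emitters([(9.0, 12.0, 4.0), (12.3, 12.0, 4.0)])
        locs = detect_localizations(stacks, geom)
        assert locs.empty

    def test_saturated_window_rejected(self):
        stacks, geom = self._movie_with_emitters([(12.0, 12.0, 4.0)], photons=10_000.0)
        locs = detect_localizations(stacks, geom, saturation_level=stacks.max() * 0.5)
        assert locs.empty


class TestGroupEvents:
    def test_separated_single_frame_locs_are_individual_events(self):
        rows = [
            {"frame": 0, "x_nm": 0.0, "y_nm": 0.0, "z_nm": 0.0},
            {"frame": 0, "x_nm": 1000.0, "y_nm": 0.0, "z_nm": 0.0},
            {"frame": 1, "x_nm": 5000.0, "y_nm": 0.0, "z_nm": 0.0},
        ]
        events = group_events(locs_frame(rows))
        assert len(events) == 3
        assert all(e.n_frames == 1 for e in events)

    def test_consecutive_frames_same_position_one_event(self):
        rows = [{"frame": f, "x_nm": 10.0, "y_nm": -5.0, "z_nm": 100.0} for f in (3, 4, 5)]
        events = group_events(locs_frame(rows))
        assert len(events) == 1
        assert events[0].n_frames == 3
        assert events[0].start_frame == 3

    def test_gap_breaks_event_at_default_max_gap(self):
        rows = [{"frame": f, "x_nm": 0.0, "y_nm": 0.0, "z_nm": 0.0} for f in (1, 5)]
        assert len(group_events(locs_frame(rows))) == 2

    def test_max_gap_allows_skipped_frame(self):
        rows = [{"frame": f, "x_nm": 0.0, "y_nm": 0.0, "z_nm": 0.0} for f in (1, 3)]
        assert len(group_events(locs_frame(rows), max_gap=1)) == 1

    def test_precision_weighted_mean_position(self):
        rows = [
            {"frame": 0, "x_nm": 0.0, "y_nm": 0.0, "z_nm": 0.0, "sigma_xy_nm": 10.0},
            {"frame": 1, "x_nm": 30.0, "y_nm": 0.0, "z_nm": 0.0, "sigma_xy_nm": 30.0},
        ]
        events = group_events(locs_frame(rows))
        assert len(events) == 1
        # weights 1/100 vs 1/900 -> x = 30 * (1/900)/(1/100 + 1/900) = 3
        assert events[0].position_nm[0] == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_oracle(self, seed):
        # sparse (PALM-regime) movies: within a frame, localizations stay
        # mutually separated by more than twice the link radius, so greedy
        # linking and graph connected components agree exactly
        rng = np.random.default_rng(seed)
        radius = 80.0
        rows = []
        per_frame: dict[int, list] = {}
        while len(rows) < 150:
            f = int(rng.integers(0, 25))
            p = rng.uniform(0, 1500, 2)
            existing = per_frame.setdefault(f, [])
            if all(np.hypot(p[0] - q[0], p[1] - q[1]) > 2 * radius for q in existing):
                existing.append(p)
                rows.append({"frame": f, "x_nm": float(p[0]), "y_nm": float(p[1]), "z_nm": 0.0})
        df = locs_frame(rows)
        assert len(group_events(df, link_radius_nm=radius)) == group_events_brute_force(
            df, link_radius_nm=radius
        )

    def test_movie_fluorophore_numbers_recovered_exactly(self):
        locs, (truth, meta) = generate_palm_movie(seed=42)
        nonfid = locs[~locs["is_fiducial"].astype(bool)]
        events = group_events(nonfid, link_radius_nm=150.0)
        centers = np.asarray(meta["cluster_centers_nm"])
        counts = [0] * len(centers)
        for e in events:
            d = np.linalg.norm(centers - np.asarray(e.position_nm), axis=1)
            counts[int(np.argmin(d))] += 1
        assert counts == meta["per_cluster_fluorophores"]


class TestDriftCorrect:
    def test_static_fiducials_identity(self):
        locs, _ = generate_palm_movie(seed=0, drift_total_nm=(0, 0, 0), fiducial_jitter_nm=0.5)
        corrected, trace = drift_correct(locs)
        assert np.allclose(trace[["dx_nm", "dy_nm", "dz_nm"]].to_numpy(), 0.0, atol=3.0)
        assert np.allclose(corrected["x_nm"], locs["x_nm"], atol=5.0)

    def test_linear_drift_removed(self):
        locs, (truth, meta) = generate_palm_movie(
            seed=1, drift_total_nm=(100.0, -50.0, 200.0), fiducial_jitter_nm=1.0
        )
        corrected, trace = drift_correct(locs)
        fid = corrected[corrected["is_fiducial"].astype(bool)]
        for col in ("x_nm", "y_nm", "z_nm"):
            assert fid[col].std() < 5.0  # residual fiducial RMS < 5 nm
        # cluster localizations match the undrifted truth within precision
        nonfid = corrected[~corrected["is_fiducial"].astype(bool)].reset_index(drop=True)
        t = truth[truth["cluster_id"] >= 0].reset_index(drop=True)
        err_x = nonfid["x_nm"] - t["x_true_nm"]
        assert np.abs(err_x.mean()) < 10.0

    def test_two_fiducials_opposite_jitter_cancel(self):
        frames = np.arange(20)
        jit = np.sin(frames / 3.0) * 30.0
        rows = []
        for f, j in zip(frames, jit):
            rows.append({"frame": int(f), "x_nm": j, "y_nm": 0.0, "z_nm": 0.0, "is_fiducial": True})
            rows.append({"frame": int(f), "x_nm": 5000.0 - j, "y_nm": 0.0, "z_nm": 0.0, "is_fiducial": True})
            rows.append({"frame": int(f), "x_nm": 2000.0, "y_nm": 0.0, "z_nm": 0.0})
        df = locs_frame(rows)
        corrected, trace = drift_correct(df)
        assert np.allclose(trace["dx_nm"], 0.0, atol=1e-9)
        nonfid = corrected[~corrected["is_fiducial"].astype(bool)]
        assert np.allclose(nonfid["x_nm"], 2000.0)

    def test_no_fiducials_error(self):
        rows = [{"frame": 0, "x_nm": 0.0, "y_nm": 0.0, "z_nm": 0.0}]
        with pytest.raises(ValueError, match="fiducial"):
            drift_correct(locs_frame(rows))

    def test_low_coverage_error(self):
        rows = [{"frame": 0, "x_nm": 0.0, "y_nm": 0.0, "z_nm": 0.0, "is_fiducial": True}]
        rows += [{"frame": f, "x_nm": 0.0, "y_nm": 0.0, "z_nm": 0.0} for f in range(1, 10)]
        with pytest.raises(ValueError, match="coverage"):
            drift_correct(locs_frame(rows))

    def test_smooth_drift_residual_under_5nm(self, rng):
        # arbitrary smooth drift up to ~500 nm total
        frames = np.arange(60)
        drift = np.stack(
            [
                250 * np.sin(frames / 20.0),
                180 * (frames / 59.0) ** 2,
                400 * np.sin(frames / 30.0) ** 2,
            ],
            axis=1,
        )
        rows = []
        for f in frames:
            for fid_x in (0.0, 4000.0):
                rows.append(
                    {
                        "frame": int(f),
                        "x_nm": fid_x + drift[f, 0],
                        "y_nm": drift[f, 1],
                        "z_nm": drift[f, 2],
                        "is_fiducial": True,
                    }
                )
        corrected, _ = drift_correct(locs_frame(rows))
        fid = corrected[corrected["is_fiducial"].astype(bool)]
        for col in ("x_nm", "y_nm", "z_nm"):
            resid = fid.groupby(fid["x_nm"] > 2000)[col].transform(lambda s: s - s.mean())
            assert np.sqrt(np.mean(resid**2)) < 5.0


class TestClusterGeometry:
    def test_too_few_points(self):
        with pytest.raises(ValueError, match=">= 4"):
            cluster_geometry(np.zeros((1, 3)))

    def test_uniform_sphere_bias_correction(self, rng):
        pts = sample_points_in_shape("sphere", 450.0, 1000, rng)
        g_raw = cluster_geometry(pts, bias_correction=False)
        g_cor = cluster_geometry(pts, bias_correction=True)
        # uncorrected q=0.9 quantile sits at 450 * 0.9^(1/3) ~ 434
        assert g_raw.enclosing_diameter_nm == pytest.approx(450 * 0.9 ** (1 / 3), rel=0.03)
        assert g_cor.enclosing_diameter_nm == pytest.approx(450.0, rel=0.05)

    def test_anaphase_ellipsoid_recovery_paper_scale_n(self):
        # at ~24 events per cluster a single polar estimate carries ~20%
        # sampling noise, so unbiasedness is asserted on the replicate mean
        eqs, pols = [], []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            pts = sample_points_in_shape("ellipsoid_xy", (350.0, 200.0), 24, rng)
            pts = pts + rng.normal(0, [20.0, 20.0, 50.0], pts.shape)
            g = cluster_geometry(pts, precision_nm=(20.0, 20.0, 50.0))
            assert g.equatorial_diameter_nm >= g.polar_distance_nm
            eqs.append(g.equatorial_diameter_nm)
            pols.append(g.polar_distance_nm)
        assert np.mean(eqs) == pytest.approx(350.0, rel=0.15)
        assert np.mean(pols) == pytest.approx(200.0, rel=0.20)

    def test_volume_formula(self, rng):
        pts = sample_points_in_shape("ellipsoid", (350.0, 200.0), 5000, rng)
        g = cluster_geometry(pts)
        a = g.equatorial_diameter_nm / 2
        c = g.polar_distance_nm / 2
        assert g.volume_nm3 == pytest.approx(4 / 3 * np.pi * a * a * c, rel=1e-9)

    def test_degenerate_collinear_flagged(self):
        pts = np.stack([np.linspace(0, 100, 10), np.zeros(10), np.zeros(10)], axis=1)
        g = cluster_geometry(pts)
        assert g.degenerate
        assert np.isnan(g.volume_nm3)
        assert np.isfinite(g.enclosing_diameter_nm)

    def test_estimator_consistency_large_n(self):
        rng = np.random.default_rng(8)
        pts = sample_points_in_shape("sphere", 450.0, 10_000, rng)
        g = cluster_geometry(pts)
        assert g.enclosing_diameter_nm == pytest.approx(450.0, rel=0.01)


class TestSplitTwoClusters:
    def test_two_separated_clusters_split(self, rng):
        a = sample_points_in_shape("sphere", 400.0, 30, rng)
        b = sample_points_in_shape("sphere", 400.0, 30, rng) + np.array([2000.0, 0, 0])
        groups = split_two_clusters(np.vstack([a, b]))
        assert len(groups) == 2
        assert sorted(len(g) for g in groups) == [30, 30]

    def test_single_cluster_not_split(self, rng):
        pts = sample_points_in_shape("sphere", 450.0, 40, rng)
        assert len(split_two_clusters(pts)) == 1


class TestCompileClusters:
    def test_identical_clusters_overlay(self, rng):
        base = sample_points_in_shape("sphere", 300.0, 20, rng)
        shiftset = [base + np.array([d, -d, 2 * d]) for d in (0.0, 500.0, 1234.0)]
        pooled = compile_clusters(shiftset, mode="G1")
        assert pooled.shape == (60, 3)
        centered = base - base.mean(axis=0)
        assert np.allclose(pooled[:20], centered)
        assert np.allclose(pooled[20:40], centered, atol=1e-9)

    def test_pooled_g1_clusters_recover_450(self):
        rng = np.random.default_rng(10)
        clusters = []
        for _ in range(10):
            pts = sample_points_in_shape("sphere", 450.0, 21, rng)
            pts += rng.normal(0, [20.0, 20.0, 50.0], pts.shape)
            clusters.append(pts + rng.uniform(-2000, 2000, 3))
        pooled = compile_clusters(clusters, mode="G1")
        g = cluster_geometry(pooled, precision_nm=(20.0, 20.0, 50.0))
        assert g.enclosing_diameter_nm == pytest.approx(450.0, rel=0.05)

    def test_anaphase_alignment_of_random_orientations(self):
        # clusters with randomly oriented in-plane polar axes: after long-axis
        # alignment the pooled minor extent matches single-cluster truth
        rng = np.random.default_rng(11)
        clusters = [
            sample_points_in_shape("ellipsoid_xy", (350.0, 200.0), 24, rng)
            + rng.uniform(-2000, 2000, 3)
            for _ in range(10)
        ]
        pooled = compile_clusters(clusters, mode="anaphase")
        g = cluster_geometry(pooled)
        assert g.polar_distance_nm == pytest.approx(200.0, rel=0.10)
        assert g.equatorial_diameter_nm == pytest.approx(350.0, rel=0.10)

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            compile_clusters([], mode="G1")


class TestVolumeRatio:
    def _geom(self, eq, polar):
        vol = 4 / 3 * np.pi * (eq / 2) ** 2 * (polar / 2)
        return ClusterGeometry(
            centroid_nm=(0, 0, 0),
            enclosing_diameter_nm=eq,
            pca_axes=np.eye(3),
            axis_extents_nm=(eq, eq, polar),
            equatorial_diameter_nm=eq,
            polar_distance_nm=polar,
            volume_nm3=vol,
            n_events=10,
            majority_fraction=0.9,
        )

    def test_identical_geometries(self):
        g = self._geom(400, 400)
        assert volume_ratio(g, g) == pytest.approx(1.0)

    def test_paper_dimensions_give_3p7(self):
        # 450 sphere vs 350 x 350 x 200 ellipsoid
        assert volume_ratio(self._geom(450, 450), self._geom(350, 200)) == pytest.approx(
            450**3 / (350 * 350 * 200), rel=1e-9
        )
        assert volume_ratio(self._geom(450, 450), self._geom(350, 200)) == pytest.approx(3.72, abs=0.01)

    def test_doubling_linear_dimensions_scales_8x(self):
        g1 = self._geom(400, 300)
        g2 = self._geom(800, 600)
        assert volume_ratio(g2, g1) == pytest.approx(8.0)

    def test_zero_volume_error(self):
        g = self._geom(400, 300)
        bad = self._geom(400, 300)
        bad.volume_nm3 = 0.0
        with pytest.raises(ValueError):
            volume_ratio(g, bad)


class TestAiryFwhm:
    def test_red_emission_configuration(self):
        # emission filter center 593 nm, NA 1.35 -> ~225 nm
        assert airy_fwhm(593.0, 1.35) == pytest.approx(0.51 * 593 / 1.35)
        assert airy_fwhm(593.0, 1.35) == pytest.approx(225.0, rel=0.01)

    def test_linearity_in_wavelength(self):
        assert airy_fwhm(1186.0, 1.35) == pytest.approx(2 * airy_fwhm(593.0, 1.35))

    def test_inverse(self):
        na = 0.51 * 600.0 / 225.0
        assert airy_fwhm(600.0, na) == pytest.approx(225.0)

    def test_invalid(self):
        with pytest.raises(ValueError):
            airy_fwhm(0.0, 1.35)


class TestLocalizationIO:
    def test_roundtrip(self, tmp_path):
        locs, _ = generate_palm_movie(seed=2)
        p = tmp_path / "locs.csv"
        write_localizations(locs, p)
        back = read_localizations(p)
        assert np.allclose(back["x_nm"], locs["x_nm"])
        assert list(back.columns) == list(locs.columns)

    def test_three_column_import(self, tmp_path):
        p = tmp_path / "xyz.csv"
        pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0], "c": [5.0, 6.0]}).to_csv(p, index=False)
        df = read_localizations(p)
        assert list(df["x_nm"]) == [1.0, 2.0]
        assert not df["is_fiducial"].any()
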