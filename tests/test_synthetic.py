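"""Bathymetry, track, point-pattern generators and the detection step."""

import numpy as np
import pandas as pd
import pytest

from auvspat.geometry import project_footprints
from auvspat.synthetic import (
    NoiseSpec,
    PointPatternSpec,
    SurveyDesign,
    detect_fish,
    gen_along_track_hardcore,
    gen_bathymetry,
    gen_point_pattern,
    gen_track_and_poses,
)

from conftest import PATTERN_REGION, csr_pattern


class TestGenBathymetry:
    def test_summit_depth_matches_hill_height(self):
        b = gen_bathymetry(plain_depth=4850, hill_height=240, cell_size=50)
        assert float(b.depth.min()) == pytest.approx(4610.0, abs=1e-9)
        assert float(b.depth.max()) == pytest.approx(4850.0, abs=1e-6)

    def test_zero_height_gives_constant_plain(self):
        b = gen_bathymetry(hill_height=0.0, cell_size=100)
        np.testing.assert_allclose(b.depth, 4850.0)

    def test_radial_gaussian_profile(self):
        sigma = 850.0
        b = gen_bathymetry(hill_sigma=sigma, cell_size=50)
        for r in (0.0, 500.0, 1500.0, 3000.0):
            got = b.depth_at(5000.0 + r, 5000.0)
            expect = 4850.0 - 240.0 * np.exp(-(r**2) / (2 * sigma**2))
            assert got == pytest.approx(expect, abs=1e-9)

    def test_rejects_nonpositive_cell_size(self):
        with pytest.raises(ValueError, match="cell_size"):
            gen_bathymetry(cell_size=0.0)


class TestGenTrack:
    def test_broad_design_has_11_lines(self):
        d = SurveyDesign.broad_default()
        assert len(d.line_offsets()) == 11

    def test_crosshatch_doubles_track_length(self):
        d = SurveyDesign.fine_default()
        single = SurveyDesign(
            scale="fine", extent=(1000.0, 1000.0), line_spacing=90.0, crosshatch=False
        )
        assert d.total_track_length() == pytest.approx(2 * single.total_track_length())

    def test_zero_noise_keeps_target_altitude(self, bathy):
        d = SurveyDesign.fine_default(origin=(4500, 4500))
        tr = gen_track_and_poses(d, bathy, noise=NoiseSpec(0.0, 0.0, 0.0, 0.0), seed=0)
        np.testing.assert_allclose(tr.poses["altitude"], 3.2)
        np.testing.assert_allclose(tr.photo_poses["pitch"], 0.0)

    def test_photo_count_matches_interval_arithmetic(self, bathy):
        d = SurveyDesign.broad_default()
        tr = gen_track_and_poses(d, bathy, seed=0)
        expected = 11 * (10_000.0 / (1.2 * 0.87))
        assert len(tr.photo_poses) == pytest.approx(expected, rel=0.01)

    def test_track_exiting_bathymetry_rejected(self, bathy):
        d = SurveyDesign.fine_default(origin=(9_800.0, 9_800.0))
        with pytest.raises(ValueError, match="exits"):
            gen_track_and_poses(d, bathy, seed=0)

    def test_pose_log_has_2s_fixes_and_depth(self, bathy):
        d = SurveyDesign.fine_default(origin=(4500, 4500))
        tr = gen_track_and_poses(d, bathy, seed=3)
        line0 = tr.poses[tr.poses["line_id"] == 0]
        np.testing.assert_allclose(np.diff(line0["timestamp"]), 2.0)
        # vehicle depth = seafloor depth - altitude
        assert (tr.poses["depth"] < 4850).all()


class TestPointPatterns:
    def test_csr_mean_count_matches_intensity(self):
        region = (0.0, 1000.0, 0.0, 1000.0)
        counts = [
            len(gen_point_pattern(PointPatternSpec("csr", 700.0, seed=s), region))
            for s in range(60)
        ]
        # Poisson(700): mean within 3 s.e. of 700
        assert abs(np.mean(counts) - 700.0) < 3 * np.sqrt(700.0 / 60)

    def test_csr_quadrat_counts_are_poisson_like(self):
        # VMR of per-cell counts pooled over replicates stays near 1
        region = (0.0, 1000.0, 0.0, 1000.0)
        all_counts = []
        for s in range(40):
            p = gen_point_pattern(PointPatternSpec("csr", 500.0, seed=100 + s), region)
            h, _, _ = np.histogram2d(
                p["easting"], p["northing"], bins=5, range=[[0, 1000], [0, 1000]]
            )
            all_counts.append(h.ravel())
        c = np.concatenate(all_counts)
        vmr = c.var(ddof=1) / c.mean()
        se = np.sqrt(2.0 / (c.size - 1))
        assert abs(vmr - 1.0) < 3 * se

    def test_hardcore_enforces_min_distance_exhaustively(self):
        p = gen_point_pattern(
            PointPatternSpec("hardcore", 300.0, hardcore_radius=30.0, seed=1),
            (0.0, 1000.0, 0.0, 1000.0),
        )
        xy = p[["easting", "northing"]].to_numpy()
        assert len(xy) > 50
        d2 = np.sum((xy[:, None, :] - xy[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        assert np.sqrt(d2.min()) >= 30.0

    def test_thomas_is_overdispersed(self):
        region = (0.0, 2000.0, 0.0, 2000.0)
        vmrs = []
        for s in range(100):
            p = gen_point_pattern(
                PointPatternSpec("thomas", 400.0, thomas_sigma=50.0, seed=s), region
            )
            h, _, _ = np.histogram2d(
                p["easting"], p["northing"], bins=10, range=[[0, 2000], [0, 2000]]
            )
            c = h.ravel()
            if c.sum() > 0:
                vmrs.append(c.var(ddof=1) / c.mean())
        assert np.mean(vmrs) > 1.5

    def test_flat_covariate_equals_csr_positions(self, bathy):
        region = (0.0, 2000.0, 0.0, 2000.0)
        a = gen_point_pattern(PointPatternSpec("csr", 300.0, seed=9), region)
        b = gen_point_pattern(
            PointPatternSpec("covariate", 300.0, covariate_decay=np.inf, seed=9),
            region,
            bathy,
        )
        np.testing.assert_array_equal(
            a[["easting", "northing"]].to_numpy(), b[["easting", "northing"]].to_numpy()
        )

    def test_covariate_concentrates_near_summit(self, bathy):
        p = gen_point_pattern(
            PointPatternSpec("covariate", 700.0, covariate_decay=2000.0, seed=4),
            PATTERN_REGION,
            bathy,
        )
        d = np.hypot(p["easting"] - 5000.0, p["northing"] - 5000.0)
        assert d.mean() < 3500.0  # uniform would give ~3825 m

    def test_runaway_request_refused(self):
        with pytest.raises(ValueError, match="guard"):
            gen_point_pattern(
                PointPatternSpec("csr", 1e9, seed=0), (0.0, 1e5, 0.0, 1e5)
            )

    def test_along_track_hardcore_gaps(self):
        pos = gen_along_track_hardcore(100, 50_000.0, 200.0, seed=3)
        gaps = np.diff(pos)
        assert np.all(gaps >= 200.0 - 1e-9)
        assert pos.min() >= 0 and pos.max() < 50_000.0


class TestDetectFish:
    def make_footprints(self, cameras, n=3, spacing=1.0):
        return project_footprints(
            np.zeros(n),
            np.arange(n) * spacing,
            np.full(n, 3.2),
            np.zeros(n),
            np.zeros(n),
            np.zeros(n),
            cameras["vertical"],
            timestamp=np.arange(n, dtype=float),
        )

    def pattern(self, coords):
        return pd.DataFrame(
            {
                "easting": [c[0] for c in coords],
                "northing": [c[1] for c in coords],
                "taxon": ["Coryphaenoides sp. 1"] * len(coords),
            }
        )

    def test_fish_outside_all_footprints(self, cameras):
        fps = self.make_footprints(cameras)
        obs = detect_fish(self.pattern([(500.0, 500.0)]), fps)
        assert len(obs) == 0

    def test_single_fish_single_footprint(self, cameras):
        fps = self.make_footprints(cameras, n=1)
        obs = detect_fish(self.pattern([(0.1, 0.1)]), fps)
        assert len(obs) == 1
        assert obs["image_id"].iloc[0] == 0

    def test_duplicate_suppression_across_overlaps(self, cameras):
        # three footprints 1 m apart overlap heavily; the fish sits at the
        # capture position of image 2, so image 2 wins
        fps = self.make_footprints(cameras, n=3, spacing=1.0)
        obs = detect_fish(self.pattern([(0.0, 2.0)]), fps)
        assert len(obs) == 1
        assert obs["image_id"].iloc[0] == 2

    def test_deterministic(self, cameras, bathy):
        fps = self.make_footprints(cameras, n=5)
        pat = csr_pattern(5, region=(-2.0, 2.0, -2.0, 6.0), intensity=5e5)
        a = detect_fish(pat, fps)
        b = detect_fish(pat, fps)
        pd.testing.assert_frame_equal(a, b)
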