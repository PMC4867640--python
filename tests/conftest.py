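"""Shared fixtures: one synthetic study area and its surveys, built once.

The heavy calibration and power tests all run over the same seeded broad
and fine surveys (session scope), varying only the fish patterns, which
mirrors how a fixed survey design observes different realisations of the
fauna.
"""

from __future__ import annotations

import numpy as np
import pytest

from auvspat.density import counts_per_image
from auvspat.geometry import FootprintIndex, calibrate_fov, select_images
from auvspat.pattern import quadrat_assign
from auvspat.synthetic import (
    BathymetryGrid,
    PointPatternSpec,
    SurveyDesign,
    gen_bathymetry,
    gen_point_pattern,
    gen_track_and_poses,
)
from auvspat.terrain import distance_to_contour, extract_contours

# Fish patterns are generated on a region padded beyond the survey domain
# so boundary footprints sample fully populated seafloor.
PAD = 50.0
DOMAIN = (0.0, 10_000.0, 0.0, 10_000.0)
PATTERN_REGION = (-PAD, 10_000.0 + PAD, -PAD, 10_000.0 + PAD)


@pytest.fixture(scope="session")
def bathy() -> BathymetryGrid:
    """Default 10 x 10 km study area: 4850 m plain, 240 m Gaussian hill.

    20 m cells keep session setup fast; contour-distance tolerances in
    tests scale with this cell size.
    """
    return gen_bathymetry(cell_size=20.0)


@pytest.fixture(scope="session")
def cameras():
    return {
        "vertical": calibrate_fov("vertical", 2.4, 3.2),
        "oblique": calibrate_fov("oblique", 16.5, 3.2),
    }


class Survey:
    """A fixed survey with its retained footprints and spatial index."""

    def __init__(self, design, track, footprints):
        self.design = design
        self.track = track
        self.footprints = footprints
        self.index = FootprintIndex(footprints)

    def detect(self, pattern):
        from auvspat.synthetic import detect_fish

        return detect_fish(pattern, self.footprints, self.index)

    def fishy_mask(self, obs):
        return np.isin(self.footprints.image_id, obs["image_id"].unique())


@pytest.fixture(scope="session")
def broad_oblique(bathy, cameras) -> Survey:
    """Broad 10 x 10 km oblique survey: retained (stride-2) footprints."""
    design = SurveyDesign.broad_default()
    track = gen_track_and_poses(design, bathy, seed=1)
    fps = select_images(track.footprints(cameras["oblique"]))
    return Survey(design, track, fps)


@pytest.fixture(scope="session")
def broad_contour_distances(bathy, broad_oblique):
    """Distance of every retained broad oblique image to the 4800 m contour."""
    contours = extract_contours(bathy)
    return distance_to_contour(broad_oblique.footprints.centre, contours)[4800.0]


@pytest.fixture(scope="session")
def fine_oblique(bathy, cameras):
    """Fine 1 x 1 km crosshatched oblique survey over the hill flank,
    with precomputed 11 x 11 quadrat cell assignments."""
    design = SurveyDesign.fine_default(origin=(4_500.0, 4_500.0), survey_id="FQ")
    track = gen_track_and_poses(design, bathy, seed=7)
    fps = select_images(track.footprints(cameras["oblique"]))
    sv = Survey(design, track, fps)
    sv.cells = quadrat_assign(fps.centre, design.origin, design.extent)
    return sv


@pytest.fixture(scope="session")
def coverage_vertical(bathy, cameras):
    """Non-overlapping vertical survey for bootstrap calibration.

    2 x 2 km crosshatch at 180 m spacing with a 2.0 s photo interval, so
    consecutive 2.4 m^2 footprints never overlap and the detected count
    is exactly Poisson with mean = density x summed area.
    """
    design = SurveyDesign(
        scale="fine",
        extent=(2_000.0, 2_000.0),
        line_spacing=180.0,
        photo_interval=2.0,
        origin=(4_000.0, 7_000.0),
        survey_id="COV",
        crosshatch=True,
    )
    track = gen_track_and_poses(design, bathy, seed=2)
    fps = select_images(track.footprints(cameras["vertical"]))
    return Survey(design, track, fps)


def csr_pattern(seed: int, intensity: float = 700.0, region=PATTERN_REGION, bathy=None):
    return gen_point_pattern(
        PointPatternSpec(regime="csr", intensity=intensity, seed=seed), region, bathy
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
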