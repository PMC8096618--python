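"""Route simulation: mechanisms, conservation laws, solvers."""

from datetime import date

import numpy as np
import pytest

from vectornav.geomag import FieldModelConfig, FieldVector, STUDY_EPOCH, field_at
from vectornav.geometry import (
    GeoPosition,
    STUDY_SITE,
    advance,
    gc_bearing,
    gc_distance_km,
    rhumb_course,
)
from vectornav.routes import (
    MagnetoclinicState,
    RouteSpec,
    SOUTH_JAPAN,
    magnetoclinic_heading,
    shared_direction_min_mean_distance,
    simulate_route,
    solve_initial_direction,
)

DEP_DATE = date(2005, 9, 1)


def test_geographic_loxodrome_headings_constant(field_cfg):
    spec = RouteSpec("geographic_loxodrome", STUDY_SITE, DEP_DATE, 113.0)
    route = simulate_route(spec, field_cfg)
    assert np.allclose(route.headings, 113.0)
    assert not route.terminated_early


def test_rhumb_crosses_meridians_at_constant_angle(field_cfg):
    """Recomputed bearing between consecutive 10 km steps never deviates
    more than 0.2 deg from the constant course."""
    spec = RouteSpec("geographic_loxodrome", STUDY_SITE, DEP_DATE, 113.0)
    route = simulate_route(spec, field_cfg)
    bearings = [
        gc_bearing((route.lats[i], route.lons[i]), (route.lats[i + 1], route.lons[i + 1]))
        for i in range(0, len(route.lats) - 1, 7)
    ]
    assert np.max(np.abs(np.asarray(bearings) - 113.0)) < 0.2


def test_step_spacing_matches_step_length(field_cfg):
    spec = RouteSpec("magnetic_loxodrome", STUDY_SITE, DEP_DATE, 113.0,
                     total_length_km=500.0)
    route = simulate_route(spec, field_cfg)
    for i in range(0, len(route.lats) - 1, 11):
        d = gc_distance_km((route.lats[i], route.lons[i]),
                           (route.lats[i + 1], route.lons[i + 1]))
        assert d == pytest.approx(10.0, rel=1e-3)


def test_magnetic_equals_geographic_in_dipole_field(dipole_cfg):
    """With zero declination everywhere the two loxodromes coincide to
    better than 1 km over 5000 km."""
    geo = simulate_route(RouteSpec("geographic_loxodrome", STUDY_SITE, DEP_DATE, 235.0),
                         dipole_cfg)
    mag = simulate_route(RouteSpec("magnetic_loxodrome", STUDY_SITE, DEP_DATE, 235.0),
                         dipole_cfg)
    sep = gc_distance_km((geo.lats, geo.lons), (mag.lats, mag.lons))
    assert np.max(sep) < 1.0


def test_magnetoclinic_heading_along_meridian_when_gamma_matches():
    local = FieldVector(declination=12.0, inclination=65.0,
                        horizontal_intensity=20000.0, total_intensity=45000.0)
    h = magnetoclinic_heading(MagnetoclinicState(gamma_prime=65.0, side=1), local)
    assert h == pytest.approx(12.0)


def test_magnetoclinic_heading_fails_when_dip_exceeds_apparent():
    local = FieldVector(declination=0.0, inclination=80.0,
                        horizontal_intensity=1.0, total_intensity=1.0)
    assert magnetoclinic_heading(MagnetoclinicState(gamma_prime=70.0, side=1), local) is None


@pytest.mark.parametrize("spec_kwargs", [
    dict(initial_direction=113.0),
    dict(branch="SE", switch_longitude=-158.0, onward_course_at_switch=150.0),
    dict(branch="NW", switch_longitude=175.0, onward_course_at_switch=225.0),
])
def test_magnetoclinic_apparent_inclination_conserved(field_cfg, spec_kwargs):
    """Along any magnetoclinic route, the apparent inclination recomputed
    from the local field and flown heading stays within 0.05 deg of the
    fixed gamma'."""
    spec = RouteSpec("magnetoclinic", STUDY_SITE, DEP_DATE, **spec_kwargs)
    route = simulate_route(spec, field_cfg)
    gp = route.apparent_inclination[~np.isnan(route.apparent_inclination)]
    assert gp.size > 100
    assert np.max(gp) - np.min(gp) < 0.05


def test_magnetoclinic_failure_terminates_early(dipole_cfg):
    """Flying poleward, the dip soon exceeds the fixed apparent inclination
    and the route stops with a reason instead of raising."""
    spec = RouteSpec("magnetoclinic", GeoPosition(10.0, 0.0), DEP_DATE,
                     initial_direction=0.0)
    route = simulate_route(spec, dipole_cfg)
    assert route.terminated_early
    assert "no solution" in route.termination_reason


def test_step_halving_moves_terminal_less_than_5km(field_cfg):
    a = simulate_route(RouteSpec("magnetic_loxodrome", STUDY_SITE, DEP_DATE, 250.0,
                                 step_length_km=10.0), field_cfg)
    b = simulate_route(RouteSpec("magnetic_loxodrome", STUDY_SITE, DEP_DATE, 250.0,
                                 step_length_km=5.0), field_cfg)
    assert gc_distance_km(a.terminal, b.terminal) < 5.0


def test_sun_compass_approximates_orthodrome(field_cfg):
    """Started along the great-circle bearing to the southern-Japan goal,
    the sun-compass route ends within 5% of the route length from the goal
    — an order of magnitude closer than the constant-course route flown
    from the same initial bearing (the mechanism approximates the
    orthodrome, which the rhumb does not)."""
    length = float(gc_distance_km(STUDY_SITE, SOUTH_JAPAN))
    bearing = gc_bearing(STUDY_SITE, SOUTH_JAPAN)
    sun = simulate_route(RouteSpec("sun_compass", STUDY_SITE, DEP_DATE, bearing,
                                   total_length_km=length), field_cfg)
    rhumb = simulate_route(RouteSpec("geographic_loxodrome", STUDY_SITE, DEP_DATE,
                                     bearing, total_length_km=length), field_cfg)
    miss_sun = gc_distance_km(sun.terminal, SOUTH_JAPAN)
    miss_rhumb = gc_distance_km(rhumb.terminal, SOUTH_JAPAN)
    assert miss_sun < 0.05 * length
    assert miss_sun < 0.1 * miss_rhumb


def test_solver_matches_closed_form_rhumb_for_reachable_goal(field_cfg):
    """For a goal placed 4500 km down the 235-deg rhumb, the shooting
    solver recovers the closed-form course within 0.5 deg."""
    goal = STUDY_SITE
    for _ in range(450):
        goal = advance(goal, 235.0, 10.0)
    solved = solve_initial_direction("geographic_loxodrome", STUDY_SITE, DEP_DATE,
                                     goal, field_cfg, total_length_km=4500.0)
    assert abs(solved - rhumb_course(STUDY_SITE, goal)) < 0.5


def test_shared_direction_brute_force_band(field_cfg):
    """Goal on the 235-deg rhumb at 4500 km: the shared-direction grid
    argmin lands within +/- 15 deg of 235."""
    goal = STUDY_SITE
    for _ in range(450):
        goal = advance(goal, 235.0, 10.0)
    d = shared_direction_min_mean_distance(STUDY_SITE, DEP_DATE, goal, field_cfg,
                                           step_length_km=20.0)
    assert abs((d - 235.0 + 180.0) % 360.0 - 180.0) <= 15.0


def test_shared_direction_deterministic_tiebreak(field_cfg):
    """Goal at the departure point: every direction ties at route-length
    scale; the scan still returns the same (lowest) argmin on repeat."""
    d1 = shared_direction_min_mean_distance(STUDY_SITE, DEP_DATE, STUDY_SITE,
                                            field_cfg, total_length_km=400.0,
                                            step_length_km=50.0)
    d2 = shared_direction_min_mean_distance(STUDY_SITE, DEP_DATE, STUDY_SITE,
                                            field_cfg, total_length_km=400.0,
                                            step_length_km=50.0)
    assert d1 == d2
    assert 0.0 <= d1 < 360.0


def test_spec_validation():
    with pytest.raises(ValueError):
        RouteSpec("warp_drive", STUDY_SITE, DEP_DATE, 10.0)
    with pytest.raises(ValueError):
        RouteSpec("sun_compass", STUDY_SITE, DEP_DATE, None)
    with pytest.raises(ValueError):
        RouteSpec("magnetoclinic", STUDY_SITE, DEP_DATE)  # no direction, no branch
    with pytest.raises(ValueError):
        RouteSpec("magnetic_loxodrome", STUDY_SITE, DEP_DATE, 10.0, step_length_km=500.0)
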