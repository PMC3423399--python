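"""MFPT quadrature, boundary selection, rate series and Kramers check."""

import numpy as np
import pandas as pd
import pytest

from flipkin import (
    FptProblem,
    FreeEnergyProfile,
    ProfileSpec,
    kramers_estimate,
    make_pmf,
    mfpt,
    pressure_series_mfpt,
    select_boundaries,
)


def test_flat_profile_closed_form(flat_profile):
    """Reflecting a, absorbing b, start at a: tau = (b-a)^2 / (2D)."""
    prob = FptProblem(profile=flat_profile, diffusion_constant=1.0,
                      start=-50.0, reflecting=-50.0, absorbing=70.0)
    res = mfpt(prob)
    L = 120.0
    assert abs(2.0 * res.mfpt / L**2 - 1.0) < 1e-3
    assert res.effective_rate == pytest.approx(1.0 / res.mfpt)


def test_flat_profile_interior_start(flat_profile):
    """tau(x0) = (b^2 - x0^2)/(2D) + a(x0 - b)/D for reflecting a=0 is the
    textbook parabola; check an interior start against it."""
    prob = FptProblem(profile=flat_profile, diffusion_constant=1.0,
                      start=30.0, reflecting=0.0, absorbing=90.0)
    res = mfpt(prob)
    expect = (90.0**2 - 30.0**2) / 2.0
    assert res.mfpt == pytest.approx(expect, rel=1e-3)


def test_start_at_absorbing_boundary(flat_profile):
    prob = FptProblem(profile=flat_profile, diffusion_constant=1.0,
                      start=50.0, reflecting=-50.0, absorbing=50.0)
    res = mfpt(prob)
    assert res.mfpt == 0.0
    assert res.effective_rate == np.inf


def test_tau_scales_inversely_with_diffusion(double_well):
    taus = []
    for D in (0.5, 1.0, 2.0):
        prob = FptProblem(profile=double_well, diffusion_constant=D,
                          start=0.0, reflecting=-40.0, absorbing=120.0)
        taus.append(mfpt(prob).mfpt)
    assert taus[0] / taus[1] == pytest.approx(2.0, rel=1e-6)
    assert taus[1] / taus[2] == pytest.approx(2.0, rel=1e-6)


def test_mirrored_orientation_on_symmetric_profile():
    spec = ProfileSpec(minima=((0.0, 3.0),), barrier_height=5.0,
                       barrier_position=90.0)
    prof = make_pmf(spec, 1.0)
    mirror = ProfileSpec(minima=((0.0, 3.0),), barrier_height=5.0,
                         barrier_position=-90.0)
    mprof = make_pmf(mirror, 1.0)
    fwd = mfpt(FptProblem(profile=prof, diffusion_constant=1.0, start=0.0,
                          reflecting=-40.0, absorbing=120.0))
    bwd = mfpt(FptProblem(profile=mprof, diffusion_constant=1.0, start=0.0,
                          reflecting=40.0, absorbing=-120.0))
    assert bwd.mfpt == pytest.approx(fwd.mfpt, rel=1e-9)


def test_high_barrier_no_overflow():
    spec = ProfileSpec(minima=((0.0, 3.0),), barrier_height=60.0)
    prof = make_pmf(spec, 1.0)
    prob = FptProblem(profile=prof, diffusion_constant=1.0, start=0.0,
                      reflecting=-40.0, absorbing=120.0)
    res = mfpt(prob)
    assert np.isfinite(res.mfpt)
    assert res.mfpt > 1e20


def test_problem_validation(flat_profile):
    with pytest.raises(ValueError, match="between the boundaries"):
        FptProblem(profile=flat_profile, diffusion_constant=1.0, start=100.0,
                   reflecting=-50.0, absorbing=50.0)
    with pytest.raises(ValueError, match="distinct"):
        FptProblem(profile=flat_profile, diffusion_constant=1.0, start=0.0,
                   reflecting=0.0, absorbing=0.0)
    with pytest.raises(ValueError, match="positive"):
        FptProblem(profile=flat_profile, diffusion_constant=0.0, start=0.0,
                   reflecting=-50.0, absorbing=50.0)


def test_masked_bins_inside_interval_raise():
    grid = -180.0 + 1.0 * np.arange(360)
    mask = np.abs(grid) > 10.0
    prof = FreeEnergyProfile(grid=grid, values=np.zeros(360), mask=mask)
    prob = FptProblem(profile=prof, diffusion_constant=1.0, start=-40.0,
                      reflecting=-60.0, absorbing=60.0)
    with pytest.raises(ValueError, match="masked"):
        mfpt(prob)


def test_select_boundaries_double_well(double_well):
    prob = select_boundaries(double_well, flip_target=120.0,
                             reflect_offset=3.0)
    assert prob.start == pytest.approx(0.0, abs=1.0)
    assert prob.absorbing == 120.0
    # the wall is left of the start and F there is >= F(x0) + 3 kT, unless
    # the scan ran off the domain edge
    assert prob.reflecting < prob.start
    if prob.reflecting > double_well.grid.min():
        wall_F = float(double_well.energy(prob.reflecting))
        assert wall_F >= 3.0 - 1e-9


def test_select_boundaries_rejects_target_at_minimum(double_well):
    with pytest.raises(ValueError, match="coincides"):
        select_boundaries(double_well, flip_target=0.0)


def test_select_boundaries_mirrored_target(double_well):
    """A target left of the deepest minimum flips the scan direction: the
    reflecting wall must land on the right of the start."""
    prob = select_boundaries(double_well, flip_target=-150.0,
                             reflect_offset=3.0)
    assert prob.start == pytest.approx(0.0, abs=1.0)
    assert prob.absorbing == -150.0
    assert prob.reflecting > prob.start


def test_select_boundaries_tie_warning():
    spec = ProfileSpec(minima=((-90.0, 2.0), (90.0, 2.0)), barrier_height=4.0,
                       barrier_position=0.0, well_width=15.0,
                       barrier_width=15.0)
    prof = make_pmf(spec, 1.0)
    with pytest.warns(UserWarning, match="equal-depth"):
        prob = select_boundaries(prof, flip_target=0.0, reflect_offset=1.0)
    assert prob.start == pytest.approx(-90.0, abs=1.0)


def test_pressure_series_monotonic():
    profiles = []
    for p in (0.0, 0.5, 1.0):
        spec = ProfileSpec(minima=((0.0, 3.0), (-100.0, 1.5)),
                           barrier_height=5.0, pressure_knob=p)
        profiles.append((p, make_pmf(spec, 1.0)))
    df = pressure_series_mfpt(profiles)
    assert isinstance(df, pd.DataFrame)
    assert list(df["label"]) == [0.0, 0.5, 1.0]
    assert np.all(np.diff(df["tau"]) > 0)
    assert np.allclose(df["k_eff"], 1.0 / df["tau"])


def test_kramers_agrees_with_quadrature_at_high_barrier():
    spec = ProfileSpec(minima=((0.0, 3.0),), barrier_height=10.0)
    prof = make_pmf(spec, 1.0)
    prob = FptProblem(profile=prof, diffusion_constant=1.0, start=0.0,
                      reflecting=-60.0, absorbing=120.0)
    res = mfpt(prob)
    est = kramers_estimate(prof, 1.0, 0.0, 70.0)
    assert not est.low_barrier
    assert est.rate == pytest.approx(res.effective_rate, rel=0.35)


def test_kramers_flags_low_barrier_and_bad_curvature(single_well):
    est = kramers_estimate(
        make_pmf(ProfileSpec(minima=((0.0, 1.0),), barrier_height=1.5)),
        1.0, 0.0, 70.0)
    assert est.low_barrier
    with pytest.raises(ValueError, match="curvature"):
        kramers_estimate(single_well, 1.0, 70.0, 0.0)  # swapped locations
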