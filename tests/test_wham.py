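"""WHAM reconstruction, binning and profile feature extraction."""

import numpy as np
import pytest

from flipkin import (
    FreeEnergyProfile,
    ProfileSpec,
    UmbrellaWindow,
    bin_windows,
    make_pmf,
    pmf_from_probability,
    profile_features,
    wham_solve,
)


def _boltzmann_windows(profile, centers, k, n_per_window, seed):
    """Draw exact Boltzmann samples from each biased distribution by
    multinomial sampling on a fine grid (no dynamics, no autocorrelation)."""
    rng = np.random.default_rng(seed)
    fine = np.linspace(-180.0, 180.0, 3601)[:-1] + 0.05
    F = profile.energy(fine)
    wins = []
    for i, c in enumerate(centers):
        d = (fine - c + 180.0) % 360.0 - 180.0
        w = F + 0.5 * k * d * d
        p = np.exp(-(w - w.min()))
        p /= p.sum()
        counts = rng.multinomial(n_per_window, p)
        samples = np.repeat(fine, counts)
        wins.append(UmbrellaWindow(f"w{i}", float(c), k, samples))
    return wins


def test_wham_recovers_boltzmann_sampled_profile(double_well):
    centers = np.linspace(-180.0, 180.0, 19)
    wins = _boltzmann_windows(double_well, centers, 0.01, 20_000, seed=12)
    sol = wham_solve(bin_windows(wins, 2.0), wins, tol=1e-10)
    assert sol.converged
    pmf = pmf_from_probability(sol)
    truth = double_well.energy(pmf.grid)
    truth = truth - truth.min()
    sel = truth < 8.0
    rmse = np.sqrt(np.mean((pmf.values[sel] - truth[sel]) ** 2))
    assert rmse < 0.1


def test_wham_unbiased_window_degeneracy():
    rng = np.random.default_rng(2)
    w = UmbrellaWindow("u", 0.0, 0.0, rng.uniform(-180, 180, 5000))
    h = bin_windows([w], 5.0)
    sol = wham_solve(h, [w], tol=1e-12)
    dens = h.counts[0] / (h.totals[0] * h.bin_width)
    occ = dens > 0
    assert np.allclose(sol.probability[occ], dens[occ], rtol=0, atol=1e-12)
    assert sol.window_free_energies[0] == 0.0


def test_wham_gauge_and_normalisation(double_well):
    wins = _boltzmann_windows(double_well, np.linspace(-180, 180, 19),
                              0.01, 2000, seed=3)
    sol = wham_solve(bin_windows(wins, 2.0), wins)
    assert sol.window_free_energies[0] == 0.0
    assert np.sum(sol.probability * sol.bin_width) == pytest.approx(1.0)


def test_periodic_bias_evaluation_matters():
    """A window centered at 180 deg restrains samples near -180 deg only if
    the bias acts on the minimum-image difference."""
    rng = np.random.default_rng(0)
    samples = -180.0 + np.abs(rng.normal(0.0, 5.0, 4000)) % 10.0
    w = UmbrellaWindow("edge", 179.0, 0.05, samples)
    per = w.bias_energy(-179.0, periodic=True)
    lin = w.bias_energy(-179.0, periodic=False)
    assert per == pytest.approx(0.05 * 0.5 * 4.0)
    assert lin > 1000 * per


def test_bin_windows_wraps_and_validates():
    w = UmbrellaWindow("a", 0.0, 0.01, np.array([179.999, -180.0, 0.0]))
    h = bin_windows([w], 2.0)
    assert h.counts.sum() == 3
    assert h.bin_centers[0] == -179.0
    with pytest.raises(ValueError, match="divide"):
        bin_windows([w], 7.0)
    with pytest.raises(ValueError, match="no umbrella windows"):
        bin_windows([], 2.0)
    empty = UmbrellaWindow("e", 0.0, 0.01, np.array([]))
    with pytest.raises(ValueError, match="zero samples"):
        bin_windows([empty], 2.0)


def test_wham_window_histogram_mismatch():
    w = UmbrellaWindow("a", 0.0, 0.01, np.zeros(10))
    h = bin_windows([w], 2.0)
    with pytest.raises(ValueError, match="does not match"):
        wham_solve(h, [w, w])


def test_wham_gap_warning():
    """A single empty bin flanked by occupied bins signals missing overlap."""
    w1 = UmbrellaWindow("a", -3.0, 0.05, np.full(100, -3.0))
    w2 = UmbrellaWindow("b", 1.0, 0.05, np.full(100, 1.0))
    h = bin_windows([w1, w2], 2.0)
    with pytest.warns(UserWarning, match="empty bin"):
        wham_solve(h, [w1, w2], max_iter=50)


def test_wham_nonconvergence_flag():
    wins = _boltzmann_windows(
        make_pmf(ProfileSpec(minima=((0.0, 2.0),), barrier_height=4.0)),
        np.linspace(-180, 180, 19), 0.01, 500, seed=1)
    sol = wham_solve(bin_windows(wins, 2.0), wins, tol=1e-14, max_iter=3)
    assert not sol.converged
    assert sol.iterations == 3


def test_pmf_from_probability_masks_empty_bins():
    w1 = UmbrellaWindow("a", -100.0, 0.05, np.full(50, -100.0))
    w2 = UmbrellaWindow("b", 100.0, 0.05, np.full(50, 100.0))
    h = bin_windows([w1, w2], 2.0)
    sol = wham_solve(h, [w1, w2], max_iter=200)
    pmf = pmf_from_probability(sol)
    assert pmf.defined.sum() == 2
    assert pmf.values[pmf.defined].min() == 0.0


def test_profile_features_double_well(double_well):
    feats = profile_features(double_well)
    assert len(feats.minima) == 2
    positions = sorted(p for p, _ in feats.minima)
    assert positions[0] == pytest.approx(-100.0, abs=1.0)
    assert positions[1] == pytest.approx(0.0, abs=1.0)
    assert len(feats.barriers) == 2
    # looping-out barrier (rightward arc from 0 deg) is ~5 kT above the
    # primary minimum but reported relative to the shallower minimum
    heights = {(round(a), round(b)): h for a, b, h in feats.barriers}
    assert heights[(0, -100)] == pytest.approx(5.0 - 1.5, abs=0.1)


def test_profile_features_single_minimum(single_well):
    feats = profile_features(single_well)
    assert len(feats.minima) == 1
    assert feats.minima[0][0] == pytest.approx(0.0, abs=1.0)
    a, b, h = feats.barriers[0]
    assert a == b
    assert h == pytest.approx(single_well.values.max(), abs=1e-9)


def test_profile_features_prominence_filter():
    grid = -180.0 + 1.0 * np.arange(360)
    v = 2.0 - 2.0 * np.cos(np.radians(grid))          # single broad well at 0
    v += 0.05 * np.cos(np.radians(7 * grid))          # shallow ripples
    prof = FreeEnergyProfile(grid=grid, values=v - v.min())
    bare = profile_features(prof)
    assert len(bare.minima) > 1
    filtered = profile_features(prof, min_prominence=0.3)
    assert len(filtered.minima) == 1
    # ripples shift the surviving minimum slightly off the well center
    assert filtered.minima[0][0] == pytest.approx(0.0, abs=10.0)


def test_profile_features_masked_segment():
    grid = -180.0 + 1.0 * np.arange(360)
    v = (grid / 60.0) ** 2
    mask = (grid > -90) & (grid < 90)
    prof = FreeEnergyProfile(grid=grid, values=v, mask=mask)
    feats = profile_features(prof)
    assert len(feats.minima) == 1
    assert feats.minima[0][0] == pytest.approx(0.0, abs=1.0)


def test_profile_features_needs_three_bins():
    prof = FreeEnergyProfile(grid=np.array([0.0, 1.0, 2.0]),
                             values=np.zeros(3),
                             mask=np.array([True, True, False]))
    with pytest.raises(ValueError, match="at least 3"):
        profile_features(prof)
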