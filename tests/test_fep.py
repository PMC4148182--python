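"""FEP increments and umbrella profiles against analytic references."""

import numpy as np
import pytest

import evbcold as ec
from evbcold.fep import _barrier_from_arrays
from evbcold.reference import exact_free_energy_change, exact_gap_profile


def _profile_from(values, mask=None):
    values = np.asarray(values, dtype=float)
    return ec.FreeEnergyProfile(
        bin_centers=np.arange(values.size, dtype=float),
        free_energy=values, counts=np.full(values.size, 100),
        mask=np.zeros(values.size, bool) if mask is None else np.asarray(mask),
        temperature=300.0)


def _edges_of(profile):
    w = profile.bin_centers[1] - profile.bin_centers[0]
    return np.r_[profile.bin_centers - w / 2, profile.bin_centers[-1] + w / 2]


# ------------------------------------------------------------- increments

def test_constant_offset_recovered_exactly():
    """Zwanzig on potentials differing by a constant returns that
    constant whatever the samples."""
    s1 = ec.DiabaticState([0.0], [8.0])
    s2 = ec.DiabaticState([0.0], [8.0], offset=2.75)
    sys_ = ec.EVBSystem(s1, s2, coupling=0.0)
    wins = ec.run_ladder(sys_, [0.0, 0.5, 1.0], seed=1, n_prod=300)
    incs = ec.fep_increments(wins)
    assert np.allclose(incs, 2.75 / 2, atol=1e-10)
    assert ec.cumulative_free_energies(wins)[-1] == pytest.approx(2.75)


def test_identical_potentials_give_zero_increment():
    s = ec.DiabaticState([0.4], [6.0])
    sys_ = ec.EVBSystem(s, s, coupling=0.0)
    wins = ec.run_ladder(sys_, [0.0, 0.5, 1.0], seed=1, n_prod=300)
    assert np.allclose(ec.fep_increments(wins), 0.0, atol=1e-12)


def test_reversing_window_order_negates_increments(ladder_300):
    fwd = ec.fep_increments(ladder_300)
    bwd = ec.fep_increments(ladder_300[::-1])
    np.testing.assert_allclose(fwd, -bwd[::-1], atol=1e-12)


def test_cumulative_fep_matches_partition_function_quadrature():
    """Harmonic diabats with unequal stiffness: dG(0->1) has the closed
    form (RT/2) ln(k2/k1) + offset."""
    s1 = ec.DiabaticState([0.0], [4.0])
    s2 = ec.DiabaticState([1.0], [8.0], offset=1.0)
    sys_ = ec.EVBSystem(s1, s2, coupling=0.0)
    wins = ec.run_ladder(sys_, np.linspace(0, 1, 21), temperature=300.0,
                         seed=5, n_prod=12000)
    dg = ec.cumulative_free_energies(wins)[-1]
    assert dg == pytest.approx(exact_free_energy_change(sys_, 300.0), abs=0.1)


def test_fewer_than_two_windows_rejected(symmetric_toy):
    w = ec.simulate_window(symmetric_toy, 0.0, 300.0, 10, 50, seed=1)
    with pytest.raises(ec.ProfileError):
        ec.fep_increments([w])


# ---------------------------------------------------------------- profile

def test_profile_symmetric_system_is_symmetric(ladder_300):
    prof = ec.umbrella_profile(ladder_300, n_bins=40)
    ok = ~prof.mask
    f, c = prof.free_energy[ok], prof.bin_centers[ok]
    # compare F(g) with F(-g) via interpolation on the overlapping range
    lo, hi = max(c.min(), -c.max()), min(c.max(), -c.min())
    g = np.linspace(lo, hi, 15)
    diff = np.interp(g, c, f) - np.interp(-g, c[::-1] * -1, f[::-1])
    assert np.abs(diff).max() < 0.35


def test_profile_matches_quadrature_oracle(ladder_300, symmetric_toy):
    prof = ec.umbrella_profile(ladder_300, n_bins=40)
    oracle = exact_gap_profile(symmetric_toy, 300.0, _edges_of(prof))
    ok = ~prof.mask & ~oracle.mask
    dev = (prof.free_energy[ok] - prof.free_energy[ok].min()) \
        - (oracle.free_energy[ok] - oracle.free_energy[ok].min())
    assert np.abs(dev).max() < 0.3
    assert ec.extract_barrier(prof) == pytest.approx(oracle.barrier, abs=0.2)


def test_profile_stable_under_bin_refinement(ladder_300):
    coarse = ec.umbrella_profile(ladder_300, n_bins=30, min_count=160)
    fine = ec.umbrella_profile(ladder_300, n_bins=60, min_count=80)
    c_ok, f_ok = ~coarse.mask, ~fine.mask
    lo = coarse.bin_centers[c_ok][0]
    hi = coarse.bin_centers[c_ok][-1]
    inside = f_ok & (fine.bin_centers >= lo) & (fine.bin_centers <= hi)
    interp = np.interp(fine.bin_centers[inside],
                       coarse.bin_centers[c_ok], coarse.free_energy[c_ok])
    assert np.abs(fine.free_energy[inside] - interp).max() < 0.35


def test_barrier_decreases_with_coupling():
    """Quadrature oracle across an H12 grid: stronger mixing lowers the
    adiabatic barrier monotonically."""
    edges = np.linspace(-60, 60, 121)
    barriers = []
    for h12 in (0.0, 0.5, 1.0, 2.0, 4.0):
        prof = exact_gap_profile(ec.make_toy_system(32.0, 0.0, h12),
                                 300.0, edges)
        barriers.append(prof.barrier)
    assert np.all(np.diff(barriers) < 0)


def test_low_temperature_profile_approaches_potential_barrier():
    """As T -> 0 the free-energy barrier tends to the potential-energy
    barrier of the 1D surface (entropy freeze-out)."""
    from evbcold.reference import potential_energy_barrier
    sys_ = ec.make_toy_system(32.0, 0.0, 2.0)
    edges = np.linspace(-40, 40, 161)
    b_cold = exact_gap_profile(sys_, 30.0, edges).barrier
    assert b_cold == pytest.approx(potential_energy_barrier(sys_), abs=0.15)


# ---------------------------------------------------------------- barrier

def test_barrier_hand_example():
    assert ec.extract_barrier(_profile_from([3, 1, 4, 0])) == pytest.approx(3.0)


@pytest.mark.parametrize("values", [[2, 2, 2, 2], [4, 3, 2, 1], [1, 2, 3, 4]])
def test_flat_or_monotone_profile_has_no_barrier(values):
    with pytest.raises(ec.ProfileError, match="no barrier|unresolved|too few"):
        ec.extract_barrier(_profile_from(values))


def test_fully_masked_profile_is_unresolved():
    prof = _profile_from([1, 2, 1], mask=[True, True, True])
    with pytest.raises(ec.ProfileError, match="unresolved"):
        ec.extract_barrier(prof)


def test_barrier_agrees_with_exhaustive_scan():
    """Independent brute-force oracle: enumerate every (minimum, interior
    maximum) pairing per the stated convention."""
    rng = np.random.default_rng(0)

    def brute(v):
        v = np.asarray(v, float)
        n = v.size
        mins = [i for i in range(n)
                if ((i == 0 or v[i] < v[i - 1]) and (i == n - 1 or v[i] <= v[i + 1]))
                or ((i == 0 or v[i] <= v[i - 1]) and (i == n - 1 or v[i] < v[i + 1]))]
        if len(mins) < 2:
            return None
        inner = list(range(mins[0] + 1, mins[-1]))
        if not inner:
            return None
        ts = max(inner, key=lambda i: v[i])
        rmin = min(range(ts), key=lambda i: v[i])
        return v[ts] - v[rmin] if v[ts] > v[rmin] else None

    checked_barriers = 0
    for _ in range(200):
        v = np.round(rng.uniform(0, 5, rng.integers(4, 12)), 1)
        expected = brute(v)
        if expected is None:
            with pytest.raises(ec.ProfileError):
                ec.extract_barrier(_profile_from(v))
        else:
            assert ec.extract_barrier(_profile_from(v)) == pytest.approx(expected)
            checked_barriers += 1
    assert checked_barriers > 50


def test_masked_bins_excluded_from_barrier_search():
    values = [3.0, 1.0, 9.0, 4.0, 0.0]
    mask = [False, False, True, False, False]
    i_min, v_min, i_ts, v_ts = _barrier_from_arrays(values, np.asarray(mask))
    assert (v_ts - v_min) == pytest.approx(3.0)
    assert i_ts == 3  # the masked 9.0 bin must be skipped
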