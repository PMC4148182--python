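"""Closed-form and quadrature references for toy EVB systems.

These routines never touch the sampler or the FEP estimators: they
evaluate the same observables analytically (Gaussian integrals) or by
dense quadrature, and exist to validate the stochastic pipeline on
systems small enough to integrate exactly.

All of them exploit that the toy diabats are harmonic.  Those marked
"equal-k" additionally require every coordinate to carry the same force
constant in both states, which makes the energy gap a linear function
of the coordinates and hence exactly Gaussian in any mapping ensemble.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad

from .core import R_GAS, EVBError, EVBSystem, ground_state_energy
from .fep import FreeEnergyProfile, ProfileError, _barrier_from_arrays


def _equal_k_params(system: EVBSystem):
    k1, c1, o1 = system._state_params(1)
    k2, c2, o2 = system._state_params(2)
    if not np.allclose(k1, k2):
        raise EVBError("reference requires equal force constants in both states")
    return k1, c1, o1, c2, o2


def exact_free_energy_change(system: EVBSystem, temperature: float) -> float:
    """-RT ln(Z2/Z1) for the harmonic diabats (any force constants)."""
    k1, _, o1 = system._state_params(1)
    k2, _, o2 = system._state_params(2)
    rt = R_GAS * temperature
    return float(o2 - o1 + 0.5 * rt * np.sum(np.log(k2 / k1)))


def reorganization_energy(system: EVBSystem) -> float:
    """Total reorganization energy 0.5 * sum k_j * (dc_j)^2 (equal-k)."""
    k, c1, _, c2, _ = _equal_k_params(system)
    return float(0.5 * np.sum(k * (c2 - c1) ** 2))


def gap_moments(system: EVBSystem, lam: float, temperature: float):
    """Mean and variance of the (linear, hence Gaussian) gap in the
    ``lam`` mapping ensemble of an equal-k system."""
    k, c1, o1, c2, o2 = _equal_k_params(system)
    mu = system.mapping_minimum(lam)
    e1 = 0.5 * np.sum(k * (mu - c1) ** 2) + o1
    e2 = 0.5 * np.sum(k * (mu - c2) ** 2) + o2
    var = float(np.sum((k * (c2 - c1)) ** 2 * (R_GAS * temperature / k)))
    return float(e1 - e2), var


def exact_gap_profile(system: EVBSystem, temperature: float,
                      bin_edges: np.ndarray) -> FreeEnergyProfile:
    """Exact binned free energy along the gap for an equal-k system.

    In the lam = 1/2 ensemble the gap g is Gaussian and
    ``exp(-eg/RT) = exp(-E_half/RT) * exp(s(g)/(2RT))`` with
    ``s = sqrt(g^2 + 4 H12^2)``, so the ground-state bin probability is
    a one-dimensional quadrature over the Gaussian gap density.
    """
    rt = R_GAS * temperature
    m, v = gap_moments(system, 0.5, temperature)
    h12 = system.coupling
    edges = np.asarray(bin_edges, dtype=float)
    smax = float(np.hypot(max(abs(edges[0] - m), abs(edges[-1] - m)) + m, 2 * h12))

    def integrand(g):
        # exp factors combined in log space to avoid overflow
        logphi = -0.5 * (g - m) ** 2 / v
        return np.exp(logphi + (np.hypot(g, 2 * h12) - smax) / (2 * rt))

    probs = np.empty(edges.size - 1)
    for i in range(probs.size):
        probs[i], _ = quad(integrand, edges[i], edges[i + 1], limit=200)
    mask = probs <= 0
    free = np.full(probs.size, np.nan)
    free[~mask] = -rt * np.log(probs[~mask])
    centers = 0.5 * (edges[:-1] + edges[1:])
    profile = FreeEnergyProfile(bin_centers=centers, free_energy=free,
                                counts=np.where(mask, 0, np.iinfo(np.int64).max),
                                mask=mask, temperature=temperature)
    try:
        i_min, v_min, i_ts, v_ts = _barrier_from_arrays(free, mask)
        profile.free_energy = free - v_min
        profile.reactant_min = (int(i_min), 0.0)
        profile.ts_max = (int(i_ts), float(v_ts - v_min))
        profile.barrier = float(v_ts - v_min)
    except ProfileError:
        profile.free_energy = free - np.nanmin(free)
    return profile


def potential_energy_scan(system: EVBSystem, n_grid: int = 20001,
                          padding: float = 1.5):
    """Dense scan of the 1D adiabatic ground-state potential.

    Only defined for systems with a single degree of freedom.  Returns
    (x, eg) arrays covering both wells with ``padding`` times the
    well separation on each side.
    """
    if system.n_dof != 1:
        raise EVBError("potential scan requires a strictly 1D system")
    _, c1, _ = system._state_params(1)
    _, c2, _ = system._state_params(2)
    lo, hi = min(c1[0], c2[0]), max(c1[0], c2[0])
    span = max(hi - lo, 1.0)
    x = np.linspace(lo - padding * span, hi + padding * span, n_grid)
    e1, e2 = system.diabatic_energies(x[:, None])
    eg = ground_state_energy(e1, e2, system.coupling)
    return x, np.asarray(eg)


def potential_energy_barrier(system: EVBSystem, **kw) -> float:
    """Adiabatic barrier of a 1D system from a dense grid scan:
    highest interior maximum between the outer minima, measured from
    the reactant-side minimum."""
    _, eg = potential_energy_scan(system, **kw)
    _, v_min, _, v_ts = _barrier_from_arrays(eg)
    return float(v_ts - v_min)


def exact_mean_ground_energy(system: EVBSystem, lam: float,
                             temperature: float) -> float:
    """<eg> in the ``lam`` mapping ensemble of an equal-k system.

    <(e1+e2)/2> is a Gaussian quadratic-form moment; <s(g)/2> is a 1D
    quadrature over the Gaussian gap.
    """
    k, c1, o1, c2, o2 = _equal_k_params(system)
    rt = R_GAS * temperature
    mu = system.mapping_minimum(lam)
    var = rt / k
    mean_e1 = 0.5 * np.sum(k * ((mu - c1) ** 2 + var)) + o1
    mean_e2 = 0.5 * np.sum(k * ((mu - c2) ** 2 + var)) + o2
    m, v = gap_moments(system, lam, temperature)
    sd = np.sqrt(v)
    h12 = system.coupling

    def integrand(g):
        return np.hypot(g, 2 * h12) * np.exp(-0.5 * (g - m) ** 2 / v) \
            / np.sqrt(2 * np.pi * v)

    mean_s, _ = quad(integrand, m - 12 * sd, m + 12 * sd, limit=200)
    return float(0.5 * (mean_e1 + mean_e2) - 0.5 * mean_s)
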