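"""Seeded generators for every input the analysis pipeline consumes.

The generators emulate the statistical structure the method assumes:
replicate activation barriers scattered around a dH - T*dS/1000 line on
an eight-temperature 275-310 K grid; tagged per-frame energies with
distinct reactant/transition-state means; and multi-frame trajectories
with a stiff core and a radially softening surface.  Every generator is
a pure function of its arguments and seed.
"""

from __future__ import annotations

from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .arrhenius import DEFAULT_TEMPERATURES
from .core import BathMode, DiabaticState, EVBError, EVBSystem
from .softness import BACKBONE_ATOMS, Trajectory


def make_toy_system(reorg_energy: float, dG0: float = 0.0, h12: float = 0.0,
                    bath: Sequence[tuple[float, float, str]] = ()) -> EVBSystem:
    """One-dimensional Marcus pair with optional tagged bath modes.

    The reactive coordinate carries harmonic diabats with wells at
    +/- 1 A realising reorganization energy ``reorg_energy`` (so
    ``k = reorg_energy / 2``) and a product offset ``dG0``; for the
    bath-free symmetric case the diabatic crossing barrier is
    ``reorg/4`` and the saddle sits ``reorg/4 - h12`` above the
    diabatic well energy (the adiabatic barrier gains a further
    ``h12**2/reorg`` because the coupling depresses the ground-state
    minimum below the diabatic well).  Bath
    entries are ``(force_constant, displacement, tag)`` tuples: each
    mode sits at 0 in state 1 and at ``displacement`` in state 2,
    adding ``0.5 * k * displacement**2`` of its own reorganization.
    """
    if reorg_energy <= 0:
        raise EVBError("reorganization energy must be positive")
    k = reorg_energy / 2.0
    s1 = DiabaticState(well_center=[-1.0], force_constants=[k], offset=0.0)
    s2 = DiabaticState(well_center=[1.0], force_constants=[k], offset=float(dG0))
    modes = tuple(BathMode(force_constant=kb, eq1=0.0, eq2=dx, tag=tag)
                  for kb, dx, tag in bath)
    return EVBSystem(state1=s1, state2=s2, coupling=float(h12), bath=modes)


#: bath presets differing only in the ss force constants: a compliant
#: ("soft", cold-adapted-like) vs rigid ("stiff", warm-adapted-like)
#: surrounding.  Reactive states and coupling are shared.
_BATH_PRESETS = {
    "soft": [(8.0, 0.5, "rs"), (3.0, 0.6, "ss"), (3.0, -0.6, "ss")],
    "stiff": [(8.0, 0.5, "rs"), (24.0, 0.6, "ss"), (24.0, -0.6, "ss")],
}


def toy_preset(kind: str, reorg_energy: float = 20.0, dG0: float = 0.0,
               h12: float = 2.0) -> EVBSystem:
    """'soft' or 'stiff' toy system; the two differ only in the
    ss-tagged bath stiffness."""
    if kind not in _BATH_PRESETS:
        raise EVBError(f"unknown preset {kind!r}; choose from {sorted(_BATH_PRESETS)}")
    return make_toy_system(reorg_energy, dG0, h12, _BATH_PRESETS[kind])


def synth_barriers(dH: float, dS: float, temps: Sequence[float] | None = None,
                   n_reps: int = 100, sigma: float = 0.5,
                   seed: int = 0) -> pd.DataFrame:
    """Replicate barrier table around the line dG(T) = dH - T*dS/1000.

    ``dS`` in e.u.; Gaussian replicate noise of width ``sigma``
    (kcal/mol, default 0.5 to mimic realistic replicate scatter).
    """
    temps = DEFAULT_TEMPERATURES if temps is None else np.asarray(temps, dtype=float)
    if temps.size == 0:
        raise ValueError("temps must be non-empty")
    if n_reps < 1 or sigma < 0:
        raise ValueError("need n_reps >= 1 and sigma >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for t in temps:
        line = dH - t * dS / 1000.0
        noise = rng.normal(0.0, sigma, n_reps) if sigma > 0 else np.zeros(n_reps)
        for rep in range(n_reps):
            rows.append((float(t), rep, line + noise[rep]))
    return pd.DataFrame(rows, columns=["temperature", "replicate", "barrier"])


def synth_energy_frames(means_rs: Mapping[str, float],
                        means_ts: Mapping[str, float], sigma: float,
                        n: int, seed: int = 0):
    """I.i.d. Gaussian tagged energy frames for the RS and TS ensembles."""
    if set(means_rs) != set(means_ts):
        raise ValueError("RS and TS must carry identical tag sets")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    tags = sorted(means_rs)
    rs = pd.DataFrame({t: means_rs[t] + sigma * rng.standard_normal(n)
                       for t in tags})
    ts = pd.DataFrame({t: means_ts[t] + sigma * rng.standard_normal(n)
                       for t in tags})
    return rs, ts


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


#: invented radial fluctuation profiles sigma(r) in Angstrom: both have a
#: stiff core; the "salmon_like" preset softens earlier and further out,
#: the "bovine_like" one stays closer to the threshold.  These shapes are
#: qualitative stand-ins, not fits to any real enzyme.
RADIAL_PRESETS: dict[str, Callable] = {
    "bovine_like": lambda r: 0.18 + 0.45 * _sigmoid((np.asarray(r) - 14.0) / 3.0),
    "salmon_like": lambda r: 0.18 + 0.75 * _sigmoid((np.asarray(r) - 11.0) / 3.0),
}


def step_profile(r_switch: float, sigma_in: float, sigma_out: float) -> Callable:
    """sigma(r) stepping from ``sigma_in`` inside ``r_switch`` to
    ``sigma_out`` outside."""
    return lambda r: np.where(np.asarray(r) < r_switch, sigma_in, sigma_out)


def synth_trajectory(n_residues: int, n_frames: int,
                     radial_sigma="salmon_like",
                     radii: Sequence[float] | None = None,
                     sigma_scatter: float = 0.0,
                     seed: int = 0) -> Trajectory:
    """Backbone trajectory with residue mobility prescribed by radius.

    Residues (4 backbone atoms each) are placed at the given distances
    from the origin (default: evenly spaced 0.5-25 A) in seeded random
    directions.  Every frame displaces each residue rigidly by an
    isotropic Gaussian of width ``sigma(r)`` per axis, so the expected
    residue RMSF is ``sigma * sqrt(3)``.  ``sigma_scatter`` adds
    lognormal residue-to-residue variation around the radial profile.
    """
    if n_residues < 2 or n_frames < 2:
        raise ValueError("need n_residues >= 2 and n_frames >= 2")
    profile = RADIAL_PRESETS[radial_sigma] if isinstance(radial_sigma, str) \
        else radial_sigma
    rng = np.random.default_rng(seed)
    radii = np.linspace(0.5, 25.0, n_residues) if radii is None \
        else np.asarray(radii, dtype=float)
    if radii.size != n_residues or (radii < 0).any():
        raise ValueError("radii must be non-negative, one per residue")

    # random directions on the unit sphere
    vec = rng.standard_normal((n_residues, 3))
    vec /= np.linalg.norm(vec, axis=1, keepdims=True)
    centers = vec * radii[:, None]

    # rigid local backbone geometry around each residue center
    offsets = np.array([[-0.7, 0.4, 0.0],   # N
                        [0.0, 0.0, 0.0],    # CA
                        [0.8, 0.5, 0.2],    # C
                        [1.0, 1.4, 0.6]])   # O
    base = (centers[:, None, :] + offsets[None, :, :]).reshape(-1, 3)

    sigmas = np.asarray(profile(radii), dtype=float)
    if sigma_scatter > 0:
        sigmas = sigmas * np.exp(sigma_scatter * rng.standard_normal(n_residues))
    disp = rng.standard_normal((n_frames, n_residues, 3)) * sigmas[None, :, None]
    coords = base[None] + np.repeat(disp, len(BACKBONE_ATOMS), axis=1)

    atoms = pd.DataFrame({
        "res_id": np.repeat(np.arange(1, n_residues + 1), len(BACKBONE_ATOMS)),
        "res_name": "ALA",
        "atom_name": list(BACKBONE_ATOMS) * n_residues,
        "chain": "A",
        "backbone": True,
    })
    return Trajectory(coords=coords, atoms=atoms)
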