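"""Two-state empirical valence bond (EVB) energetics.

The reactive surface is the lowest eigenvalue of the 2x2 diabatic
Hamiltonian ``[[e1, H12], [H12, e2]]`` built from two valence states.
Each state is a set of harmonic wells over the reactive degrees of
freedom plus a collection of harmonic bath modes whose equilibrium
positions depend on the end state.  The energy gap ``e1 - e2`` is the
collective reaction coordinate; mapping potentials
``(1 - lam) * e1 + lam * e2`` drive sampling between the states.

Every bath mode carries a component tag (``rr``, ``rs`` or ``ss``:
within the reacting fragments, reacting-fragment/surroundings coupling,
and internal to the surroundings); the reactive degrees of freedom,
state offsets and the adiabatic coupling cross-term are booked under
``rr``.  Component energies are defined with the ground-state mixing
weights so they always sum exactly to the ground-state energy.

Units are fixed package-wide: kcal/mol, Angstrom, Kelvin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: Gas constant, kcal/(mol K)
R_GAS = 1.9872e-3
#: Boltzmann constant over Planck constant, 1/(s K)
KB_OVER_H = 2.0837e10
#: Recognised energy-component tags
COMPONENT_TAGS = ("rr", "rs", "ss")


class EVBError(ValueError):
    """Invalid EVB system definition or evaluation input."""


@dataclass(frozen=True)
class DiabaticState:
    """One valence state: independent harmonic wells plus a constant offset.

    Parameters
    ----------
    well_center
        Equilibrium position of each reactive degree of freedom (A).
    force_constants
        Harmonic force constant per reactive degree of freedom
        (kcal/mol/A^2); all strictly positive.
    offset
        Constant energy shift (kcal/mol).  The gas-phase shift ``alpha``
        of state 2 lives here; state 1 conventionally has offset 0.
    """

    well_center: np.ndarray
    force_constants: np.ndarray
    offset: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "well_center",
                           np.atleast_1d(np.asarray(self.well_center, dtype=float)))
        object.__setattr__(self, "force_constants",
                           np.atleast_1d(np.asarray(self.force_constants, dtype=float)))
        if self.well_center.shape != self.force_constants.shape:
            raise EVBError("well_center and force_constants must have equal length")
        if not np.all(self.force_constants > 0):
            raise EVBError("force constants must be strictly positive")
        if not np.isfinite(self.offset):
            raise EVBError("offset must be finite")
        if not (np.isfinite(self.well_center).all()
                and np.isfinite(self.force_constants).all()):
            raise EVBError("state parameters must be finite")

    @property
    def n_dof(self) -> int:
        return self.well_center.size


@dataclass(frozen=True)
class BathMode:
    """Harmonic bath coordinate with end-state-dependent equilibrium.

    A displaced equilibrium (``eq1 != eq2``) couples the mode to the
    reaction and contributes ``0.5 * k * (eq2 - eq1)**2`` to the total
    reorganization energy.
    """

    force_constant: float
    eq1: float
    eq2: float
    tag: str

    def __post_init__(self):
        if self.force_constant <= 0 or not np.isfinite(self.force_constant):
            raise EVBError("bath force constant must be positive and finite")
        if self.tag not in COMPONENT_TAGS:
            raise EVBError(f"bath tag must be one of {COMPONENT_TAGS}, got {self.tag!r}")
        if not (np.isfinite(self.eq1) and np.isfinite(self.eq2)):
            raise EVBError("bath equilibrium positions must be finite")


@dataclass(frozen=True)
class EVBSystem:
    """Two diabatic states, a constant coupling and tagged bath modes."""

    state1: DiabaticState
    state2: DiabaticState
    coupling: float = 0.0
    bath: tuple[BathMode, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "bath", tuple(self.bath))
        if self.state1.n_dof != self.state2.n_dof:
            raise EVBError("both states must span the same reactive degrees of freedom")
        if self.coupling < 0 or not np.isfinite(self.coupling):
            raise EVBError("coupling H12 must be finite and >= 0")

    @property
    def n_reactive(self) -> int:
        return self.state1.n_dof

    @property
    def n_dof(self) -> int:
        """Reactive degrees of freedom followed by the bath modes."""
        return self.n_reactive + len(self.bath)

    # --- per-state quadratic parameters over the full coordinate vector ---

    def _state_params(self, which: int) -> tuple[np.ndarray, np.ndarray, float]:
        """Force constants, centers and offset of diabat 1 or 2."""
        state = self.state1 if which == 1 else self.state2
        k = np.concatenate([state.force_constants,
                            [m.force_constant for m in self.bath]]) \
            if self.bath else state.force_constants
        eq = [m.eq1 for m in self.bath] if which == 1 else [m.eq2 for m in self.bath]
        c = np.concatenate([state.well_center, eq]) if self.bath else state.well_center
        return k, c, state.offset

    def diabatic_energies(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """e1 and e2 for configurations ``x`` of shape (..., n_dof)."""
        x = self._check_config(x)
        k1, c1, o1 = self._state_params(1)
        k2, c2, o2 = self._state_params(2)
        e1 = 0.5 * np.sum(k1 * (x - c1) ** 2, axis=-1) + o1
        e2 = 0.5 * np.sum(k2 * (x - c2) ** 2, axis=-1) + o2
        return e1, e2

    def mode_energies(self, x: np.ndarray, which: int) -> np.ndarray:
        """Per-mode diabatic energies, shape (..., n_dof); offsets excluded."""
        x = self._check_config(x)
        k, c, _ = self._state_params(which)
        return 0.5 * k * (x - c) ** 2

    def mapping_minimum(self, lam: float) -> np.ndarray:
        """Minimum-energy configuration of the mapping potential at ``lam``."""
        k1, c1, _ = self._state_params(1)
        k2, c2, _ = self._state_params(2)
        w1, w2 = (1.0 - lam) * k1, lam * k2
        return (w1 * c1 + w2 * c2) / (w1 + w2)

    @property
    def stiffest_k(self) -> float:
        k1, _, _ = self._state_params(1)
        k2, _, _ = self._state_params(2)
        return float(max(k1.max(), k2.max()))

    def _check_config(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != self.n_dof:
            raise EVBError(
                f"configuration has {x.shape[-1]} coordinates, system has {self.n_dof}")
        return x

    def reactant_minimum(self) -> np.ndarray:
        """State-1 well geometry (reactive wells + bath eq1)."""
        return self.mapping_minimum(0.0)


@dataclass(frozen=True)
class EnergyBreakdown:
    """All energies of one configuration, mutually consistent.

    ``gap = e1 - e2`` (reactant minus product); ``eg`` is the adiabatic
    ground-state energy; ``components`` sum to ``eg`` exactly.
    """

    e1: float
    e2: float
    eg: float
    gap: float
    components: Mapping[str, float] = field(default_factory=dict)


def ground_state_energy(e1, e2, h12):
    """Lowest eigenvalue of the two-state EVB Hamiltonian.

    ``eg = (e1 + e2)/2 - sqrt((e1 - e2)**2 + 4 h12**2)/2``; always at or
    below ``min(e1, e2)``, with equality iff ``h12 == 0``.  Accepts
    scalars or broadcastable arrays.
    """
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    if np.any(h12 < 0):
        raise EVBError("coupling H12 must be >= 0")
    if not (np.all(np.isfinite(e1)) and np.all(np.isfinite(e2))
            and np.all(np.isfinite(h12))):
        raise EVBError("non-finite input to ground_state_energy")
    eg = 0.5 * (e1 + e2) - 0.5 * np.hypot(e1 - e2, 2.0 * np.asarray(h12, float))
    return eg if eg.ndim else float(eg)


def mapping_energy(e1, e2, lam):
    """FEP mapping potential ``(1 - lam) * e1 + lam * e2`` for 0 <= lam <= 1."""
    lam = float(lam)
    if not 0.0 <= lam <= 1.0:
        raise EVBError(f"lambda must lie in [0, 1], got {lam}")
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    em = (1.0 - lam) * e1 + lam * e2
    return em if em.ndim else float(em)


def _ground_weights(e1: np.ndarray, e2: np.ndarray, h12: float):
    """Squared ground-state eigenvector coefficients (c1^2, c2^2).

    For ``h12 == 0`` the lower diabat takes weight 1 (ties go to state 1).
    """
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    if h12 == 0.0:
        c1sq = np.where(e1 <= e2, 1.0, 0.0)
        return c1sq, 1.0 - c1sq
    eg = ground_state_energy(e1, e2, h12)
    t = (np.asarray(eg) - e1) / h12  # c2/c1 for the ground eigenvector
    c1sq = 1.0 / (1.0 + t * t)
    return c1sq, 1.0 - c1sq


def evaluate_many(system: EVBSystem, configs: np.ndarray) -> dict:
    """Vectorised energy breakdown for configurations of shape (n, n_dof).

    Returns arrays ``e1, e2, eg, gap`` and a ``components`` dict keyed by
    tag.  The reactive modes, both state offsets and the adiabatic
    coupling cross-term are assigned to ``rr``; bath modes follow their
    own tags.  Components sum to ``eg`` to machine precision.
    """
    x = system._check_config(np.atleast_2d(configs))
    e1, e2 = system.diabatic_energies(x)
    h12 = system.coupling
    eg = ground_state_energy(e1, e2, h12)
    c1sq, c2sq = _ground_weights(e1, e2, h12)

    m1 = system.mode_energies(x, 1)
    m2 = system.mode_energies(x, 2)
    mixed = c1sq[..., None] * m1 + c2sq[..., None] * m2  # (n, n_dof)

    nr = system.n_reactive
    components = {tag: np.zeros(x.shape[0]) for tag in COMPONENT_TAGS}
    components["rr"] += mixed[:, :nr].sum(axis=-1)
    components["rr"] += c1sq * system.state1.offset + c2sq * system.state2.offset
    for j, mode in enumerate(system.bath):
        components[mode.tag] += mixed[:, nr + j]
    # adiabatic coupling cross-term 2*c1*c2*H12, booked under rr so the
    # tagged pieces reproduce eg exactly
    components["rr"] += eg - (c1sq * e1 + c2sq * e2)
    return {"e1": e1, "e2": e2, "eg": np.asarray(eg), "gap": e1 - e2,
            "components": components}


def evaluate(system: EVBSystem, config: np.ndarray) -> EnergyBreakdown:
    """Energy breakdown of a single configuration."""
    config = np.asarray(config, dtype=float)
    if config.ndim != 1:
        raise EVBError("evaluate expects a single configuration vector")
    out = evaluate_many(system, config[None, :])
    comps = {tag: float(v[0]) for tag, v in out["components"].items()}
    return EnergyBreakdown(
        e1=float(out["e1"][0]), e2=float(out["e2"][0]),
        eg=float(out["eg"][0]), gap=float(out["gap"][0]),
        components=comps)
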