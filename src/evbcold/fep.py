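"""FEP between adjacent lambda windows and umbrella binning on the gap.

The free-energy increment between mapping potentials m and m+1 is the
average of the forward and backward Zwanzig estimates; the ground-state
profile along the energy-gap coordinate is reconstructed per bin as

    dg(X) = dG_m - RT ln < exp(-(Eg - E_m)/RT) >_{m, frames in bin X}

with contributions from different windows combined by count-weighted
averaging, the classic EVB/FEP umbrella-sampling estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .core import R_GAS
from .sampler import WindowSamples


class ProfileError(RuntimeError):
    """Profile could not be constructed or holds no barrier."""


@dataclass
class FreeEnergyProfile:
    """Binned free energy along the energy-gap coordinate.

    ``free_energy`` is shifted so the reactant minimum sits at 0; bins
    whose total count fell below the threshold are masked (``mask``
    True) and carry NaN, never a value.  ``reactant_min`` and ``ts_max``
    are (bin_index, value) pairs; they and ``barrier`` are ``None`` when
    no barrier could be resolved.
    """

    bin_centers: np.ndarray
    free_energy: np.ndarray
    counts: np.ndarray
    mask: np.ndarray
    temperature: float
    reactant_min: tuple[int, float] | None = None
    ts_max: tuple[int, float] | None = None
    barrier: float | None = None

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_center": self.bin_centers,
            "free_energy": self.free_energy,
            "counts": self.counts,
            "mask": self.mask.astype(int),
        })


def _common_temperature(windows: Sequence[WindowSamples]) -> float:
    temps = {w.temperature for w in windows}
    if len(temps) != 1:
        raise ProfileError(f"windows span several temperatures: {sorted(temps)}")
    return temps.pop()


def _mapping_energies(w: WindowSamples, lam: float) -> np.ndarray:
    return (1.0 - lam) * w.e1 + lam * w.e2


def fep_increments(windows: Sequence[WindowSamples]) -> np.ndarray:
    """Dual-direction Zwanzig increments dG(m -> m+1), one per window pair.

    Forward: ``-RT ln<exp(-(E_{m+1}-E_m)/RT)>_m``; backward:
    ``+RT ln<exp(-(E_m-E_{m+1})/RT)>_{m+1}``; the increment is their mean.
    Exponentials go through log-sum-exp, so constant offsets of any size
    are handled exactly.
    """
    if len(windows) < 2:
        raise ProfileError("need at least two windows for FEP")
    rt = R_GAS * _common_temperature(windows)
    out = np.empty(len(windows) - 1)
    for m in range(len(windows) - 1):
        w_m, w_n = windows[m], windows[m + 1]
        if len(w_m) == 0 or len(w_n) == 0:
            raise ProfileError(f"empty window at index {m if len(w_m) == 0 else m + 1}")
        de_f = _mapping_energies(w_m, w_n.lam) - _mapping_energies(w_m, w_m.lam)
        de_b = _mapping_energies(w_n, w_m.lam) - _mapping_energies(w_n, w_n.lam)
        fwd = -rt * (logsumexp(-de_f / rt) - np.log(de_f.size))
        bwd = rt * (logsumexp(-de_b / rt) - np.log(de_b.size))
        out[m] = 0.5 * (fwd + bwd)
    return out


def cumulative_free_energies(windows: Sequence[WindowSamples]) -> np.ndarray:
    """Cumulative dG_m relative to the first window (dG_0 = 0)."""
    return np.concatenate([[0.0], np.cumsum(fep_increments(windows))])


def umbrella_profile(windows: Sequence[WindowSamples], n_bins: int = 50,
                     min_count: int | None = None,
                     bin_edges: np.ndarray | None = None) -> FreeEnergyProfile:
    """Ground-state free-energy profile along the gap coordinate.

    Per window and bin, the umbrella estimate ``dG_m - RT ln<exp(-(Eg -
    E_m)/RT)>`` is computed from the frames falling in the bin; the
    per-bin values from different windows are combined by count-weighted
    average.  Bins with fewer than ``min_count`` total frames are
    masked; the default is 1% of the median window length (at least
    10), below which correlated Langevin samples cannot pin a bin's
    free energy to better than a few tenths of RT.  The profile is
    shifted so the reactant minimum is 0 and barrier metadata is
    attached when a barrier is resolvable.
    """
    if bin_edges is None:
        if n_bins < 10:
            raise ProfileError("n_bins must be >= 10")
        lo = min(w.gap.min() for w in windows)
        hi = max(w.gap.max() for w in windows)
        bin_edges = np.linspace(lo, hi, n_bins + 1)
    else:
        bin_edges = np.asarray(bin_edges, dtype=float)
        n_bins = bin_edges.size - 1
    if min_count is None:
        min_count = max(10, round(0.01 * float(np.median([len(w) for w in windows]))))
    temperature = _common_temperature(windows)
    rt = R_GAS * temperature
    dgs = cumulative_free_energies(windows)

    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    value_sum = np.zeros(n_bins)
    weight_sum = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for w, dg_m in zip(windows, dgs):
        idx = np.digitize(w.gap, bin_edges) - 1
        idx = np.clip(idx, 0, n_bins - 1)  # right edge belongs to last bin
        logw = -(w.eg - w.e_map) / rt
        for b in np.unique(idx):
            sel = idx == b
            n_b = int(sel.sum())
            f_mb = dg_m - rt * (logsumexp(logw[sel]) - np.log(len(w)))
            value_sum[b] += n_b * f_mb
            weight_sum[b] += n_b
            counts[b] += n_b

    mask = counts < min_count
    free = np.full(n_bins, np.nan)
    ok = ~mask
    free[ok] = value_sum[ok] / weight_sum[ok]

    profile = FreeEnergyProfile(bin_centers=centers, free_energy=free,
                                counts=counts, mask=mask, temperature=temperature)
    try:
        _attach_barrier(profile)
    except ProfileError:
        # monotone/flat or unresolved: keep the profile, anchored at its minimum
        if ok.any():
            profile.free_energy = free - np.nanmin(free)
    return profile


def _barrier_from_arrays(values: np.ndarray, mask: np.ndarray | None = None):
    """Barrier on a binned profile: highest interior maximum between the
    two outermost local minima, measured from the lowest bin on its
    reactant (left / negative-gap) side.

    Returns ``(i_min, v_min, i_ts, v_ts)`` with indices into the
    original (unmasked) array.  Raises ``ProfileError`` when the profile
    is monotone or flat (no interior barrier).
    """
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.zeros(values.size, dtype=bool)
    keep = np.flatnonzero(~mask)
    v = values[keep]
    if v.size < 3:
        raise ProfileError("too few unmasked bins to resolve a barrier")

    # local minima, endpoints included (strict on at least one side)
    minima = []
    for i in range(v.size):
        left = v[i - 1] if i > 0 else np.inf
        right = v[i + 1] if i < v.size - 1 else np.inf
        if v[i] < left and v[i] <= right or v[i] <= left and v[i] < right:
            minima.append(i)
    if len(minima) < 2:
        raise ProfileError("no barrier: profile is monotone or flat")
    lo, hi = minima[0], minima[-1]
    interior = np.arange(lo + 1, hi)
    if interior.size == 0:
        raise ProfileError("no barrier: adjacent minima with no interior bin")
    i_ts = interior[np.argmax(v[interior])]
    left_side = np.arange(0, i_ts)
    i_min = left_side[np.argmin(v[left_side])]
    if v[i_ts] - v[i_min] <= 0:
        raise ProfileError("no barrier: flat transition region")
    return keep[i_min], values[keep[i_min]], keep[i_ts], values[keep[i_ts]]


def _attach_barrier(profile: FreeEnergyProfile) -> None:
    i_min, v_min, i_ts, v_ts = _barrier_from_arrays(profile.free_energy, profile.mask)
    profile.free_energy = profile.free_energy - v_min
    profile.reactant_min = (int(i_min), 0.0)
    profile.ts_max = (int(i_ts), float(v_ts - v_min))
    profile.barrier = float(v_ts - v_min)


def extract_barrier(profile: FreeEnergyProfile) -> float:
    """Activation free energy of a profile (kcal/mol).

    The transition state is the highest interior maximum between the two
    outermost minima of the unmasked bins; the reactant minimum is the
    lowest bin on its reactant side.  Monotone or flat profiles raise
    ``ProfileError`` ("no barrier"); an unsampled transition region
    (masked bins only) raises an "unresolved barrier" error.
    """
    if profile.mask.all():
        raise ProfileError("unresolved barrier: all bins masked")
    _, v_min, _, v_ts = _barrier_from_arrays(profile.free_energy, profile.mask)
    return float(v_ts - v_min)
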