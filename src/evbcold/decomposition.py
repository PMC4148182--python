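"""Decomposition of the activation internal energy into component terms.

The activation enthalpy dH (with the pressure-volume term dropped, so
dH ~ dU) splits into contributions from within the reacting fragments
(rr), their interactions with the surroundings (rs), and interactions
internal to the surroundings (ss).  The rr and rs terms are direct
transition-state-minus-reactant-state ensemble averages of tagged
energies; the ss term involves too many interactions to converge
directly in real systems and is instead estimated indirectly as

    dU_ss = dH - (dU_rr + dU_rs).

On toy systems the ss term *is* directly computable, which turns the
indirect estimator into a testable self-consistency check
(``direct_ss_check``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class DecompositionError(ValueError):
    pass


@dataclass
class ComponentDelta:
    """Activation internal-energy components (kcal/mol).

    ``dU_rr_rs = dU_rr + dU_rs`` and ``dU_ss_indirect = dH - dU_rr_rs``
    hold exactly by construction; ``dU_ss_direct`` is present only when
    ss-tagged energies were directly averaged (toy systems).
    """

    dU_rr: float
    dU_rs: float
    dH: float
    dU_rr_sem: float = np.nan
    dU_rs_sem: float = np.nan
    dU_ss_direct: float | None = None
    dU_ss_direct_sem: float = np.nan

    @property
    def dU_rr_rs(self) -> float:
        return self.dU_rr + self.dU_rs

    @property
    def dU_ss_indirect(self) -> float:
        return self.dH - self.dU_rr_rs


def _as_frame(frames) -> pd.DataFrame:
    if isinstance(frames, pd.DataFrame):
        return frames
    return pd.DataFrame(dict(frames))


def block_sem(values: np.ndarray, n_blocks: int = 10) -> float:
    """Standard error of the mean by block averaging.

    Contiguous-block means absorb serial correlation; the SEM is the
    standard deviation of the block means over sqrt(n_blocks).
    """
    values = np.asarray(values, dtype=float)
    if values.size < n_blocks:
        raise DecompositionError(
            f"{values.size} frames cannot form {n_blocks} blocks")
    blocks = [b.mean() for b in np.array_split(values, n_blocks)]
    return float(np.std(blocks, ddof=1) / np.sqrt(n_blocks))


def component_means(rs_frames, ts_frames, n_blocks: int = 10) -> pd.DataFrame:
    """Per-tag TS-minus-RS mean energy differences with block SEMs.

    Both inputs are tagged per-frame energy tables (columns = tags);
    the tag sets must match.  The SEM of a difference combines the two
    ensembles' block SEMs in quadrature.
    """
    rs, ts = _as_frame(rs_frames), _as_frame(ts_frames)
    if rs.empty or ts.empty:
        raise DecompositionError("both ensembles must be non-empty")
    if set(rs.columns) != set(ts.columns):
        raise DecompositionError(
            f"tag mismatch: {sorted(rs.columns)} vs {sorted(ts.columns)}")
    rows = []
    for tag in sorted(rs.columns):
        diff = ts[tag].mean() - rs[tag].mean()
        sem = np.hypot(block_sem(ts[tag].to_numpy(), n_blocks),
                       block_sem(rs[tag].to_numpy(), n_blocks))
        rows.append({"tag": tag, "delta": float(diff), "sem": sem})
    return pd.DataFrame(rows).set_index("tag")


def indirect_ss(dH: float, dU_rr_rs: float) -> float:
    """Surroundings term estimated as dH minus the directly averaged terms."""
    if not (np.isfinite(dH) and np.isfinite(dU_rr_rs)):
        raise DecompositionError("indirect_ss requires finite inputs")
    return float(dH - dU_rr_rs)


def decompose(rs_frames, ts_frames, dH: float,
              n_blocks: int = 10) -> ComponentDelta:
    """Full decomposition from RS/TS ensembles and an externally
    determined dH (typically the Arrhenius-fit slope)."""
    means = component_means(rs_frames, ts_frames, n_blocks)
    for tag in ("rr", "rs"):
        if tag not in means.index:
            raise DecompositionError(f"ensembles carry no '{tag}' tag")
    delta = ComponentDelta(
        dU_rr=means.loc["rr", "delta"], dU_rs=means.loc["rs", "delta"],
        dH=float(dH),
        dU_rr_sem=means.loc["rr", "sem"], dU_rs_sem=means.loc["rs", "sem"])
    if "ss" in means.index:
        delta.dU_ss_direct = means.loc["ss", "delta"]
        delta.dU_ss_direct_sem = means.loc["ss", "sem"]
    return delta


def surroundings_contrast(a: ComponentDelta, b: ComponentDelta) -> float:
    """Difference of indirect surroundings terms, a minus b (kcal/mol)."""
    return float(a.dU_ss_indirect - b.dU_ss_indirect)


@dataclass
class SsCheck:
    """Direct vs indirect surroundings estimates on a toy system.

    ``combined_sem`` is the standard error of the discrepancy itself:
    since direct - indirect reduces to (sampled total dU) - dH, it is
    the block SEM of the total tagged energy difference combined with
    the dH uncertainty — per-tag SEMs cannot simply be added in
    quadrature because the tagged components covary within a frame.
    """

    direct: float
    direct_sem: float
    indirect: float
    indirect_sem: float
    discrepancy: float
    combined_sem: float


def direct_ss_check(rs_frames, ts_frames, dH: float, dH_sem: float = 0.0,
                    n_blocks: int = 10) -> SsCheck:
    """Compare the directly averaged ss term with the indirect estimate.

    Validation only: meaningful when ``dH`` comes from an independent
    route (Arrhenius fit, separate run, or exact reference), otherwise
    the two estimators coincide algebraically.  If no ss-tagged column
    exists the direct term is 0 by definition.
    """
    delta = decompose(rs_frames, ts_frames, dH, n_blocks)
    direct = 0.0 if delta.dU_ss_direct is None else delta.dU_ss_direct
    direct_sem = 0.0 if delta.dU_ss_direct is None else delta.dU_ss_direct_sem
    indirect_sem = float(np.sqrt(dH_sem ** 2 + delta.dU_rr_sem ** 2
                                 + delta.dU_rs_sem ** 2))
    rs, ts = _as_frame(rs_frames), _as_frame(ts_frames)
    total_sem = np.hypot(block_sem(rs.sum(axis=1).to_numpy(), n_blocks),
                         block_sem(ts.sum(axis=1).to_numpy(), n_blocks))
    return SsCheck(direct=float(direct), direct_sem=float(direct_sem),
                   indirect=delta.dU_ss_indirect, indirect_sem=indirect_sem,
                   discrepancy=float(direct - delta.dU_ss_indirect),
                   combined_sem=float(np.hypot(total_sem, dH_sem)))
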