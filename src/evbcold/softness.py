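"""Per-residue RMSF and the radial surface-softness statistic.

After rigid-body least-squares superposition of all frames onto an
iteratively refined mean structure, the per-atom root-mean-square
fluctuation is ``sqrt(<|r - <r>|^2>)``; residue values average over the
backbone atoms (or C-alpha only).  The softness statistic bins residues
into spherical shells around the active-site center and reports, per
shell, the percentage of residues whose RMSF exceeds a threshold
(default 1.1 A) — cold-adapted enzymes show a stiff core and a high
prevalence of mobile residues in the outer shells.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class SoftnessError(ValueError):
    pass


@dataclass
class Trajectory:
    """Multi-frame coordinates plus a per-atom metadata table.

    ``coords`` has shape (n_frames, n_atoms, 3) in Angstrom; ``atoms``
    carries columns ``res_id`` (1-based), ``res_name``, ``atom_name``,
    ``chain`` and ``backbone`` (bool), one row per atom.
    """

    coords: np.ndarray
    atoms: pd.DataFrame

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise SoftnessError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise SoftnessError("atom table length does not match coordinates")
        required = {"res_id", "res_name", "atom_name", "chain", "backbone"}
        missing = required - set(self.atoms.columns)
        if missing:
            raise SoftnessError(f"atom table lacks columns {sorted(missing)}")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def mean_structure(self) -> np.ndarray:
        return self.coords.mean(axis=0)


def select(traj: Trajectory, expr: str) -> np.ndarray:
    """Boolean atom mask from a simple selection expression.

    Clauses joined by ``and``; each clause is ``name <names...>``,
    ``resi <numbers or lo-hi ranges...>``, ``chain <ids...>`` or the
    bare word ``backbone``.  Example: ``"resi 5-10 and name CA"``.
    """
    mask = np.ones(traj.n_atoms, dtype=bool)
    for clause in [c.strip() for c in expr.split(" and ")]:
        if not clause:
            continue
        parts = clause.split()
        key, args = parts[0].lower(), parts[1:]
        if key == "backbone" and not args:
            mask &= traj.atoms["backbone"].to_numpy()
        elif key == "name" and args:
            mask &= traj.atoms["atom_name"].isin(args).to_numpy()
        elif key == "chain" and args:
            mask &= traj.atoms["chain"].isin(args).to_numpy()
        elif key == "resi" and args:
            ids = set()
            for a in args:
                if "-" in a[1:]:
                    lo, hi = a.split("-")
                    ids.update(range(int(lo), int(hi) + 1))
                else:
                    ids.add(int(a))
            mask &= traj.atoms["res_id"].isin(ids).to_numpy()
        else:
            raise SoftnessError(f"cannot parse selection clause {clause!r}")
    return mask


def _resolve_selection(traj: Trajectory, selection) -> np.ndarray:
    if isinstance(selection, str):
        sel = select(traj, selection)
    else:
        sel = np.asarray(selection, dtype=bool)
    if not sel.any():
        raise SoftnessError("empty atom selection")
    return sel


def _kabsch(mobile: np.ndarray, ref: np.ndarray):
    """Optimal proper rotation R and translation so mobile maps onto ref."""
    mc, rc = mobile.mean(axis=0), ref.mean(axis=0)
    h = (mobile - mc).T @ (ref - rc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    flip = np.diag([1.0, 1.0, d])
    rot = u @ flip @ vt
    return rot, mc, rc


def superpose(traj: Trajectory, selection="backbone", n_iter: int = 2) -> Trajectory:
    """Rigid-body least-squares fit of every frame (Kabsch, proper
    rotations only) to an iteratively refined mean structure computed
    over the selected atoms.

    Two passes by default: fit to the first frame, rebuild the mean,
    refit to it.  Collinear or single-point selections are degenerate
    (the optimal rotation is not unique) and rejected.
    """
    if traj.n_frames < 2:
        raise SoftnessError("superposition needs at least two frames")
    sel = _resolve_selection(traj, selection)
    ref_sel = traj.coords[0, sel]
    sv = np.linalg.svd(ref_sel - ref_sel.mean(axis=0), compute_uv=False)
    if sel.sum() < 3 or sv[1] < 1e-8 * max(sv[0], 1.0):
        raise SoftnessError("degenerate (collinear) superposition selection")

    coords = traj.coords.copy()
    for _ in range(n_iter):
        for f in range(coords.shape[0]):
            rot, mc, rc = _kabsch(coords[f, sel], ref_sel)
            coords[f] = (coords[f] - mc) @ rot + rc
        ref_sel = coords[:, sel].mean(axis=0)
    return replace(traj, coords=coords, atoms=traj.atoms)


def rmsf(traj: Trajectory, per_residue: bool = True,
         atoms: str = "backbone") -> pd.Series | pd.DataFrame:
    """Root-mean-square fluctuation about the mean structure.

    The trajectory must already be superposed.  ``atoms`` picks which
    atoms enter the residue average: ``"backbone"`` (N, CA, C, O) or
    ``"ca"``.  With ``per_residue=False`` the per-atom values are
    returned instead.
    """
    if traj.n_frames < 2:
        raise SoftnessError("RMSF needs at least two frames")
    dev = traj.coords - traj.mean_structure()
    per_atom = np.sqrt(np.mean(np.sum(dev ** 2, axis=2), axis=0))
    if not per_residue:
        return pd.Series(per_atom, name="rmsf")
    if atoms == "backbone":
        keep = traj.atoms["backbone"].to_numpy()
    elif atoms.lower() == "ca":
        keep = (traj.atoms["atom_name"] == "CA").to_numpy()
    else:
        raise SoftnessError("atoms must be 'backbone' or 'ca'")
    if not keep.any():
        raise SoftnessError(f"no {atoms} atoms present")
    df = pd.DataFrame({"res_id": traj.atoms["res_id"][keep],
                       "rmsf": per_atom[keep]})
    return df.groupby("res_id")["rmsf"].mean()


def active_site_center(traj: Trajectory, selection) -> np.ndarray:
    """Geometric centroid of the selected atoms in the mean structure."""
    sel = _resolve_selection(traj, selection)
    return traj.mean_structure()[sel].mean(axis=0)


def residue_distances(traj: Trajectory, center: np.ndarray) -> pd.Series:
    """Distance of each residue's mean-structure C-alpha to ``center``."""
    ca = (traj.atoms["atom_name"] == "CA").to_numpy()
    if not ca.any():
        raise SoftnessError("no CA atoms to assign residues to shells")
    mean = traj.mean_structure()
    d = np.linalg.norm(mean[ca] - np.asarray(center, dtype=float), axis=1)
    return pd.Series(d, index=traj.atoms["res_id"][ca].to_numpy(), name="distance")


@dataclass
class SoftnessProfile:
    """Radial softness summary: per-shell % of residues with RMSF above
    threshold, plus the per-residue inputs.  Empty shells carry NaN
    prevalence and ``occupied`` False."""

    rmsf: pd.Series
    distances: pd.Series
    shell_edges: np.ndarray
    prevalence: np.ndarray
    counts: np.ndarray
    occupied: np.ndarray
    threshold: float

    def shells_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "shell_lo": self.shell_edges[:-1], "shell_hi": self.shell_edges[1:],
            "prevalence_pct": self.prevalence, "n_residues": self.counts,
        })


def shell_prevalence(rmsf_values: pd.Series, distances: pd.Series,
                     threshold: float = 1.1,
                     shell_width: float = 5.0) -> SoftnessProfile:
    """Percentage of high-RMSF residues per spherical shell.

    Residues are binned by their distance to the active-site center in
    consecutive shells of ``shell_width`` starting at 0; each shell
    reports ``100 * (count RMSF > threshold) / count``.
    """
    if shell_width <= 0:
        raise SoftnessError("shell width must be positive")
    r, d = pd.Series(rmsf_values).align(pd.Series(distances), join="inner")
    if r.empty:
        raise SoftnessError("no residues shared between RMSF and distances")
    if (d < 0).any():
        raise SoftnessError("distances must be non-negative")
    n_shells = int(np.floor(d.max() / shell_width)) + 1
    edges = shell_width * np.arange(n_shells + 1)
    idx = np.minimum((d.to_numpy() / shell_width).astype(int), n_shells - 1)
    counts = np.bincount(idx, minlength=n_shells)
    above = np.bincount(idx, weights=(r.to_numpy() > threshold), minlength=n_shells)
    occupied = counts > 0
    prevalence = np.full(n_shells, np.nan)
    prevalence[occupied] = 100.0 * above[occupied] / counts[occupied]
    return SoftnessProfile(rmsf=r, distances=d, shell_edges=edges,
                           prevalence=prevalence, counts=counts,
                           occupied=occupied, threshold=float(threshold))
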