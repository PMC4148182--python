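"""File formats: system configs (YAML), tabular window/barrier/profile
data (TSV/CSV), and multi-frame coordinates (multi-MODEL PDB via
biotite, plain XYZ).

All tables are written with a ``# config_hash: <hex>`` comment header
when a hash is supplied, so artifacts from different pipeline configs
can be told apart; readers can verify an expected hash and refuse
mismatched inputs.

System config schema (YAML)::

    system:
      state1: {wells: [..], force_constants: [..], offset: 0.0}
      state2: {wells: [..], force_constants: [..], offset: ..}
      coupling: ..
      bath:                       # optional
        - {force_constant: .., eq1: .., eq2: .., tag: rr|rs|ss}

Energies kcal/mol, lengths Angstrom throughout; there are no unit
options.
"""

from __future__ import annotations

import hashlib
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
import biotite.structure as bst
import biotite.structure.io.pdb as bpdb

from .core import BathMode, DiabaticState, EVBSystem
from .fep import FreeEnergyProfile
from .sampler import WindowSamples
from .softness import BACKBONE_ATOMS, SoftnessError, Trajectory


class IOError_(RuntimeError):
    """Unparseable or inconsistent input file."""


# ---------------------------------------------------------------- config

def config_hash(obj) -> str:
    """Short stable hash of a config mapping (canonical YAML, sha256)."""
    dumped = yaml.safe_dump(obj, sort_keys=True)
    return hashlib.sha256(dumped.encode()).hexdigest()[:12]


def system_to_dict(system: EVBSystem) -> dict:
    def state(s: DiabaticState):
        return {"wells": [float(v) for v in s.well_center],
                "force_constants": [float(v) for v in s.force_constants],
                "offset": float(s.offset)}
    return {"system": {
        "state1": state(system.state1), "state2": state(system.state2),
        "coupling": float(system.coupling),
        "bath": [{"force_constant": m.force_constant, "eq1": m.eq1,
                  "eq2": m.eq2, "tag": m.tag} for m in system.bath],
    }}


def system_from_dict(d: dict) -> EVBSystem:
    try:
        s = d["system"]
        mk = lambda e: DiabaticState(well_center=e["wells"],
                                     force_constants=e["force_constants"],
                                     offset=float(e.get("offset", 0.0)))
        bath = tuple(BathMode(force_constant=float(m["force_constant"]),
                              eq1=float(m["eq1"]), eq2=float(m["eq2"]),
                              tag=m["tag"]) for m in s.get("bath", []))
        return EVBSystem(state1=mk(s["state1"]), state2=mk(s["state2"]),
                         coupling=float(s.get("coupling", 0.0)), bath=bath)
    except (KeyError, TypeError) as exc:
        raise IOError_(f"invalid system config: {exc}") from exc


def load_system(path) -> EVBSystem:
    with open(path) as fh:
        return system_from_dict(yaml.safe_load(fh))


def save_system(system: EVBSystem, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(system_to_dict(system), fh, sort_keys=True)


# ---------------------------------------------------------------- tables

def _write_table(df: pd.DataFrame, path, sep: str, cfg_hash: str | None):
    with open(path, "w") as fh:
        if cfg_hash:
            fh.write(f"# config_hash: {cfg_hash}\n")
        df.to_csv(fh, sep=sep, index=False)


def _read_table(path, sep: str, expect_hash: str | None = None) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
        found = None
        if first.startswith("# config_hash:"):
            found = first.split(":", 1)[1].strip()
            body = fh.read()
        else:
            body = first + fh.read()
    if expect_hash is not None and found != expect_hash:
        raise IOError_(
            f"config hash mismatch in {path}: expected {expect_hash}, "
            f"found {found}; refusing to mix artifacts from different runs")
    return pd.read_csv(_io.StringIO(body), sep=sep)


def write_windows(windows, path, cfg_hash: str | None = None) -> None:
    """Serialize windows to TSV, one row per frame.

    Column order: lam, temperature, gap, e1, e2, eg, e_map, then one
    ``comp_<tag>`` column per tag in sorted order.  Coordinates are not
    serialized.
    """
    table = pd.concat([w.to_table() for w in windows], ignore_index=True)
    _write_table(table, path, "\t", cfg_hash)


def read_windows(path, expect_hash: str | None = None) -> list[WindowSamples]:
    """Rebuild windows (without coordinates) from the tabular format."""
    df = _read_table(path, "\t", expect_hash)
    comp_cols = [c for c in df.columns if c.startswith("comp_")]
    out = []
    for (lam, temp), grp in df.groupby(["lam", "temperature"], sort=True):
        out.append(WindowSamples(
            lam=float(lam), temperature=float(temp), seed=-1,
            n_equil=0, n_prod=len(grp),
            gap=grp["gap"].to_numpy(), e1=grp["e1"].to_numpy(),
            e2=grp["e2"].to_numpy(), eg=grp["eg"].to_numpy(),
            e_map=grp["e_map"].to_numpy(),
            components={c[5:]: grp[c].to_numpy() for c in comp_cols}))
    return out


def write_barriers(table: pd.DataFrame, path, cfg_hash: str | None = None):
    _write_table(table[["temperature", "replicate", "barrier"]], path, ",", cfg_hash)


def read_barriers(path, expect_hash: str | None = None) -> pd.DataFrame:
    return _read_table(path, ",", expect_hash)


def write_profile(profile: FreeEnergyProfile, path, cfg_hash: str | None = None):
    _write_table(profile.to_table(), path, "\t", cfg_hash)


def read_profile(path, expect_hash: str | None = None) -> FreeEnergyProfile:
    df = _read_table(path, "\t", expect_hash)
    return FreeEnergyProfile(
        bin_centers=df["bin_center"].to_numpy(),
        free_energy=df["free_energy"].to_numpy(),
        counts=df["counts"].to_numpy(),
        mask=df["mask"].to_numpy().astype(bool),
        temperature=np.nan)


# ---------------------------------------------------------- trajectories

def _is_backbone(names) -> np.ndarray:
    return np.isin(np.asarray(names), BACKBONE_ATOMS)


def read_pdb_frames(path) -> Trajectory:
    """Multi-MODEL PDB to Trajectory (biotite-backed).

    Residue numbers are kept as printed (1-based); backbone flags are
    assigned by atom name (N, CA, C, O).  MODELs with differing atom
    counts fail with the offending MODEL named.
    """
    _check_model_atom_counts(path)
    try:
        stack = bpdb.PDBFile.read(str(path)).get_structure()
    except Exception as exc:
        raise IOError_(f"cannot parse PDB {path}: {exc}") from exc
    if not isinstance(stack, bst.AtomArrayStack):
        stack = bst.stack([stack])
    atoms = pd.DataFrame({
        "res_id": stack.res_id, "res_name": stack.res_name,
        "atom_name": stack.atom_name, "chain": stack.chain_id,
        "backbone": _is_backbone(stack.atom_name),
    })
    return Trajectory(coords=np.asarray(stack.coord, dtype=float), atoms=atoms)


def _check_model_atom_counts(path) -> None:
    counts, model_ids, current, in_model = [], [], 0, False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            rec = line[:6].strip()
            if rec == "MODEL":
                in_model, current = True, 0
                model_ids.append(line[6:].strip() or str(len(model_ids) + 1))
            elif rec == "ENDMDL":
                counts.append(current)
                in_model = False
            elif rec in ("ATOM", "HETATM") and in_model:
                current += 1
    if counts and len(set(counts)) > 1:
        bad = [m for m, c in zip(model_ids, counts) if c != counts[0]]
        raise IOError_(
            f"{path}: MODELs have inconsistent atom counts "
            f"(first differing MODEL {bad[0]}; counts {sorted(set(counts))})")


def write_pdb_frames(traj: Trajectory, path) -> None:
    """Trajectory to multi-MODEL PDB via biotite."""
    n = traj.n_atoms
    arrays = []
    for f in range(traj.n_frames):
        arr = bst.AtomArray(n)
        arr.coord = traj.coords[f]
        arr.res_id = traj.atoms["res_id"].to_numpy()
        arr.res_name = traj.atoms["res_name"].to_numpy(dtype="U5")
        arr.atom_name = traj.atoms["atom_name"].to_numpy(dtype="U6")
        arr.chain_id = traj.atoms["chain"].to_numpy(dtype="U4")
        arr.element = np.array([a[0] for a in traj.atoms["atom_name"]], dtype="U2")
        arrays.append(arr)
    pf = bpdb.PDBFile()
    pf.set_structure(bst.stack(arrays))
    pf.write(str(path))


def read_xyz_frames(path) -> Trajectory:
    """Multi-frame XYZ to Trajectory.

    XYZ carries no residue topology: each atom becomes its own residue
    (1-based index), the symbol column is kept as the atom name, and
    backbone flags are assigned by name as for PDB.
    """
    frames, names = [], None
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise IOError_(f"{path}:{i + 1}: expected atom count, got "
                           f"{lines[i].strip()!r}") from exc
        block = lines[i + 2: i + 2 + n]
        if len(block) < n:
            raise IOError_(f"{path}:{i + 1}: truncated frame ({len(block)}/{n} atoms)")
        fnames, coords = [], []
        for j, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise IOError_(f"{path}:{i + 3 + j}: unparseable XYZ record {ln!r}")
            fnames.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
        if names is None:
            names = fnames
        elif fnames != names or len(coords) != len(frames[0]):
            raise IOError_(f"{path}:{i + 1}: frame differs in atoms from frame 1")
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise IOError_(f"{path}: no frames found")
    names = np.asarray(names)
    atoms = pd.DataFrame({
        "res_id": np.arange(1, names.size + 1), "res_name": "UNK",
        "atom_name": names, "chain": "A", "backbone": _is_backbone(names),
    })
    return Trajectory(coords=np.asarray(frames, dtype=float), atoms=atoms)


def write_xyz_frames(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\nframe {f + 1}\n")
            for name, (x, y, z) in zip(traj.atoms["atom_name"], traj.coords[f]):
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


def read_trajectory(path) -> Trajectory:
    """Dispatch on extension: .pdb -> PDB, .xyz -> XYZ."""
    suffix = Path(path).suffix.lower()
    if suffix == ".pdb":
        return read_pdb_frames(path)
    if suffix == ".xyz":
        return read_xyz_frames(path)
    raise IOError_(f"unsupported trajectory format {suffix!r} (use .pdb or .xyz)")
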