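"""Structure, table and config I/O.

Structures travel as standard fixed-column PDB (one MODEL per frame, chain A
= strand I 5'->3', chain B = strand II, ions as HETATM with element-named
residues) via biotite, or as bare XYZ with the duplex topology supplied as a
sidecar.  Tables are CSV with unit-bearing column names; generator and
pipeline configuration is YAML.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .model import (
    BASE_OF_RESNAME,
    ConcSeries,
    DuplexConformation,
    DuplexTopology,
    IonFrames,
    RotExtCurve,
    Trajectory,
    TwistSeries,
)

ION_RESNAMES = {"LI", "NA", "K", "RB", "CS", "MG", "CA", "SR", "BA"}
ION_VALENCE = {"LI": 1, "NA": 1, "K": 1, "RB": 1, "CS": 1, "MG": 2, "CA": 2, "SR": 2, "BA": 2}


class ParseError(ValueError):
    """Malformed or inconsistent structure file."""


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------


def _atom_array(traj: Trajectory, frame: int, ions: IonFrames | None) -> struc.AtomArray:
    top = traj.topology
    n_ion = ions.n_ions if ions is not None else 0
    arr = struc.AtomArray(top.n_atoms + n_ion)
    arr.chain_id[: top.n_atoms] = top.chain_id
    arr.res_id[: top.n_atoms] = top.res_id
    arr.res_name[: top.n_atoms] = top.res_name
    arr.atom_name[: top.n_atoms] = top.atom_name
    arr.element[: top.n_atoms] = top.element
    arr.hetero[: top.n_atoms] = False
    arr.coord[: top.n_atoms] = traj.coords[frame]
    if ions is not None:
        s = slice(top.n_atoms, None)
        arr.chain_id[s] = "I"
        arr.res_id[s] = np.arange(1, n_ion + 1)
        arr.res_name[s] = ions.species
        arr.atom_name[s] = ions.species
        arr.element[s] = [sp.capitalize() for sp in ions.species]
        arr.hetero[s] = True
        arr.coord[s] = ions.coords[frame]
    return arr


def write_structure(path, traj: Trajectory | DuplexConformation, ions: IonFrames | None = None) -> None:
    """Write a (multi-model) PDB; one MODEL per frame, ions as HETATM."""
    from .frames import _traj_of

    traj = _traj_of(traj)
    if ions is not None and ions.n_frames not in (traj.n_frames,):
        raise ValueError("ion frames must match trajectory frames")
    pdb = PDBFile()
    if traj.n_frames == 1:
        pdb.set_structure(_atom_array(traj, 0, ions))
    else:
        arrays = [_atom_array(traj, f, ions) for f in range(traj.n_frames)]
        pdb.set_structure(struc.stack(arrays))
    pdb.write(str(path))


def read_structure(path) -> tuple[Trajectory, IonFrames | None]:
    """Read a (multi-model) PDB into a Trajectory plus optional ion frames.

    Residue/chain numbering is preserved; HETATM records with ion residue
    names become :class:`IonFrames`.  Raises :class:`ParseError` on
    malformed files or duplex strands of unequal length.
    """
    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    first = stack[0]
    ion_mask = np.isin(first.res_name, list(ION_RESNAMES)) & first.hetero
    dup_mask = ~ion_mask
    dup = first[dup_mask]
    for cid in ("A", "B"):
        if not np.any(dup.chain_id == cid):
            raise ParseError(f"{path}: missing duplex chain {cid!r}")
    n_a = len(np.unique(dup.res_id[dup.chain_id == "A"]))
    n_b = len(np.unique(dup.res_id[dup.chain_id == "B"]))
    if n_a != n_b:
        raise ParseError(f"{path}: duplex strands of unequal length ({n_a} vs {n_b} residues)")
    seq = []
    chain_a = dup[dup.chain_id == "A"]
    for rid in np.unique(chain_a.res_id):
        rname = chain_a.res_name[chain_a.res_id == rid][0]
        if rname not in BASE_OF_RESNAME:
            raise ParseError(f"{path}: unknown residue name {rname!r} in chain A")
        seq.append(BASE_OF_RESNAME[rname])
    topology = DuplexTopology(
        "".join(seq),
        dup.chain_id.astype("U1"),
        dup.res_id,
        dup.res_name.astype("U3"),
        dup.atom_name.astype("U4"),
        dup.element.astype("U2"),
    )
    coords = stack.coord[:, dup_mask]
    traj = Trajectory(topology, coords)
    ions = None
    if ion_mask.any():
        species = first.res_name[ion_mask].astype("U2")
        ions = IonFrames(
            species=species,
            valence=np.array([ION_VALENCE.get(s, 1) for s in species]),
            coords=stack.coord[:, ion_mask],
        )
    return traj, ions


# ---------------------------------------------------------------------------
# XYZ (element + coordinates; topology supplied separately)
# ---------------------------------------------------------------------------


def write_xyz(path, traj: Trajectory | DuplexConformation, comment: str = "") -> None:
    """Write frames as concatenated XYZ blocks (element x y z, A)."""
    from .frames import _traj_of

    traj = _traj_of(traj)
    top = traj.topology
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{top.n_atoms}\n{comment or f'frame {f}'}\n")
            for el, (x, y, z) in zip(top.element, traj.coords[f]):
                fh.write(f"{el:2s} {x:14.6f} {y:14.6f} {z:14.6f}\n")


def read_xyz(path, topology: DuplexTopology | None = None):
    """Read concatenated XYZ frames; returns a Trajectory if topology given,
    else a plain coordinate array (n_frames, n_atoms, 3)."""
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(f"{path}:{i + 1}: expected atom count, got {lines[i]!r}") from exc
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ParseError(f"{path}:{i + 1}: truncated frame")
        coords = np.array([[float(v) for v in ln.split()[1:4]] for ln in block])
        frames.append(coords)
        i += 2 + n
    coords = np.stack(frames)
    if topology is None:
        return coords
    if coords.shape[1] != topology.n_atoms:
        raise ParseError(f"{path}: {coords.shape[1]} atoms but topology has {topology.n_atoms}")
    return Trajectory(topology, coords)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------


def write_twist_csv(path, series: TwistSeries) -> None:
    pd.DataFrame(
        {
            "frame": np.arange(len(series.twist_deg_bp)),
            "time_ns": series.times_ns,
            "twist_deg_bp": series.twist_deg_bp,
        }
    ).to_csv(path, index=False)


def write_curve_csv(path, curve: RotExtCurve) -> None:
    df = pd.DataFrame({"turns": curve.turns, "ext_um": curve.ext_um})
    df["ext_sd"] = curve.ext_sd if curve.ext_sd is not None else np.nan
    df.to_csv(path, index=False)


def read_curve_csv(path, force_pn: float | None = None) -> RotExtCurve:
    df = pd.read_csv(path)
    for col in ("turns", "ext_um"):
        if col not in df:
            raise ParseError(f"{path}: missing column {col!r}")
    sd = df["ext_sd"].to_numpy() if "ext_sd" in df and df["ext_sd"].notna().all() else None
    return RotExtCurve(df["turns"].to_numpy(), df["ext_um"].to_numpy(), sd, force_pn, label=str(path))


def write_series_csv(path, series: ConcSeries) -> None:
    pd.DataFrame(
        {
            "conc_mM": series.conc_mM,
            "dtw_deg_bp": series.dtw_deg_bp,
            "sigma": series.sigma,
            "ion": series.ion,
            "valence": series.valence,
        }
    ).to_csv(path, index=False)


def read_series_csv(path) -> ConcSeries:
    df = pd.read_csv(path)
    for col in ("conc_mM", "dtw_deg_bp", "sigma"):
        if col not in df:
            raise ParseError(f"{path}: missing column {col!r}")
    ion = str(df["ion"].iloc[0]) if "ion" in df else ""
    valence = int(df["valence"].iloc[0]) if "valence" in df else 1
    return ConcSeries(
        df["conc_mM"].to_numpy(), df["dtw_deg_bp"].to_numpy(), df["sigma"].to_numpy(), ion, valence
    )


def write_opendx(path, grid) -> None:
    """Write a :class:`~salt_twist.ion_atmosphere.GridDensity` as OpenDX."""
    d = grid.density_M
    nx, ny, nz = d.shape
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.4f} {:.4f} {:.4f}\n".format(*grid.origin))
        fh.write(f"delta {grid.voxel:.4f} 0 0\ndelta 0 {grid.voxel:.4f} 0\ndelta 0 0 {grid.voxel:.4f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items {d.size} data follows\n")
        flat = d.ravel(order="C")
        for i in range(0, len(flat), 3):
            fh.write(" ".join(f"{v:.6e}" for v in flat[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Configuration of the end-to-end analysis pipeline."""

    sample: str
    reference: str
    out_dir: str = "salt_twist_out"
    equilibration_ns: float = 200.0
    block_ns: float = 200.0
    radial_bin_A: float = 1.0
    radial_max_A: float = 30.0
    site_cutoff_A: float = 3.5
    terminal_k: int = 1
    seed: int = 0

    def validate(self) -> None:
        for name in ("equilibration_ns", "block_ns", "radial_bin_A", "radial_max_A", "site_cutoff_A"):
            if getattr(self, name) < 0 or (name != "equilibration_ns" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")
        if self.terminal_k < 1:
            raise ValueError("terminal_k must be >= 1")


def load_pipeline_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = PipelineConfig(**data)
    cfg.validate()
    return cfg


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_json(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
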