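"""Ion-atmosphere analysis in helix-centered coordinates.

Ions are described in curvilinear cylindrical coordinates around the duplex:
``r`` is the distance to the helical-axis polyline (the base-pair origins),
``z_s`` the arclength of the foot point along that polyline, and ``phi`` the
azimuth in the local base-pair plane measured from its x-axis (0 deg toward
the major groove).  From these the module builds radial molarity profiles,
site-occupancy tables (backbone phosphate oxygens vs N7/O6 nucleobase
atoms vs grooves vs diffuse) and an optional 3D grid density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .frames import _traj_of, all_bp_frames
from .model import DuplexConformation, IonFrames, Trajectory

N_AVOGADRO = 6.02214076e23
A3_TO_L = 1e-27

#: azimuthal sector assigned to the minor groove; the complement (at small
#: radius) is the major groove
MINOR_GROOVE_PHI = (120.0, 240.0)
#: ions beyond this axial distance are not assigned to a groove
GROOVE_RADIUS = 12.0


def _frames_for_ions(conf, n_ion_frames: int):
    """bp frames/origins per ion frame; a single conformation broadcasts."""
    traj = _traj_of(conf)
    axes, origins = all_bp_frames(traj)
    if traj.n_frames == 1 and n_ion_frames > 1:
        axes = np.broadcast_to(axes, (n_ion_frames,) + axes.shape[1:])
        origins = np.broadcast_to(origins, (n_ion_frames,) + origins.shape[1:])
    elif traj.n_frames != n_ion_frames:
        raise ValueError(
            f"ion frames ({n_ion_frames}) do not match duplex frames ({traj.n_frames})"
        )
    return axes, origins


def curvilinear_coords(
    ions: IonFrames,
    conf: Trajectory | DuplexConformation,
    z_padding: float = 5.0,
) -> pd.DataFrame:
    """Helix-centered coordinates of every ion in every frame.

    Returns a tidy DataFrame with columns frame, ion, species, r_A, phi_deg,
    z_A and in_range; ions whose axial foot point falls beyond the polyline
    caps plus ``z_padding`` are flagged out of range.
    """
    axes, origins = _frames_for_ions(conf, ions.n_frames)
    F, n_bp = origins.shape[:2]
    a = origins[:, :-1]  # (F, S, 3)
    b = origins[:, 1:]
    ab = b - a
    seg_len = np.linalg.norm(ab, axis=-1)  # (F, S)
    arc0 = np.concatenate([np.zeros((F, 1)), np.cumsum(seg_len, axis=1)[:, :-1]], axis=1)
    pts = ions.coords  # (F, m, 3)
    ap = pts[:, :, None, :] - a[:, None, :, :]  # (F, m, S, 3)
    denom = np.einsum("fsi,fsi->fs", ab, ab)
    t_raw = np.einsum("fmsi,fsi->fms", ap, ab) / denom[:, None, :]
    t = np.clip(t_raw, 0.0, 1.0)
    closest = a[:, None, :, :] + t[..., None] * ab[:, None, :, :]
    dist = np.linalg.norm(pts[:, :, None, :] - closest, axis=-1)  # (F, m, S)
    seg = np.argmin(dist, axis=-1)  # (F, m)
    fidx = np.arange(F)[:, None]
    midx = np.arange(ions.n_ions)[None, :]
    r = dist[fidx, midx, seg]
    t_sel = t_raw[fidx, midx, seg]
    z = arc0[fidx, seg] + np.clip(t_sel, 0.0, 1.0) * seg_len[fidx, seg]
    total_len = seg_len.sum(axis=1)
    # axial overhang beyond the caps, measured along the terminal segments
    over_lo = np.where(seg == 0, np.minimum(t_sel, 0.0) * seg_len[fidx, seg], 0.0)
    over_hi = np.where(seg == axes.shape[1] - 2, np.maximum(t_sel - 1.0, 0.0) * seg_len[fidx, seg], 0.0)
    in_range = (over_lo >= -z_padding) & (over_hi <= z_padding)
    # azimuth in the nearest bp frame
    near_bp = np.where(t_sel > 0.5, seg + 1, seg)
    frame_sel = axes[fidx, near_bp]  # (F, m, 3, 3)
    v = pts - closest[fidx, midx, seg]
    vx = np.einsum("fmi,fmi->fm", v, frame_sel[..., :, 0])
    vy = np.einsum("fmi,fmi->fm", v, frame_sel[..., :, 1])
    phi = np.mod(np.rad2deg(np.arctan2(vy, vx)), 360.0)
    phi = np.where(r < 1e-12, 0.0, phi)
    return pd.DataFrame(
        {
            "frame": np.repeat(np.arange(F), ions.n_ions),
            "ion": np.tile(np.arange(ions.n_ions), F),
            "species": np.tile(ions.species, F),
            "r_A": r.ravel(),
            "phi_deg": phi.ravel(),
            "z_A": (z + over_lo + over_hi).ravel(),
            "in_range": in_range.ravel(),
            "axis_length_A": np.repeat(total_len, ions.n_ions),
        }
    )


@dataclass
class RadialProfile:
    """Radial molarity profile around the helical axis, per species."""

    bin_edges: np.ndarray  # (k+1,) A
    species: list[str]
    concentration_M: np.ndarray  # (n_species, k)
    counts: np.ndarray  # (n_species, k) summed over frames
    n_out_of_range: int
    n_frames: int
    z_length_A: float

    @property
    def r_mid(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"r_mid_A": self.r_mid})
        for s, conc in zip(self.species, self.concentration_M):
            df[f"conc_M_{s}"] = conc
        return df


def radial_profile(
    ions: IonFrames,
    conf: Trajectory | DuplexConformation,
    bin_edges: np.ndarray | None = None,
    z_range: tuple[float, float] | None = None,
    trim_bp: int = 1,
) -> RadialProfile:
    """Shell-averaged molarity vs distance from the helical axis.

    ``c_k = N_k / (N_A V_k n_frames)`` with cylindrical-shell volumes
    ``V_k = pi (r_{k+1}^2 - r_k^2) L_z`` in litres.  The axial window
    defaults to the polyline trimmed ``trim_bp`` base pairs at each end.
    """
    if bin_edges is None:
        bin_edges = np.arange(0.0, 30.5, 1.0)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if bin_edges.ndim != 1 or len(bin_edges) < 2 or np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    coords = curvilinear_coords(ions, conf)
    _, origins = all_bp_frames(_traj_of(conf))
    total_len = float(np.linalg.norm(np.diff(origins[0], axis=0), axis=-1).sum())
    if z_range is None:
        seg = total_len / (_traj_of(conf).n_bp - 1)
        z_range = (trim_bp * seg, total_len - trim_bp * seg)
    z_lo, z_hi = z_range
    L_z = z_hi - z_lo
    if L_z <= 0:
        raise ValueError("empty axial range")
    sel = coords[(coords["z_A"] >= z_lo) & (coords["z_A"] < z_hi)]
    species = sorted(set(ions.species.tolist()))
    counts = np.zeros((len(species), len(bin_edges) - 1))
    for i, s in enumerate(species):
        r = sel.loc[sel["species"] == s, "r_A"].to_numpy()
        counts[i], _ = np.histogram(r, bins=bin_edges)
    shell_vol = np.pi * (bin_edges[1:] ** 2 - bin_edges[:-1] ** 2) * L_z * A3_TO_L
    conc = counts / (N_AVOGADRO * shell_vol[None, :] * ions.n_frames)
    n_out = int(len(coords) - len(sel))
    return RadialProfile(
        bin_edges, species, conc, counts, n_out, ions.n_frames, float(L_z)
    )


def site_occupancy(
    ions: IonFrames,
    conf: Trajectory | DuplexConformation,
    cutoff: float = 3.5,
) -> pd.DataFrame:
    """Fraction of ions at each binding environment, per species.

    Each ion is assigned to the nearest qualifying site within ``cutoff``
    (backbone = O1P/O2P, base = N7/O6; exact ties go to the backbone), else
    to a groove by azimuthal sector if it lies within ``GROOVE_RADIUS`` of
    the axis, else counted as diffuse.  Fractions sum to 1 per species.
    """
    from scipy.spatial import cKDTree

    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    traj = _traj_of(conf)
    top = traj.topology
    bb_mask = top.select(("O1P", "O2P"))
    base_mask = top.select(("N7", "O6"))
    coords = curvilinear_coords(ions, conf)
    cats = ["backbone", "base_N7_O6", "minor_groove", "major_groove", "diffuse"]
    species = sorted(set(ions.species.tolist()))
    tallies = {s: dict.fromkeys(cats, 0) for s in species}
    single = traj.n_frames == 1
    for f in range(ions.n_frames):
        duplex = traj.coords[0 if single else f]
        bb_tree = cKDTree(duplex[bb_mask])
        base_tree = cKDTree(duplex[base_mask]) if base_mask.any() else None
        pts = ions.coords[f]
        d_bb, _ = bb_tree.query(pts)
        d_base = base_tree.query(pts)[0] if base_tree is not None else np.full(len(pts), np.inf)
        sub = coords[coords["frame"] == f]
        r = sub["r_A"].to_numpy()
        phi = sub["phi_deg"].to_numpy()
        for i, s in enumerate(ions.species):
            if d_bb[i] <= cutoff and (d_bb[i] <= d_base[i] or d_base[i] > cutoff):
                cat = "backbone"
            elif d_base[i] <= cutoff:
                cat = "base_N7_O6"
            elif r[i] < GROOVE_RADIUS:
                lo, hi = MINOR_GROOVE_PHI
                cat = "minor_groove" if lo <= phi[i] < hi else "major_groove"
            else:
                cat = "diffuse"
            tallies[s][cat] += 1
    rows = []
    for s in species:
        total = sum(tallies[s].values())
        row = {"species": s}
        for c in cats:
            row[c] = tallies[s][c] / total if total else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class GridDensity:
    """3D ion density on a regular grid, in mol/L per voxel."""

    origin: np.ndarray  # (3,) A, corner of the grid
    voxel: float  # A
    density_M: np.ndarray  # (nx, ny, nz)
    n_frames: int

    @property
    def mean_count(self) -> float:
        """Integral of the density over the grid, in ions per frame."""
        return float(self.density_M.sum() * N_AVOGADRO * self.voxel**3 * A3_TO_L)


def grid_density(
    ions: IonFrames,
    conf: Trajectory | DuplexConformation,
    voxel: float = 1.0,
    padding: float = 5.0,
) -> GridDensity:
    """Histogram ion positions on a regular grid after frame superposition.

    Frames are rigidly superposed onto the first frame using the base-pair
    origins (stable under base fluctuations); voxel molarity is
    count / (N_A V_voxel n_frames).
    """
    from .geometry import kabsch

    if voxel <= 0:
        raise ValueError("voxel size must be positive")
    traj = _traj_of(conf)
    axes, origins = _frames_for_ions(conf, ions.n_frames)
    ref = origins[0]
    pts = np.array(ions.coords, copy=True)
    for f in range(1, ions.n_frames):
        R, t = kabsch(origins[f], ref)
        pts[f] = pts[f] @ R.T + t
    flat = pts.reshape(-1, 3)
    lo = flat.min(axis=0) - padding
    hi = flat.max(axis=0) + padding
    nbins = np.maximum(np.ceil((hi - lo) / voxel).astype(int), 1)
    edges = [lo[k] + voxel * np.arange(nbins[k] + 1) for k in range(3)]
    H, _ = np.histogramdd(flat, bins=edges)
    density = H / (N_AVOGADRO * voxel**3 * A3_TO_L * ions.n_frames)
    return GridDensity(origin=lo, voxel=float(voxel), density_M=density, n_frames=ions.n_frames)
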