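"""Conformational observables of the duplex: crookedness, radius, sugar
pucker, groove width, backbone substates, block-averaged errors and
correlations.

Crookedness quantifies axial compaction: with ``h`` the end-to-end length of
the helix (distance between terminal base-pair origins) and ``d`` the
summed per-step rises, ``cos(beta) = h/d``.  A perfectly straight helix has
``beta = 0``; bending and compression raise it.

The helix radius is measured as the mean distance of backbone phosphorus
atoms to the helical-axis polyline through the base-pair origins; "radius"
has no single standard operational definition, so this package declares
that interpretation (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .frames import _traj_of, steps_of, twist_profile
from .geometry import dihedral, wrap_angle
from .model import DuplexConformation, Trajectory

SIN36_SIN72 = np.sin(np.deg2rad(36.0)) + np.sin(np.deg2rad(72.0))

#: subtracted from minimum cross-strand P-P distances: two phosphate radii
PHOSPHATE_DIAMETER = 5.8

# ---------------------------------------------------------------------------
# Crookedness and radius
# ---------------------------------------------------------------------------


def crookedness(
    traj: Trajectory | DuplexConformation,
    h_estimator: str = "end_to_end",
    d_estimator: str = "sum_rise",
    _steps: dict | None = None,
) -> pd.DataFrame:
    """Per-frame crookedness: columns ``h``, ``d``, ``beta_deg``.

    ``h`` is the end-to-end distance between the first and last base-pair
    origins (``h_estimator="sum_helical_rise"`` selects the summed helical
    rises instead, equivalent for straight helices); ``d`` the summed
    per-step rise magnitudes (``d_estimator="polyline"`` uses the base-pair
    origin polyline length, which bounds ``h`` from above exactly);
    ``beta = arccos(h/d)`` with the ratio clamped into [0, 1] so thermal
    shift/slide noise cannot produce NaN.
    """
    traj = _traj_of(traj)
    out = _steps if _steps is not None else steps_of(traj)
    origins = out["bp_origins"]
    if h_estimator == "end_to_end":
        h = np.linalg.norm(origins[:, -1] - origins[:, 0], axis=-1)
    elif h_estimator == "sum_helical_rise":
        h = out["helical_rise"].sum(axis=1)
    else:
        raise ValueError(f"unknown h estimator {h_estimator!r}")
    if d_estimator == "sum_rise":
        d = np.abs(out["rise"]).sum(axis=1)
    elif d_estimator == "polyline":
        d = np.linalg.norm(np.diff(origins, axis=1), axis=-1).sum(axis=1)
    else:
        raise ValueError(f"unknown d estimator {d_estimator!r}")
    if np.any(d <= 0):
        raise ValueError("degenerate geometry: summed rise is zero")
    beta = np.rad2deg(np.arccos(np.clip(h / d, 0.0, 1.0)))
    return pd.DataFrame({"time_ns": traj.times_ns, "h": h, "d": d, "beta_deg": beta})


def _point_polyline_distance(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Min distance of each point (..., m, 3) to a per-batch polyline (..., k, 3)."""
    a = vertices[..., :-1, :]  # (..., k-1, 3)
    b = vertices[..., 1:, :]
    ab = b - a
    ap = points[..., :, None, :] - a[..., None, :, :]  # (..., m, k-1, 3)
    denom = np.einsum("...ki,...ki->...k", ab, ab)
    t = np.einsum("...mki,...ki->...mk", ap, ab) / denom[..., None, :]
    t = np.clip(t, 0.0, 1.0)
    closest = a[..., None, :, :] + t[..., None] * ab[..., None, :, :]
    dist = np.linalg.norm(points[..., :, None, :] - closest, axis=-1)
    return dist.min(axis=-1)


def helix_radius(traj: Trajectory | DuplexConformation, _steps: dict | None = None) -> np.ndarray:
    """Per-frame mean distance of P atoms to the base-pair-origin polyline."""
    traj = _traj_of(traj)
    mask = traj.topology.select("P")
    if not mask.any():
        raise ValueError("no phosphorus atoms present")
    out = _steps if _steps is not None else steps_of(traj)
    p_atoms = traj.coords[:, mask]
    return _point_polyline_distance(p_atoms, out["bp_origins"]).mean(axis=-1)


# ---------------------------------------------------------------------------
# Sugar pucker
# ---------------------------------------------------------------------------


def pucker_phase(nu: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pseudorotation phase P (deg, [0, 360)) and amplitude from nu0..nu4.

    Uses the standard phase formula
    ``tan P = ((nu4 + nu1) - (nu3 + nu0)) / (2 nu2 (sin 36 + sin 72))``
    resolved by the two-argument arctangent (+180 deg when nu2 < 0), with
    ``numax = nu2 / cos P``.
    """
    nu = np.asarray(nu, dtype=float)
    if nu.shape[-1] != 5:
        raise ValueError("expected five endocyclic torsions")
    num = (nu[..., 4] + nu[..., 1]) - (nu[..., 3] + nu[..., 0])
    den = 2.0 * nu[..., 2] * SIN36_SIN72
    degenerate = (np.abs(nu[..., 2]) < 1e-12) & (np.abs(num) < 1e-12)
    P = np.mod(np.rad2deg(np.arctan2(num, den)), 360.0)
    numax = nu[..., 2] / np.cos(np.deg2rad(P))
    P = np.where(degenerate, np.nan, P)
    numax = np.where(degenerate, np.nan, numax)
    return P, numax


_RING_CHAIN = ("C4'", "O4'", "C1'", "C2'", "C3'")


def ring_torsions(traj: Trajectory | DuplexConformation, strand: str, residue: int) -> np.ndarray:
    """Endocyclic torsions nu0..nu4 (deg) per frame, shape (n_frames, 5)."""
    traj = _traj_of(traj)
    top = traj.topology
    idx = {}
    for a in ("C1'", "C2'", "C3'", "C4'", "O4'"):
        if not top.has_atom(strand, residue, a):
            raise KeyError(f"residue {strand}:{residue} is missing sugar atom {a!r}")
        idx[a] = top.atom_index(strand, residue, a)
    c = {a: traj.coords[:, i] for a, i in idx.items()}
    nu = np.stack(
        [
            dihedral(c["C4'"], c["O4'"], c["C1'"], c["C2'"]),
            dihedral(c["O4'"], c["C1'"], c["C2'"], c["C3'"]),
            dihedral(c["C1'"], c["C2'"], c["C3'"], c["C4'"]),
            dihedral(c["C2'"], c["C3'"], c["C4'"], c["O4'"]),
            dihedral(c["C3'"], c["C4'"], c["O4'"], c["C1'"]),
        ],
        axis=-1,
    )
    return nu


def sugar_pucker(
    conf: Trajectory | DuplexConformation, strand: str, residue: int
) -> tuple[np.ndarray, np.ndarray]:
    """(P, numax) of one residue; scalars for a conformation, arrays per frame."""
    traj = _traj_of(conf)
    P, numax = pucker_phase(ring_torsions(traj, strand, residue))
    if isinstance(conf, DuplexConformation):
        return float(P[0]), float(numax[0])
    return P, numax


def mean_pucker(traj: Trajectory | DuplexConformation, trim: int = 1) -> np.ndarray:
    """Per-frame circular-mean pucker phase (deg) over all residues.

    ``trim`` terminal base pairs are excluded on each strand end.  The mean
    is circular (resultant-vector direction) since P is an angle.
    """
    traj = _traj_of(traj)
    n = traj.n_bp
    phases = []
    for chain in "AB":
        for res in range(1 + trim, n + 1 - trim):
            P, _ = pucker_phase(ring_torsions(traj, chain, res))
            phases.append(P)
    phases = np.deg2rad(np.stack(phases, axis=-1))
    mean = np.arctan2(np.sin(phases).mean(axis=-1), np.cos(phases).mean(axis=-1))
    return np.mod(np.rad2deg(mean), 360.0)


# ---------------------------------------------------------------------------
# Grooves and backbone substates
# ---------------------------------------------------------------------------


def minor_groove_width(
    traj: Trajectory | DuplexConformation,
    window: tuple[int, int] = (-6, -2),
    refine: float = PHOSPHATE_DIAMETER,
) -> pd.DataFrame:
    """Minor-groove width per position and frame.

    For P(i) on strand I the minimum cross-strand P-P distance over pairing
    offsets in ``window`` is found and ``refine`` (two phosphate radii,
    5.8 A) subtracted.  Returns a long DataFrame (frame, position, width_A).
    """
    traj = _traj_of(traj)
    top = traj.topology
    n = top.n_bp
    if n < 4:
        raise ValueError("duplex too short for groove analysis")
    lo, hi = window
    rows = []
    pa_idx = {r: top.atom_index("A", r, "P") for r in range(1, n + 1) if top.has_atom("A", r, "P")}
    pb_idx = {r: top.atom_index("B", r, "P") for r in range(1, n + 1) if top.has_atom("B", r, "P")}
    if not pa_idx or not pb_idx:
        raise ValueError("phosphorus atoms missing on one or both strands")
    for i, ia in pa_idx.items():
        partners = []
        for off in range(lo, hi + 1):
            j = n + 1 - (i + off)  # chain B residue at pairing position i+off
            if j in pb_idx:
                partners.append(pb_idx[j])
        if not partners:
            continue
        d = np.linalg.norm(
            traj.coords[:, ia, None, :] - traj.coords[:, partners, :], axis=-1
        ).min(axis=-1)
        for f in range(traj.n_frames):
            rows.append((f, i, d[f] - refine))
    return pd.DataFrame(rows, columns=["frame", "position", "width_A"])


def backbone_epsilon_zeta(traj: Trajectory | DuplexConformation) -> np.ndarray:
    """epsilon - zeta (deg, wrapped) for every step with complete backbone.

    epsilon(i) = C4'(i)-C3'(i)-O3'(i)-P(i+1); zeta(i) =
    C3'(i)-O3'(i)-P(i+1)-O5'(i+1).  Shape (n_frames, n_usable_steps).
    """
    import warnings

    traj = _traj_of(traj)
    top = traj.topology
    n = top.n_bp
    cols = []
    skipped = []
    for chain in "AB":
        for res in range(1, n):
            needed = [
                (chain, res, "C4'"), (chain, res, "C3'"), (chain, res, "O3'"),
                (chain, res + 1, "P"), (chain, res + 1, "O5'"),
            ]
            if not all(top.has_atom(*k) for k in needed):
                skipped.append((chain, res))
                continue
            pts = [traj.coords[:, top.atom_index(*k)] for k in needed]
            eps = dihedral(pts[0], pts[1], pts[2], pts[3])
            zeta = dihedral(pts[1], pts[2], pts[3], pts[4])
            cols.append(wrap_angle(eps - zeta))
    if skipped:
        warnings.warn(f"excluded {len(skipped)} steps with incomplete backbone", stacklevel=2)
    return np.stack(cols, axis=-1)


def bi_bii_fraction(traj: Trajectory | DuplexConformation) -> float:
    """Fraction of backbone steps in the BI substate (epsilon - zeta < 0)."""
    diff = backbone_epsilon_zeta(traj)
    return float((diff < 0.0).mean())


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


@dataclass
class BlockAverage:
    """Block-averaged mean with standard error for a correlated series."""

    mean: float
    se: float
    block_ns: float
    n_blocks: int


def block_average(
    series: np.ndarray,
    times_ns: np.ndarray,
    block_ns: float = 200.0,
    equilibration_ns: float = 200.0,
) -> BlockAverage:
    """Block-averaged mean +/- SE after discarding the equilibration window.

    The series is cut into contiguous ``block_ns`` blocks (trailing partial
    block dropped); SE = SD(block means)/sqrt(n_blocks).
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times_ns, dtype=float)
    if series.shape != times.shape:
        raise ValueError("series and times must have equal length")
    keep = times >= times[0] + equilibration_ns
    series, times = series[keep], times[keep]
    if len(series) == 0:
        raise ValueError("no data left after equilibration discard")
    rel = times - times[0]
    block_idx = np.floor(rel / block_ns).astype(int)
    n_blocks = block_idx.max() + 1
    # drop trailing partial block: a block is complete if the next block starts
    span = rel[-1] + (rel[1] - rel[0] if len(rel) > 1 else 0.0)
    if span < n_blocks * block_ns:
        n_blocks -= 1
    if n_blocks < 2:
        raise ValueError("need at least 2 complete blocks for a block-averaged SE")
    means = np.array([series[block_idx == b].mean() for b in range(n_blocks)])
    return BlockAverage(
        mean=float(means.mean()),
        se=float(means.std(ddof=1) / np.sqrt(n_blocks)),
        block_ns=float(block_ns),
        n_blocks=int(n_blocks),
    )


def correlate(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient; NaN if either series is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length 1-d series with >= 3 points")
    if x.std() == 0.0 or y.std() == 0.0:
        import warnings

        warnings.warn("zero-variance input: correlation undefined", stacklevel=2)
        return float("nan")
    from scipy.stats import pearsonr

    return float(pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# Profile assembly
# ---------------------------------------------------------------------------


def helix_profile(traj: Trajectory | DuplexConformation, groove: bool = True) -> pd.DataFrame:
    """Tidy per-frame summary of the main conformational observables.

    Columns: frame, time_ns, h, d, beta_deg, radius_A, pucker_deg,
    groove_A (optional), twist_deg_bp (end-to-end).
    """
    traj = _traj_of(traj)
    out = steps_of(traj)
    crook = crookedness(traj, _steps=out)
    radius = helix_radius(traj, _steps=out)
    pucker = mean_pucker(traj)
    twist = twist_profile(traj, "end_to_end").twist_deg_bp
    df = pd.DataFrame(
        {
            "frame": np.arange(traj.n_frames),
            "time_ns": traj.times_ns,
            "h": crook["h"],
            "d": crook["d"],
            "beta_deg": crook["beta_deg"],
            "radius_A": radius,
            "pucker_deg": pucker,
            "twist_deg_bp": twist,
        }
    )
    if groove:
        g = minor_groove_width(traj)
        df["groove_A"] = g.groupby("frame")["width_A"].mean().reindex(df["frame"]).to_numpy()
    return df
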