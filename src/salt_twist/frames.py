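"""Base, base-pair and step reference frames, and the three twist measures.

The twist of a duplex can be quantified three ways, which agree on ideal
helices but differ on bent ones:

``local_helical``
    sum of per-step helical twists (rotation angle about each step's own
    screw axis), normalized per bp;
``bp_twist``
    sum of per-step twist angles from the mid-frame construction;
``end_to_end``
    a reference frame is assigned to each end of the helix by quaternion
    averaging of terminal base-pair frames, and the twist is the rotation
    angle between the two end frames about the mean helix axis, unwrapped to
    the branch nearest the cumulative bp-twist sum.

All angles are degrees; per-bp values divide the total by (n_bp - 1) steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    kabsch,
    mean_rotation,
    rotation_about_axis,
    rotvec_of,
    signed_angle,
    unit,
    wrap_angle,
)
from .model import DuplexConformation, ReferenceFrame, Trajectory, TwistSeries

# ---------------------------------------------------------------------------
# Idealized planar base templates (standard reference frame: base in the
# xy-plane, origin on the pairing axis, y toward the strand-I backbone,
# z normal to the base plane).  Ring + carbonyl/amino atoms are used for
# frame fitting; C1' anchors the sugar during construction.
# ---------------------------------------------------------------------------

BASE_TEMPLATES: dict[str, dict[str, tuple[float, float, float]]] = {
    "A": {
        "N9": (-1.291, 4.498, 0.0),
        "C8": (0.024, 4.897, 0.0),
        "N7": (0.877, 3.902, 0.0),
        "C5": (0.071, 2.771, 0.0),
        "C6": (0.369, 1.398, 0.0),
        "N6": (1.611, 0.909, 0.0),
        "N1": (-0.668, 0.532, 0.0),
        "C2": (-1.912, 1.023, 0.0),
        "N3": (-2.320, 2.290, 0.0),
        "C4": (-1.267, 3.124, 0.0),
        "C1'": (-2.479, 5.346, 0.0),
    },
    "G": {
        "N9": (-1.289, 4.551, 0.0),
        "C8": (0.023, 4.962, 0.0),
        "N7": (0.870, 3.969, 0.0),
        "C5": (0.071, 2.833, 0.0),
        "C6": (0.424, 1.460, 0.0),
        "O6": (1.554, 0.955, 0.0),
        "N1": (-0.700, 0.641, 0.0),
        "C2": (-1.999, 1.087, 0.0),
        "N3": (-2.342, 2.364, 0.0),
        "C4": (-1.265, 3.177, 0.0),
        "C1'": (-2.477, 5.399, 0.0),
    },
    "C": {
        "N1": (-1.285, 4.542, 0.0),
        "C2": (-1.472, 3.158, 0.0),
        "O2": (-2.628, 2.709, 0.0),
        "N3": (-0.391, 2.344, 0.0),
        "C4": (0.837, 2.868, 0.0),
        "N4": (1.875, 2.027, 0.0),
        "C5": (1.056, 4.275, 0.0),
        "C6": (-0.023, 5.068, 0.0),
        "C1'": (-2.477, 5.402, 0.0),
    },
    "T": {
        "N1": (-1.284, 4.500, 0.0),
        "C2": (-1.462, 3.135, 0.0),
        "O2": (-2.562, 2.608, 0.0),
        "N3": (-0.298, 2.407, 0.0),
        "C4": (0.994, 2.897, 0.0),
        "O4": (1.944, 2.119, 0.0),
        "C5": (1.106, 4.338, 0.0),
        "C6": (-0.024, 5.057, 0.0),
        "C1'": (-2.481, 5.354, 0.0),
    },
}

#: atoms used for least-squares base-frame fitting, per base
RING_ATOMS: dict[str, tuple[str, ...]] = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N3", "C4"),
    "C": ("N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"),
    "T": ("N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"),
}

#: glycosidic nitrogen and its in-ring neighbour used to anchor the sugar
GLYCOSIDIC = {"A": ("N9", "C4"), "G": ("N9", "C4"), "C": ("N1", "C2"), "T": ("N1", "C2")}

#: axis flip applied to complementary-strand frames (negate y and z)
FLIP = np.diag([1.0, -1.0, -1.0])


def template_coords(base: str, atoms) -> np.ndarray:
    tpl = BASE_TEMPLATES[base]
    return np.array([tpl[a] for a in atoms], dtype=float)


# ---------------------------------------------------------------------------
# Frame fitting
# ---------------------------------------------------------------------------


def fit_base_frame(conf: DuplexConformation, strand: str, residue_index: int) -> ReferenceFrame:
    """Fit the reference frame of one base by rigid template superposition.

    The idealized planar template of the residue's base is superposed onto
    the observed ring atoms by least squares (proper rotation only); the
    frame origin is the transformed template origin.
    """
    base = conf.topology.base(strand, residue_index)
    names = RING_ATOMS[base]
    idx = []
    for a in names:
        if not conf.topology.has_atom(strand, residue_index, a):
            raise KeyError(f"residue {strand}:{residue_index} is missing base atom {a!r}")
        idx.append(conf.topology.atom_index(strand, residue_index, a))
    observed = conf.coords[idx]
    centered = observed - observed.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError(f"ring atoms of {strand}:{residue_index} are collinear/degenerate")
    R, t = kabsch(template_coords(base, names), observed)
    frame = ReferenceFrame(t, R)
    frame.validate(tol=1e-6)
    return frame


def _traj_of(obj) -> Trajectory:
    if isinstance(obj, Trajectory):
        return obj
    if isinstance(obj, DuplexConformation):
        return Trajectory(obj.topology, obj.coords[None])
    raise TypeError(f"expected Trajectory or DuplexConformation, got {type(obj)!r}")


def all_base_frames(traj: Trajectory | DuplexConformation) -> tuple[np.ndarray, np.ndarray]:
    """Base frames of every residue on both strands, batched over frames.

    Returns ``(axes, origins)`` with shapes (n_frames, 2, n_bp, 3, 3) and
    (n_frames, 2, n_bp, 3); index 0 along the strand axis is chain A residue
    ``i+1``, index 1 its chain-B partner.
    """
    traj = _traj_of(traj)
    top = traj.topology
    n_bp, F = top.n_bp, traj.n_frames
    axes = np.empty((F, 2, n_bp, 3, 3))
    origins = np.empty((F, 2, n_bp, 3))
    # group (strand, bp) slots by base type so each group fits in one batch
    groups: dict[str, list[tuple[int, int, list[int]]]] = {}
    for bp in range(1, n_bp + 1):
        res_a, res_b = top.paired_residues(bp)
        for s_idx, (chain, res) in enumerate((("A", res_a), ("B", res_b))):
            base = top.base(chain, res)
            idx = [top.atom_index(chain, res, a) for a in RING_ATOMS[base]]
            groups.setdefault(base, []).append((s_idx, bp - 1, idx))
    for base, slots in groups.items():
        tpl = template_coords(base, RING_ATOMS[base])
        gather = np.array([idx for _, _, idx in slots])  # (n_slot, n_ring)
        obs = traj.coords[:, gather]  # (F, n_slot, n_ring, 3)
        R, t = kabsch(tpl, obs)
        for j, (s_idx, col, _) in enumerate(slots):
            axes[:, s_idx, col] = R[:, j]
            origins[:, s_idx, col] = t[:, j]
    return axes, origins


def bp_frame(f1: ReferenceFrame, f2: ReferenceFrame) -> ReferenceFrame:
    """Base-pair frame: flip the complementary frame, then average.

    The partner frame's y and z axes are negated (anti-parallel convention),
    the origin is the midpoint and the orientation the quaternion mean of the
    two rotations.  Warns if the frames are not approximately anti-parallel.
    """
    import warnings

    R2f = f2.axes @ FLIP
    if float(f1.z @ R2f[:, 2]) < 0:
        warnings.warn(
            "base frames are not anti-parallel after flipping; dubious pairing",
            stacklevel=2,
        )
    axes = mean_rotation(np.stack([f1.axes, R2f]))
    return ReferenceFrame((f1.origin + f2.origin) / 2.0, axes)


def all_bp_frames(traj: Trajectory | DuplexConformation) -> tuple[np.ndarray, np.ndarray]:
    """Base-pair frames per frame: (n_frames, n_bp, 3, 3), (n_frames, n_bp, 3)."""
    axes, origins = all_base_frames(traj)
    flipped = axes[:, 1] @ FLIP
    stacked = np.stack([axes[:, 0], flipped], axis=-3)  # (F, n_bp, 2, 3, 3)
    bp_axes = mean_rotation(stacked)
    bp_origins = origins.mean(axis=1)
    return bp_axes, bp_origins


# ---------------------------------------------------------------------------
# Step parameters (mid-frame construction, exactly invertible)
# ---------------------------------------------------------------------------


@dataclass
class StepParams:
    """Rigid-body parameters of one base-pair step."""

    twist: float
    roll: float
    tilt: float
    shift: float
    slide: float
    rise: float
    helical_twist: float
    helical_rise: float


def _steps_batch(R1, R2, o1, o2) -> dict[str, np.ndarray]:
    """Mid-frame step parameters for batched frame pairs.

    ``R*`` are (..., 3, 3) with axis columns, ``o*`` (..., 3).  Returns a dict
    of parameter arrays plus the mid-frame for reuse.
    """
    z1, z2 = R1[..., :, 2], R2[..., :, 2]
    cosg = np.clip(np.einsum("...i,...i->...", z1, z2), -1.0, 1.0)
    gamma = np.rad2deg(np.arccos(cosg))
    hinge_raw = np.cross(z1, z2)
    hnorm = np.linalg.norm(hinge_raw, axis=-1, keepdims=True)
    # parallel z-axes: rotation by gamma/2 ~ identity about any perpendicular
    fallback = R1[..., :, 0]
    hinge = np.where(hnorm > 1e-12, hinge_raw / np.where(hnorm == 0, 1.0, hnorm), fallback)
    R1p = rotation_about_axis(hinge, gamma / 2.0) @ R1
    R2p = rotation_about_axis(hinge, -gamma / 2.0) @ R2
    zm = R1p[..., :, 2]
    x1p, x2p = R1p[..., :, 0], R2p[..., :, 0]
    twist = signed_angle(x1p, x2p, zm)
    xm = unit(x1p + x2p)
    ym = np.cross(zm, xm)
    Rm = np.stack([xm, ym, zm], axis=-1)
    disp = o2 - o1
    local = np.einsum("...ji,...j->...i", Rm, disp)
    phi = signed_angle(hinge, ym, zm)
    roll = gamma * np.cos(np.deg2rad(phi))
    tilt = gamma * np.sin(np.deg2rad(phi))
    # screw decomposition of the full relative rotation
    A = np.einsum("...ji,...jk->...ik", R1, R2)
    rv = rotvec_of(A)
    theta = np.linalg.norm(rv, axis=-1)
    zm_local = np.einsum("...ji,...j->...i", R1, zm)
    axis = np.where(theta[..., None] > 1e-12, rv / np.where(theta[..., None] == 0, 1.0, theta[..., None]), zm_local)
    sgn = np.sign(np.einsum("...i,...i->...", axis, zm_local))
    sgn = np.where(sgn == 0, 1.0, sgn)
    axis = axis * sgn[..., None]
    helical_twist = np.rad2deg(theta) * sgn
    axis_global = np.einsum("...ij,...j->...i", R1, axis)
    helical_rise = np.einsum("...i,...i->...", disp, axis_global)
    return {
        "twist": twist,
        "roll": roll,
        "tilt": tilt,
        "shift": local[..., 0],
        "slide": local[..., 1],
        "rise": local[..., 2],
        "helical_twist": helical_twist,
        "helical_rise": helical_rise,
        "mid_axes": Rm,
    }


def step_params(bp1: ReferenceFrame, bp2: ReferenceFrame) -> StepParams:
    """Step parameters between two consecutive base-pair frames."""
    out = _steps_batch(bp1.axes, bp2.axes, bp1.origin, bp2.origin)
    return StepParams(
        twist=float(out["twist"]),
        roll=float(out["roll"]),
        tilt=float(out["tilt"]),
        shift=float(out["shift"]),
        slide=float(out["slide"]),
        rise=float(out["rise"]),
        helical_twist=float(out["helical_twist"]),
        helical_rise=float(out["helical_rise"]),
    )


def _rebuild_batch(R1, o1, twist, roll, tilt, shift, slide, rise):
    """Inverse of :func:`_steps_batch`: construct frame 2 from frame 1."""
    twist, roll, tilt = (np.asarray(v, dtype=float) for v in (twist, roll, tilt))
    gamma = np.hypot(roll, tilt)
    phi = np.rad2deg(np.arctan2(tilt, roll))
    sphi, cphi = np.sin(np.deg2rad(phi)), np.cos(np.deg2rad(phi))
    hinge_local = np.stack([sphi, cphi, np.zeros_like(sphi)], axis=-1)
    z_axis = np.array([0.0, 0.0, 1.0])
    z_local = np.broadcast_to(z_axis, hinge_local.shape)
    B1 = rotation_about_axis(hinge_local, -gamma / 2.0) @ rotation_about_axis(z_local, -twist / 2.0)
    M = R1 @ np.swapaxes(B1, -1, -2)
    R2 = M @ rotation_about_axis(hinge_local, gamma / 2.0) @ rotation_about_axis(z_local, twist / 2.0)
    disp_local = np.stack(
        [np.broadcast_to(np.asarray(shift, float), gamma.shape),
         np.broadcast_to(np.asarray(slide, float), gamma.shape),
         np.broadcast_to(np.asarray(rise, float), gamma.shape)],
        axis=-1,
    )
    o2 = o1 + np.einsum("...ij,...j->...i", M, disp_local)
    return R2, o2


def rebuild_step(bp1: ReferenceFrame, params: StepParams) -> ReferenceFrame:
    """Reconstruct the second base-pair frame from the first and step params."""
    R2, o2 = _rebuild_batch(
        bp1.axes, bp1.origin, params.twist, params.roll, params.tilt,
        params.shift, params.slide, params.rise,
    )
    return ReferenceFrame(o2, R2)


def steps_of(traj: Trajectory | DuplexConformation) -> dict[str, np.ndarray]:
    """All per-step parameters of a trajectory, arrays of shape (F, n_bp-1)."""
    axes, origins = all_bp_frames(traj)
    out = _steps_batch(axes[:, :-1], axes[:, 1:], origins[:, :-1], origins[:, 1:])
    out.pop("mid_axes")
    out["bp_axes"] = axes
    out["bp_origins"] = origins
    return out


# ---------------------------------------------------------------------------
# Twist measures
# ---------------------------------------------------------------------------


def _end_to_end_from_frames(axes, origins, bp_twist_sum, terminal_k: int) -> np.ndarray:
    """Total end-to-end twist (deg) per frame from bp-frame arrays.

    ``axes`` (F, n, 3, 3), ``origins`` unused except for API symmetry,
    ``bp_twist_sum`` (F,) anchors the 360-degree branch.
    """
    n = axes.shape[1]
    k = int(terminal_k)
    if not 1 <= k <= n // 2:
        raise ValueError("terminal_k must satisfy 1 <= k <= n_bp/2")
    first = mean_rotation(axes[:, :k]) if k > 1 else axes[:, 0]
    last = mean_rotation(axes[:, n - k:]) if k > 1 else axes[:, -1]
    z1, z2 = first[..., :, 2], last[..., :, 2]
    n_axis = unit(z1 + z2)
    x1, x2 = first[..., :, 0], last[..., :, 0]
    x1p = x1 - np.einsum("...i,...i->...", x1, n_axis)[..., None] * n_axis
    x2p = x2 - np.einsum("...i,...i->...", x2, n_axis)[..., None] * n_axis
    raw = signed_angle(x1p, x2p, n_axis)
    total = raw + 360.0 * np.round((bp_twist_sum - raw) / 360.0)
    return total


def end_to_end_twist(
    traj: Trajectory | DuplexConformation,
    terminal_k: int = 1,
    reference: Trajectory | float | None = None,
) -> TwistSeries:
    """End-to-end twist per bp, per frame.

    End frames are quaternion means of the first/last ``terminal_k`` bp
    frames; the raw angle between them about the mean helix axis is unwrapped
    to the branch nearest the cumulative bp-twist sum and normalized by the
    number of steps.  ``reference`` (a trajectory or a per-bp value) sets the
    baseline for reported changes.
    """
    traj = _traj_of(traj)
    if traj.n_bp < 2:
        raise ValueError("need at least 2 bp")
    out = steps_of(traj)
    anchor = out["twist"].sum(axis=1)
    total = _end_to_end_from_frames(out["bp_axes"], out["bp_origins"], anchor, terminal_k)
    per_bp = total / (traj.n_bp - 1)
    ref_value = None
    if reference is not None:
        if isinstance(reference, (int, float)):
            ref_value = float(reference)
        else:
            ref_series = end_to_end_twist(reference, terminal_k=terminal_k)
            ref_value = float(ref_series.twist_deg_bp.mean())
    return TwistSeries("end_to_end", per_bp, traj.times_ns, ref_value)


def twist_profile(traj: Trajectory | DuplexConformation, method: str) -> TwistSeries:
    """Per-frame twist per bp by any of the three definitions."""
    traj = _traj_of(traj)
    if method not in TwistSeries.VALID_METHODS:
        raise ValueError(f"unknown twist method {method!r}; choose from {TwistSeries.VALID_METHODS}")
    if method == "end_to_end":
        return end_to_end_twist(traj)
    out = steps_of(traj)
    key = "helical_twist" if method == "local_helical" else "twist"
    per_bp = out[key].sum(axis=1) / (traj.n_bp - 1)
    return TwistSeries(method, per_bp, traj.times_ns)


def subhelix_scan(
    traj: Trajectory | DuplexConformation,
    min_len: int = 2,
    method: str = "end_to_end",
    terminal_k: int = 1,
):
    """Per-bp twist of centered sub-helices vs sub-helix length.

    Ends are trimmed symmetrically; returns a DataFrame with columns
    ``length``, ``twist_deg_bp`` (mean over frames) and ``se`` (standard
    error of the mean over frames).
    """
    import pandas as pd

    traj = _traj_of(traj)
    n = traj.n_bp
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    if min_len > n:
        raise ValueError(f"min_len={min_len} exceeds helix length {n}")
    out = steps_of(traj)
    axes, origins, omega = out["bp_axes"], out["bp_origins"], out["twist"]
    rows = []
    for length in range(min_len, n + 1):
        start = (n - length) // 2
        sl = slice(start, start + length)
        sub_axes = axes[:, sl]
        sub_origins = origins[:, sl]
        anchor = omega[:, start:start + length - 1].sum(axis=1)
        k = min(terminal_k, length // 2)
        total = _end_to_end_from_frames(sub_axes, sub_origins, anchor, k)
        if method == "bp_twist":
            per_bp = anchor / (length - 1)
        elif method == "local_helical":
            per_bp = out["helical_twist"][:, start:start + length - 1].sum(axis=1) / (length - 1)
        else:
            per_bp = total / (length - 1)
        se = per_bp.std(ddof=1) / np.sqrt(len(per_bp)) if len(per_bp) > 1 else 0.0
        rows.append({"length": length, "twist_deg_bp": per_bp.mean(), "se": se})
    return pd.DataFrame(rows)
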