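"""Synthetic duplex trajectories, ion clouds and tweezers data with known truth.

This module stands in for the molecular-dynamics trajectories and
magnetic-tweezers recordings the analysis pipeline is designed for.  It
generates

* idealized or fluctuating B-DNA duplex conformations built residue by
  residue from prescribed base-pair step parameters and sugar puckers
  (the construction is the exact inverse of the analysis in
  :mod:`salt_twist.frames`, so re-analysis round-trips the inputs);
* ion clouds with a radially decaying excess density around the helical
  axis plus optional site-pinned ions at phosphate or nucleobase sites;
* rotation-extension curves with a rounded (Gaussian) apex and linear
  plectonemic wings;
* twist-vs-concentration tables following dTw = A c^B + C.

Every generator takes an explicit seed; none touches global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .frames import BASE_TEMPLATES, FLIP, GLYCOSIDIC, _rebuild_batch, template_coords
from .geometry import dihedral, nerf, unit, wrap_angle
from .model import (
    ConcSeries,
    DuplexConformation,
    DuplexTopology,
    IonFrames,
    RESNAME,
    RotExtCurve,
    Trajectory,
    reverse_complement,
)

#: 33-bp duplex sequence of the reference simulation system, written 3'->5'
REFERENCE_SEQUENCE_3TO5 = "GAGATGCTAACCCTGATCGCTGATTCCTTGGAC"
#: the same sequence read 5'->3' on strand I
REFERENCE_SEQUENCE = REFERENCE_SEQUENCE_3TO5[::-1]

#: Avogadro constant (1/mol)
N_AVOGADRO = 6.02214076e23
#: cubic Angstrom in litres
A3_TO_L = 1e-27

VALENCE = {"LI": 1, "NA": 1, "K": 1, "RB": 1, "CS": 1, "MG": 2, "CA": 2, "SR": 2, "BA": 2}

# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


def _per_step(value, n_steps: int, name: str) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(value, dtype=float), (n_steps,)).copy()
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


@dataclass
class DuplexSpec:
    """Ground-truth geometry of a duplex: sequence, step parameters, puckers.

    ``sequence`` is strand I read 5'->3'; per-step parameter lists have
    length ``len(sequence) - 1`` (scalars broadcast); ``pucker_P`` is the
    pseudorotation phase per residue (scalar broadcasts over all residues of
    both strands).
    """

    sequence: str = REFERENCE_SEQUENCE
    twist: float | np.ndarray = 34.286  # deg
    roll: float | np.ndarray = 0.0
    tilt: float | np.ndarray = 0.0
    shift: float | np.ndarray = 0.0  # A
    slide: float | np.ndarray = 0.0
    rise: float | np.ndarray = 3.4
    pucker_P: float | np.ndarray = 147.0  # deg, South (B-form)
    pucker_amplitude: float = 38.0  # deg

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 2:
            raise ValueError("sequence must have at least 2 bp")
        if any(b not in "ACGT" for b in self.sequence):
            bad = next(b for b in self.sequence if b not in "ACGT")
            raise ValueError(f"non-ACGT character in sequence: {bad!r}")
        n = self.n_bp
        for name in ("twist", "roll", "tilt", "shift", "slide", "rise"):
            setattr(self, name, _per_step(getattr(self, name), n - 1, name))
        if np.any(self.rise <= 0):
            raise ValueError("rise must be positive")
        self.pucker_P = np.broadcast_to(
            np.asarray(self.pucker_P, dtype=float), (2 * n,)
        ).copy()

    @property
    def n_bp(self) -> int:
        return len(self.sequence)

    @property
    def complement(self) -> str:
        return reverse_complement(self.sequence)


@dataclass
class FluctuationSpec:
    """Frame-to-frame Gaussian fluctuation magnitudes (thermal surrogate)."""

    sd_twist: float = 4.0  # deg
    sd_roll: float = 4.0
    sd_tilt: float = 3.0
    sd_shift: float = 0.3  # A
    sd_slide: float = 0.3
    sd_rise: float = 0.3
    sd_pucker: float = 8.0  # deg
    n_frames: int = 100
    frame_dt: float = 0.1  # ns per frame; 200-ns blocks are 2000 frames
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sd_twist", "sd_roll", "sd_tilt", "sd_shift", "sd_slide", "sd_rise", "sd_pucker"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


@dataclass
class IonCloudSpec:
    """Ion-cloud model: bulk + Gaussian radial excess + site-pinned ions."""

    species: str = "K"
    valence: int | None = None
    bulk_mM: float = 100.0
    excess_molar: float = 0.0  # mol/L amplitude of the radial excess
    decay_A: float = 3.0  # Gaussian width of the excess shell
    preferred_radius_A: float = 9.5
    n_bound_backbone: int = 0
    n_bound_base: int = 0
    pinned_distance_A: float = 2.3
    cylinder_radius_A: float = 30.0
    z_padding_A: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.species = self.species.upper()
        if self.valence is None:
            self.valence = VALENCE.get(self.species, 1)
        if self.bulk_mM < 0:
            raise ValueError("bulk concentration must be >= 0")
        if self.decay_A <= 0:
            raise ValueError("decay length must be positive")
        if self.n_bound_backbone < 0 or self.n_bound_base < 0:
            raise ValueError("pinned-ion counts must be >= 0")


@dataclass
class CurveSpec:
    """Rotation-extension curve model: Gaussian cap + linear plectonemic wings."""

    n_max: float = 0.0  # turns, torsionally relaxed point
    cap_width: float = 8.0  # turns
    cap_depth: float = 0.25  # um
    wing_slope: float = -0.04  # um per turn of |n - n_max| past buckling
    buckling_offset: float = 12.0  # turns
    apex_extension: float = 2.2  # um
    noise_sd: float = 0.0  # um
    turns: np.ndarray = field(default_factory=lambda: np.arange(-24.0, 25.0, 2.0))
    seed: int = 0

    def __post_init__(self) -> None:
        self.turns = np.asarray(self.turns, dtype=float)
        if self.turns.size == 0:
            raise ValueError("turn grid must not be empty")
        if np.any(np.diff(self.turns) <= 0):
            raise ValueError("turn grid must be strictly increasing")
        if self.cap_width <= 0 or self.cap_depth < 0:
            raise ValueError("cap width must be > 0 and depth >= 0")
        if self.wing_slope >= 0:
            raise ValueError("wing slope must be negative (extension loss per turn)")


# ---------------------------------------------------------------------------
# Sugar ring construction (pseudorotation -> coordinates)
# ---------------------------------------------------------------------------

# Endocyclic torsion convention (Altona-Sundaralingam numbering):
#   nu0: C4'-O4'-C1'-C2'   nu1: O4'-C1'-C2'-C3'   nu2: C1'-C2'-C3'-C4'
#   nu3: C2'-C3'-C4'-O4'   nu4: C3'-C4'-O4'-C1'


def pucker_torsions(P_deg, numax_deg) -> np.ndarray:
    """Endocyclic torsions nu0..nu4 (deg) from pseudorotation phase/amplitude."""
    P = np.asarray(P_deg, dtype=float)
    numax = np.asarray(numax_deg, dtype=float)
    j = np.arange(5.0)
    return numax[..., None] * np.cos(np.deg2rad(P[..., None] + 144.0 * (j - 2.0)))


_BOND_CC = 1.526
_BOND_C4O4 = 1.446

#: continuation cache: numax -> (P grid, theta grid) of the smooth solution
#: branch of the ring-closure equations
_RING_BRANCH: dict[float, tuple[np.ndarray, np.ndarray]] = {}


def _ring_theta_guess(P: np.ndarray, numax: float) -> np.ndarray:
    """Initial bond angles from a continuation sweep around the pucker circle.

    The closure equations have multiple roots; a smooth branch is traced once
    per amplitude by Newton continuation over a fine P grid starting from the
    planar-ish solution at P = 90 deg, then interpolated.
    """
    key = round(float(numax), 6)
    if key not in _RING_BRANCH:
        grid = np.arange(90.0, 90.0 + 360.0 + 1.0, 1.0)
        thetas = np.empty((len(grid), 5))
        theta = np.array([102.0, 102.5, 105.5, 0.0, 0.0])
        for i, p in enumerate(grid):
            theta = _solve_ring_single(np.array([p % 360.0]), numax, theta[None])[0]
            thetas[i] = theta
        order = np.argsort(grid % 360.0, kind="stable")
        pg = (grid % 360.0)[order][:361]
        tg = thetas[order][:361]
        _RING_BRANCH[key] = (pg, tg)
    pg, tg = _RING_BRANCH[key]
    p = np.mod(P, 360.0)
    out = np.empty(P.shape + (5,))
    for k in range(5):
        out[..., k] = np.interp(p, pg, tg[:, k], period=360.0)
    return out


def solve_sugar_ring(P_deg, numax_deg, tol: float = 1e-12, max_iter: int = 60) -> np.ndarray:
    """Five-membered ring coordinates realizing the pseudorotation torsions.

    Batched Newton solve: atoms C1', C2', C3', C4', O4' (in that order, C1'
    at the origin) are chained with the target torsions nu2 and nu3 imposed
    directly, and the three free bond angles adjusted until nu0, nu1 and nu4
    also match.  Bond angles and the O4'-C1' closure bond float; the five
    torsions are exact to ``tol`` degrees.
    """
    P = np.atleast_1d(np.asarray(P_deg, dtype=float))
    numax_arr = np.broadcast_to(np.asarray(numax_deg, dtype=float), P.shape)
    if np.ptp(numax_arr) > 1e-12:
        raise ValueError("solve_sugar_ring expects a single amplitude per call")
    numax = float(numax_arr.flat[0])
    theta0 = _ring_theta_guess(P, numax)
    theta, coords = _solve_ring_newton(P, numax, theta0, tol, max_iter, return_coords=True)
    return coords


def _solve_ring_single(P, numax, theta0, tol=1e-12, max_iter=60):
    theta, _ = _solve_ring_newton(np.asarray(P, float), numax, theta0, tol, max_iter, return_coords=False)
    return theta


def _solve_ring_newton(P, numax: float, theta0, tol, max_iter, return_coords: bool):
    numax_b = np.broadcast_to(numax, P.shape)
    targets = pucker_torsions(P, numax_b)  # (..., 5)

    def place(theta):
        t1, t2, t3 = theta[..., 0], theta[..., 1], theta[..., 2]
        b3 = _BOND_CC * np.exp(theta[..., 3])
        b4 = _BOND_C4O4 * np.exp(theta[..., 4])
        shape = t1.shape
        c1 = np.zeros(shape + (3,))
        c2 = np.zeros(shape + (3,))
        c2[..., 0] = _BOND_CC
        c3 = c2.copy()
        c3[..., 0] -= _BOND_CC * np.cos(np.deg2rad(t1))
        c3[..., 1] += _BOND_CC * np.sin(np.deg2rad(t1))
        c4 = nerf(c1, c2, c3, b3, t2, targets[..., 2])
        o4 = nerf(c2, c3, c4, b4, t3, targets[..., 3])
        return c1, c2, c3, c4, o4

    def residual(theta):
        c1, c2, c3, c4, o4 = place(theta)
        r = np.stack(
            [
                wrap_angle(dihedral(c4, o4, c1, c2) - targets[..., 0]),
                wrap_angle(dihedral(o4, c1, c2, c3) - targets[..., 1]),
                wrap_angle(dihedral(c3, c4, o4, c1) - targets[..., 4]),
            ],
            axis=-1,
        )
        return r

    # 5 unknowns (3 bond angles + 2 log-bond stretches), 3 torsion equations;
    # minimal-norm Newton steps keep the solution near ideal sugar geometry.
    # Log-bond coordinates are scaled so a unit step is comparable to degrees.
    theta = np.array(theta0, dtype=float, copy=True)
    h = 1e-6
    scale = np.array([1.0, 1.0, 1.0, 0.02, 0.02])
    for _ in range(max_iter):
        r = residual(theta)
        if np.max(np.abs(r)) < tol:
            break
        J = np.empty(P.shape + (3, 5))
        for k in range(5):
            dp = np.zeros(5)
            dp[k] = h * scale[k]
            J[..., :, k] = (residual(theta + dp) - residual(theta - dp)) / (2 * h * scale[k])
        Js = J * scale
        JJt = np.einsum("...ik,...jk->...ij", Js, Js)
        JJt += 1e-12 * np.eye(3)
        lam = np.linalg.solve(JJt, r[..., None])[..., 0]
        step = np.einsum("...ik,...i->...k", Js, lam) * scale
        step = np.clip(step, -10.0, 10.0)
        theta = theta - step
    if not return_coords:
        return theta, None
    c1, c2, c3, c4, o4 = place(theta)
    return theta, np.stack([c1, c2, c3, c4, o4], axis=-2)


# ---------------------------------------------------------------------------
# Nucleotide assembly constants (idealized internal coordinates; the exact
# values are frozen after calibrating backbone continuity on an ideal B-helix)
# ---------------------------------------------------------------------------

# Values calibrated once so that an ideal B-helix (twist 34.286 deg, rise
# 3.4 A, pucker P = 147 deg) has a continuous backbone: the O3'(i)-P(i+1)
# distance comes out at 1.60 +/- 0.01 A on both strands.
CHI_DEG = -160.19  # glycosidic torsion (high-anti)
ANG_N_C1_O4 = 108.2
TAU_SPIN = 175.82  # torsion N-C1'-O4'-C4' fixing the ring orientation
DELTA_C5 = -98.13  # C5' torsion offset from nu3 about the C3'-C4' axis
DELTA_O3 = 117.95  # O3' torsion offset from nu2 about the C2'-C3' axis
GAMMA_TORS = 57.56  # C3'-C4'-C5'-O5'
BETA_TORS = -142.16  # C4'-C5'-O5'-P
OP_TORS = (-65.0, 175.0)  # C5'-O5'-P-O1P / O2P

_BACKBONE_ATOMS = ("P", "O1P", "O2P", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'")


def _residue_atom_names(base: str) -> list[str]:
    base_atoms = [a for a in BASE_TEMPLATES[base] if a != "C1'"]
    return list(_BACKBONE_ATOMS) + base_atoms


def _element_of(name: str) -> str:
    return name[0] if name[0] != "O" or not name.startswith("O") else "O"


def build_topology(sequence: str) -> DuplexTopology:
    """Atom table of a duplex with the given strand-I sequence."""
    sequence = sequence.upper()
    comp = reverse_complement(sequence)
    chain, res_id, res_name, atom_name = [], [], [], []
    for cid, seq in (("A", sequence), ("B", comp)):
        for i, b in enumerate(seq, start=1):
            for a in _residue_atom_names(b):
                chain.append(cid)
                res_id.append(i)
                res_name.append(RESNAME[b])
                atom_name.append(a)
    element = [n[0] for n in atom_name]
    return DuplexTopology(
        sequence,
        np.array(chain),
        np.array(res_id),
        np.array(res_name),
        np.array(atom_name),
        np.array(element),
    )


def _bp_frames_from_steps(step_arrays: dict[str, np.ndarray], n_frames: int, n_bp: int):
    """Chain base-pair frames from per-frame step parameters.

    ``step_arrays`` values have shape (n_frames, n_bp - 1).  The first bp
    frame is the identity at the origin.
    """
    axes = np.empty((n_frames, n_bp, 3, 3))
    origins = np.zeros((n_frames, n_bp, 3))
    axes[:, 0] = np.eye(3)
    for s in range(n_bp - 1):
        R2, o2 = _rebuild_batch(
            axes[:, s],
            origins[:, s],
            step_arrays["twist"][:, s],
            step_arrays["roll"][:, s],
            step_arrays["tilt"][:, s],
            step_arrays["shift"][:, s],
            step_arrays["slide"][:, s],
            step_arrays["rise"][:, s],
        )
        axes[:, s + 1] = R2
        origins[:, s + 1] = o2
    return axes, origins


def _kabsch_three_point(local: np.ndarray, target: np.ndarray):
    """Rigid transform mapping three local points exactly onto three targets."""
    from .geometry import kabsch

    return kabsch(local, target) if local.ndim == 2 else None


def _build_residues(topology: DuplexTopology, bp_axes, bp_origins, pucker_P, numax):
    """Place all atoms.  Shapes: bp_axes (F, n, 3, 3); pucker_P (F, 2n)."""
    from .geometry import kabsch

    F = bp_axes.shape[0]
    n = topology.n_bp
    coords = np.empty((F, topology.n_atoms, 3))

    # residue slots: (chain_idx 0/1, res_id) -> base, frame index, pucker col
    slots = []
    for cid_idx, cid in enumerate("AB"):
        for res in range(1, n + 1):
            bp = res if cid == "A" else n + 1 - res
            slots.append((cid, res, topology.base(cid, res), bp - 1, cid_idx * n + res - 1))

    rings = solve_sugar_ring(pucker_P, numax)  # (F, 2n, 5, 3) local rings
    nu = pucker_torsions(pucker_P, np.broadcast_to(np.asarray(numax, float), pucker_P.shape))

    by_base: dict[str, list] = {}
    for slot in slots:
        by_base.setdefault(slot[2], []).append(slot)

    for base, group in by_base.items():
        tpl_names = [a for a in BASE_TEMPLATES[base]]
        tpl = template_coords(base, tpl_names)  # includes C1'
        frame_idx = np.array([g[3] for g in group])
        puck_idx = np.array([g[4] for g in group])
        flip = np.array([1.0 if g[0] == "A" else -1.0 for g in group])
        R = bp_axes[:, frame_idx].copy()  # (F, m, 3, 3)
        R[..., :, 1] *= flip[None, :, None]
        R[..., :, 2] *= flip[None, :, None]
        o = bp_origins[:, frame_idx]
        base_global = o[:, :, None, :] + np.einsum("fmij,aj->fmai", R, tpl)
        name_to_col = {nm: k for k, nm in enumerate(tpl_names)}
        n_atom, n_nb = GLYCOSIDIC[base]
        N = base_global[:, :, name_to_col[n_atom]]
        NB = base_global[:, :, name_to_col[n_nb]]
        C1 = base_global[:, :, name_to_col["C1'"]]

        ring = rings[:, puck_idx]  # (F, m, 5, 3): C1',C2',C3',C4',O4' local
        d_o4 = np.linalg.norm(ring[..., 4, :] - ring[..., 0, :], axis=-1)
        d_c4o4 = np.linalg.norm(ring[..., 4, :] - ring[..., 3, :], axis=-1)
        v1 = ring[..., 0, :] - ring[..., 4, :]
        v2 = ring[..., 3, :] - ring[..., 4, :]
        cosang = np.einsum("...i,...i->...", unit(v1), unit(v2))
        ang_c1_o4_c4 = np.rad2deg(np.arccos(np.clip(cosang, -1.0, 1.0)))

        O4 = nerf(NB, N, C1, d_o4, ANG_N_C1_O4, CHI_DEG)
        C4 = nerf(N, C1, O4, d_c4o4, ang_c1_o4_c4, TAU_SPIN)
        # map the solved ring onto the placed (C1', O4', C4') anchor triplet
        local_anchor = ring[..., [0, 4, 3], :]
        target_anchor = np.stack([C1, O4, C4], axis=-2)
        ca, cb = local_anchor.mean(axis=-2), target_anchor.mean(axis=-2)
        H = np.einsum("...mi,...mj->...ij", local_anchor - ca[..., None, :], target_anchor - cb[..., None, :])
        U, _, Vt = np.linalg.svd(H)
        dsign = np.sign(np.linalg.det(np.einsum("...ij,...jk->...ik", U, Vt)))
        D = np.zeros(H.shape)
        D[..., 0, 0] = 1.0
        D[..., 1, 1] = 1.0
        D[..., 2, 2] = dsign
        Rr = np.einsum("...ji,...jk,...lk->...il", Vt, D, U)
        tr = cb - np.einsum("...ij,...j->...i", Rr, ca)
        ring_global = np.einsum("...ij,...aj->...ai", Rr, ring) + tr[..., None, :]
        C1g, C2g, C3g, C4g, O4g = (ring_global[..., k, :] for k in range(5))

        nu2 = nu[:, puck_idx, 2]
        nu3 = nu[:, puck_idx, 3]
        C5 = nerf(C2g, C3g, C4g, 1.510, 114.7, nu3 + DELTA_C5)
        O3 = nerf(C1g, C2g, C3g, 1.423, 112.0, nu2 + DELTA_O3)
        O5 = nerf(C3g, C4g, C5, 1.440, 110.2, GAMMA_TORS)
        Patom = nerf(C4g, C5, O5, 1.593, 120.9, BETA_TORS)
        O1P = nerf(C5, O5, Patom, 1.485, 107.9, OP_TORS[0])
        O2P = nerf(C5, O5, Patom, 1.485, 107.9, OP_TORS[1])

        placed = {
            "P": Patom, "O1P": O1P, "O2P": O2P, "O5'": O5, "C5'": C5,
            "C4'": C4g, "O4'": O4g, "C3'": C3g, "O3'": O3, "C2'": C2g, "C1'": C1g,
        }
        for m, (cid, res, b, _, _) in enumerate(group):
            for nm in _residue_atom_names(b):
                ai = topology.atom_index(cid, res, nm)
                if nm in placed:
                    coords[:, ai] = placed[nm][:, m]
                else:
                    coords[:, ai] = base_global[:, m, name_to_col[nm]]
    return coords


def _realize(spec: DuplexSpec, step_arrays, pucker, times) -> Trajectory:
    topology = build_topology(spec.sequence)
    F = step_arrays["twist"].shape[0]
    bp_axes, bp_origins = _bp_frames_from_steps(step_arrays, F, spec.n_bp)
    coords = _build_residues(topology, bp_axes, bp_origins, pucker, spec.pucker_amplitude)
    return Trajectory(topology, coords, times)


def build_duplex(spec: DuplexSpec) -> DuplexConformation:
    """Build one idealized duplex conformation from a :class:`DuplexSpec`.

    Base-pair frames of the built structure reproduce the requested step
    parameters exactly when re-analyzed with :mod:`salt_twist.frames`; sugar
    ring torsions realize the requested pseudorotation phase.
    """
    steps = {k: getattr(spec, k)[None, :] for k in ("twist", "roll", "tilt", "shift", "slide", "rise")}
    traj = _realize(spec, steps, spec.pucker_P[None, :], np.zeros(1))
    return traj.frame(0)


def make_trajectory(spec: DuplexSpec, fluct: FluctuationSpec) -> Trajectory:
    """Fluctuating trajectory: spec means + independent Gaussian draws per frame."""
    rng = np.random.default_rng(fluct.seed)
    F, S = fluct.n_frames, spec.n_bp - 1
    steps = {}
    for name, sd in (
        ("twist", fluct.sd_twist), ("roll", fluct.sd_roll), ("tilt", fluct.sd_tilt),
        ("shift", fluct.sd_shift), ("slide", fluct.sd_slide), ("rise", fluct.sd_rise),
    ):
        steps[name] = getattr(spec, name)[None, :] + rng.normal(0.0, sd, size=(F, S))
    pucker = spec.pucker_P[None, :] + rng.normal(0.0, fluct.sd_pucker, size=(F, 2 * spec.n_bp))
    times = np.arange(F, dtype=float) * fluct.frame_dt
    return _realize(spec, steps, pucker, times)


# ---------------------------------------------------------------------------
# Condition ladder emulating the salt response
# ---------------------------------------------------------------------------

#: coupling of sugar pucker to twist (deg pucker per deg twist per bp step),
#: from a representative B-DNA covariation (P 147->157 with Tw 33.3->35.1)
K_PUCKER = 10.0 / 1.8
#: slide change per degree of step-twist change (A/deg); sign chosen so the
#: phosphate-to-axis radius decreases when twist increases, as in B-DNA
K_SLIDE = -0.35
#: intrinsic per-step roll of the relaxed condition (deg) and its decrease
#: with twist; gives a crooked low-salt helix that straightens at high salt
BASE_ROLL = 3.0
K_ROLL = -1.2
#: fractional reduction of bending-fluctuation sd per degree of step-twist
#: change: screened backbone repulsion straightens the helix, which is what
#: drives the crookedness decrease on long duplexes (bend contributions from
#: a small constant roll largely cancel over full helical turns)
K_BEND_SD = 0.30


def salt_condition(base: DuplexSpec, d_twist: float) -> DuplexSpec:
    """Duplex spec for a condition shifting mean step twist by ``d_twist`` deg.

    Emulates the coupled conformational response to increased cation
    screening: twist up, sugar pucker up, slide and intrinsic roll down.
    Pair with :func:`salt_condition_fluct` for the dynamic-bending part of
    the response.
    """
    return replace(
        base,
        twist=np.asarray(base.twist) + d_twist,
        slide=np.asarray(base.slide) + K_SLIDE * d_twist,
        roll=np.full_like(np.asarray(base.roll), BASE_ROLL + K_ROLL * d_twist),
        pucker_P=np.asarray(base.pucker_P) + K_PUCKER * d_twist,
    )


def salt_condition_fluct(base: FluctuationSpec, d_twist: float, seed: int | None = None) -> FluctuationSpec:
    """Fluctuation spec of a salt condition: bending noise shrinks with twist."""
    scale = max(1.0 - K_BEND_SD * d_twist, 0.1)
    return replace(
        base,
        sd_roll=base.sd_roll * scale,
        sd_tilt=base.sd_tilt * scale,
        seed=base.seed if seed is None else seed,
    )


# ---------------------------------------------------------------------------
# Ion clouds
# ---------------------------------------------------------------------------


def _axis_of(conf: DuplexConformation):
    """Straight helical axis through the terminal C1'-midpoints of the duplex."""
    top = conf.topology
    n = top.n_bp
    ends = []
    for bp in (1, n):
        ra, rb = top.paired_residues(bp)
        ends.append((conf.atom("A", ra, "C1'") + conf.atom("B", rb, "C1'")) / 2.0)
    p0, p1 = ends
    axis = np.asarray(p1) - np.asarray(p0)
    length = np.linalg.norm(axis)
    if length < 1e-9:
        raise ValueError("degenerate axis: duplex ends coincide")
    return np.asarray(p0), axis / length, length


def ion_density_profile(spec: IonCloudSpec, r: np.ndarray) -> np.ndarray:
    """Model molar density (mol/L) at axial distance r (A), clipped at zero."""
    bulk = spec.bulk_mM / 1000.0
    rho = bulk + spec.excess_molar * np.exp(
        -((np.asarray(r, float) - spec.preferred_radius_A) ** 2) / (2.0 * spec.decay_A**2)
    )
    return np.clip(rho, 0.0, None)


def expected_ion_count(spec: IonCloudSpec, conf: DuplexConformation) -> float:
    """Mean diffuse-ion count: integral of the density over the cylinder."""
    _, _, length = _axis_of(conf)
    L = length + 2.0 * spec.z_padding_A
    if spec.cylinder_radius_A <= 0 or L <= 0:
        raise ValueError("zero-volume sampling cylinder")
    r = np.linspace(0.0, spec.cylinder_radius_A, 2001)
    rho = ion_density_profile(spec, r)  # mol/L
    shell = 2.0 * np.pi * r * L  # A^2 per dr
    return float(np.trapezoid(rho * shell, r) * A3_TO_L * N_AVOGADRO)


def sample_ion_cloud(conf: DuplexConformation, spec: IonCloudSpec) -> IonFrames:
    """Sample one ion frame around a duplex conformation.

    Diffuse ions follow the radial density ``bulk + excess exp(-(r-r0)^2 /
    (2 decay^2))`` inside the bounding cylinder (count Poisson-distributed
    about the density integral); pinned ions sit at a fixed distance from
    randomly chosen phosphate oxygens (backbone) or N7/O6 atoms (base).
    """
    rng = np.random.default_rng(spec.seed)
    p0, axis_u, length = _axis_of(conf)
    L = length + 2.0 * spec.z_padding_A
    if spec.cylinder_radius_A <= 0 or L <= 0:
        raise ValueError("zero-volume sampling cylinder")
    # orthonormal frame around the axis
    trial = np.array([1.0, 0.0, 0.0])
    if abs(trial @ axis_u) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    e1 = unit(np.cross(axis_u, trial))
    e2 = np.cross(axis_u, e1)

    n_diffuse = int(rng.poisson(expected_ion_count(spec, conf)))
    positions = []
    if n_diffuse > 0:
        rgrid = np.linspace(0.0, spec.cylinder_radius_A, 4001)
        pdf = ion_density_profile(spec, rgrid) * rgrid
        cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2.0 * np.diff(rgrid))])
        if cdf[-1] <= 0:
            n_diffuse = 0
        else:
            cdf /= cdf[-1]
            u = rng.random(n_diffuse)
            rr = np.interp(u, cdf, rgrid)
            phi = rng.uniform(0.0, 2.0 * np.pi, n_diffuse)
            zz = rng.uniform(-spec.z_padding_A, length + spec.z_padding_A, n_diffuse)
            pos = (
                p0[None, :]
                + zz[:, None] * axis_u[None, :]
                + (rr * np.cos(phi))[:, None] * e1[None, :]
                + (rr * np.sin(phi))[:, None] * e2[None, :]
            )
            positions.append(pos)

    top = conf.topology
    for count, names in ((spec.n_bound_backbone, ("O1P", "O2P")), (spec.n_bound_base, ("N7", "O6"))):
        if count == 0:
            continue
        mask = top.select(names)
        sites = conf.coords[mask]
        if len(sites) == 0:
            raise ValueError(f"no {names} atoms available for pinned ions")
        chosen = sites[rng.integers(0, len(sites), count)]
        direction = rng.normal(size=(count, 3))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        positions.append(chosen + spec.pinned_distance_A * direction)

    coords = np.concatenate(positions) if positions else np.empty((0, 3))
    n = len(coords)
    return IonFrames(
        species=np.full(n, spec.species),
        valence=np.full(n, spec.valence, dtype=int),
        coords=coords[None],
    )


# ---------------------------------------------------------------------------
# Tweezers data
# ---------------------------------------------------------------------------


def rot_ext_model(spec: CurveSpec, turns: np.ndarray) -> np.ndarray:
    """Noise-free extension (um) of the cap+wings model at the given turns."""
    n = np.asarray(turns, dtype=float)
    dn = np.abs(n - spec.n_max)
    cap = spec.apex_extension - spec.cap_depth * (1.0 - np.exp(-((n - spec.n_max) ** 2) / (2.0 * spec.cap_width**2)))
    cap_at_b = spec.apex_extension - spec.cap_depth * (
        1.0 - np.exp(-(spec.buckling_offset**2) / (2.0 * spec.cap_width**2))
    )
    wing = cap_at_b + spec.wing_slope * (dn - spec.buckling_offset)
    return np.where(dn <= spec.buckling_offset, cap, wing)


def gen_rot_ext_curve(spec: CurveSpec) -> RotExtCurve:
    """Synthetic rotation-extension curve (Gaussian noise on the model)."""
    rng = np.random.default_rng(spec.seed)
    ext = rot_ext_model(spec, spec.turns)
    if spec.noise_sd > 0:
        ext = ext + rng.normal(0.0, spec.noise_sd, size=ext.shape)
    sd = np.full_like(ext, spec.noise_sd if spec.noise_sd > 0 else np.nan)
    return RotExtCurve(spec.turns.copy(), ext, sd if spec.noise_sd > 0 else None)


def gen_conc_series(
    A: float,
    B: float,
    C: float,
    concentrations_mM,
    noise_sd: float = 0.0,
    seed: int = 0,
    ion: str = "K",
    valence: int = 1,
) -> ConcSeries:
    """Twist-vs-concentration table following dTw = A c^B + C (+ noise).

    Reported per-point sigma equals ``noise_sd`` (unit sigma when noise-free,
    giving unweighted fits with zero residuals on exact data).
    """
    c = np.asarray(concentrations_mM, dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    dtw = A * np.power(c, B) + C
    if noise_sd > 0:
        dtw = dtw + rng.normal(0.0, noise_sd, size=c.shape)
    sigma = np.full_like(c, noise_sd if noise_sd > 0 else 1.0)
    return ConcSeries(c, dtw, sigma, ion=ion, valence=valence)
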